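import numpy as np
import pandas as pd
import pytest

from himseek import simulate as sim
from himseek.align import ReferenceIndex
from himseek.chimera import extract_chimeras
from himseek.io import write_fastq


@pytest.fixture(scope="session")
def mini_host():
    return sim.generate_host_genome(2, [30_000, 30_000], gene_density=0.4, seed=7)


@pytest.fixture(scope="session")
def mini_circles():
    return sim.generate_circles(6, n_with_him=4, seed=11)


@pytest.fixture(scope="session")
def mini_sim(tmp_path_factory, mini_host, mini_circles):
    """Small error-free cohort run through simulation and chimera detection.

    4 circles carry intact HIMs (conservative probability 0.85), 2 break
    only randomly; ~10 events per circle at 6x coverage.
    """
    events, genome = sim.simulate_integrations(
        mini_circles, mini_host, n_events_per_circle=10,
        conservative_prob_given_him=0.85, seed=23,
    )
    records = list(genome.scaffolds) + [(c.circle_id, c.seq) for c in mini_circles]
    r1, r2 = sim.simulate_reads(
        records, coverage=6.0, seed=29, error_rate=0.0, genome=genome
    )
    d = tmp_path_factory.mktemp("mini_sim")
    paths = [str(d / "R1.fastq"), str(d / "R2.fastq")]
    write_fastq(((r.read_id, r.comment, r.seq, r.qual) for r in r1), paths[0])
    write_fastq(((r.read_id, r.comment, r.seq, r.qual) for r in r2), paths[1])
    viral_index = ReferenceIndex(
        [(c.circle_id, c.seq) for c in mini_circles], circular=True
    )
    host_index = ReferenceIndex(mini_host.scaffolds, circular=False)
    chimeras = extract_chimeras(paths, viral_index, host_index)
    return {
        "host": mini_host,
        "circles": mini_circles,
        "events": events,
        "genome": genome,
        "reads": (r1, r2),
        "fastq": paths,
        "chimeras": chimeras,
    }


def junction_table(positions_by_side: dict[str, list[int]], circle_id: str) -> pd.DataFrame:
    """Minimal chimera table for breakpoint tests: junction positions only."""
    rows = [
        {"circle_id": circle_id, "viral_junction_pos": int(p), "junction_side": side}
        for side, positions in positions_by_side.items()
        for p in positions
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
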