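"""Forward simulator for bracovirus circle integration.

Produces a synthetic caterpillar host genome, a cohort of circular viral
segments (each opened at a WIM containing the tetramer AGCT, a subset
carrying a host integration motif), ground-truth integration events in two
break modes (conservative at the HIM with spacer deletion, or uniform
random with no deletion), three temporal waves, and 150 bp paired-end reads
with substitution errors.  Every stochastic operation takes an explicit
seed.

Circle coordinates are 1-based and inclusive, with position 1 fixed at the
first base of the WIM.  The HIM is laid out as

    ... [5-nt arm CTGGT] gap [8-nt arm TAAATTTC] spacer
        [8-nt arm GAAATTTA] gap [5-nt arm ACCAG] ...

with the 8-nt arms immediately bordering the deletable spacer.  On a
conservative event the deleted interval equals the spacer exactly and both
arm pairs are retained on the integrated copy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .io import from_bed_interval, revcomp, to_bed_interval, write_bed6

ARM8_UP = "TAAATTTC"
ARM8_DOWN = "GAAATTTA"  # revcomp(ARM8_UP)
ARM5_UP = "CTGGT"
ARM5_DOWN = "ACCAG"  # revcomp(ARM5_UP)
WIM_CORE = "AGCT"

WAVES = ("early", "mid", "late")
WAVE_TIME_RANGES = {"early": (0.0, 0.5), "mid": (0.5, 1.0), "late": (1.0, 2.0)}

# Random-break percentages printed for the 19 conservatively breaking
# circles (Fig 2B of the source study, 12%..62%); the simulator's default
# per-circle conservative probabilities are their complements.
RANDOM_BREAK_PCTS = (
    12, 13, 15, 17, 20, 22, 23, 26, 27, 29, 29, 29, 30, 30, 31, 31, 33, 39, 62,
)
DEFAULT_CONSERVATIVE_PROBS = tuple((100 - p) / 100.0 for p in RANDOM_BREAK_PCTS)
# 11 early / 5 mid / 3 late circles, matching the reported timing classes.
DEFAULT_WAVE_COUNTS = {"early": 11, "mid": 5, "late": 3}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class HIMAnnotation:
    arm8_up_span: Interval
    arm8_down_span: Interval
    arm5_up_span: Interval
    arm5_down_span: Interval
    spacer_span: Interval
    arm8_up_seq: str
    arm5_up_seq: str

    def shifted(self, delta: int, after: int) -> "HIMAnnotation":
        """Shift every coordinate > ``after`` by ``delta`` (deletions upstream)."""

        def sh(span: Interval) -> Interval:
            return tuple(p + delta if p > after else p for p in span)  # type: ignore

        return HIMAnnotation(
            sh(self.arm8_up_span), sh(self.arm8_down_span),
            sh(self.arm5_up_span), sh(self.arm5_down_span),
            sh(self.spacer_span), self.arm8_up_seq, self.arm5_up_seq,
        )


@dataclass(frozen=True)
class CircleRecord:
    circle_id: str
    seq: str
    wim_span: Interval
    him_truth: HIMAnnotation | None = None
    him_mutation: str = "none"

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def has_intact_him(self) -> bool:
        return self.him_truth is not None and self.him_mutation == "none"

    def validate(self) -> None:
        k0, k1 = self.wim_span
        if not (1 <= k0 <= k1 <= self.length):
            raise ValueError(f"{self.circle_id}: WIM span outside circle")
        if WIM_CORE not in self.seq[k0 - 1 : k1]:
            raise ValueError(f"{self.circle_id}: WIM lacks tetramer {WIM_CORE}")
        him = self.him_truth
        if him is not None:
            for span in (
                him.arm8_up_span, him.arm8_down_span, him.arm5_up_span,
                him.arm5_down_span, him.spacer_span,
            ):
                if not (1 <= span[0] <= span[1] <= self.length):
                    raise ValueError(f"{self.circle_id}: HIM span outside circle")
            if self.him_mutation == "none":
                up8 = self.seq[him.arm8_up_span[0] - 1 : him.arm8_up_span[1]]
                dn8 = self.seq[him.arm8_down_span[0] - 1 : him.arm8_down_span[1]]
                up5 = self.seq[him.arm5_up_span[0] - 1 : him.arm5_up_span[1]]
                dn5 = self.seq[him.arm5_down_span[0] - 1 : him.arm5_down_span[1]]
                if revcomp(up8) != dn8 or revcomp(up5) != dn5:
                    raise ValueError(f"{self.circle_id}: HIM arms not inverted repeats")


@dataclass(frozen=True)
class HostGenome:
    scaffolds: list[tuple[str, str]]
    genes: list[tuple[str, int, int, str]]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds}


@dataclass(frozen=True)
class IntegrationEvent:
    event_id: str
    circle_id: str
    mode: str  # conservative | random
    up_junction: int
    down_junction: int
    circle_len: int
    host_scaffold: str
    host_pos: int  # junction between host bases host_pos and host_pos+1
    orientation: str  # forward | reverse
    wave: str
    time_h: float

    @property
    def deleted_len(self) -> int:
        return (self.down_junction - self.up_junction - 1) % self.circle_len


@dataclass
class SimulatedGenome:
    """Host scaffolds after integration plus junction/segment truth maps.

    ``junctions[scaffold]`` lists ``(pos0, event_id)`` where ``pos0`` is the
    number of bases preceding the host/virus junction in the rewritten
    scaffold; ``viral_segments[scaffold]`` lists 0-based half-open spans of
    integrated viral copies.
    """

    scaffolds: list[tuple[str, str]]
    junctions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    viral_segments: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_host_genome(
    n_scaffolds: int,
    scaffold_lengths: list[int],
    gene_density: float,
    seed: int,
    mean_gene_len: int = 1500,
) -> HostGenome:
    """Uniform-composition host genome with non-overlapping gene intervals.

    Genes are tiled along each scaffold with exponential-ish lengths so the
    genic fraction approximates ``gene_density``.
    """
    if n_scaffolds < 0:
        raise ValueError("n_scaffolds must be >= 0")
    if n_scaffolds and len(scaffold_lengths) != n_scaffolds:
        raise ValueError("scaffold_lengths must match n_scaffolds")
    if any(l < 1000 for l in scaffold_lengths[:n_scaffolds]):
        raise ValueError("scaffold lengths must be >= 1 kb")
    if not 0.0 <= gene_density <= 1.0:
        raise ValueError("gene_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scaffolds = []
    genes: list[tuple[str, int, int, str]] = []
    for i in range(n_scaffolds):
        name = f"scaffold_{i + 1}"
        length = scaffold_lengths[i]
        scaffolds.append((name, _random_dna(rng, length)))
        if gene_density == 0:
            continue
        pos = 1 + int(rng.integers(0, mean_gene_len))
        while pos < length:
            gene_len = int(rng.integers(mean_gene_len // 2, mean_gene_len * 3 // 2 + 1))
            end = min(pos + gene_len - 1, length)
            genes.append((name, pos, end, "+" if rng.random() < 0.5 else "-"))
            gap = max(1, int(round(gene_len * (1 - gene_density) / max(gene_density, 1e-9))))
            gap = int(rng.integers(max(1, gap // 2), gap * 3 // 2 + 1))
            pos = end + 1 + gap
    return HostGenome(scaffolds=scaffolds, genes=genes)


def generate_circles(
    n_circles: int,
    length_range: tuple[int, int] = (700, 1500),
    n_with_him: int = 19,
    spacer_len_range: tuple[int, int] = (39, 72),
    seed: int = 0,
    him_offset_range: tuple[int, int] = (120, 470),
    arm_gap_range: tuple[int, int] = (4, 8),
) -> list[CircleRecord]:
    """Cohort of circular segments; the first ``n_with_him`` carry intact HIMs."""
    if n_with_him > n_circles:
        raise ValueError("n_with_him cannot exceed n_circles")
    if length_range[0] < 500:
        raise ValueError("circle lengths must be >= 500")
    him_footprint = 2 * (len(ARM5_UP) + arm_gap_range[1] + len(ARM8_UP))
    if spacer_len_range[1] + him_footprint + him_offset_range[0] + 50 > length_range[0]:
        raise ValueError("spacer/HIM layout does not fit the smallest circle")
    rng = np.random.default_rng(seed)
    circles: list[CircleRecord] = []
    for i in range(n_circles):
        circle_id = f"circle_{i + 1:02d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        wim_len = int(rng.integers(8, 13))
        wim_offset = int(rng.integers(0, wim_len - len(WIM_CORE) + 1))
        wim = (
            _random_dna(rng, wim_offset)
            + WIM_CORE
            + _random_dna(rng, wim_len - wim_offset - len(WIM_CORE))
        )
        seq = list(wim + _random_dna(rng, length - wim_len))
        him = None
        if i < n_with_him:
            spacer_len = int(rng.integers(spacer_len_range[0], spacer_len_range[1] + 1))
            gap = int(rng.integers(arm_gap_range[0], arm_gap_range[1] + 1))
            motif_len = 2 * (len(ARM5_UP) + gap + len(ARM8_UP)) + spacer_len
            max_offset = min(him_offset_range[1], length - motif_len - 30)
            offset = int(rng.integers(him_offset_range[0], max_offset + 1))
            # offset = 1-based start of the upstream 5-nt arm
            motif = (
                ARM5_UP + _random_dna(rng, gap) + ARM8_UP
                + _random_dna(rng, spacer_len)
                + ARM8_DOWN + _random_dna(rng, gap) + ARM5_DOWN
            )
            seq[offset - 1 : offset - 1 + motif_len] = list(motif)
            a5u = (offset, offset + 4)
            a8u = (a5u[1] + gap + 1, a5u[1] + gap + 8)
            spacer = (a8u[1] + 1, a8u[1] + spacer_len)
            a8d = (spacer[1] + 1, spacer[1] + 8)
            a5d = (a8d[1] + gap + 1, a8d[1] + gap + 5)
            him = HIMAnnotation(
                arm8_up_span=a8u, arm8_down_span=a8d,
                arm5_up_span=a5u, arm5_down_span=a5d,
                spacer_span=spacer, arm8_up_seq=ARM8_UP, arm5_up_seq=ARM5_UP,
            )
        record = CircleRecord(
            circle_id=circle_id, seq="".join(seq), wim_span=(1, wim_len),
            him_truth=him,
        )
        record.validate()
        circles.append(record)
    return circles


def mutate_him(circle: CircleRecord, mutation: str) -> CircleRecord:
    """Apply an arm mutation (M1: TTTC of the upstream 8-nt arm deleted;
    M2: upstream 5-nt arm deleted; M3: both), shifting coordinates."""
    if mutation not in ("M1_del_TTTC", "M2_del_CTGGT", "M3_both"):
        raise ValueError(f"unknown mutation {mutation!r}")
    if circle.him_truth is None:
        raise ValueError(f"{circle.circle_id} has no HIM to mutate")
    him = circle.him_truth
    deletions: list[Interval] = []
    if mutation in ("M1_del_TTTC", "M3_both"):
        # last four bases of the upstream 8-nt arm (TAAATTTC -> TAAA)
        deletions.append((him.arm8_up_span[1] - 3, him.arm8_up_span[1]))
    if mutation in ("M2_del_CTGGT", "M3_both"):
        deletions.append(him.arm5_up_span)
    seq = circle.seq
    for start, end in sorted(deletions, reverse=True):
        seq = seq[: start - 1] + seq[end:]
        him = him.shifted(-(end - start + 1), after=end)
    return replace(
        circle, seq=seq, him_truth=him,
        him_mutation={"M1_del_TTTC": "M1_del_TTTC",
                      "M2_del_CTGGT": "M2_del_CTGGT",
                      "M3_both": "M3_both"}[mutation],
    )


# ---------------------------------------------------------------------------
# integration events
# ---------------------------------------------------------------------------

def draw_event(
    circle: CircleRecord,
    mode: str,
    host: HostGenome,
    rng: np.random.Generator,
    event_id: str,
    wave: str,
    intergenic_bias: float | None = None,
) -> IntegrationEvent:
    """One integration event; conservative mode demands an intact HIM."""
    if mode == "conservative":
        if not circle.has_intact_him:
            raise ValueError(
                f"conservative break requested for {circle.circle_id} "
                f"without an intact HIM (mutation={circle.him_mutation})"
            )
        spacer = circle.him_truth.spacer_span
        up, down = spacer[0] - 1, spacer[1] + 1
    elif mode == "random":
        up = int(rng.integers(1, circle.length + 1))
        down = up % circle.length + 1
    else:
        raise ValueError(f"unknown break mode {mode!r}")
    scaffold_idx = int(rng.integers(0, len(host.scaffolds)))
    name, seq = host.scaffolds[scaffold_idx]
    if intergenic_bias is not None and rng.random() < intergenic_bias:
        host_pos = _sample_intergenic(host, name, rng)
    else:
        host_pos = int(rng.integers(1, len(seq)))
    t0, t1 = WAVE_TIME_RANGES[wave]
    return IntegrationEvent(
        event_id=event_id, circle_id=circle.circle_id, mode=mode,
        up_junction=up, down_junction=down, circle_len=circle.length,
        host_scaffold=name, host_pos=host_pos,
        orientation="forward" if rng.random() < 0.5 else "reverse",
        wave=wave, time_h=float(rng.uniform(t0, t1)),
    )


def _sample_intergenic(host: HostGenome, scaffold: str, rng: np.random.Generator) -> int:
    length = dict(host.scaffold_lengths)[scaffold]
    genic = sorted(
        (s, e) for sc, s, e, _ in host.genes if sc == scaffold
    )
    for _ in range(200):
        pos = int(rng.integers(1, length))
        if not any(s <= pos <= e for s, e in genic):
            return pos
    return int(rng.integers(1, length))  # fully genic scaffold fallback


def linearized_copy(circle: CircleRecord, event: IntegrationEvent) -> str:
    """Sequence of the integrated copy: down_junction around to up_junction."""
    seq, up, down = circle.seq, event.up_junction, event.down_junction
    if down > up:
        copy = seq[down - 1 :] + seq[:up]
    else:
        copy = seq[down - 1 : up]
    if event.orientation == "reverse":
        copy = revcomp(copy)
    return copy


def default_wave_assignment(circles: Iterable[CircleRecord]) -> dict[str, str]:
    """11 early / 5 mid / 3 late for intact-HIM circles (cycled if more),
    'early' for the rest."""
    order = [w for w in WAVES for _ in range(DEFAULT_WAVE_COUNTS[w])]
    assignment = {}
    i = 0
    for c in circles:
        if c.has_intact_him:
            assignment[c.circle_id] = order[i % len(order)]
            i += 1
        else:
            assignment[c.circle_id] = "early"
    return assignment


def simulate_integrations(
    circles: list[CircleRecord],
    host: HostGenome,
    n_events_per_circle: dict[str, int] | int,
    conservative_prob_given_him: dict[str, float] | float,
    seed: int,
    wave_assignment: dict[str, str] | None = None,
    intergenic_bias: dict[str, float] | None = None,
) -> tuple[list[IntegrationEvent], SimulatedGenome]:
    """Draw integration events and splice linearized copies into the host.

    Circles with an intact HIM draw each event conservative with the given
    probability; HIM-less or HIM-mutated circles only ever break randomly.
    """
    rng = np.random.default_rng(seed)
    if wave_assignment is None:
        wave_assignment = default_wave_assignment(circles)
    events: list[IntegrationEvent] = []
    counter = 0
    for circle in circles:
        n = (
            n_events_per_circle
            if isinstance(n_events_per_circle, int)
            else n_events_per_circle.get(circle.circle_id, 0)
        )
        p = (
            conservative_prob_given_him
            if isinstance(conservative_prob_given_him, (int, float))
            else conservative_prob_given_him.get(circle.circle_id, 0.0)
        )
        if not 0.0 <= float(p) <= 1.0:
            raise ValueError("conservative probability must be in [0, 1]")
        bias = None if intergenic_bias is None else intergenic_bias.get(circle.circle_id)
        for _ in range(n):
            mode = (
                "conservative"
                if circle.has_intact_him and rng.random() < float(p)
                else "random"
            )
            counter += 1
            events.append(
                draw_event(
                    circle, mode, host, rng, f"ev{counter:05d}",
                    wave_assignment[circle.circle_id], intergenic_bias=bias,
                )
            )
    genome = _apply_events(circles, host, events)
    return events, genome


def _apply_events(
    circles: list[CircleRecord], host: HostGenome, events: list[IntegrationEvent]
) -> SimulatedGenome:
    by_circle = {c.circle_id: c for c in circles}
    by_scaffold: dict[str, list[IntegrationEvent]] = {}
    for ev in events:
        by_scaffold.setdefault(ev.host_scaffold, []).append(ev)
    out = SimulatedGenome(scaffolds=[])
    for name, seq in host.scaffolds:
        evs = sorted(by_scaffold.get(name, []), key=lambda e: (e.host_pos, e.event_id))
        parts: list[str] = []
        junctions: list[tuple[int, str]] = []
        segments: list[tuple[int, int, str]] = []
        cursor = 0  # 0-based position in the original scaffold
        new_len = 0
        for ev in evs:
            host_chunk = seq[cursor : ev.host_pos]
            parts.append(host_chunk)
            new_len += len(host_chunk)
            copy = linearized_copy(by_circle[ev.circle_id], ev)
            junctions.append((new_len, ev.event_id))
            parts.append(copy)
            segments.append((new_len, new_len + len(copy), ev.event_id))
            new_len += len(copy)
            junctions.append((new_len, ev.event_id))
            cursor = ev.host_pos
        parts.append(seq[cursor:])
        out.scaffolds.append((name, "".join(parts)))
        out.junctions[name] = junctions
        out.viral_segments[name] = segments
    return out


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def events_to_bed(events: list[IntegrationEvent], path: str) -> None:
    """Truth events as BED6 on the *original* host coordinates.

    The interval is the single host base immediately following the insertion
    junction (0-based half-open); name = ``circle_id|mode``; score = deleted
    length; strand reflects copy orientation.
    """
    rows = []
    for ev in events:
        start0, end0 = to_bed_interval(ev.host_pos + 1, ev.host_pos + 1)
        rows.append(
            (
                ev.host_scaffold, start0, end0, f"{ev.circle_id}|{ev.mode}",
                float(ev.deleted_len), "+" if ev.orientation == "forward" else "-",
            )
        )
    write_bed6(rows, path)


def events_to_json(events: list[IntegrationEvent], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([ev.__dict__ for ev in events], fh, indent=1, sort_keys=True)
        fh.write("\n")


def events_from_json(path: str) -> list[IntegrationEvent]:
    with open(path) as fh:
        return [IntegrationEvent(**d) for d in json.load(fh)]


def events_from_bed(path: str) -> list[tuple[str, int, str, str, int, str]]:
    """Parse the truth BED back to (scaffold, host_pos, circle_id, mode,
    deleted_len, orientation)."""
    from .io import read_bed6

    out = []
    for chrom, start0, end0, name, score, strand in read_bed6(path):
        start1, _ = from_bed_interval(start0, end0)
        circle_id, mode = name.split("|")
        out.append(
            (
                chrom, start1 - 1, circle_id, mode, int(score),
                "forward" if strand == "+" else "reverse",
            )
        )
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    comment: str
    seq: str
    qual: str


def _provenance(
    start0: int,
    end0: int,
    junctions: np.ndarray,
    junction_ids: list[str],
    segments: list[tuple[int, int, str]],
) -> str:
    """Truth tag for a read interval on a rewritten scaffold."""
    lo = int(np.searchsorted(junctions, start0, side="right"))
    hi = int(np.searchsorted(junctions, end0, side="left"))
    inside = [(int(junctions[i]), junction_ids[i]) for i in range(lo, hi)]
    if inside:
        evs = ",".join(ev for _, ev in inside)
        offs = ",".join(str(pos - start0) for pos, _ in inside)
        return f"src:chimeric;ev={evs};joff={offs}"
    for seg_start, seg_end, _ in segments:
        if start0 >= seg_start and end0 <= seg_end:
            return "src:viral-only"
    return "src:host-only"


def simulate_reads(
    records: list[tuple[str, str]],
    coverage: float,
    seed: int,
    read_len: int = 150,
    fragment_len: int | None = None,
    error_rate: float = 0.0,
    genome: SimulatedGenome | None = None,
) -> tuple[list[SimulatedRead], list[SimulatedRead]]:
    """Paired-end reads by uniform fragment sampling.

    ``genome`` (when the records come from :func:`simulate_integrations`)
    supplies the junction map used to write truth provenance tags; records
    absent from it are tagged viral-only (episomal circles) .
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if fragment_len is None:
        fragment_len = 2 * read_len
    if read_len > fragment_len:
        raise ValueError("read_len exceeds fragment length")
    rng = np.random.default_rng(seed)
    qual_char = (
        "I" if error_rate <= 0
        else chr(33 + max(2, min(40, int(round(-10 * np.log10(error_rate))))))
    )
    r1: list[SimulatedRead] = []
    r2: list[SimulatedRead] = []
    counter = 0
    for name, seq in records:
        if len(seq) < fragment_len:
            continue
        n_pairs = int(round(coverage * len(seq) / (2 * read_len)))
        if n_pairs == 0:
            continue
        junctions = np.array([], dtype=np.int64)
        junction_ids: list[str] = []
        segments: list[tuple[int, int, str]] = []
        if genome is not None and name in genome.junctions:
            juncs = genome.junctions[name]
            junctions = np.array([p for p, _ in juncs], dtype=np.int64)
            junction_ids = [e for _, e in juncs]
            segments = genome.viral_segments[name]
        elif genome is None or name not in {n for n, _ in genome.scaffolds}:
            segments = [(0, len(seq), "episome")]
        starts = rng.integers(0, len(seq) - fragment_len + 1, size=n_pairs)
        for s in np.sort(starts):
            s = int(s)
            counter += 1
            frag = seq[s : s + fragment_len]
            fwd = frag[:read_len]
            rev = revcomp(frag[-read_len:])
            tag1 = _provenance(s, s + read_len, junctions, junction_ids, segments)
            tag2 = _provenance(
                s + fragment_len - read_len, s + fragment_len,
                junctions, junction_ids, segments,
            )
            rid = f"{name}_frag{counter:07d}"
            r1.append(
                SimulatedRead(rid + "/1", tag1, _with_errors(fwd, error_rate, rng), qual_char * read_len)
            )
            r2.append(
                SimulatedRead(rid + "/2", tag2, _with_errors(rev, error_rate, rng), qual_char * read_len)
            )
    return r1, r2


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def parse_provenance(comment: str) -> tuple[str, list[str], list[int]]:
    """Invert the FASTQ truth tag -> (kind, event_ids, junction_offsets)."""
    fields = dict(
        part.split(":", 1) if ":" in part else part.split("=", 1)
        for part in comment.split(";")
    )
    kind = fields.get("src", "unknown")
    evs = fields.get("ev", "")
    offs = fields.get("joff", "")
    return (
        kind,
        evs.split(",") if evs else [],
        [int(x) for x in offs.split(",")] if offs else [],
    )
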