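"""Host-side insertion landscape: genic preference, window tracks, flank motifs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import from_bed_interval, revcomp, to_bed_interval

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_FLANK = 20
DEFAULT_MERGE_TOL = 3
PREFERENCE_MARGIN = 0.1  # |genic fraction - background| needed to call a preference


@dataclass(frozen=True)
class InsertionSite:
    scaffold: str
    pos: int  # 1-based host junction coordinate
    circle_id: str
    annotation: str  # genic | intergenic
    supporting_reads: int


@dataclass(frozen=True)
class WindowTrack:
    window_size: int
    counts: dict[str, np.ndarray]  # scaffold -> per-window insertion-event counts

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def _merged_gene_arrays(
    genes: list[tuple[str, int, int, str]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end, _ in genes:
        by_scaffold.setdefault(scaffold, []).append((start, end))
    out = {}
    for scaffold, ivls in by_scaffold.items():
        ivls.sort()
        merged: list[list[int]] = []
        for s, e in ivls:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        out[scaffold] = (arr[:, 0], arr[:, 1])
    return out


def genic_fraction_of_genome(
    genes: list[tuple[str, int, int, str]], scaffold_lengths: dict[str, int]
) -> float:
    merged = _merged_gene_arrays(genes)
    genic = sum(int((e - s + 1).sum()) for s, e in merged.values())
    total = sum(scaffold_lengths.values())
    return genic / total if total else 0.0


def annotate_sites(
    chimeras: pd.DataFrame,
    genes: list[tuple[str, int, int, str]],
    scaffold_lengths: dict[str, int],
    merge_tol: int = DEFAULT_MERGE_TOL,
) -> tuple[list[InsertionSite], pd.DataFrame]:
    """Collapse chimeras into insertion sites and annotate genic/intergenic.

    Chimeras from the same circle landing within ``merge_tol`` on one
    scaffold are merged into a single site with summed support.  The
    returned table holds per-circle genic fractions next to the genome
    background fraction.
    """
    known = set(scaffold_lengths)
    bad = sorted(set(chimeras["host_scaffold"]) - known) if not chimeras.empty else []
    if bad:
        raise ValueError(f"chimera table names unknown scaffolds: {bad}")
    merged_genes = _merged_gene_arrays(genes)
    sites: list[InsertionSite] = []
    if not chimeras.empty:
        grouped = chimeras.sort_values("host_junction_pos").groupby(
            ["host_scaffold", "circle_id"], sort=True
        )
        for (scaffold, circle_id), sub in grouped:
            cluster_pos: list[int] = []
            counts: list[int] = []
            for pos in sub["host_junction_pos"].astype(int):
                if cluster_pos and pos - cluster_pos[-1] <= merge_tol:
                    counts[-1] += 1
                else:
                    cluster_pos.append(pos)
                    counts.append(1)
            for pos, n in zip(cluster_pos, counts):
                if not 1 <= pos <= scaffold_lengths[scaffold]:
                    raise ValueError(f"site {scaffold}:{pos} outside scaffold")
                genic = False
                if scaffold in merged_genes:
                    starts, ends = merged_genes[scaffold]
                    i = int(np.searchsorted(starts, pos, side="right")) - 1
                    genic = i >= 0 and pos <= ends[i]
                sites.append(
                    InsertionSite(
                        scaffold, pos, circle_id,
                        "genic" if genic else "intergenic", n,
                    )
                )
    background = genic_fraction_of_genome(genes, scaffold_lengths)
    rows = []
    by_circle: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_circle.setdefault(s.circle_id, []).append(s)
    for circle_id in sorted(by_circle):
        circle_sites = by_circle[circle_id]
        genic_frac = sum(s.annotation == "genic" for s in circle_sites) / len(circle_sites)
        if genic_frac < background - PREFERENCE_MARGIN:
            pref = "intergenic"
        elif genic_frac > background + PREFERENCE_MARGIN:
            pref = "genic"
        else:
            pref = "none"
        rows.append(
            {
                "circle_id": circle_id,
                "n_sites": len(circle_sites),
                "genic_fraction": genic_frac,
                "background_genic_fraction": background,
                "preference": pref,
            }
        )
    return sites, pd.DataFrame(rows)


def window_counts(
    sites: list[InsertionSite],
    scaffold_lengths: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> WindowTrack:
    """Insertion-event counts in half-open windows [0,w), [w,2w), ...; the
    last partial window is kept."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    counts = {
        name: np.zeros(max(1, -(-length // window_size)), dtype=np.int64)
        for name, length in scaffold_lengths.items()
    }
    for s in sites:
        counts[s.scaffold][(s.pos - 1) // window_size] += 1
    return WindowTrack(window_size=window_size, counts=counts)


def track_to_bedgraph_rows(
    track: WindowTrack, scaffold_lengths: dict[str, int]
) -> list[tuple[str, int, int, float]]:
    rows = []
    for name, arr in sorted(track.counts.items()):
        length = scaffold_lengths[name]
        for i, n in enumerate(arr):
            start0 = i * track.window_size
            end0 = min((i + 1) * track.window_size, length)
            rows.append((name, start0, end0, float(n)))
    return rows


def flank_motif_scan(
    sites: list[InsertionSite],
    scaffolds: dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> tuple[float, pd.DataFrame]:
    """Shannon information content of host flanks around insertion sites.

    Flanks of ``2*flank + 1`` bases centered on each site are stacked;
    sites too close to a scaffold edge are truncated out of the stack (they
    cannot be aligned).  Returns the maximum per-column information (bits,
    0..2) and the position-frequency matrix.
    """
    flanks = []
    for s in sites:
        seq = scaffolds[s.scaffold]
        lo, hi = s.pos - 1 - flank, s.pos + flank
        if lo < 0 or hi > len(seq):
            continue  # edge-truncated flank, flagged by omission
        flanks.append(seq[lo:hi])
    if not flanks:
        return 0.0, pd.DataFrame(index=["A", "C", "G", "T"])
    arr = np.array([list(f.upper()) for f in flanks])
    bases = ["A", "C", "G", "T"]
    freqs = np.stack([(arr == b).mean(axis=0) for b in bases])
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    ic = 2.0 + (freqs * logs).sum(axis=0)
    pfm = pd.DataFrame(freqs, index=bases)
    return float(ic.max()), pfm


def sites_to_bed(sites: list[InsertionSite], path: str) -> None:
    from .io import write_bed6

    rows = []
    for s in sites:
        start0, end0 = to_bed_interval(s.pos, s.pos)
        rows.append((s.scaffold, start0, end0, s.circle_id, float(s.supporting_reads), "+"))
    write_bed6(rows, path)


def sites_from_bed(path: str) -> list[tuple[str, int, str, int]]:
    from .io import read_bed6

    out = []
    for chrom, start0, end0, name, score, _ in read_bed6(path):
        pos, _ = from_bed_interval(start0, end0)
        out.append((chrom, pos, name, int(score)))
    return out
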