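"""Per-circle break-site profiles and CBC/RBC classification.

Junction tallies are kept separately for the two junction classes a
linearized copy produces: "end"-side junctions (viral segment ends at the
junction; these cluster at the upstream boundary U of a conservative
break) and "start"-side junctions (viral segment starts there; downstream
boundary D).  A circle whose modal junction pair captures at least the
classification threshold of all its chimeras is a Conservative-Broken
Circle (CBC); otherwise it is Random-Broken (RBC).  Membership in either
modal cluster counts as "the same site": one conservative event necessarily
creates both junction classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_CLUSTER_TOL = 3
DEFAULT_CBC_THRESHOLD = 0.35
DEFAULT_MIN_SUPPORT = 20


@dataclass(frozen=True)
class BreakSiteProfile:
    circle_id: str
    circle_len: int
    left_counts: dict[int, int]  # "end"-side junction tallies (U class)
    right_counts: dict[int, int]  # "start"-side junction tallies (D class)
    n_chimeras: int
    modal_pair: tuple[int, int] | None  # (U, D)
    conserved_count: int
    conserved_fraction: float


@dataclass(frozen=True)
class CircleClassification:
    circle_id: str
    label: str | None  # CBC | RBC | None when support is insufficient
    status: str  # ok | insufficient_support
    conserved_fraction: float
    random_fraction: float
    support: int


def _modal_cluster(
    counts: dict[int, int], tol: int, circle_len: int
) -> tuple[int | None, int]:
    """Highest-count window of width 2*tol+1 (circular).

    Ties are broken toward the center with the most direct hits, then the
    lowest position, so a stray junction one base off cannot displace the
    dominant site.  Returns (center position, window count)."""
    if not counts:
        return None, 0
    best = None  # (window count, direct count, -position)
    best_pos = None
    for center in sorted(counts):
        n = 0
        for delta in range(-tol, tol + 1):
            pos = (center - 1 + delta) % circle_len + 1
            n += counts.get(pos, 0)
        key = (n, counts[center], -center)
        if best is None or key > best:
            best, best_pos = key, center
    return best_pos, best[0]


def _window_count(counts: dict[int, int], center: int, tol: int, circle_len: int) -> int:
    return sum(
        counts.get((center - 1 + d) % circle_len + 1, 0) for d in range(-tol, tol + 1)
    )


def build_profile(
    chimeras: pd.DataFrame,
    circle_id: str,
    circle_len: int,
    cluster_tol: int = DEFAULT_CLUSTER_TOL,
) -> BreakSiteProfile:
    """Tally viral-side junctions of one circle and find the modal pair.

    ``chimeras`` needs columns ``circle_id``, ``viral_junction_pos`` and
    ``junction_side``; rows for other circles are rejected.
    """
    if not chimeras.empty:
        sub = chimeras[chimeras["circle_id"] == circle_id]
        if len(sub) != len(chimeras):
            raise ValueError("build_profile expects chimeras of a single circle")
    else:
        sub = chimeras
    left: dict[int, int] = {}
    right: dict[int, int] = {}
    for row in sub.itertuples(index=False):
        target = left if row.junction_side == "end" else right
        pos = int(row.viral_junction_pos)
        target[pos] = target.get(pos, 0) + 1
    n = len(sub)
    u_pos, u_count = _modal_cluster(left, cluster_tol, circle_len)
    d_pos, d_count = _modal_cluster(right, cluster_tol, circle_len)
    modal_pair = (u_pos, d_pos) if (u_pos is not None and d_pos is not None) else None
    conserved = u_count + d_count if n else 0
    return BreakSiteProfile(
        circle_id=circle_id,
        circle_len=circle_len,
        left_counts=left,
        right_counts=right,
        n_chimeras=n,
        modal_pair=modal_pair,
        conserved_count=conserved,
        conserved_fraction=conserved / n if n else 0.0,
    )


def classify_circle(
    profile: BreakSiteProfile,
    threshold: float = DEFAULT_CBC_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> CircleClassification:
    """CBC iff the conserved fraction reaches ``threshold`` with enough reads."""
    frac = profile.conserved_fraction
    if profile.n_chimeras < min_support:
        return CircleClassification(
            profile.circle_id, None, "insufficient_support", frac, 1 - frac,
            profile.n_chimeras,
        )
    label = "CBC" if frac >= threshold else "RBC"
    return CircleClassification(
        profile.circle_id, label, "ok", frac, 1 - frac, profile.n_chimeras
    )


def random_fraction_report(
    classifications: list[CircleClassification],
) -> pd.DataFrame:
    """Per-circle random-break percentages, sorted by circle id (the
    Fig 2B-style table)."""
    rows = [
        {
            "circle_id": c.circle_id,
            "label": c.label if c.label else "NA",
            "status": c.status,
            "conserved_fraction": c.conserved_fraction,
            "random_fraction": c.random_fraction,
            "random_pct": 100.0 * c.random_fraction,
            "support": c.support,
        }
        for c in classifications
    ]
    return pd.DataFrame(rows).sort_values("circle_id").reset_index(drop=True)


def partition_summary(cbc_reads: int, rbc_reads: int) -> dict[str, float]:
    """Chimeric-read partition between CBCs and RBCs.

    Returns the total and each class's percentage share."""
    total = cbc_reads + rbc_reads
    if total <= 0:
        raise ValueError("no reads to partition")
    return {
        "total": float(total),
        "cbc_share_pct": 100.0 * cbc_reads / total,
        "rbc_share_pct": 100.0 * rbc_reads / total,
    }
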