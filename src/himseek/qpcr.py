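"""The qPCR-derived integration index and its temporal classification.

The integration index of a circle at time t is

    index(t) = (1 - 2^-ddCT(t)) * 100 %

with dCT = CT(HIM amplicon) - CT(WIM amplicon) and ddCT(t) = dCT(t) -
dCT(0 h).  The WIM amplicon (present on every copy, integrated or not)
acts as internal control; the HIM amplicon is destroyed by a conservative
integration, so the index estimates the fraction of a circle's copies
disrupted at their HIM.  Circles are classed by onset time: EIC (<= 0.5 h),
MIC (<= 1 h), LIC (<= 2 h).

A CT-value simulator (the inverse model of the readout) makes the
statistic testable without instruments: a truly disrupted fraction f
raises CT(HIM) by -log_{1+E}(1 - f) cycles at amplification efficiency E,
so at E = 1 and zero noise the index round-trips to exactly 100 f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TIMEPOINTS_H = (0.0, 0.5, 1.0, 2.0, 4.0)
DEFAULT_ONSET_THRESHOLD_PCT = 25.0
DEFAULT_BINS_H = (0.5, 1.0)
DEFAULT_NOISE_SD = 0.15
DEFAULT_REPLICATES = 3

CT_COLUMNS = ["circle_id", "timepoint_h", "replicate", "ct_him", "ct_wim"]


@dataclass(frozen=True)
class IntegrationIndexSeries:
    circle_id: str
    timepoints_h: tuple[float, ...]
    delta_ct: tuple[float, ...]
    delta_delta_ct: tuple[float, ...]
    index_pct: tuple[float, ...]  # replicate-mean index, 0 at baseline
    index_sd: tuple[float, ...]
    below_baseline: tuple[bool, ...]
    timing_class: str = "unclassified"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "circle_id": self.circle_id,
                "timepoint_h": self.timepoints_h,
                "delta_ct": self.delta_ct,
                "delta_delta_ct": self.delta_delta_ct,
                "index_pct": self.index_pct,
                "index_sd": self.index_sd,
                "below_baseline": self.below_baseline,
                "timing_class": self.timing_class,
            }
        )


def _validate_ct(measurements: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"CT table lacks columns {missing}")
    for col in ("ct_him", "ct_wim"):
        vals = measurements[col]
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col} outside the plausible (0, 45) cycle range")


def compute_index(measurements: pd.DataFrame) -> IntegrationIndexSeries:
    """Integration-index series for one circle across timepoints.

    The per-timepoint mean dCT is referenced to the 0 h baseline, so the
    baseline index is exactly 0; the replicate sd is propagated through the
    same transform.  Negative indices (ddCT < 0) are reported as-is with a
    below-baseline flag.
    """
    _validate_ct(measurements)
    circle_ids = measurements["circle_id"].unique()
    if len(circle_ids) != 1:
        raise ValueError("compute_index expects measurements of a single circle")
    circle_id = circle_ids[0]
    df = measurements.copy()
    df["delta_ct"] = df["ct_him"] - df["ct_wim"]
    if not (df["timepoint_h"] == 0.0).any():
        raise ValueError(f"{circle_id}: no 0 h baseline measurement")
    n_reps = df.groupby("timepoint_h")["replicate"].nunique()
    if (n_reps < 3).any():
        warnings.warn(
            f"{circle_id}: fewer than 3 replicates at some timepoints; "
            "summary statistics will be unstable",
            stacklevel=2,
        )
    baseline = df.loc[df["timepoint_h"] == 0.0, "delta_ct"].mean()
    times, dcts, ddcts, idx_means, idx_sds, below = [], [], [], [], [], []
    for t, sub in df.groupby("timepoint_h", sort=True):
        dct = sub["delta_ct"].mean()
        ddct = 0.0 if t == 0.0 else dct - baseline
        rep_idx = (1.0 - np.power(2.0, -(sub["delta_ct"] - baseline))) * 100.0
        times.append(float(t))
        dcts.append(float(dct))
        ddcts.append(float(ddct))
        idx_means.append(float((1.0 - 2.0 ** -ddct) * 100.0))
        idx_sds.append(float(rep_idx.std(ddof=1)) if len(sub) > 1 else 0.0)
        below.append(bool(ddct < 0))
    return IntegrationIndexSeries(
        circle_id=circle_id,
        timepoints_h=tuple(times),
        delta_ct=tuple(dcts),
        delta_delta_ct=tuple(ddcts),
        index_pct=tuple(idx_means),
        index_sd=tuple(idx_sds),
        below_baseline=tuple(below),
    )


def classify_timing(
    series: IntegrationIndexSeries,
    onset_threshold_pct: float = DEFAULT_ONSET_THRESHOLD_PCT,
    bins_h: tuple[float, float] = DEFAULT_BINS_H,
) -> str:
    """Onset-based timing class: EIC / MIC / LIC / unclassified.

    The onset is the earliest timepoint whose mean index reaches the
    threshold without falling back below it (minus one replicate sd of
    tolerance) at any later timepoint; a transient noise crossing is
    thereby rejected while plateau jitter is not.
    """
    t = np.asarray(series.timepoints_h)
    idx = np.asarray(series.index_pct)
    sd = np.asarray(series.index_sd)
    onset = None
    for i in range(len(t)):
        if idx[i] < onset_threshold_pct:
            continue
        later = idx[i + 1 :]
        tol = np.maximum(sd[i + 1 :], 1e-9)
        if np.all(later >= onset_threshold_pct - tol):
            onset = t[i]
            break
    if onset is None:
        return "unclassified"
    if onset <= bins_h[0]:
        return "EIC"
    if onset <= bins_h[1]:
        return "MIC"
    if onset <= 2.0:
        return "LIC"
    return "unclassified"


def simulate_ct(
    fractions: dict[float, float],
    baseline_ct: float,
    seed: int,
    circle_id: str = "circle",
    efficiency: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicates: int = DEFAULT_REPLICATES,
    wim_ct: float | None = None,
) -> pd.DataFrame:
    """CT measurements implied by true disrupted fractions per timepoint.

    ``fractions`` maps timepoint (h) to the fraction of copies whose HIM
    amplicon is destroyed; the HIM CT shifts by -log_{1+efficiency}(1-f)
    while the WIM CT stays constant, both subject to Gaussian replicate
    noise.
    """
    if not 0.8 < efficiency <= 1.0:
        raise ValueError("amplification efficiency must be in (0.8, 1.0]")
    if any(not 0.0 <= f < 1.0 for f in fractions.values()):
        raise ValueError("disrupted fractions must be in [0, 1); 1 implies infinite CT")
    rng = np.random.default_rng(seed)
    if wim_ct is None:
        wim_ct = baseline_ct
    rows = []
    log_base = np.log(1.0 + efficiency)
    for t in sorted(fractions):
        shift = -np.log(1.0 - fractions[t]) / log_base
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "circle_id": circle_id,
                    "timepoint_h": float(t),
                    "replicate": rep,
                    "ct_him": baseline_ct + shift + rng.normal(0.0, noise_sd),
                    "ct_wim": wim_ct + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def wave_fraction(wave: str, t: float, plateau: float = 0.8) -> float:
    """True disrupted-fraction trajectory implied by a temporal wave.

    Piecewise-linear ramps: early circles rise from 0 h, mid from 0.5 h,
    late from 1 h, each saturating at ``plateau``.
    """
    onsets = {"early": (0.0, 0.4), "mid": (0.5, 0.5), "late": (1.0, 0.8)}
    if wave not in onsets:
        raise ValueError(f"unknown wave {wave!r}")
    t0, ramp = onsets[wave]
    return plateau * min(1.0, max(0.0, (t - t0) / ramp))
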