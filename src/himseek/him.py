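"""Host-integration-motif discovery from break-site profiles.

Given a circle's modal junction pair (U, D) the deleted spacer is the
circular interval U+1 .. D-1.  The motif itself is recovered by scanning
the retained flanks for exact inverted-repeat arm pairs: an upstream arm
ending at or before U paired with a downstream arm starting at or after D
whose sequence is the upstream arm's reverse complement.  The canonical
structure is an 8-nt pair (TAAATTTC / GAAATTTA) bordering the deletion and
a 5-nt pair (CTGGT / ACCAG) a few bases further out.

WIM-HIM proximity follows the convention that reproduces the published
coordinate arithmetic on both linear and origin-wrapping circles: the
number of bases strictly between the first WIM base and the nearest
deletion boundary, minimized over the two circular directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breakpoints import BreakSiteProfile
from .io import revcomp

DEFAULT_SEARCH_WINDOW = 30
MIN_PRIMARY_ARM = 6  # shortest run accepted as the 8-nt-class arm
MIN_SECONDARY_ARM = 4  # shortest run accepted as the 5-nt-class arm


@dataclass(frozen=True)
class DeletionCall:
    circle_id: str
    del_start: int
    del_end: int
    del_len: int
    up_junction: int
    down_junction: int
    circle_len: int
    status: str  # ok | degenerate | not_applicable


@dataclass(frozen=True)
class ArmPair:
    up_seq: str
    down_seq: str
    up_span: tuple[int, int]
    down_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.up_seq)


@dataclass(frozen=True)
class HIMCall:
    deletion: DeletionCall
    arm8: ArmPair | None
    arm5: ArmPair | None
    intact: bool
    pairs: list[ArmPair]  # every maximal inverted-repeat pair in the windows
    wim_him_proximity: int | None = None


def infer_deletion(profile: BreakSiteProfile, circle_len: int | None = None) -> DeletionCall:
    """Deleted interval implied by the modal junction pair (circular)."""
    L = circle_len if circle_len is not None else profile.circle_len
    if profile.modal_pair is None:
        return DeletionCall(profile.circle_id, 0, 0, 0, 0, 0, L, "not_applicable")
    u, d = profile.modal_pair
    del_start = u % L + 1
    del_end = (d - 2) % L + 1
    del_len = (d - u - 1) % L
    status = "degenerate" if del_len == 0 else "ok"
    return DeletionCall(profile.circle_id, del_start, del_end, del_len, u, d, L, status)


def _circular_char(seq: str, pos1: int) -> str:
    return seq[(pos1 - 1) % len(seq)]


def _circular_slice(seq: str, start1: int, length: int) -> str:
    return "".join(_circular_char(seq, start1 + i) for i in range(length))


def detect_inverted_repeat(
    circle_seq: str,
    deletion: DeletionCall,
    arm_lens: tuple[int, int] = (8, 5),
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> HIMCall:
    """Find the inverted-repeat arm pairs bordering a called deletion.

    All maximal exact inverted repeats between the upstream window (ending
    at U) and the downstream window (starting at D) are enumerated; the
    longest (>= 6 nt, ties resolved toward the junctions) is reported in
    the 8-nt slot and the longest remaining pair lying outside it (>= 4 nt)
    in the 5-nt slot.  ``intact`` requires the two slots to reach the
    canonical arm lengths.  Reported arm lengths are the detected maximal
    lengths, which may exceed the canonical ones when flanking bases happen
    to extend the repeat.
    """
    L = len(circle_seq)
    if search_window >= L:
        raise ValueError("search window exceeds circle length")
    if deletion.status == "not_applicable":
        raise ValueError("cannot scan arms without a modal junction pair")
    u, d = deletion.up_junction, deletion.down_junction
    w = search_window
    up_window = _circular_slice(circle_seq, u - w + 1, w)  # ends at U
    down_window = _circular_slice(circle_seq, d, w)  # starts at D
    comp = str.maketrans("ACGT", "TGCA")
    down_comp = down_window.translate(comp)

    pairs: list[ArmPair] = []
    for i in range(w):  # up-arm end index within up_window
        for j in range(w):  # down-arm start index within down_window
            if up_window[i] != down_comp[j]:
                continue
            # only record runs at their junction-proximal anchor
            if i + 1 < w and j >= 1 and up_window[i + 1] == down_comp[j - 1]:
                continue
            length = 1
            while (
                i - length >= 0
                and j + length < w
                and up_window[i - length] == down_comp[j + length]
            ):
                length += 1
            if length < MIN_SECONDARY_ARM:
                continue
            up_end = u - (w - 1 - i)
            down_start = d + j
            pairs.append(
                ArmPair(
                    up_seq=up_window[i - length + 1 : i + 1],
                    down_seq=down_window[j : j + length],
                    up_span=((up_end - length) % L + 1, (up_end - 1) % L + 1),
                    down_span=((down_start - 1) % L + 1, (down_start + length - 2) % L + 1),
                )
            )

    def junction_distance(p: ArmPair) -> int:
        up_d = (u - p.up_span[1]) % L
        down_d = (p.down_span[0] - d) % L
        return up_d + down_d

    pairs.sort(key=lambda p: (-p.length, junction_distance(p)))
    primary = next((p for p in pairs if p.length >= MIN_PRIMARY_ARM), None)
    secondary = None
    for p in pairs:
        if p is primary or p.length < MIN_SECONDARY_ARM:
            continue
        if primary is not None:
            outside = ((u - p.up_span[1]) % L > (u - primary.up_span[0]) % L) and (
                (p.down_span[0] - d) % L > (primary.down_span[1] - d) % L
            )
            if not outside:
                continue
        secondary = p
        break
    long_arm, short_arm = max(arm_lens), min(arm_lens)
    intact = (
        primary is not None
        and primary.length >= long_arm
        and secondary is not None
        and secondary.length >= short_arm
    )
    return HIMCall(
        deletion=deletion, arm8=primary, arm5=secondary, intact=intact, pairs=pairs
    )


def wim_him_proximity(circle_len: int, deletion: DeletionCall, wim_start: int = 1) -> int:
    """Bases strictly between the first WIM base and the nearest deletion
    boundary, taking the shorter circular direction (linear case:
    del_start - 2)."""
    L = circle_len
    gap_back = (deletion.del_start - wim_start - 1) % L
    gap_forward = (wim_start - deletion.del_end - 1) % L
    return min(gap_back, gap_forward)


def consensus_logo(flanks: list[str]) -> tuple[pd.DataFrame, str]:
    """Column-wise base frequencies over aligned flanks plus the
    most-frequent-base string."""
    if len(flanks) < 2:
        raise ValueError("need at least two flanks")
    lengths = {len(f) for f in flanks}
    if len(lengths) != 1:
        raise ValueError(f"unequal flank lengths: {sorted(lengths)}")
    arr = np.array([list(f.upper()) for f in flanks])
    bases = ["A", "C", "G", "T"]
    freqs = np.stack([(arr == b).mean(axis=0) for b in bases])
    pfm = pd.DataFrame(freqs, index=bases)
    consensus = "".join(bases[i] for i in freqs.argmax(axis=0))
    return pfm, consensus


def him_table(
    calls: list[tuple[str, tuple[int, int], HIMCall]],
) -> pd.DataFrame:
    """HIM summary table: WIM span, deleted span/length, proximity, arms."""
    rows = []
    for circle_id, wim_span, call in calls:
        d = call.deletion
        rows.append(
            {
                "circle_id": circle_id,
                "wim_span": f"{wim_span[0]}-{wim_span[1]}",
                "del_start": d.del_start,
                "del_end": d.del_end,
                "del_len": d.del_len,
                "wim_him_proximity": call.wim_him_proximity,
                "arm8_up": call.arm8.up_seq if call.arm8 else "",
                "arm8_down": call.arm8.down_seq if call.arm8 else "",
                "arm5_up": call.arm5.up_seq if call.arm5 else "",
                "arm5_down": call.arm5.down_seq if call.arm5 else "",
                "intact": call.intact,
            }
        )
    return pd.DataFrame(rows)
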