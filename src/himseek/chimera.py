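"""Screening reads for virus-host chimeras.

A read is chimeric when its best viral-circle alignment and its best host
alignment tile the read into two compatible segments, each covering at
least ``min_aln_len`` read bases (28 by default, applied to each side) and
each passing the E-value cutoff.  Junction coordinates are normalized to
the forward strand of the circle: side "end" means the viral segment's
3'-most circle base abuts the host (the upstream boundary U of an
integrated copy), side "start" means its 5'-most base does (the downstream
boundary D).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import LocalAlignment, ReferenceIndex, align_local
from .io import iter_fastq

DEFAULT_MIN_ALN_LEN = 28
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MAX_OVERLAP = 10
DEFAULT_MAX_GAP = 10

CHIMERA_COLUMNS = [
    "read_id", "circle_id", "viral_junction_pos", "junction_side",
    "viral_strand", "host_scaffold", "host_junction_pos", "host_strand",
    "geometry", "junction_read_offset", "viral_read_start", "viral_read_end",
    "host_read_start", "host_read_end", "viral_score", "host_score",
    "viral_evalue", "host_evalue", "provenance",
]


@dataclass(frozen=True)
class ChimericRead:
    read_id: str
    viral_segment: LocalAlignment
    host_segment: LocalAlignment
    junction_read_offset: int
    viral_junction_pos: int
    host_junction_pos: int
    geometry: str  # viral-left | viral-right (read orientation)
    junction_side: str  # end | start (circle-forward orientation)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _wrap(aln: LocalAlignment, pos: int) -> int:
    if aln.circular and aln.ref_len:
        return (pos - 1) % aln.ref_len + 1
    return max(1, min(pos, aln.ref_len)) if aln.ref_len else pos


def _left_pos_at(aln: LocalAlignment, k: int) -> int:
    """Reference coordinate of the left segment's last base when the
    junction sits at read offset ``k`` (anchored at the junction-facing end,
    assuming no gaps within the refined window)."""
    if aln.strand == "+":
        return _wrap(aln, aln.ref_end - (aln.read_end - k))
    return _wrap(aln, aln.ref_start + (aln.read_end - k))


def _right_pos_at(aln: LocalAlignment, k: int) -> int:
    """Reference coordinate of the right segment's first base at offset k."""
    if aln.strand == "+":
        return _wrap(aln, aln.ref_start + (k - aln.read_start))
    return _wrap(aln, aln.ref_end - (k - aln.read_start))


def _segment_base(aln: LocalAlignment, index, read_offset: int, is_left: bool) -> str:
    pos = (
        _left_pos_at(aln, read_offset + 1)
        if is_left
        else _right_pos_at(aln, read_offset)
    )
    base = index.base(aln.ref_name, pos)
    return base if aln.strand == "+" else base.translate(_COMP)


def _refine_junction(
    read_seq: str,
    left: LocalAlignment,
    right: LocalAlignment,
    left_index,
    right_index,
    viral_is_left: bool = True,
    max_shift: int = 10,
) -> int:
    """Read offset of the junction, refined by the best two-segment split.

    A local alignment can run a few bases past the true junction whenever
    the other reference happens to continue similarly (micro-homology or a
    cheap mismatch-containing tail), so the boundary is re-chosen as the
    split point maximizing the summed match/mismatch score of the left
    prefix against the left reference plus the right suffix against the
    right reference.  Ties (true micro-homology) are resolved toward the
    longer viral segment, which makes the call invariant under
    reverse-complementing the read."""
    default = left.read_end
    if read_seq is None or left_index is None or right_index is None:
        return default
    lo = max(right.read_start, left.read_end - max_shift, left.read_start + 1)
    hi = min(left.read_end, right.read_end - 1)
    if lo >= hi:
        return default
    offsets = range(lo, hi)
    left_match = [
        read_seq[o] == _segment_base(left, left_index, o, True) for o in offsets
    ]
    right_match = [
        read_seq[o] == _segment_base(right, right_index, o, False) for o in offsets
    ]
    def w(match: bool) -> int:
        return 1 if match else -2

    # score(k) for k = lo..hi; start from k = hi (all bases to the left arm)
    score = sum(w(m) for m in left_match)
    best_k, best_score = hi, score
    for i in range(len(offsets) - 1, -1, -1):
        score += w(right_match[i]) - w(left_match[i])
        k = lo + i
        if score > best_score or (score == best_score and not viral_is_left):
            best_k, best_score = k, score
    return best_k


def _junction_on_ref(
    aln: LocalAlignment, is_left: bool, junction_offset: int
) -> tuple[int, str]:
    """Reference coordinate adjacent to the junction plus the circle-forward
    side ("end": the segment's 3'-most circle base abuts the junction)."""
    if is_left:
        return _left_pos_at(aln, junction_offset), (
            "end" if aln.strand == "+" else "start"
        )
    return _right_pos_at(aln, junction_offset), (
        "start" if aln.strand == "+" else "end"
    )


def classify_read(
    read_id: str,
    viral_alns: list[LocalAlignment],
    host_alns: list[LocalAlignment],
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    max_gap: int = DEFAULT_MAX_GAP,
    read_seq: str | None = None,
    viral_index: ReferenceIndex | None = None,
    host_index: ReferenceIndex | None = None,
) -> ChimericRead | None:
    """Pair the best viral and best host alignments into a chimera call.

    Returns None whenever the pair is absent, too short, insignificant,
    nested, or separated by more than ``max_gap`` unaligned read bases.
    When the read sequence and both reference indexes are supplied the
    junction offset is refined by the best two-segment split.
    """
    if not viral_alns or not host_alns:
        return None
    v = viral_alns[0]
    h = host_alns[0]
    for aln in (v, h):
        if aln.read_span_len < min_aln_len or aln.evalue > evalue_max:
            return None
    # reject nesting
    if (v.read_start <= h.read_start and v.read_end >= h.read_end) or (
        h.read_start <= v.read_start and h.read_end >= v.read_end
    ):
        return None
    viral_is_left = v.read_start < h.read_start or (
        v.read_start == h.read_start and v.read_end < h.read_end
    )
    left, right = (v, h) if viral_is_left else (h, v)
    overlap = left.read_end - right.read_start
    if overlap > max_overlap or -overlap > max_gap:
        return None
    left_index, right_index = (
        (viral_index, host_index) if viral_is_left else (host_index, viral_index)
    )
    junction_offset = _refine_junction(
        read_seq, left, right, left_index, right_index, viral_is_left=viral_is_left
    )
    viral_pos, side = _junction_on_ref(v, viral_is_left, junction_offset)
    host_pos, _ = _junction_on_ref(h, not viral_is_left, junction_offset)
    return ChimericRead(
        read_id=read_id,
        viral_segment=v,
        host_segment=h,
        junction_read_offset=junction_offset,
        viral_junction_pos=viral_pos,
        host_junction_pos=host_pos,
        geometry="viral-left" if viral_is_left else "viral-right",
        junction_side=side,
    )


def _chimera_row(c: ChimericRead, provenance: str) -> list:
    return [
        c.read_id, c.viral_segment.ref_name, c.viral_junction_pos, c.junction_side,
        c.viral_segment.strand, c.host_segment.ref_name, c.host_junction_pos,
        c.host_segment.strand, c.geometry, c.junction_read_offset,
        c.viral_segment.read_start, c.viral_segment.read_end,
        c.host_segment.read_start, c.host_segment.read_end,
        c.viral_segment.score, c.host_segment.score,
        c.viral_segment.evalue, c.host_segment.evalue, provenance,
    ]


def extract_chimeras(
    fastq_paths: list[str],
    viral_index: ReferenceIndex,
    host_index: ReferenceIndex,
    read_len: int = 150,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Screen FASTQ files and return one row per chimeric read.

    Reads are aligned to the viral circles first; the host pass is skipped
    unless the best viral segment is significant, long enough, and leaves
    room on the read for a host segment — reads fully explained by one
    reference cannot be chimeric under the two-segment model.
    """
    reads = (
        (read_id, comment, seq)
        for path in fastq_paths
        for read_id, comment, seq, _ in iter_fastq(path)
    )
    return extract_chimeras_from_reads(
        reads, viral_index, host_index, read_len=read_len,
        min_aln_len=min_aln_len, evalue_max=evalue_max,
        max_overlap=max_overlap, max_gap=max_gap,
    )


def extract_chimeras_from_reads(
    reads,
    viral_index: ReferenceIndex,
    host_index: ReferenceIndex,
    read_len: int = 150,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """In-memory variant of :func:`extract_chimeras` over ``(read_id,
    comment, sequence)`` tuples."""
    rows = []
    max_viral_span = read_len - min_aln_len + max_overlap
    for read_id, comment, seq in reads:
        viral_alns = align_local(seq, viral_index)
        if not viral_alns:
            continue
        best = viral_alns[0]
        if (
            best.read_span_len < min_aln_len
            or best.evalue > evalue_max
            or best.read_span_len > max_viral_span
        ):
            continue
        host_alns = align_local(seq, host_index)
        call = classify_read(
            read_id, viral_alns, host_alns, min_aln_len=min_aln_len,
            evalue_max=evalue_max, max_overlap=max_overlap, max_gap=max_gap,
            read_seq=seq, viral_index=viral_index, host_index=host_index,
        )
        if call is not None:
            rows.append(_chimera_row(call, comment))
    return pd.DataFrame(rows, columns=CHIMERA_COLUMNS)


def per_circle_counts(chimeras: pd.DataFrame) -> pd.Series:
    """Chimeric-read tally per circle (the S5-table style summary)."""
    if chimeras.empty:
        return pd.Series(dtype=int)
    return chimeras.groupby("circle_id").size().sort_index()


def chimeras_to_bedpe(chimeras: pd.DataFrame, path: str) -> None:
    """BEDPE export: viral side as a circle interval, host side as a
    scaffold interval (both single-base junction intervals, 0-based)."""
    from .io import to_bed_interval

    with open(path, "w") as fh:
        for row in chimeras.itertuples(index=False):
            vs, ve = to_bed_interval(row.viral_junction_pos, row.viral_junction_pos)
            hs, he = to_bed_interval(row.host_junction_pos, row.host_junction_pos)
            fh.write(
                f"{row.circle_id}\t{vs}\t{ve}\t{row.host_scaffold}\t{hs}\t{he}\t"
                f"{row.read_id}\t{row.viral_score}\t{row.viral_strand}\t{row.host_strand}\n"
            )
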