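"""Seed-and-extend local alignment against small reference sets.

This is the in-package replacement for an external BLASTN screen: reads are
seeded with exact k-mers (k=13 by default, so any exact match of 28 nt or
more is guaranteed to be seeded), seed hits are clustered by diagonal, and
each cluster is resolved with an exact Smith-Waterman pass over a padded
window, so reported scores are optimal within the seeded region.

Circular references (viral circles) are searched across the origin by
internally doubling the sequence and wrapping coordinates back to the
1..L range; an alignment whose 1-based inclusive span has end < start
crosses the origin.

Significance is a Karlin-Altschul style E-value with fixed ungapped
parameters for +1/-2 scoring (lambda = 1.33, K = 0.621); gaps are rare in
this setting and the screen only uses the E-value as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from ._sw import encode, smith_waterman
from .io import revcomp

MATCH = 1
MISMATCH = -2
GAP = -3
KA_LAMBDA = 1.33
KA_K = 0.621

DEFAULT_K = 13
_DIAG_BAND = 16  # seed hits within this diagonal band share one cluster
_WINDOW_PAD = 12  # extra reference bases around the seeded window
_MIN_REPORT_SCORE = 16
_MAX_CLUSTERS = 6


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a read against a named reference.

    ``read_span`` is 0-based half-open on the original (forward) read;
    ``ref_start``/``ref_end`` are 1-based inclusive on the forward reference
    and ``ref_end < ref_start`` indicates an origin-crossing alignment on a
    circular reference.
    """

    read_start: int
    read_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    mismatches: int
    gaps: int
    score: int
    evalue: float
    ref_len: int = 0
    circular: bool = False

    @property
    def read_span_len(self) -> int:
        return self.read_end - self.read_start


class ReferenceIndex:
    """k-mer index over a set of reference sequences.

    With ``circular=True`` every sequence is doubled internally; seeds are
    only taken from first-copy start positions so each alignment is found
    once, and coordinates are wrapped back modulo the true length.
    """

    def __init__(
        self, records: list[tuple[str, str]], circular: bool = False, k: int = DEFAULT_K
    ):
        if not records or all(len(seq) == 0 for _, seq in records):
            raise ValueError("empty reference")
        self.k = k
        self.circular = circular
        self.names = [name for name, _ in records]
        self._name_to_idx = {name: i for i, (name, _) in enumerate(records)}
        self.lengths = [len(seq) for _, seq in records]
        self.total_length = sum(self.lengths)
        self._seqs = []
        self._encoded = []
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ref_idx, (_, seq) in enumerate(records):
            seq = seq.upper()
            stored = seq + seq if circular else seq
            self._seqs.append(stored)
            self._encoded.append(encode(stored))
            n_starts = len(seq) if circular else max(0, len(seq) - k + 1)
            for pos in range(n_starts):
                kmer = stored[pos : pos + k]
                self._index.setdefault(kmer, []).append((ref_idx, pos))

    def base(self, ref_name: str, pos1: int) -> str:
        """Reference base at a 1-based position (wrapped on circular refs)."""
        idx = self._name_to_idx[ref_name]
        length = self.lengths[idx]
        if self.circular:
            pos1 = (pos1 - 1) % length + 1
        elif not 1 <= pos1 <= length:
            return "N"
        return self._seqs[idx][pos1 - 1]

    def seed_hits(self, read: str) -> dict[int, list[tuple[int, int]]]:
        """Map ref_idx -> [(diagonal, read_pos), ...] for exact k-mer hits."""
        k = self.k
        idx = self._index
        out: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(len(read) - k + 1):
            hits = idx.get(read[qpos : qpos + k])
            if hits:
                for ref_idx, tpos in hits:
                    out.setdefault(ref_idx, []).append((tpos - qpos, qpos))
        return out


def _align_one_strand(
    read: str, index: ReferenceIndex, strand: str, read_len: int
) -> list[LocalAlignment]:
    encoded_read = None
    alignments: list[LocalAlignment] = []
    for ref_idx, hits in index.seed_hits(read).items():
        stored = index._encoded[ref_idx]
        true_len = index.lengths[ref_idx]
        hits.sort()
        # cluster seed hits by diagonal
        clusters: list[list[tuple[int, int]]] = []
        for diag, qpos in hits:
            if clusters and diag - clusters[-1][-1][0] <= _DIAG_BAND:
                clusters[-1].append((diag, qpos))
            else:
                clusters.append([(diag, qpos)])
        clusters.sort(key=len, reverse=True)
        seen_spans: set[tuple] = set()
        for cluster in clusters[:_MAX_CLUSTERS]:
            diags = [d for d, _ in cluster]
            win_start = max(0, min(diags) - _WINDOW_PAD)
            win_end = min(len(stored), max(diags) + len(read) + _WINDOW_PAD)
            if win_end <= win_start:
                continue
            if encoded_read is None:
                encoded_read = encode(read)
            score, qs, qe, ts, te, n_match, n_mis, n_gap = smith_waterman(
                encoded_read, stored[win_start:win_end], MATCH, MISMATCH, GAP
            )
            if score < _MIN_REPORT_SCORE:
                continue
            ref_start0 = (win_start + ts) % true_len
            ref_end0_incl = (win_start + te - 1) % true_len
            if strand == "+":
                r_start, r_end = qs, qe
            else:  # map back onto the forward read
                r_start, r_end = read_len - qe, read_len - qs
            key = (ref_start0, ref_end0_incl, r_start, r_end)
            if key in seen_spans:
                continue
            seen_spans.add(key)
            alignments.append(
                LocalAlignment(
                    read_start=r_start,
                    read_end=r_end,
                    ref_name=index.names[ref_idx],
                    ref_start=ref_start0 + 1,
                    ref_end=ref_end0_incl + 1,
                    strand=strand,
                    matches=int(n_match),
                    mismatches=int(n_mis),
                    gaps=int(n_gap),
                    score=int(score),
                    evalue=karlin_altschul_evalue(
                        int(score), read_len, index.total_length
                    ),
                    ref_len=true_len,
                    circular=index.circular,
                )
            )
    return alignments


def karlin_altschul_evalue(score: int, read_len: int, ref_len: int) -> float:
    return KA_K * read_len * ref_len * exp(-KA_LAMBDA * score)


def align_local(read: str, reference: ReferenceIndex) -> list[LocalAlignment]:
    """All seeded local alignments of a read on both strands, best first.

    Ties in score are broken by longer aligned read span, then reference
    name, then lower reference coordinate.
    """
    if len(read) < reference.k:
        raise ValueError(
            f"read shorter than seed size ({len(read)} < {reference.k})"
        )
    read = read.upper()
    alns = _align_one_strand(read, reference, "+", len(read))
    alns += _align_one_strand(revcomp(read), reference, "-", len(read))
    alns.sort(key=lambda a: (-a.score, -a.read_span_len, a.ref_name, a.ref_start))
    return alns


def best_alignment(alns: list[LocalAlignment]) -> LocalAlignment | None:
    return alns[0] if alns else None
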