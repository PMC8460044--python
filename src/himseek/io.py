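"""Format readers/writers and the single coordinate-conversion chokepoint.

Conventions used throughout the package:

* FASTA / GFF3 / TSV coordinates are 1-based, inclusive.
* BED6 / BEDPE / bedGraph coordinates are 0-based, half-open.
* The only functions allowed to change basis are :func:`to_bed_interval`
  and :func:`from_bed_interval`.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coordinate basis conversion (the one chokepoint)
# ---------------------------------------------------------------------------

def to_bed_interval(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive ``(start, end)`` -> 0-based half-open BED interval."""
    if start1 < 1 or end1 < start1:
        raise ValueError(f"malformed 1-based interval ({start1}, {end1})")
    return start1 - 1, end1


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive ``(start, end)``."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"malformed BED interval ({start0}, {end0})")
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA into ``[(name, sequence), ...]``."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def iter_fastq(path: str) -> Iterator[tuple[str, str, str, str]]:
    """Yield ``(read_id, comment, sequence, quality)`` from plain or gzipped FASTQ.

    Raises a ValueError naming the file and record position on malformed input.
    """
    import pysam

    try:
        with pysam.FastxFile(str(path)) as fh:
            for i, entry in enumerate(fh):
                if entry.sequence is None or entry.quality is None:
                    raise ValueError(f"{path}: malformed FASTQ record #{i + 1}")
                yield entry.name, entry.comment or "", entry.sequence.upper(), entry.quality
    except OSError as exc:  # unreadable / truncated file
        raise IOError(f"cannot read FASTQ {path}: {exc}") from exc


def write_fastq(reads: Iterable[tuple[str, str, str, str]], path: str) -> None:
    """Write ``(read_id, comment, sequence, quality)`` tuples as FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, comment, seq, qual in reads:
            header = f"@{rid} {comment}" if comment else f"@{rid}"
            fh.write(f"{header}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3_genes(genes: Iterable[tuple[str, int, int, str]], path: str) -> None:
    """Write gene intervals (scaffold, start1, end1, strand) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (scaffold, start, end, strand) in enumerate(genes, 1):
            if start < 1 or end < start:
                raise ValueError(f"malformed gene interval {scaffold}:{start}-{end}")
            fh.write(
                f"{scaffold}\thimseek\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID=gene{i:05d}\n"
            )


def read_gff3_genes(
    path: str, scaffold_lengths: dict[str, int] | None = None
) -> list[tuple[str, int, int, str]]:
    """Parse gene features from GFF3 via gffutils.

    When ``scaffold_lengths`` is given, out-of-bounds features are rejected
    with the offending coordinates in the message.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[tuple[str, int, int, str]] = []
    for feat in db.features_of_type("gene"):
        if feat.start < 1 or feat.end < feat.start:
            raise ValueError(
                f"{path}: malformed feature {feat.seqid}:{feat.start}-{feat.end}"
            )
        if scaffold_lengths is not None:
            length = scaffold_lengths.get(feat.seqid)
            if length is None:
                raise ValueError(f"{path}: unknown scaffold {feat.seqid!r}")
            if feat.end > length:
                raise ValueError(
                    f"{path}: feature {feat.seqid}:{feat.start}-{feat.end} exceeds "
                    f"scaffold length {length}"
                )
        genes.append((feat.seqid, feat.start, feat.end, feat.strand or "."))
    return genes


# ---------------------------------------------------------------------------
# BED6 / bedGraph
# ---------------------------------------------------------------------------

def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, float, str]], path: str
) -> None:
    """Write BED6 rows ``(chrom, start0, end0, name, score, strand)``."""
    with open(path, "w") as fh:
        for chrom, start0, end0, name, score, strand in intervals:
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"malformed BED interval {chrom}:{start0}-{end0}")
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path: str) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, start0, end0, name, score, strand = fields[:6]
            rows.append((chrom, int(start0), int(end0), name, float(score), strand))
    return rows


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="himseek insertion events"\n')
        for chrom, start0, end0, value in rows:
            fh.write(f"{chrom}\t{start0}\t{end0}\t{value:g}\n")


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
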