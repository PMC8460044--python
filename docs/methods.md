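# Methods

`himseek` reconstructs, end to end and on simulated data, the computational
procedure for discovering how bracovirus DNA circles integrate into the
genome of a parasitized caterpillar: chimeric-read detection, viral
break-site profiling, conservative-vs-random break classification,
inverted-repeat host-integration-motif (HIM) discovery, host
insertion-landscape analysis, and the qPCR-derived integration index with
its temporal classification.

## Biological model

A bracovirus genome persists as proviral segments in the wasp genome and is
injected into the caterpillar host as ~30 circular dsDNA segments.  Each
circle's coordinate origin is fixed at the first base of its wasp
integration motif (WIM, a short junction sequence containing the tetramer
AGCT); coordinates are 1-based and inclusive.

Circles integrate into the host genome in two modes:

* **Conservative** — the circle opens at its HIM, an element composed of
  two inverted-repeat arm pairs (8 nt, `TAAATTTC`/`GAAATTTA`; 5 nt,
  `CTGGT`/`ACCAG`) flanking a non-conserved spacer of a few tens of bases.
  The spacer is deleted; both arm pairs are retained on the integrated
  copy, bordering the deletion.  Under this convention the deleted interval
  equals the spacer exactly, which makes the coordinate arithmetic of the
  deletion table reproducible (`length = end − start + 1`).
* **Random** — the circle opens at a uniformly random position with no
  deletion (`down = up + 1` circularly).

A circle whose chimeric junctions concentrate at one modal pair is a
Conservative-Broken Circle (CBC); one whose junctions are scattered is a
Random-Broken Circle (RBC).

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions
for every downstream stage.  Defaults (one number per line, with why):

| parameter | default | rationale |
|---|---|---|
| circles / with HIM | 30 / 19 | the cohort composition reported for CvBV |
| circle length | 700–1500 nt | scaled down ~5x from the real 3.8–38.8 kb segments to keep a full cohort run on one CPU in tens of seconds; all coordinate logic is length-independent |
| spacer length | 39–72 nt | the span of reported deleted-spacer lengths (the table's largest row is 72 nt) |
| HIM offset from WIM | 120–470 nt | the span of reported WIM–HIM proximities for typical circles |
| conservative probability per HIM circle | 0.88 … 0.38 | complements of the 19 published per-circle random-break percentages (12%…62%) |
| events per circle | 48 | pooled hemocytes from hundreds of larvae contain many independent integration loci; 48 keeps the event-level binomial noise of the conserved fraction small at desk scale |
| waves | 11 early / 5 mid / 3 late | the published EIC/MIC/LIC split |
| reads | 150 bp paired-end, 300 bp fragments, 8x coverage, substitution rate 0.002 | Illumina-like; ~240 chimeric reads per circle (the real study had ~1300) |

Host genome: 2 scaffolds x 150 kb of i.i.d. uniform sequence with
non-overlapping gene intervals tiled to a requested genic density (default
0.4).  This is deliberate plumbing, not a model of a real genome: it has no
repeats, GC structure, or gene families.  Passing tests therefore
demonstrate correctness of the *method* (alignment, clustering, coordinate
arithmetic, classification), not robustness to repetitive or biased real
data, where a BLAST-style screen would face ambiguous mappings the
simulator never produces.

Every stochastic operation takes an explicit seed; an absent seed is an
error, never silent entropy.  Truth is written as BED6 (0-based, half-open,
insertion point on the original host coordinates, `name = circle_id|mode`)
and JSON (full event records); reads carry a provenance tag
(`host-only | viral-only | chimeric` with event ids and junction offsets)
in the FASTQ comment.

## Chimeric-read detection

Reads are screened with an internal seed-and-extend aligner instead of an
external BLASTN binary: exact 13-mers seed candidate diagonals (any exact
match ≥ 28 nt necessarily contains a 13-mer seed), diagonal clusters are
resolved by an exact Smith–Waterman pass (numba-compiled; match +1,
mismatch −2, linear gap −3) over a ±12 nt padded window, so reported scores
are optimal within the seeded region — a property the test suite checks
against an independent full-matrix local-alignment oracle.  Circular
references are searched across the origin by internal sequence doubling
with coordinate wrap-back.  Significance is a Karlin–Altschul E-value with
fixed ungapped parameters (λ = 1.33, K = 0.621) — an approximation adequate
for a filter at E < 10⁻⁵.

A read is chimeric when its best viral and best host alignments tile the
read: each side ≥ 28 nt (the published per-side rule, applied strictly to
both sides), each passing the E-value cutoff, non-nested, overlapping by
≤ 10 read bases and separated by ≤ 10 unaligned bases.  Only the best
viral/host pair per read is reported; mates are classified independently.

**Junction refinement.**  A local alignment can run a few bases past the
true junction whenever the other reference happens to continue similarly —
either true micro-homology or a mismatch-containing tail that still scores
positively.  The junction offset is therefore re-chosen as the split point
maximizing the summed match/mismatch score of the left prefix against the
left reference plus the right suffix against the right reference, within
±10 bases of the alignment boundary.  Ties (true micro-homology, which is
inherently ambiguous) resolve toward the longer viral segment, making the
call invariant under reverse-complementing the read.  Junction coordinates
are normalized to the circle's forward strand: side "end" means the viral
segment's 3'-most circle base abuts the host (the upstream boundary U of
an integrated copy), side "start" its 5'-most base (downstream boundary D).

## Break-site profiling and classification

Per circle, junction tallies are kept separately for the two junction
classes and clustered with a ±3 nt circular window (absorbing residual
alignment-end jitter).  The modal pair (U, D) takes the highest-count
window per class; ties break toward the center with the most direct hits,
then the lowest coordinate.  The conserved count is the number of chimeras
falling in *either* modal window — one conservative event necessarily
produces both junction classes, so the two boundaries are one "site".

A circle is a CBC when its conserved fraction ≥ 0.35 with ≥ 20 supporting
chimeras (below that, the label is withheld as `insufficient_support`).
The 0.35 threshold sits between the most random published CBC (38%
conserved) and the "completely random" RBCs, and is exposed as a flag.  At
desk scale the conserved fraction of the borderline 0.38-probability
circle carries binomial noise from both the 48 events and the ~240 reads,
so a single-seed misclassification of that one circle is expected
occasionally; cohort-level checks therefore use the modal count over five
consecutive seeds.

## HIM discovery

Given a modal pair, the deleted spacer is the circular interval
`U+1 … D−1` (RBCs yield a `not_applicable` status, adjacent junctions a
`degenerate` one).  Arms are found by enumerating all maximal exact
inverted-repeat pairs between the retained flanks — an upstream arm ending
at or before U within a 30 nt window, paired with a downstream arm starting
at or after D whose sequence is its reverse complement.  Mirrored offsets
are *not* required: deleting 4 nt from one 8-nt arm (the M1 mutant) shifts
the surviving 5-nt pair asymmetrically, and the detector must still find
it.  The longest pair (≥ 6 nt) fills the 8-nt slot; the longest remaining
pair lying strictly outside it (≥ 4 nt) fills the 5-nt slot; `intact`
requires both slots to reach the canonical 8 and 5.  Reported arm lengths
are the detected maximal lengths, which can exceed the canonical ones when
flanking bases extend the repeat by chance (~25% per boundary per circle) —
`intact` is unaffected.  A second, ≤ 1-mismatch "degraded" tier is not
reported by default because the canonical arms are exact.

**WIM–HIM proximity** is the number of bases strictly between the first WIM
base and the nearest deletion boundary, minimized over the two circular
directions.  This exclusive-gap convention is the only one consistent with
both the small-coordinate published rows (405 = 407 − 2) and the
wrap-around row (220 = 4572 − 4352); the source material never defines it,
so it is stated here prominently.

Junction flanks of all CBCs are stacked into a position-frequency matrix
with a most-frequent-base consensus; on simulated cohorts the consensus
recovers `…TAAATTTC | GAAATTTA…` while the deleted spacers show no shared
consensus.

## Host insertion landscape

Chimeras from one circle landing within ±3 nt on a scaffold merge into one
insertion site with summed support.  A site is genic when it falls inside
any gene feature's full span (the coarse genic/intergenic dichotomy; no
exon/intron distinction).  Per-circle genic fractions are compared
descriptively against the genome background; a preference is flagged only
beyond a ±0.1 margin, and no statistical test is applied because the
source analysis reports none.  Insertion events are counted in half-open
100-kb windows (last partial window kept; counts conserved), and flank
motif content is summarized as per-column Shannon information (0–2 bits)
over ±20 nt flanks, truncating sites too close to scaffold edges out of
the stack.

## Integration index

For each circle, ΔCT = CT(HIM amplicon) − CT(WIM amplicon), ΔΔCT(t) =
ΔCT(t) − ΔCT(0 h), and the index is (1 − 2^(−ΔΔCT)) × 100%.  Per-timepoint
mean ΔCT is referenced to the 0 h baseline so the baseline index is exactly
0; replicate-wise indices give the sd; negative indices are reported with a
below-baseline flag rather than clamped, since clamping would hide assay
noise.  Amplification efficiency defaults to 1.0 (the base-2 formula
presumes it).  Fewer than 3 replicates warns but computes.

Timing classes use the onset — the earliest timepoint on the
{0, 0.5, 1, 2, 4} h grid whose mean index reaches 25% without any later
timepoint falling below threshold − 1 sd (rejecting transient noise
crossings while tolerating plateau jitter): onset ≤ 0.5 h → EIC, ≤ 1 h →
MIC, ≤ 2 h → LIC, otherwise unclassified.  Both the threshold and the bin
edges are config-exposed since they are inferred from a verbal definition.

The CT simulator inverts the readout: a truly disrupted fraction f raises
CT(HIM) by −log₍₁₊E₎(1 − f) cycles at efficiency E (f = 1 would be an
infinite CT and is rejected), with Gaussian replicate noise (default sd
0.15 cycles).  At E = 1 and zero noise the index round-trips to exactly
100 f.  Wave trajectories are piecewise-linear ramps (early from 0 h, mid
from 0.5 h, late from 1 h, saturating at 0.8) chosen so the three classes
separate cleanly on the measurement grid.

## Pipeline and reproducibility

`run_pipeline` executes simulate → detect → profile → him → landscape →
index, writing plain-text outputs (FASTA/GFF3/FASTQ/TSV/BED6/BEDPE/
bedGraph/JSON) plus a manifest with the full configuration, the master
seed, per-stage statistics, and a sha256 per file; re-running with the
same config and seed is byte-identical.  Stage-derived seeds are small
fixed offsets of the master seed.  All coordinate-basis changes go through
one conversion chokepoint (`himseek.io`), property-tested with random
intervals.

## Known limitations

* The host genome model is structureless; mapping ambiguity, repeats and
  PCR duplicates are out of scope, as is SAM emission.
* The two-segment chimera model ignores reads spanning two insertion
  junctions (rare at simulated densities; such reads are tagged in truth
  and excluded from recall accounting).
* Arm detection reports maximal repeats, so detected lengths can exceed
  8/5 by chance extension into flanking bases.
* E-values use ungapped Karlin–Altschul constants with a gapped aligner;
  the screen is a filter, not a significance estimate.
* The integration index presumes perfect primer efficiency by default and
  models no melting-curve artifacts or absolute copy-number calibration.
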