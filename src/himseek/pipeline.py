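"""End-to-end driver: simulate -> detect -> profile -> him -> landscape -> index.

Every stage writes plain-text outputs into the result directory and the
manifest records the configuration, the seed, and a sha256 for each file,
so re-running with an identical config and seed is byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import breakpoints, chimera, him, landscape, qpcr, simulate
from .align import ReferenceIndex
from .config import PipelineConfig
from .io import (
    ensure_dir,
    sha256_of,
    write_bedgraph,
    write_fasta,
    write_fastq,
    write_gff3_genes,
    write_json,
)

log = logging.getLogger("himseek")


@dataclass
class PipelineResult:
    outdir: str
    classification: pd.DataFrame = field(default_factory=pd.DataFrame)
    chimeras: pd.DataFrame = field(default_factory=pd.DataFrame)
    him_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    genic_fractions: pd.DataFrame = field(default_factory=pd.DataFrame)
    index_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    manifest: dict = field(default_factory=dict)


def simulate_cohort(config: PipelineConfig, seed: int | None = None):
    """Generate host, circles, events, integrated genome and reads."""
    seed = config.seed if seed is None else seed
    host = simulate.generate_host_genome(
        config.n_scaffolds,
        [config.scaffold_length] * config.n_scaffolds,
        config.gene_density,
        seed=seed,
    )
    circles = simulate.generate_circles(
        config.n_circles,
        length_range=config.circle_len_range,
        n_with_him=config.n_with_him,
        spacer_len_range=config.spacer_len_range,
        seed=seed + 1,
    )
    probs = {}
    i = 0
    for c in circles:
        if c.has_intact_him:
            probs[c.circle_id] = config.conservative_probs[
                i % len(config.conservative_probs)
            ]
            i += 1
        else:
            probs[c.circle_id] = 0.0
    events, genome = simulate.simulate_integrations(
        circles, host, config.events_per_circle, probs, seed=seed + 2
    )
    records = list(genome.scaffolds)
    if config.include_episomes:
        records += [(c.circle_id, c.seq) for c in circles]
    r1, r2 = simulate.simulate_reads(
        records,
        coverage=config.coverage,
        seed=seed + 3,
        read_len=config.read_len,
        error_rate=config.error_rate,
        genome=genome,
    )
    return host, circles, probs, events, genome, (r1, r2)


def classify_cohort(config: PipelineConfig, seed: int) -> pd.DataFrame:
    """simulate -> detect -> profile without touching disk; returns the
    per-circle classification report (the Fig 2B-style table)."""
    host, circles, _, _, genome, (r1, r2) = simulate_cohort(config, seed)
    viral_index = ReferenceIndex(
        [(c.circle_id, c.seq) for c in circles], circular=True, k=config.seed_k
    )
    host_index = ReferenceIndex(host.scaffolds, circular=False, k=config.seed_k)
    chimeras = chimera.extract_chimeras_from_reads(
        ((r.read_id, r.comment, r.seq) for r in r1 + r2),
        viral_index,
        host_index,
        read_len=config.read_len,
        min_aln_len=config.min_aln_len,
        evalue_max=config.evalue_max,
        max_overlap=config.max_overlap,
        max_gap=config.max_gap,
    )
    classifications = []
    for c in circles:
        prof = breakpoints.build_profile(
            chimeras[chimeras["circle_id"] == c.circle_id], c.circle_id, c.length,
            cluster_tol=config.cluster_tol,
        )
        classifications.append(
            breakpoints.classify_circle(
                prof, threshold=config.cbc_threshold, min_support=config.min_support
            )
        )
    return breakpoints.random_fraction_report(classifications)


def run_pipeline(
    config: PipelineConfig, outdir: str, seed: int | None = None
) -> PipelineResult:
    seed = config.seed if seed is None else seed
    ensure_dir(outdir)
    result = PipelineResult(outdir=outdir)
    manifest: dict = {"config": _jsonable(config.to_dict()), "seed": seed, "stages": {}}
    written: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(outdir, name)
        written.append(path)
        return path

    stage = "simulate"
    try:
        log.info("stage %s: seed=%d", stage, seed)
        host, circles, probs, events, genome, (r1, r2) = simulate_cohort(config, seed)
        write_fasta(host.scaffolds, out("host.fa"))
        write_gff3_genes(host.genes, out("host_genes.gff3"))
        write_fasta([(c.circle_id, c.seq) for c in circles], out("circles.fa"))
        write_fasta(genome.scaffolds, out("integrated_host.fa"))
        simulate.events_to_bed(events, out("truth_events.bed"))
        simulate.events_to_json(events, out("truth_events.json"))
        write_fastq(
            ((r.read_id, r.comment, r.seq, r.qual) for r in r1), out("reads_R1.fastq")
        )
        write_fastq(
            ((r.read_id, r.comment, r.seq, r.qual) for r in r2), out("reads_R2.fastq")
        )
        manifest["stages"][stage] = {
            "n_events": len(events),
            "n_read_pairs": len(r1),
            "conservative_probs": probs,
        }

        stage = "detect"
        log.info("stage %s", stage)
        viral_index = ReferenceIndex(
            [(c.circle_id, c.seq) for c in circles], circular=True, k=config.seed_k
        )
        host_index = ReferenceIndex(host.scaffolds, circular=False, k=config.seed_k)
        chimeras = chimera.extract_chimeras(
            [os.path.join(outdir, "reads_R1.fastq"), os.path.join(outdir, "reads_R2.fastq")],
            viral_index,
            host_index,
            read_len=config.read_len,
            min_aln_len=config.min_aln_len,
            evalue_max=config.evalue_max,
            max_overlap=config.max_overlap,
            max_gap=config.max_gap,
        )
        chimeras.to_csv(out("chimeras.tsv"), sep="\t", index=False)
        chimera.chimeras_to_bedpe(chimeras, out("chimeras.bedpe"))
        result.chimeras = chimeras
        manifest["stages"][stage] = {
            "n_chimeras": int(len(chimeras)),
            "per_circle": {
                k: int(v) for k, v in chimera.per_circle_counts(chimeras).items()
            },
        }

        stage = "profile"
        log.info("stage %s", stage)
        profiles = {}
        classifications = []
        for c in circles:
            sub = chimeras[chimeras["circle_id"] == c.circle_id]
            prof = breakpoints.build_profile(
                sub, c.circle_id, c.length, cluster_tol=config.cluster_tol
            )
            profiles[c.circle_id] = prof
            classifications.append(
                breakpoints.classify_circle(
                    prof, threshold=config.cbc_threshold, min_support=config.min_support
                )
            )
        report = breakpoints.random_fraction_report(classifications)
        report.to_csv(out("classification.tsv"), sep="\t", index=False)
        result.classification = report
        counts_rows = [
            {"circle_id": cid, "junction_side": side, "position": pos, "count": n}
            for cid, prof in profiles.items()
            for side, counts in (("end", prof.left_counts), ("start", prof.right_counts))
            for pos, n in sorted(counts.items())
        ]
        pd.DataFrame(
            counts_rows, columns=["circle_id", "junction_side", "position", "count"]
        ).to_csv(out("breaksite_counts.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_cbc": int((report["label"] == "CBC").sum()),
            "n_rbc": int((report["label"] == "RBC").sum()),
        }

        stage = "him"
        log.info("stage %s", stage)
        cbc_ids = set(report.loc[report["label"] == "CBC", "circle_id"])
        calls = []
        up_flanks, down_flanks = [], []
        for c in circles:
            if c.circle_id not in cbc_ids:
                continue
            deletion = him.infer_deletion(profiles[c.circle_id])
            if deletion.status == "not_applicable":
                continue
            call = him.detect_inverted_repeat(
                c.seq, deletion, search_window=config.search_window
            )
            prox = him.wim_him_proximity(c.length, deletion)
            call = him.HIMCall(
                deletion=call.deletion, arm8=call.arm8, arm5=call.arm5,
                intact=call.intact, pairs=call.pairs, wim_him_proximity=prox,
            )
            calls.append((c.circle_id, c.wim_span, call))
            up_flanks.append(
                him._circular_slice(c.seq, deletion.up_junction - 19, 20)
            )
            down_flanks.append(
                him._circular_slice(c.seq, deletion.down_junction, 20)
            )
        table = him.him_table(calls)
        table.to_csv(out("him_table.tsv"), sep="\t", index=False)
        result.him_table = table
        write_fasta(
            [(f"{cid}_up", f) for (cid, _, _), f in zip(calls, up_flanks)]
            + [(f"{cid}_down", f) for (cid, _, _), f in zip(calls, down_flanks)],
            out("junction_flanks.fa"),
        )
        if len(up_flanks) >= 2:
            pfm_up, cons_up = him.consensus_logo(up_flanks)
            pfm_down, cons_down = him.consensus_logo(down_flanks)
            pfm = pd.concat([pfm_up, pfm_down], axis=1)
            pfm.columns = [f"up_{i}" for i in range(pfm_up.shape[1])] + [
                f"down_{i}" for i in range(pfm_down.shape[1])
            ]
            pfm.to_csv(out("consensus_pfm.tsv"), sep="\t")
            manifest["stages"][stage] = {
                "n_him_calls": len(calls),
                "consensus_up": cons_up,
                "consensus_down": cons_down,
            }
        else:
            manifest["stages"][stage] = {"n_him_calls": len(calls)}

        stage = "landscape"
        log.info("stage %s", stage)
        lengths = host.scaffold_lengths
        sites, genic = landscape.annotate_sites(
            chimeras, host.genes, lengths, merge_tol=config.merge_tol
        )
        genic.to_csv(out("genic_fractions.tsv"), sep="\t", index=False)
        result.genic_fractions = genic
        landscape.sites_to_bed(sites, out("insertion_sites.bed"))
        track = landscape.window_counts(sites, lengths, window_size=config.window_size)
        write_bedgraph(
            landscape.track_to_bedgraph_rows(track, lengths), out("windows.bedgraph")
        )
        max_ic, _ = landscape.flank_motif_scan(
            sites, dict(host.scaffolds), flank=config.flank
        )
        manifest["stages"][stage] = {
            "n_sites": len(sites),
            "max_flank_ic_bits": round(max_ic, 4),
        }

        stage = "index"
        log.info("stage %s", stage)
        waves = simulate.default_wave_assignment(circles)
        ct_frames = []
        index_rows = []
        for i, c in enumerate(circles):
            if not c.has_intact_him:
                continue
            fractions = {
                t: qpcr.wave_fraction(waves[c.circle_id], t, plateau=config.plateau)
                for t in qpcr.TIMEPOINTS_H
            }
            ct = qpcr.simulate_ct(
                fractions, config.baseline_ct, seed=seed + 100 + i,
                circle_id=c.circle_id, efficiency=config.efficiency,
                noise_sd=config.ct_noise_sd, replicates=config.ct_replicates,
            )
            ct_frames.append(ct)
            series = qpcr.compute_index(ct)
            timing = qpcr.classify_timing(
                series, onset_threshold_pct=config.onset_threshold_pct,
                bins_h=config.bins_h,
            )
            frame = series.as_frame()
            frame["timing_class"] = timing
            frame["true_wave"] = waves[c.circle_id]
            index_rows.append(frame)
        if ct_frames:
            pd.concat(ct_frames).to_csv(out("ct_measurements.tsv"), sep="\t", index=False)
            index_table = pd.concat(index_rows).reset_index(drop=True)
        else:
            index_table = pd.DataFrame()
        index_table.to_csv(out("integration_index.tsv"), sep="\t", index=False)
        result.index_table = index_table
        manifest["stages"][stage] = {"n_series": len(index_rows)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["files"] = {
        os.path.basename(p): sha256_of(p) for p in written if os.path.exists(p)
    }
    write_json(manifest, os.path.join(outdir, "manifest.json"))
    result.manifest = manifest
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
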