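"""Forward-simulator contracts: determinism, motif layout, event truth, reads."""

import json

import numpy as np
import pytest

from himseek import simulate as sim
from himseek.io import read_fasta, revcomp, write_fasta, write_gff3_genes


class TestHostGenome:
    def test_empty_genome_is_valid(self, tmp_path):
        host = sim.generate_host_genome(0, [], gene_density=0.4, seed=1)
        assert host.scaffolds == [] and host.genes == []
        write_gff3_genes(host.genes, tmp_path / "empty.gff3")
        assert (tmp_path / "empty.gff3").read_text() == "##gff-version 3\n"

    def test_gene_density_matches_request(self):
        host = sim.generate_host_genome(2, [100_000, 100_000], 0.4, seed=3)
        genic = sum(e - s + 1 for _, s, e, _ in host.genes)
        assert abs(genic / 200_000 - 0.4) < 0.05
        for scaffold, s, e, _ in host.genes:
            assert 1 <= s <= e <= host.scaffold_lengths[scaffold]

    def test_genes_do_not_overlap(self):
        host = sim.generate_host_genome(1, [50_000], 0.5, seed=5)
        ivls = sorted((s, e) for _, s, e, _ in host.genes)
        assert all(a[1] < b[0] for a, b in zip(ivls, ivls[1:]))

    def test_same_seed_byte_identical(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            host = sim.generate_host_genome(2, [5_000, 5_000], 0.3, seed=42)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            write_fasta(host.scaffolds, fa)
            write_gff3_genes(host.genes, gff)
            outputs.append((fa.read_bytes(), gff.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            sim.generate_host_genome(1, [500], 0.4, seed=1)
        with pytest.raises(ValueError):
            sim.generate_host_genome(1, [5_000], 1.5, seed=1)


class TestCircles:
    def test_him_counts(self):
        circles = sim.generate_circles(30, n_with_him=19, seed=1)
        assert sum(c.him_truth is not None for c in circles) == 19
        assert sum(c.him_truth is None for c in circles) == 11
        none = sim.generate_circles(5, n_with_him=0, seed=1)
        assert all(c.him_truth is None for c in none)

    def test_wim_and_arm_structure(self, mini_circles):
        for c in mini_circles:
            assert c.wim_span[0] == 1
            assert "AGCT" in c.seq[: c.wim_span[1]]
            c.validate()
            if c.him_truth is None:
                continue
            him = c.him_truth
            up8 = c.seq[him.arm8_up_span[0] - 1 : him.arm8_up_span[1]]
            dn8 = c.seq[him.arm8_down_span[0] - 1 : him.arm8_down_span[1]]
            assert revcomp(up8) == dn8 == "GAAATTTA"
            spacer_len = him.spacer_span[1] - him.spacer_span[0] + 1
            assert 20 <= spacer_len <= 100

    def test_rejects_impossible_layout(self):
        with pytest.raises(ValueError):
            sim.generate_circles(
                2, length_range=(500, 600), n_with_him=1,
                spacer_len_range=(450, 480), seed=1,
            )


class TestMutations:
    @pytest.mark.parametrize(
        "mutation,delta", [("M1_del_TTTC", 4), ("M2_del_CTGGT", 5), ("M3_both", 9)]
    )
    def test_mutation_shortens_circle(self, mini_circles, mutation, delta):
        wt = mini_circles[0]
        mut = sim.mutate_him(wt, mutation)
        assert mut.length == wt.length - delta
        assert mut.him_mutation == mutation
        assert not mut.has_intact_him
        # spacer coordinates shift but spacer length is untouched
        wt_sp = wt.him_truth.spacer_span
        mut_sp = mut.him_truth.spacer_span
        assert mut_sp[1] - mut_sp[0] == wt_sp[1] - wt_sp[0]
        assert mut_sp[0] == wt_sp[0] - delta

    def test_mutating_himless_circle_fails(self, mini_circles):
        himless = next(c for c in mini_circles if c.him_truth is None)
        with pytest.raises(ValueError):
            sim.mutate_him(himless, "M1_del_TTTC")


class TestIntegrations:
    def test_no_events_leaves_host_unchanged(self, mini_host, mini_circles):
        events, genome = sim.simulate_integrations(
            mini_circles, mini_host, 0, 1.0, seed=1
        )
        assert events == []
        assert genome.scaffolds == mini_host.scaffolds

    def test_conservative_deletion_equals_spacer(self, mini_host, mini_circles):
        him_circle = mini_circles[0]
        events, _ = sim.simulate_integrations(
            [him_circle], mini_host, 50, 1.0, seed=9
        )
        spacer = him_circle.him_truth.spacer_span
        spacer_len = spacer[1] - spacer[0] + 1
        assert len(events) == 50
        for ev in events:
            assert ev.mode == "conservative"
            assert ev.deleted_len == spacer_len
            assert ev.up_junction == spacer[0] - 1
            assert ev.down_junction == spacer[1] + 1

    @pytest.mark.parametrize("mutation", ["M1_del_TTTC", "M2_del_CTGGT", "M3_both"])
    def test_mutants_only_break_randomly(self, mini_host, mini_circles, mutation):
        mut = sim.mutate_him(mini_circles[0], mutation)
        events, _ = sim.simulate_integrations([mut], mini_host, 40, 1.0, seed=13)
        assert all(ev.mode == "random" for ev in events)
        assert all(ev.deleted_len == 0 for ev in events)

    def test_forcing_conservative_without_him_is_a_contract_violation(
        self, mini_host, mini_circles
    ):
        mut = sim.mutate_him(mini_circles[0], "M3_both")
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="intact HIM"):
            sim.draw_event(mut, "conservative", mini_host, rng, "ev1", "early")

    def test_integrated_copy_excludes_spacer(self, mini_host, mini_circles):
        circle = mini_circles[0]
        events, genome = sim.simulate_integrations([circle], mini_host, 1, 1.0, seed=3)
        ev = events[0]
        copy = sim.linearized_copy(circle, ev)
        assert len(copy) == circle.length - ev.deleted_len
        name, new_seq = next(
            (n, s) for n, s in genome.scaffolds if n == ev.host_scaffold
        )
        assert copy in new_seq

    def test_truth_round_trips_through_bed_and_json(
        self, tmp_path, mini_host, mini_circles
    ):
        events, _ = sim.simulate_integrations(mini_circles, mini_host, 5, 0.7, seed=17)
        jpath, bpath = tmp_path / "truth.json", tmp_path / "truth.bed"
        sim.events_to_json(events, jpath)
        sim.events_to_bed(events, bpath)
        assert sim.events_from_json(jpath) == events
        reparsed = sim.events_from_bed(bpath)
        assert len(reparsed) == len(events)
        for row, ev in zip(
            sorted(reparsed), sorted(
                (e.host_scaffold, e.host_pos, e.circle_id, e.mode, e.deleted_len,
                 e.orientation) for e in events
            ),
        ):
            assert row == ev


class TestReads:
    def test_coverage_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        r1, r2 = sim.simulate_reads([("ref", seq)], coverage=30.0, seed=1)
        assert len(r1) == len(r2) == round(30 * 10_000 / 300)

    def test_error_free_reads_are_exact_substrings(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        r1, r2 = sim.simulate_reads([("ref", seq)], coverage=5.0, seed=2, error_rate=0.0)
        for read in list(r1)[:50] + list(r2)[:50]:
            assert read.seq in seq or revcomp(read.seq) in seq

    def test_error_rate_perturbs_reads(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        r1, _ = sim.simulate_reads([("ref", seq)], coverage=5.0, seed=2, error_rate=0.05)
        assert any(read.seq not in seq and revcomp(read.seq) not in seq for read in r1)

    def test_read_len_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reads([("r", "ACGT" * 100)], 1.0, seed=1, read_len=150,
                               fragment_len=100)

    def test_chimeric_tags_match_junction_overlap(self, mini_sim):
        genome = mini_sim["genome"]
        r1, r2 = mini_sim["reads"]
        tagged = [r for r in r1 + r2 if r.comment.startswith("src:chimeric")]
        assert tagged, "expected some junction-spanning reads"
        junctions = {ev.event_id: ev for ev in mini_sim["events"]}
        for read in tagged:
            kind, evs, offs = sim.parse_provenance(read.comment)
            assert kind == "chimeric"
            assert evs and all(e in junctions for e in evs)
            assert all(0 < o < len(read.seq) for o in offs)

    def test_chimeric_yield_scales_with_coverage(self, mini_host, mini_circles):
        _, genome = sim.simulate_integrations(
            mini_circles, mini_host, 10, 0.85, seed=23
        )
        counts = []
        for coverage in (4.0, 8.0):
            r1, r2 = sim.simulate_reads(
                list(genome.scaffolds), coverage=coverage, seed=31, genome=genome
            )
            counts.append(
                sum(r.comment.startswith("src:chimeric") for r in r1 + r2)
            )
        # doubling coverage should double the yield within 3 sigma (Poisson)
        expected = 2 * counts[0]
        assert abs(counts[1] - expected) < 3 * np.sqrt(expected)
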