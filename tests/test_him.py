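"""Deletion calls, inverted-repeat arm detection, proximity, consensus."""

import numpy as np
import pytest

from himseek import simulate as sim
from himseek.breakpoints import BreakSiteProfile, build_profile
from himseek.him import (
    consensus_logo,
    detect_inverted_repeat,
    infer_deletion,
    wim_him_proximity,
)
from himseek.io import revcomp
from conftest import junction_table

ARM8_UP, ARM8_DOWN = "TAAATTTC", "GAAATTTA"
ARM5_UP, ARM5_DOWN = "CTGGT", "ACCAG"


def profile_at(u: int, d: int, circle_len: int, circle_id: str = "c") -> BreakSiteProfile:
    table = junction_table({"end": [u] * 30, "start": [d] * 30}, circle_id)
    return build_profile(table, circle_id, circle_len)


def planted_circle(rng, length=2_000, u=500, spacer_len=50, gap="CATTC"):
    """Circle with canonical arms around a random spacer; deletion at
    (u+1 .. u+spacer_len).  The fixed gap sequences prevent accidental
    outward extension of the arms."""
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
    block = ARM5_UP + gap + ARM8_UP + spacer + ARM8_DOWN + gap[::-1] + ARM5_DOWN
    start = u - len(ARM5_UP) - len(gap) - len(ARM8_UP)  # 0-based block start
    seq[start : start + len(block)] = list(block)
    return "".join(seq), u, u + spacer_len + 1


class TestInferDeletion:
    @pytest.mark.parametrize(
        "u,d,circle_len,exp_start,exp_end,exp_len",
        [
            (4302, 4353, 4572, 4303, 4352, 50),  # published CvBV_02 coordinates
            (129, 202, 4572, 130, 201, 72),  # published CvBV_30 coordinates
        ],
    )
    def test_published_coordinate_arithmetic(self, u, d, circle_len, exp_start, exp_end, exp_len):
        call = infer_deletion(profile_at(u, d, circle_len))
        assert (call.del_start, call.del_end, call.del_len) == (exp_start, exp_end, exp_len)
        assert call.status == "ok"

    def test_adjacent_junctions_flagged_degenerate(self):
        call = infer_deletion(profile_at(100, 101, 4_000))
        assert call.del_len == 0 and call.status == "degenerate"

    def test_wrap_around_deletion(self):
        call = infer_deletion(profile_at(3_990, 15, 4_000))
        assert (call.del_start, call.del_end) == (3_991, 14)
        assert call.del_len == 24

    def test_no_modal_pair_is_not_applicable(self):
        import pandas as pd

        prof = build_profile(pd.DataFrame(), "c", 4_000)
        call = infer_deletion(prof)
        assert call.status == "not_applicable"

    def test_circular_length_identity_holds_for_all_calls(self, rng):
        """del_len always equals the circular end-start+1 arithmetic."""
        L = 3_000
        for _ in range(50):
            u = int(rng.integers(1, L + 1))
            d = int(rng.integers(1, L + 1))
            if d == u:
                continue
            call = infer_deletion(profile_at(u, d, L))
            assert call.del_len == (call.del_end - call.del_start) % L + 1 or (
                call.status == "degenerate"
            )


class TestDetectInvertedRepeat:
    def test_printed_arms_recovered_exactly(self, rng):
        seq, u, d = planted_circle(rng)
        call = detect_inverted_repeat(seq, infer_deletion(profile_at(u, d, len(seq))))
        assert call.intact
        assert call.arm8.up_seq == ARM8_UP and call.arm8.down_seq == ARM8_DOWN
        assert call.arm5.up_seq == ARM5_UP and call.arm5.down_seq == ARM5_DOWN
        assert revcomp(call.arm8.up_seq) == call.arm8.down_seq
        assert revcomp(call.arm5.up_seq) == call.arm5.down_seq
        assert call.arm8.up_span == (u - 7, u) and call.arm8.down_span == (d, d + 7)

    def test_random_sequence_has_no_arms(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        call = detect_inverted_repeat(seq, infer_deletion(profile_at(500, 551, 2_000)))
        assert not call.intact

    def test_window_exceeding_circle_rejected(self, rng):
        seq, u, d = planted_circle(rng)
        with pytest.raises(ValueError):
            detect_inverted_repeat(
                seq, infer_deletion(profile_at(u, d, len(seq))), search_window=5_000
            )

    def test_m1_mutant_loses_8nt_arm_but_keeps_5nt_pair(self, mini_circles):
        wt = mini_circles[0]
        mut = sim.mutate_him(wt, "M1_del_TTTC")
        spacer = mut.him_truth.spacer_span
        call = detect_inverted_repeat(
            mut.seq, infer_deletion(profile_at(spacer[0] - 1, spacer[1] + 1, mut.length))
        )
        assert not call.intact
        assert call.arm8 is None or call.arm8.length < 8
        assert any(
            ARM5_UP in p.up_seq and ARM5_DOWN in p.down_seq for p in call.pairs
        ), "5-nt pair should survive the M1 mutation"

    def test_m2_mutant_loses_5nt_pair_but_keeps_8nt_arm(self, mini_circles):
        wt = mini_circles[0]
        mut = sim.mutate_him(wt, "M2_del_CTGGT")
        spacer = mut.him_truth.spacer_span
        call = detect_inverted_repeat(
            mut.seq, infer_deletion(profile_at(spacer[0] - 1, spacer[1] + 1, mut.length))
        )
        assert not call.intact
        assert call.arm8 is not None and ARM8_UP in call.arm8.up_seq
        assert not any(
            ARM5_UP in p.up_seq and ARM5_DOWN in p.down_seq
            for p in call.pairs
            if p is not call.arm8
        )

    def test_revcomp_involution(self, rng):
        """Scanning the reverse-complemented circle finds the mirrored arms."""
        seq, u, d = planted_circle(rng)
        L = len(seq)
        rc = revcomp(seq)
        # junction pair maps to (L-d+1, L-u+1) with roles swapped
        call = detect_inverted_repeat(
            rc, infer_deletion(profile_at(L - d + 1, L - u + 1, L))
        )
        assert call.intact
        assert call.arm8.up_seq == ARM8_UP  # the motif is its own mirror image
        assert call.arm8.up_span == (L - d - 6, L - d + 1)

    def test_planted_him_recovery_across_cohort(self, mini_sim):
        """Called deletion within 2 nt of truth and intact arms on every
        simulated conservative circle with enough chimeras."""
        chimeras = mini_sim["chimeras"]
        checked = 0
        for c in mini_sim["circles"]:
            if not c.has_intact_him:
                continue
            sub = chimeras[chimeras["circle_id"] == c.circle_id]
            if len(sub) < 50:
                continue
            prof = build_profile(sub, c.circle_id, c.length)
            call = infer_deletion(prof)
            spacer = c.him_truth.spacer_span
            assert abs(call.del_start - spacer[0]) <= 2
            assert abs(call.del_end - spacer[1]) <= 2
            him_call = detect_inverted_repeat(c.seq, call)
            assert him_call.intact
            checked += 1
        assert checked >= 3


class TestProximity:
    def test_published_linear_row(self):
        # WIM 1-10, deletion 407-445 on a long circle -> 405
        call = infer_deletion(profile_at(406, 446, 2_000))
        assert wim_him_proximity(2_000, call) == 405

    def test_published_wraparound_row(self):
        # circle of 4,572 nt, deletion 4303-4352: wrap gap 220 < linear 4301
        call = infer_deletion(profile_at(4302, 4353, 4_572))
        gaps = (call.del_start - 2, 4_572 - call.del_end)
        assert min(gaps) == 220
        assert wim_him_proximity(4_572, call) == 220

    def test_deletion_immediately_after_wim_base(self):
        call = infer_deletion(profile_at(1, 52, 3_000))
        assert call.del_start == 2
        assert wim_him_proximity(3_000, call) == 0


class TestConsensus:
    def test_identical_flanks_give_unit_frequencies(self):
        pfm, consensus = consensus_logo(["ACGTACGT"] * 19)
        assert consensus == "ACGTACGT"
        assert (pfm.max(axis=0) == 1.0).all()

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            consensus_logo(["ACGT", "ACG"])

    def test_cohort_consensus_contains_planted_arms(self, rng):
        ups, downs = [], []
        for _ in range(19):
            seq, u, d = planted_circle(rng)
            ups.append(seq[u - 20 : u])
            downs.append(seq[d - 1 : d + 19])
        _, cons_up = consensus_logo(ups)
        _, cons_down = consensus_logo(downs)
        assert cons_up.endswith(ARM8_UP)
        assert cons_down.startswith(ARM8_DOWN)

    def test_deleted_spacers_share_no_consensus(self, rng):
        spacers = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(19)]
        pfm, _ = consensus_logo(spacers)
        assert pfm.max(axis=0).max() < 0.6
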