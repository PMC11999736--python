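"""Structure-constraint combinatorics, distance distributions and scanners."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexdyn import (
    StructureConstraint,
    exact_match_probability,
    exhaustive_distance_distribution,
    frame_count,
    min_distance_scan,
    mismatch_joint_probability,
    multi_frame_distribution,
    multi_frame_exact_probability,
    parse_structure,
    sample_min_distance_distribution,
    scan_pool,
    single_frame_distribution,
)
from selexdyn.structure import _placements, _scan_pool_generic, format_structure


def _round2sf(x):
    return float(f"{x:.2g}")


class TestParseStructure:
    def test_round_trip(self, hammerhead):
        text = format_structure(hammerhead)
        again = parse_structure(text)
        assert again == hammerhead
        assert format_structure(again) == text

    def test_fixture_counts(self, hammerhead, twister, triphosphorylation):
        assert (hammerhead.length, hammerhead.s, hammerhead.b, hammerhead.n_modules) == (39, 13, 8, 3)
        assert (twister.length, twister.s, twister.b, twister.n_modules) == (54, 11, 17, 3)
        assert (triphosphorylation.length, triphosphorylation.s, triphosphorylation.b) == (44, 13, 11)
        assert triphosphorylation.n_modules == 2 and triphosphorylation.anchored5

    def test_empty_constraint(self):
        sc = parse_structure("LENGTH 5\n")
        assert (sc.s, sc.b, sc.n_modules) == (0, 0, 1)

    def test_one_based_coordinates(self):
        with pytest.raises(ValueError):
            parse_structure("LENGTH 5\nCONS 0=G\n")

    def test_overlapping_constraints_rejected(self):
        with pytest.raises(ValueError, match="conserved and paired"):
            parse_structure("LENGTH 6\nCONS 2=G\nPAIR 2:5\n")
        with pytest.raises(ValueError, match="two pairs"):
            parse_structure("LENGTH 8\nPAIR 1:4 4:7\n")

    def test_t_normalized_to_u(self):
        sc = parse_structure("LENGTH 3\nCONS 1=T\n")
        assert sc.conserved == {1: "U"}

    def test_unknown_directive(self):
        with pytest.raises(ValueError, match="unknown directive"):
            parse_structure("LENGTH 4\nSTEM 1:4\n")


class TestExactMatchProbability:
    @pytest.mark.parametrize(
        "s,b,expected", [(13, 8, 5.8e-12), (11, 17, 1.4e-14), (13, 11, 3.1e-13)]
    )
    def test_ribozyme_values_to_2sf(self, s, b, expected):
        assert _round2sf(exact_match_probability(s, b)) == expected

    def test_no_constraints(self):
        assert exact_match_probability(0, 0) == 1.0

    @given(s=st.integers(0, 30), b=st.integers(0, 30))
    @settings(max_examples=100, derandomize=True)
    def test_closed_form(self, s, b):
        assert exact_match_probability(s, b) == pytest.approx(0.25**s * 0.375**b, rel=1e-12)


class TestFrameCount:
    @pytest.mark.parametrize(
        "Lran,Lstr,M,anchored,expected",
        [
            (80, 39, 3, False, 13244),
            (80, 54, 3, False, 3654),
            (80, 39, 1, False, 42),
            (80, 44, 2, True, 37),
        ],
    )
    def test_ribozyme_values(self, Lran, Lstr, M, anchored, expected):
        assert frame_count(Lran, Lstr, M, anchored) == expected

    @given(Lran=st.integers(1, 200), Lstr=st.integers(1, 200))
    @settings(max_examples=100, derandomize=True)
    def test_single_module_is_sliding_window(self, Lran, Lstr):
        if Lstr <= Lran:
            assert frame_count(Lran, Lstr, 1) == Lran - Lstr + 1

    def test_structure_too_long(self):
        with pytest.raises(ValueError):
            frame_count(30, 39, 1)


class TestMultiFrameExact:
    def test_hammerhead_wq(self):
        q = exact_match_probability(13, 8)
        pw, wq = multi_frame_exact_probability(q, 13244)
        assert _round2sf(wq) == 7.7e-8
        assert pw == pytest.approx(wq, rel=1e-3)  # q tiny: PW ~ Wq

    def test_triphosphorylation_wq(self):
        q = exact_match_probability(13, 11)
        _, wq = multi_frame_exact_probability(q, 37)
        assert _round2sf(wq) == 1.1e-11

    def test_zero_q(self):
        assert multi_frame_exact_probability(0.0, 100) == (0.0, 0.0)


class TestDistanceDistributions:
    def test_joint_reduces_to_q(self, hammerhead):
        s, b = hammerhead.s, hammerhead.b
        assert mismatch_joint_probability(0, 0, s, b) == pytest.approx(
            exact_match_probability(s, b), rel=1e-12
        )

    def test_joint_normalizes(self):
        s, b = 5, 4
        total = sum(
            mismatch_joint_probability(m1, m2, s, b) for m1 in range(s + 1) for m2 in range(b + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_joint_hand_value(self):
        assert mismatch_joint_probability(1, 0, 2, 0) == pytest.approx(2 * 0.75 * 0.25)

    def test_single_frame_one_conserved_site(self):
        assert single_frame_distribution(1, 0).probs == pytest.approx([0.25, 0.75])

    def test_single_frame_mass_at_zero_is_q(self, hammerhead):
        dist = single_frame_distribution(hammerhead.s, hammerhead.b)
        assert dist[0] == exact_match_probability(hammerhead.s, hammerhead.b)
        assert _round2sf(dist[0]) == 5.8e-12

    @pytest.mark.parametrize("s,b", [(0, 0), (1, 1), (13, 8), (11, 17)])
    def test_single_frame_normalizes(self, s, b):
        assert single_frame_distribution(s, b).probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_multi_frame_identity_at_one_frame(self):
        single = single_frame_distribution(3, 2)
        assert multi_frame_distribution(single, 1) is single

    def test_multi_frame_mass_at_zero(self, hammerhead):
        q = exact_match_probability(hammerhead.s, hammerhead.b)
        single = single_frame_distribution(hammerhead.s, hammerhead.b)
        multi = multi_frame_distribution(single, 13244)
        assert multi[0] == pytest.approx(-math.expm1(13244 * math.log1p(-q)), rel=1e-9)
        assert _round2sf(multi[0]) == 7.7e-8

    def test_near_misses_dominate_exact_matches(self, hammerhead):
        """PW(m) for m=1..3 exceeds PW(0) by orders of magnitude."""
        single = single_frame_distribution(hammerhead.s, hammerhead.b)
        multi = multi_frame_distribution(single, 13244)
        for m in (1, 2, 3):
            assert multi[m] > 10 * multi[0]

    def test_min_of_frames_shifts_mass_down(self):
        """The best of W frames stochastically dominates one frame toward small m."""
        single = single_frame_distribution(4, 3)
        multi = multi_frame_distribution(single, 25)
        cdf_single = np.cumsum(single.probs)
        cdf_multi = np.cumsum(multi.probs)
        assert np.all(cdf_multi >= cdf_single - 1e-12)


class TestMinDistanceScan:
    def test_planted_match_is_found(self, hammerhead):
        seq = ["A"] * 80
        offsets = [3, 10, 20]
        for p, b in hammerhead.conserved.items():
            seq[p - 1 + offsets[hammerhead.module_of(p)]] = b
        for i, j in hammerhead.pairs:
            m = hammerhead.module_of(i)
            seq[i - 1 + offsets[m]] = "G"
            seq[j - 1 + offsets[m]] = "C"
        assert min_distance_scan("".join(seq), hammerhead) == 0

    def test_everything_violated(self):
        # conserved G plus a pair; poly-A violates both in every frame
        sc = StructureConstraint(length=4, conserved={1: "G"}, pairs=((2, 4),))
        assert min_distance_scan("A" * 10, sc) == 2

    def test_hand_enumerated_toy(self):
        # Lstr=4, conserved G at 1, pair 2:4; sequence GAACAA, W=3 placements:
        # offset 0: G|AAC -> G ok, A:C not canonical -> 1
        # offset 1: A|ACA -> not G, A:A not canonical -> 2
        # offset 2: A|CAA -> not G, C:A not canonical -> 2
        sc = StructureConstraint(length=4, conserved={1: "G"}, pairs=((2, 4),))
        assert min_distance_scan("GAACAA", sc) == 1

    def test_invalid_alphabet(self, toy):
        with pytest.raises(ValueError, match="invalid base"):
            min_distance_scan("GXAC", toy)

    def test_sequence_shorter_than_structure(self, toy):
        with pytest.raises(ValueError):
            min_distance_scan("GA", toy)

    @pytest.mark.parametrize("Lran", [4, 6, 9])
    def test_placement_count_equals_frame_count(self, toy, toy_two_module, Lran):
        for sc in (toy, toy_two_module):
            if Lran >= sc.length:
                n = sum(1 for _ in _placements(sc, Lran))
                assert n == sc.frame_count(Lran)

    def test_anchored_placements(self, triphosphorylation):
        offs = list(_placements(triphosphorylation, 50))
        assert len(offs) == triphosphorylation.frame_count(50) == 7
        assert all(o[0] == 0 for o in offs)  # first module pinned to the 5' end


class TestScanPool:
    def test_dp_generic_and_scalar_paths_agree(self, toy, toy_two_module, rng):
        for sc, Lran in ((toy, 8), (toy_two_module, 10)):
            seqs = rng.integers(0, 4, size=(300, Lran), dtype=np.int8)
            dp = scan_pool(seqs, sc)
            generic = _scan_pool_generic(seqs, sc)
            scalar = np.array([min_distance_scan(s, sc) for s in seqs])
            assert np.array_equal(dp, generic)
            assert np.array_equal(dp, scalar)

    def test_cross_module_pairs_use_generic_path(self, rng):
        sc = StructureConstraint(length=6, conserved={2: "A"}, pairs=((1, 5),), breaks=(3,))
        seqs = rng.integers(0, 4, size=(200, 9), dtype=np.int8)
        scalar = np.array([min_distance_scan(s, sc) for s in seqs])
        assert np.array_equal(scan_pool(seqs, sc), scalar)

    def test_hammerhead_fast_path_agrees(self, hammerhead, rng):
        seqs = rng.integers(0, 4, size=(15, 80), dtype=np.int8)
        assert np.array_equal(scan_pool(seqs, hammerhead), _scan_pool_generic(seqs, hammerhead))


class TestExhaustiveOracle:
    def test_matches_single_frame_formula_exactly(self, toy):
        """With Lran = Lstr there is one frame; enumeration of all 256
        sequences must reproduce the closed form to rounding."""
        ex = exhaustive_distance_distribution(toy, 4)
        th = single_frame_distribution(toy.s, toy.b)
        assert np.allclose(ex.probs, th.probs, rtol=1e-12, atol=0)

    def test_two_module_single_frame(self, toy_two_module):
        ex = exhaustive_distance_distribution(toy_two_module, 6)
        th = single_frame_distribution(2, 2)
        assert np.allclose(ex.probs, th.probs, rtol=1e-12, atol=0)

    def test_union_bound_brackets_multi_frame_mass(self, toy):
        """For overlapping frames the exact P(match in >= 1 frame) lies
        between q and W*q; the independence formula also lies in that
        bracket, and its deviation from truth is the overlap bias."""
        ex = exhaustive_distance_distribution(toy, 6)
        q = exact_match_probability(toy.s, toy.b)
        W = toy.frame_count(6)
        assert q <= ex[0] <= W * q
        multi = multi_frame_distribution(single_frame_distribution(toy.s, toy.b), W)
        assert q <= multi[0] <= W * q

    def test_no_constraints_all_mass_at_zero(self):
        sc = StructureConstraint(length=3)
        ex = exhaustive_distance_distribution(sc, 5)
        assert ex.probs == pytest.approx([1.0])

    def test_guard(self, toy):
        with pytest.raises(ValueError):
            exhaustive_distance_distribution(toy, 13)


class TestSampledDistribution:
    def test_agrees_with_exhaustive_oracle(self, toy_two_module):
        """Monte Carlo vs exact enumeration on the same scanner: every m
        with expected count >= 100 agrees within 3 sigma of binomial error."""
        Lran, n = 8, 100_000
        exact = exhaustive_distance_distribution(toy_two_module, Lran)
        emp = sample_min_distance_distribution(toy_two_module, Lran, n, seed=0)
        for m, p in enumerate(exact.probs):
            if n * p >= 100:
                sigma = math.sqrt(p * (1 - p) / n)
                assert abs(emp[m] - p) < 3 * sigma

    def test_reproducible(self, toy):
        a = sample_min_distance_distribution(toy, 6, 2000, seed=42)
        b = sample_min_distance_distribution(toy, 6, 2000, seed=42)
        assert np.array_equal(a.probs, b.probs)

    def test_unconstrained_structure(self):
        sc = StructureConstraint(length=3)
        emp = sample_min_distance_distribution(sc, 5, 100, seed=1)
        assert emp.probs == pytest.approx([1.0])
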