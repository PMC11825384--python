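"""Candidate enumeration, shape distances, ranking, Pareto front."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shapemut import (
    DistanceConfig,
    FocalRegion,
    MutationSpec,
    NucleotideSequence,
    enumerate_candidates,
    focal_indices,
    pareto_front,
    physchem_distance,
    reverse_complement,
    run_design,
    shape_distance_euclidean,
    shape_distance_pearson,
    synth_table,
)
from shapemut.design_core import CandidateResult, substitutions_of
from shapemut.errors import (
    CoordinateError,
    DegenerateCorrelationError,
    EmptyFocalError,
    InsufficientFocalError,
    PositionLimitError,
)
from shapemut.shape_engine import FeatureClass, ShapeProfile


def profile(n, **vectors):
    return ShapeProfile(n=n, values={k: np.asarray(v, float) for k, v in vectors.items()})


class TestEnumeration:
    def test_single_position_contents(self):
        cands = enumerate_candidates("ACGT", MutationSpec([2]))
        assert cands == ["AAGT", "ACGT", "AGGT", "ATGT"]

    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_counts_are_four_to_the_m(self, m):
        wt = "ACGTACGTAC"
        cands = enumerate_candidates(wt, MutationSpec(range(1, m + 1)))
        assert len(cands) == 4**m
        assert len(set(cands)) == 4**m
        assert wt in cands

    def test_seven_positions_gives_16384(self):
        cands = enumerate_candidates("ACGTACGT", MutationSpec(range(1, 8)))
        assert len(cands) == 4**7 == 16384

    def test_eight_positions_rejected(self):
        with pytest.raises(PositionLimitError):
            MutationSpec(range(1, 9))

    def test_out_of_range_position_rejected(self):
        with pytest.raises(CoordinateError):
            enumerate_candidates("ACGT", MutationSpec([5]))
        with pytest.raises(CoordinateError):
            MutationSpec([2, 2])

    @pytest.mark.parametrize("positions", [(1,), (2, 5), (1, 4, 8)])
    def test_candidates_differ_only_at_spec_positions(self, positions):
        wt = "ACGTACGT"
        for cand in enumerate_candidates(wt, MutationSpec(positions)):
            diffs = {p for p, _, _ in substitutions_of(wt, cand)}
            assert diffs <= set(positions)


class TestFocalIndices:
    def test_groove_uses_positions_directly(self):
        idx = focal_indices(FocalRegion([3, 4, 5]), FeatureClass.GROOVE, 10)
        assert idx.tolist() == [3, 4, 5]

    def test_inter_bp_includes_both_adjacent_steps(self):
        # brute force: step j touches positions j and j+1
        focal = FocalRegion([3, 4, 5])
        expected = [
            j
            for j in range(1, 10)
            if {j, j + 1} & set(focal.positions)
        ]
        idx = focal_indices(focal, FeatureClass.INTER_BP, 10)
        assert idx.tolist() == expected == [2, 3, 4, 5]

    def test_first_position_touches_only_step_one(self):
        idx = focal_indices(FocalRegion([1]), FeatureClass.INTER_BP, 10)
        assert idx.tolist() == [1]


class TestEuclideanDistance:
    def test_identical_profiles_zero(self):
        p = profile(4, MGW=[1, 2, 3, 4])
        d, per = shape_distance_euclidean(p, p, DistanceConfig(features=("MGW",)))
        assert d == 0.0 and per == {"MGW": 0.0}

    def test_three_four_five(self):
        a = profile(2, MGW=[0.0, 0.0])
        b = profile(2, MGW=[3.0, 4.0])
        d, _ = shape_distance_euclidean(a, b, DistanceConfig(features=("MGW",)))
        assert d == pytest.approx(5.0)

    def test_matches_hand_recomputation_on_lookup_outputs(self, mgw_table):
        wt = NucleotideSequence("ACGTACGTAC")
        mut = NucleotideSequence("ACGTTCGTAC")  # substitution at position 5
        pa, pb = mgw_table.predict(wt), mgw_table.predict(mut)
        d, _ = shape_distance_euclidean(
            pa, pb, DistanceConfig(features=("MGW",), normalize=False)
        )
        expected = math.sqrt(float(np.sum((pa["MGW"] - pb["MGW"]) ** 2)))
        assert d == pytest.approx(expected)

    def test_multi_feature_pools_sum_of_squares(self):
        a = profile(3, MGW=[0, 0, 0], ProT=[0, 0, 0])
        b = profile(3, MGW=[3, 0, 0], ProT=[4, 0, 0])
        cfg = DistanceConfig(features=("MGW", "ProT"), normalize=False)
        d, per = shape_distance_euclidean(a, b, cfg)
        assert d == pytest.approx(5.0)
        assert per == {"MGW": pytest.approx(3.0), "ProT": pytest.approx(4.0)}

    def test_focal_restriction_and_monotonicity(self, mgw_table):
        wt = NucleotideSequence("ACGTACGTACGT")
        mut = NucleotideSequence("ACGTAGGTACGT")
        pa, pb = mgw_table.predict(wt), mgw_table.predict(mut)
        prev = 0.0
        for upper in range(1, 13):
            cfg = DistanceConfig(
                features=("MGW",),
                focal=FocalRegion(range(1, upper + 1)),
                normalize=False,
            )
            d, _ = shape_distance_euclidean(pa, pb, cfg)
            assert d >= prev - 1e-12  # enlarging focal never decreases it
            prev = d


class TestPearsonDistance:
    def test_identical_nonconstant_zero(self):
        p = profile(4, MGW=[1, 2, 3, 5])
        d, _ = shape_distance_pearson(
            p, p, DistanceConfig(features=("MGW",), shape_metric="pearson")
        )
        assert d == pytest.approx(0.0)

    def test_constant_offset_zero(self):
        a = profile(5, MGW=[1, 2, 3, 4, 6])
        b = profile(5, MGW=[11, 12, 13, 14, 16])
        d, _ = shape_distance_pearson(
            a, b, DistanceConfig(features=("MGW",), shape_metric="pearson")
        )
        assert d == pytest.approx(0.0)

    def test_negated_centered_profile_two(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        a = profile(5, MGW=v)
        b = profile(5, MGW=-(v - v.mean()) + v.mean())
        d, _ = shape_distance_pearson(
            a, b, DistanceConfig(features=("MGW",), shape_metric="pearson")
        )
        assert d == pytest.approx(2.0)

    def test_zero_variance_raises(self):
        a = profile(4, MGW=[1, 1, 1, 1])
        b = profile(4, MGW=[1, 2, 3, 4])
        with pytest.raises(DegenerateCorrelationError):
            shape_distance_pearson(
                a, b, DistanceConfig(features=("MGW",), shape_metric="pearson")
            )

    def test_too_few_focal_values_raises(self):
        a = profile(5, MGW=[1, 2, 3, 4, 5])
        cfg = DistanceConfig(
            features=("MGW",), shape_metric="pearson", focal=FocalRegion([1, 2])
        )
        with pytest.raises(InsufficientFocalError):
            shape_distance_pearson(a, a, cfg)


class TestRunDesign:
    def test_single_position_wildtype_flagged(self, mgw_table):
        results = run_design(
            "ACGTACGTAC",
            MutationSpec([5]),
            DistanceConfig(features=("MGW",)),
            mgw_table,
        )
        assert len(results) == 4
        wt_rows = [r for r in results if r.is_wildtype]
        assert len(wt_rows) == 1
        assert wt_rows[0].base_distance == 0.0
        assert wt_rows[0].shape_distance == 0.0
        assert wt_rows[0].substitutions == ()
        assert sorted(r.rank for r in results) == [1, 2, 3, 4]

    def test_two_position_physchem_distance_values(self, mgw_table):
        results = run_design(
            "ACGTACGTACGTACGTACGT",
            MutationSpec([5, 9]),
            DistanceConfig(features=("MGW",), base_metric="physchem"),
            mgw_table,
        )
        assert len(results) == 16
        observed = {r.base_distance for r in results}
        # brute force over the frozen encoding: per-substitution costs are
        # {6, 8}, so 0/1/2-substitution sums are {0} | {6,8} | {12,14,16}
        expected = {0.0}
        for a, b in itertools.product("ACGT", repeat=2):
            expected.add(float(physchem_distance("AA", a + b)))
        assert observed == expected == {0.0, 6.0, 8.0, 12.0, 14.0, 16.0}

    def test_deterministic_repeat(self, mgw_table):
        args = (
            "ACGTACGTAC",
            MutationSpec([3, 7]),
            DistanceConfig(features=("MGW",)),
            mgw_table,
        )
        r1, r2 = run_design(*args), run_design(*args)
        assert [(r.sequence, r.rank, r.shape_distance) for r in r1] == [
            (r.sequence, r.rank, r.shape_distance) for r in r2
        ]

    def test_base_distances_consistent_with_metric(self, full_table):
        results = run_design(
            "ACGTACGTAC",
            MutationSpec([2, 8]),
            DistanceConfig(features=("MGW",), base_metric="levenshtein"),
            full_table,
        )
        for r in results:
            assert r.base_distance == len(r.substitutions)

    def test_strand_invariance_multiset(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 12
            wt = "".join(rng.choice(list("ACGT"), size=n))
            positions = sorted(rng.choice(range(1, n + 1), size=2, replace=False))
            table = synth_table(5, ["MGW", "Shift"], 100 + trial)
            cfg = DistanceConfig(
                features=("MGW", "Shift"), normalize=False
            )
            fwd = run_design(wt, MutationSpec(positions), cfg, table)
            mirrored = [n + 1 - p for p in positions]
            rev = run_design(
                reverse_complement(wt), MutationSpec(mirrored), cfg, table
            )
            pairs_fwd = sorted(
                (r.base_distance, round(r.shape_distance, 9)) for r in fwd
            )
            pairs_rev = sorted(
                (r.base_distance, round(r.shape_distance, 9)) for r in rev
            )
            assert pairs_fwd == pairs_rev

    def test_focal_locality_zero_distance(self, mgw_table):
        # mutations >= (k-1)/2 + 1 = 3 positions away from every focal point
        # cannot change the focal shape values
        wt = "ACGTACGTACGTACGTACGT"
        results = run_design(
            wt,
            MutationSpec([1, 20]),
            DistanceConfig(
                features=("MGW",),
                focal=FocalRegion([10, 11]),
                normalize=False,
            ),
            mgw_table,
        )
        assert all(r.shape_distance == 0.0 for r in results)

    def test_normalization_auto_default(self):
        cfg1 = DistanceConfig(features=("MGW",))
        cfg2 = DistanceConfig(features=("MGW", "Roll"))
        assert not cfg1.normalize_effective
        assert cfg2.normalize_effective
        assert not DistanceConfig(
            features=("MGW", "Roll"), normalize=False
        ).normalize_effective


def _cand(base, shape, wt=False, seq="ACGT"):
    return CandidateResult(
        sequence=seq,
        substitutions=(),
        base_distance=float(base),
        shape_distance=float(shape),
        feature_distances={},
        is_wildtype=wt,
    )


class TestParetoFront:
    def brute_force_front(self, pts, objective):
        """Exhaustive dominance check, independent of the sweep."""
        out = []
        for p in pts:
            dominated = False
            for q in pts:
                shape_better = (
                    q.shape_distance > p.shape_distance
                    if objective == "max"
                    else q.shape_distance < p.shape_distance
                )
                shape_geq = (
                    q.shape_distance >= p.shape_distance
                    if objective == "max"
                    else q.shape_distance <= p.shape_distance
                )
                if (q.base_distance <= p.base_distance and shape_geq) and (
                    q.base_distance < p.base_distance or shape_better
                ):
                    dominated = True
                    break
            if not dominated:
                out.append(p)
        return out

    def test_spec_example(self):
        pts = [_cand(1, 5), _cand(2, 9), _cand(3, 8)]
        front = pareto_front(pts, objective="max")
        assert {(r.base_distance, r.shape_distance) for r in front} == {
            (1.0, 5.0),
            (2.0, 9.0),
        }

    def test_single_candidate(self):
        pts = [_cand(2, 3)]
        assert pareto_front(pts, objective="max") == pts
        assert pareto_front(pts, objective="min") == pts

    def test_equal_base_keeps_best_shape_with_ties(self):
        pts = [_cand(2, 1), _cand(2, 7), _cand(2, 7), _cand(2, 4)]
        front = pareto_front(pts, objective="max")
        assert [r.shape_distance for r in front] == [7.0, 7.0]

    def test_wildtype_excluded_under_maximize(self):
        pts = [_cand(0, 0, wt=True), _cand(1, 5)]
        front = pareto_front(pts, objective="max")
        assert all(not r.is_wildtype for r in front)
        front_min = pareto_front(pts, objective="min")
        assert any(r.is_wildtype for r in front_min)

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 20)), min_size=1, max_size=40))
    def test_matches_exhaustive_dominance(self, raw):
        pts = [_cand(b, s) for b, s in raw]
        for objective in ("max", "min"):
            got = {
                (r.base_distance, r.shape_distance)
                for r in pareto_front(pts, objective=objective)
            }
            want = {
                (r.base_distance, r.shape_distance)
                for r in self.brute_force_front(pts, objective)
            }
            assert got == want

    def test_run_design_front_cross_checked(self, mgw_table):
        results = run_design(
            "ACGTACGTACGT",
            MutationSpec([4, 7]),
            DistanceConfig(features=("MGW",)),
            mgw_table,
        )
        front = pareto_front(results, objective="max")
        pool = [r for r in results if not r.is_wildtype]
        want = {
            (r.base_distance, r.shape_distance)
            for r in self.brute_force_front(pool, "max")
        }
        got = {(r.base_distance, r.shape_distance) for r in front}
        assert got == want
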