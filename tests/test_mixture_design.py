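"""Region geometry, pseudo-component coding and D-optimal selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixdes import (
    Blend,
    ComponentBound,
    Design,
    MixtureRegion,
    build_candidate_set,
    d_efficiency,
    d_optimal_select,
    from_pseudo,
    to_pseudo,
)
from mixdes import fixtures as fx
from mixdes.design import real_to_pseudo
from mixdes.errors import BoundViolationError, DegenerateRegionError, InfeasibleDesignError
from mixdes.scheffe import model_matrix


def simplex_region(q=3, total=1.0):
    return MixtureRegion(
        components=tuple(ComponentBound(f"x{i}", 0.0, total) for i in range(q)), total=total
    )


class TestPseudoCoding:
    @pytest.mark.parametrize(
        "real, expected",
        [
            ((6.00, 2.50, 2.00, 2.50, 87.00), (0.363636, 0.090909, 0.181818, 0.181818, 0.181818)),
            ((4.0, 2.0, 1.0, 1.5, 91.5), (0.0, 0.0, 0.0, 0.0, 1.0)),
            ((5.00, 2.50, 1.50, 2.25, 88.75), (0.181818, 0.090909, 0.090909, 0.136364, 0.5)),
        ],
    )
    def test_hand_worked_transforms(self, region, real, expected):
        pseudo = to_pseudo(Blend(real), region)
        assert pseudo.as_array() == pytest.approx(expected, abs=5e-7)
        assert pseudo.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4).map(tuple),
    )
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_round_trip_identity_on_random_blends(self, fracs):
        """from_pseudo inverts to_pseudo to 1e-9 anywhere inside the region."""
        region = fx.region()
        lo, hi = region.lowers, region.uppers
        amounts = lo.copy()
        amounts[:4] = lo[:4] + np.array(fracs) * (hi[:4] - lo[:4])
        amounts[4] = region.total - amounts[:4].sum()
        if not (lo[4] <= amounts[4] <= hi[4]):
            return  # outside the feasible slice of the box
        blend = Blend(tuple(amounts))
        pseudo = to_pseudo(blend, region)
        assert np.all(pseudo.as_array() >= -1e-12)
        assert pseudo.as_array().sum() == pytest.approx(1.0, abs=1e-9)
        back = from_pseudo(pseudo, region)
        assert back.as_array() == pytest.approx(amounts, abs=1e-9)

    def test_degenerate_region_rejected(self):
        region = MixtureRegion(
            components=(ComponentBound("a", 40.0, 60.0), ComponentBound("b", 60.0, 60.0)),
            total=100.0,
        )
        with pytest.raises(DegenerateRegionError):
            to_pseudo(Blend((40.0, 60.0)), region)

    def test_out_of_bounds_blend_rejected(self, region):
        with pytest.raises(BoundViolationError):
            to_pseudo(Blend((7.0, 2.0, 1.0, 1.5, 88.5)), region)


class TestCandidateSet:
    def test_study_region_grid(self, region, table1_design):
        """The bounded 5-component region yields the 81-point 3-level grid,
        and every distinct composition of the published design is on it."""
        cands = build_candidate_set(region, "quadratic")
        assert len(cands) == 81
        cset = {tuple(np.round(b.as_array(), 9)) for b in cands}
        for b in table1_design.runs:
            assert tuple(np.round(b.as_array(), 9)) in cset

    def test_unconstrained_simplex_centroid_construction(self):
        cands = build_candidate_set(simplex_region(3), "linear")
        assert len(cands) == 7  # 3 vertices + 3 edge midpoints + centroid
        arrs = sorted(tuple(np.round(b.as_array(), 9)) for b in cands)
        assert (1.0, 0.0, 0.0) in {tuple(sorted(a, reverse=True)) for a in arrs}
        assert any(np.allclose(a, (1 / 3, 1 / 3, 1 / 3)) for a in arrs)

    def test_collapsed_dimension_gives_segment(self):
        region = MixtureRegion(
            components=(
                ComponentBound("a", 0.2, 0.8),
                ComponentBound("b", 0.2, 0.8),
                ComponentBound("c", 0.0, 0.0),
            ),
            total=1.0,
        )
        cands = build_candidate_set(region)
        pts = sorted(b.as_array()[0] for b in cands)
        assert pts == pytest.approx([0.2, 0.5, 0.8])  # endpoints + midpoint


class TestDEfficiency:
    def test_three_vertex_identity_design(self):
        """Three simplex vertices under a 3-term linear model give X = I,
        so det(X'X/3)^(1/3) = 1/3 exactly."""
        region = simplex_region(3)
        runs = [Blend((1.0, 0.0, 0.0)), Blend((0.0, 1.0, 0.0)), Blend((0.0, 0.0, 1.0))]
        des = Design(runs=runs, region=region)
        assert d_efficiency(des, "linear") == pytest.approx(1 / 3, rel=1e-12)

    def test_reordering_invariance(self, table1_design, region):
        eff = d_efficiency(table1_design, "quadratic")
        assert eff > 0
        shuffled = Design(runs=list(reversed(table1_design.runs)), region=region)
        assert d_efficiency(shuffled, "quadratic") == pytest.approx(eff, rel=1e-10)

    def test_rank_deficient_design_reports_zero(self):
        region = simplex_region(3)
        runs = [Blend((1.0, 0.0, 0.0))] * 3
        with pytest.warns(UserWarning, match="rank-deficient"):
            assert d_efficiency(Design(runs=runs, region=region), "linear") == 0.0


class TestDOptimalSelect:
    def test_no_freedom_returns_candidates_in_order(self):
        region = simplex_region(3)
        cands = [Blend((1.0, 0.0, 0.0)), Blend((0.0, 1.0, 0.0)), Blend((0.0, 0.0, 1.0))]
        des = d_optimal_select(cands, "linear", 3, 0, seed=1, region=region)
        assert [b.amounts for b in des.runs] == [b.amounts for b in cands]

    def test_vertices_beat_centroid_for_linear_model(self):
        """With 4 candidates (3 vertices + centroid) and 3 slots, the vertices
        maximize det(X'X); verified against exhaustive enumeration."""
        region = simplex_region(3)
        cands = [
            Blend((1.0, 0.0, 0.0)),
            Blend((0.0, 1.0, 0.0)),
            Blend((0.0, 0.0, 1.0)),
            Blend((1 / 3, 1 / 3, 1 / 3)),
        ]
        des = d_optimal_select(cands, "linear", 3, 0, seed=0, region=region)
        chosen = {b.amounts for b in des.runs}
        assert chosen == {c.amounts for c in cands[:3]}

    def test_exchange_matches_exhaustive_search(self):
        """On small instances the point-exchange determinant is within 1% of
        the exhaustive-search optimum (usually equal)."""
        region = MixtureRegion(
            components=(
                ComponentBound("a", 0.1, 0.5),
                ComponentBound("b", 0.1, 0.5),
                ComponentBound("c", 0.2, 0.8),
            ),
            total=1.0,
        )
        cands = build_candidate_set(region, "quadratic")
        assert len(cands) <= 12
        for order, n_total in [("linear", 4), ("quadratic", 6)]:
            des = d_optimal_select(cands, order, n_total, 0, seed=7, region=region)
            got = d_efficiency(des, order) ** len(
                model_matrix(des, order)[0]
            )  # back to det scale (det(X'X/n))
            best = 0.0
            for subset in itertools.combinations(range(len(cands)), n_total):
                sub = Design(runs=[cands[i] for i in subset], region=region)
                best = max(best, d_efficiency(sub, order) ** len(model_matrix(sub, order)[0]))
            assert got >= 0.99 * best

    def test_matches_or_beats_published_design(self, region, table1_design):
        cands = build_candidate_set(region, "quadratic")
        des = d_optimal_select(cands, "quadratic", 24, 4, seed=42, region=region, n_restarts=3)
        assert des.n_runs == 24
        # four replicate slots at the overall centroid
        cen = tuple(region.centroid().amounts)
        assert sum(1 for b in des.runs if b.amounts == cen) >= 4
        assert d_efficiency(des, "quadratic") >= d_efficiency(table1_design, "quadratic")

    def test_run_budget_below_term_count_rejected(self, region):
        cands = build_candidate_set(region, "quadratic")
        with pytest.raises(InfeasibleDesignError):
            d_optimal_select(cands, "quadratic", 10, 0, seed=0, region=region)


def test_replicate_groups_partition_runs(table1_design):
    """Auto-detected groups partition all 24 runs; the centroid appears four
    times and one off-centroid composition twice."""
    groups = table1_design.replicate_groups
    assert sorted(i for g in groups for i in g) == list(range(24))
    sizes = sorted(len(g) for g in table1_design.replicated_groups())
    assert sizes == [2, 4]
    centroid_group = max(groups, key=len)
    arr = table1_design.as_array()
    assert np.allclose(arr[centroid_group], (5.00, 2.50, 1.50, 2.25, 88.75))


def test_pseudo_coding_of_full_design_sums_to_one(table1_design, region):
    pseudo = real_to_pseudo(table1_design.as_array(), region)
    assert np.allclose(pseudo.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(pseudo >= -1e-12)
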