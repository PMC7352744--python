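"""ANOVA decomposition, fit statistics and model selection."""

import numpy as np
import pytest

from mixdes import (
    Design,
    adequate_precision,
    adj_r_squared,
    anova,
    fit,
    predicted_vs_actual,
    r_squared,
    select_model,
)
from mixdes import fixtures as fx
from mixdes.synthetic import SimulationSpec, simulate_design_responses


class TestRSquared:
    def test_particle_size_fits_match_reported_values(self, ps_dtx_fit, ps_ccm_fit):
        assert r_squared(ps_dtx_fit) == pytest.approx(0.9922, abs=0.005)
        assert r_squared(ps_ccm_fit) == pytest.approx(0.9984, abs=0.005)

    def test_vmd_fit_matches_reported_value(self, vmd_dtx_fit):
        assert r_squared(vmd_dtx_fit) == pytest.approx(0.6894, abs=0.01)

    def test_perfect_interpolation_gives_unity(self, table1_design, published_models):
        truth = published_models["ps_dtx"]
        y = truth.predict_many(table1_design.as_array())
        assert r_squared(fit(table1_design, y, "quadratic")) == pytest.approx(1.0, abs=1e-10)

    def test_adjusted_below_raw(self, ps_dtx_fit):
        assert adj_r_squared(ps_dtx_fit) < r_squared(ps_dtx_fit)


class TestAdequatePrecision:
    def test_dtx_fits(self, ps_dtx_fit, vmd_dtx_fit):
        """Signal-to-noise of the two docetaxel fits: ~35.6 for particle size,
        ~11.8 for aerosol size (refit from 2-dp responses shifts them a few %)."""
        assert adequate_precision(ps_dtx_fit) == pytest.approx(35.58, rel=0.05)
        assert adequate_precision(vmd_dtx_fit) == pytest.approx(11.80, rel=0.05)

    def test_all_study_fits_clear_the_threshold(self, ps_dtx_fit, ps_ccm_fit, vmd_dtx_fit):
        for fr in (ps_dtx_fit, ps_ccm_fit, vmd_dtx_fit):
            assert adequate_precision(fr) > 4.0

    def test_noiseless_fit_is_infinite(self, table1_design, published_models):
        y = published_models["ps_dtx"].predict_many(table1_design.as_array())
        fr = fit(table1_design, y, "quadratic")
        with pytest.warns(UserWarning, match="infinite"):
            assert adequate_precision(fr) == np.inf


class TestAnova:
    def test_model_row_matches_reported_mean_square(self, ps_dtx_anova):
        model_row = ps_dtx_anova.row("Model")
        assert model_row.dof == 14
        assert model_row.ms == pytest.approx(37.87, rel=0.005)
        assert model_row.p_value < 1e-4

    def test_model_f_against_direct_ratio(self, ps_dtx_fit, ps_dtx_anova):
        f = (ps_dtx_fit.ss_model / 14) / (ps_dtx_fit.ss_residual / 9)
        assert ps_dtx_anova.row("Model").f_value == pytest.approx(f, rel=1e-12)

    def test_pure_error_from_centroid_replicates_by_hand(self):
        """Within-group SS/df of the four centroid particle sizes
        (102.93, 102.89, 103.88, 103.76) is 0.279 (the paper rounds to 0.27)."""
        y = np.array([102.93, 102.89, 103.88, 103.76])
        ms = ((y - y.mean()) ** 2).sum() / 3
        assert ms == pytest.approx(0.279, abs=0.001)

    def test_lack_of_fit_split(self, ps_dtx_fit, ps_dtx_anova):
        lof = ps_dtx_anova.row("Lack of fit")
        pe = ps_dtx_anova.row("Pure error")
        res = ps_dtx_anova.row("Residual")
        assert lof.ss + pe.ss == pytest.approx(res.ss, rel=1e-6)
        assert lof.dof + pe.dof == res.dof
        # not significant: the quadratic surface explains the non-replicate runs
        assert lof.p_value > 0.05

    def test_term_partial_ss_bounded_by_model_ss(self, ps_dtx_anova, ps_dtx_fit):
        term_rows = [
            r for r in ps_dtx_anova.rows
            if r.label not in ("Model", "Residual", "Lack of fit", "Pure error")
        ]
        assert len(term_rows) == 10  # all pairwise interactions of 5 components
        for r in term_rows:
            assert 0 <= r.ss <= ps_dtx_fit.ss_model
            assert 0 <= r.p_value <= 1

    def test_interaction_term_f_matches_reported_scale(self, ps_dtx_anova):
        """The AB deletion test reproduces the reported mean square within the
        rounding of the printed responses (printed: MS 3.05, F 6.54)."""
        ab = ps_dtx_anova.row("AB")
        assert ab.ms == pytest.approx(3.05, rel=0.2)
        assert ab.f_value == pytest.approx(6.54, rel=0.25)

    def test_dof_accounting(self, ps_dtx_anova):
        model = ps_dtx_anova.row("Model")
        residual = ps_dtx_anova.row("Residual")
        assert model.dof + residual.dof == 24 - 1

    def test_no_replicates_drops_lack_of_fit(self, region, table1_responses):
        distinct = [fx.design().runs[i] for i in range(10)]
        des = Design(runs=distinct, region=region)
        y = table1_responses["vmd_dtx"].to_numpy()[:10]
        with pytest.warns(UserWarning, match="no replicate"):
            table = anova(fit(des, y, "linear"), des)
        with pytest.raises(KeyError):
            table.row("Lack of fit")


class TestSelectModel:
    def test_particle_size_selects_quadratic(self, table1_design, table1_responses):
        chosen, candidates = select_model(table1_design, table1_responses["ps_dtx"])
        assert chosen == "quadratic"
        assert "special_cubic" not in candidates  # 25 terms exceed 24 runs

    def test_vmd_selects_linear(self, table1_design, table1_responses):
        chosen, _ = select_model(table1_design, table1_responses["vmd_dtx"])
        assert chosen == "linear"

    def test_linear_truth_recovered_under_noise(self, table1_design, published_models):
        """With a linear ground truth and small noise, the selection rule
        picks linear in at least 90% of seeded repetitions."""
        truth = published_models["vmd_dtx"]
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            y = simulate_design_responses(
                SimulationSpec(truth, noise_sd=0.05, seed=seed), table1_design
            )
            chosen, _ = select_model(table1_design, y)
            hits += chosen == "linear"
        assert hits / n_rep >= 0.90


class TestPredictedVsActual:
    def test_noiseless_fit_pairs_equal_with_unit_slope(self, table1_design, published_models):
        y = published_models["ps_dtx"].predict_many(table1_design.as_array())
        frame, slope = predicted_vs_actual(fit(table1_design, y, "quadratic"))
        assert np.allclose(frame["actual"], frame["predicted"])
        assert slope == pytest.approx(1.0, abs=1e-9)

    def test_particle_size_residual_scale(self, ps_dtx_fit):
        """All particle-size residuals stay below 2.5 nm, the scale implied by
        a residual mean square near 0.47 nm²."""
        frame, slope = predicted_vs_actual(ps_dtx_fit)
        assert np.max(np.abs(frame["actual"] - frame["predicted"])) < 2.5
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_vmd_slope_degraded_relative_to_particle_size(self, vmd_dtx_fit, ps_dtx_fit):
        _, slope_vmd = predicted_vs_actual(vmd_dtx_fit)
        _, slope_ps = predicted_vs_actual(ps_dtx_fit)
        assert slope_vmd < slope_ps
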