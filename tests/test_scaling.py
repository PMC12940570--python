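"""Power-law and plane fits on the dissipation plane."""

import numpy as np
import pandas as pd
import pytest

from cycledissip import (
    EnsembleSpec,
    ImposedScaling,
    compare_slopes,
    fit_plane,
    fit_power_law,
    generate_scaling_ensemble,
)


def exact_law_frame(n=40, slope=0.75, intercept=2.0, seed=0):
    rng = np.random.default_rng(seed)
    log_x = rng.uniform(2, 9, n)
    kcat = 10.0 ** rng.uniform(-1, 5, n)
    eff = 10.0**log_x
    return pd.DataFrame(
        {
            "name": [f"e{i}" for i in range(n)],
            "kcat": kcat,
            "km": kcat / eff,
            "kcat_over_km": eff,
            "dissipation_rt": 10.0 ** (intercept + slope * log_x),
            "forward_driven": True,
        }
    )


class TestPowerLaw:
    def test_exact_law_recovered_perfectly(self):
        fit = fit_power_law(exact_law_frame(), "kcat_over_km")
        assert fit.slope == pytest.approx(0.75, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_ci95[0] <= fit.slope <= fit.slope_ci95[1]

    def test_noisy_ensemble_recovery_within_ci(self):
        spec = EnsembleSpec(seed=11, n_enzymes=75, scaling=ImposedScaling(slope=0.72, scatter_sd=0.5))
        fit = fit_power_law(generate_scaling_ensemble(spec), "kcat_over_km")
        lo, hi = fit.slope_ci95
        assert lo < 0.72 < hi
        assert fit.n == 75

    def test_backward_driven_rows_excluded(self):
        frame = exact_law_frame()
        frame.loc[:4, "forward_driven"] = False
        fit = fit_power_law(frame, "kcat_over_km")
        assert fit.n == len(frame) - 5
        assert fit.n_rejected == 5

    def test_nonpositive_rows_rejected_with_reason(self, caplog):
        frame = exact_law_frame()
        frame.loc[0, "dissipation_rt"] = 0.0
        with caplog.at_level("WARNING"):
            fit = fit_power_law(frame, "kcat_over_km")
        assert fit.n == len(frame) - 1
        assert any("nonpositive" in rec.message for rec in caplog.records)

    def test_too_few_rows_fails(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_power_law(exact_law_frame(n=2), "kcat_over_km")

    def test_row_order_invariance(self):
        frame = exact_law_frame(seed=3)
        shuffled = frame.sample(frac=1.0, random_state=1)
        a = fit_power_law(frame, "kcat")
        b = fit_power_law(shuffled, "kcat")
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-12)

    def test_predictor_rescaling_shifts_only_intercept(self):
        frame = exact_law_frame(seed=4)
        rescaled = frame.copy()
        rescaled["kcat_over_km"] *= 1e3  # unit change M^-1 -> mM^-1
        a = fit_power_law(frame, "kcat_over_km")
        b = fit_power_law(rescaled, "kcat_over_km")
        assert b.slope == pytest.approx(a.slope, rel=1e-10)
        assert b.intercept == pytest.approx(a.intercept - 3 * a.slope, rel=1e-9)

    def test_orthogonal_mode_agrees_on_noiseless_data(self):
        fit = fit_power_law(exact_law_frame(), "kcat_over_km", method="orthogonal")
        assert fit.slope == pytest.approx(0.75, abs=1e-10)


class TestSlopeComparison:
    def test_identical_predictors_give_zero_delta(self):
        frame = exact_law_frame()
        frame["kcat"] = frame["kcat_over_km"]
        cmp_res = compare_slopes(frame, n_boot=200, seed=1)
        assert cmp_res.delta_slope == pytest.approx(0.0, abs=1e-12)
        assert cmp_res.ci95 == pytest.approx((0.0, 0.0), abs=1e-12)
        assert not cmp_res.significant

    def test_seeded_reproducibility(self):
        frame = exact_law_frame(seed=5)
        a = compare_slopes(frame, n_boot=500, seed=42)
        b = compare_slopes(frame, n_boot=500, seed=42)
        assert a.ci95 == b.ci95

    def test_requires_seed_and_enough_draws(self):
        frame = exact_law_frame()
        with pytest.raises(ValueError, match="seed"):
            compare_slopes(frame, n_boot=200)
        with pytest.raises(ValueError, match="n_boot"):
            compare_slopes(frame, n_boot=50, seed=1)

    def test_equal_true_slopes_ci_covers_zero(self):
        # both predictors carry the same true slope: the bootstrap CI of
        # the difference should cover 0 in most seeded meta-replicates
        rng = np.random.default_rng(77)
        covered = 0
        n_rep = 20
        for rep in range(n_rep):
            log_x = rng.uniform(2, 9, 60)
            y = 1.0 + 0.8 * log_x + rng.normal(0, 0.3, 60)
            x2 = log_x + rng.normal(0, 0.05, 60)  # nearly the same predictor
            frame = pd.DataFrame(
                {
                    "kcat_over_km": 10.0**log_x,
                    "kcat": 10.0**x2,
                    "km": 10.0 ** (x2 - log_x),
                    "dissipation_rt": 10.0**y,
                }
            )
            res = compare_slopes(frame, n_boot=300, seed=rep)
            covered += res.ci95[0] <= 0.0 <= res.ci95[1]
        assert covered >= int(0.8 * n_rep)

    def test_distinct_slopes_detected(self):
        # response built with slope 0.72 against efficiency; kcat is an
        # independent draw, so its slope is near zero and the difference
        # should be flagged significant
        spec = EnsembleSpec(seed=9, n_enzymes=75, scaling=ImposedScaling(slope=0.72, scatter_sd=0.3))
        res = compare_slopes(generate_scaling_ensemble(spec), n_boot=1000, seed=2)
        assert res.significant


class TestPlane:
    def test_exactly_planar_data_has_zero_thickness(self):
        frame = exact_law_frame()
        frame["dissipation_rt"] = 10.0 ** (
            1.5 + 0.9 * np.log10(frame["kcat"]) - 0.2 * np.log10(frame["km"])
        )
        fit = fit_plane(frame)
        assert fit.alpha == pytest.approx(0.9, abs=1e-10)
        assert fit.beta == pytest.approx(-0.2, abs=1e-10)
        assert fit.gamma == pytest.approx(1.5, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_plane_recovery(self):
        rng = np.random.default_rng(8)
        n = 100
        lk = rng.uniform(-1, 6, n)
        lm = rng.uniform(-7, -2, n)
        ld = 0.5 + 0.8 * lk - 0.3 * lm + rng.normal(0, 0.2, n)
        frame = pd.DataFrame({"kcat": 10.0**lk, "km": 10.0**lm, "dissipation_rt": 10.0**ld})
        fit = fit_plane(frame)
        assert fit.alpha == pytest.approx(0.8, abs=0.1)
        assert fit.beta == pytest.approx(-0.3, abs=0.1)
        assert fit.residual_sd == pytest.approx(0.2, abs=0.05)

    def test_rank_deficient_predictors_flagged(self):
        frame = exact_law_frame()
        frame["km"] = frame["kcat"]  # collinear on the log scale
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_plane(frame)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_plane(exact_law_frame(n=3))
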