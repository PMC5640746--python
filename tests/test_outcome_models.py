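"""Outcome models: ICC arithmetic, estimator identities, stepwise behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from carenet.outcome_models import (
    fit_continuity_bivariate,
    fit_continuity_stepwise,
    fit_six_model,
    fit_six_multinomial,
    icc,
    render_model_tables,
    screen_candidates,
)
from carenet.synthetic_data import SimulationConfig, generate_study

from conftest import fit_inputs


@pytest.fixture(scope="module")
def planted_density_study():
    cfg = SimulationConfig(
        n_networks=10,
        size_min=15,
        size_max=40,
        patients_per_network=60,
        cluster_size=10,
        recruitment_clusters=(
            "primary_care",
            "crisis_outreach",
            "psychiatric_ward",
            "psychiatric_ward",
            "sheltered_housing",
            "social_services",
        ),
        continuity_effects={"density": 0.5},
        six_effects={},
        seed=11,
    )
    return fit_inputs(generate_study(cfg))


class TestIcc:
    def test_equal_components_give_half(self):
        assert icc(2.0, 2.0) == pytest.approx(0.5)

    def test_zero_between_variance_gives_zero(self):
        assert icc(0.0, 3.7) == 0.0

    def test_ordinal_uses_logistic_within_variance(self):
        assert icc(1.0, ordinal=True) == pytest.approx(1.0 / (1.0 + math.pi**2 / 3.0))

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(0.0, 0.0)

    def test_ordinal_rejects_explicit_within(self):
        with pytest.raises(ValueError):
            icc(1.0, 2.0, ordinal=True)


class TestStandardizationIdentity:
    def test_standardized_beta_equals_scaled_raw_coefficient(self, planted_density_study):
        import statsmodels.api as sm

        from carenet.outcome_models import _design

        patients, rows = planted_density_study
        res = fit_continuity_bivariate(patients, "density", rows, random_intercept=False)

        df, X, zcols = _design(patients, rows, ["density"], "continuity")
        raw = df.merge(rows[["density"]], left_on="network_id", right_index=True)
        X_raw = X.copy()
        X_raw[zcols[0]] = raw["density"].to_numpy()
        fit_raw = sm.OLS(df["y"].to_numpy(), sm.add_constant(X_raw.to_numpy(dtype=float))).fit()
        beta_raw = fit_raw.params[1]  # first column after the constant
        sd_x = rows["density"].std(ddof=1)
        sd_y = df["y"].std(ddof=1)
        assert res.estimates["density"] == pytest.approx(beta_raw * sd_x / sd_y, abs=1e-8)


class TestBivariate:
    def test_planted_effect_detected(self, planted_density_study):
        patients, rows = planted_density_study
        res = fit_continuity_bivariate(patients, "density", rows)
        assert res.pvalues["density"] < 0.05
        assert res.estimates["density"] > 0.2
        assert 0.0 <= res.icc <= 1.0
        assert res.n_groups == 10

    def test_constant_metric_rejected(self, planted_density_study):
        patients, rows = planted_density_study
        rows = rows.copy()
        rows["const_metric"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            fit_continuity_bivariate(patients, "const_metric", rows)

    def test_zero_variance_networks_give_tiny_icc(self):
        cfg = SimulationConfig(
            n_networks=8,
            size_min=15,
            size_max=30,
            patients_per_network=100,
            cluster_size=20,
            recruitment_clusters=("primary_care", "crisis_outreach", "psychiatric_ward", "sheltered_housing", "social_services"),
            continuity_effects={},
            six_effects={},
            network_intercept_sd=0.0,
            seed=5,
        )
        patients, rows = fit_inputs(generate_study(cfg))
        res = fit_continuity_bivariate(patients, "density", rows)
        assert res.icc <= 0.01


class TestStepwise:
    def test_single_significant_candidate_selected(self, planted_density_study):
        patients, rows = planted_density_study
        res = fit_continuity_stepwise(patients, ["density"], rows)
        assert res.selected == ["density"]

    def test_duplicate_column_enters_once(self, planted_density_study):
        patients, rows = planted_density_study
        rows = rows.copy()
        rows["density_copy"] = rows["density"]
        res = fit_continuity_stepwise(patients, ["density", "density_copy"], rows)
        assert len(res.selected) == 1
        assert res.selected[0] in ("density", "density_copy")

    def test_empty_candidates_give_controls_only_model(self, planted_density_study):
        patients, rows = planted_density_study
        with pytest.warns(UserWarning, match="empty candidate"):
            res = fit_continuity_stepwise(patients, [], rows)
        assert res.selected == []
        assert "age" in res.estimates

    def test_aic_improves_when_true_covariate_added(self, planted_density_study):
        patients, rows = planted_density_study
        with pytest.warns(UserWarning):
            controls_only = fit_continuity_stepwise(patients, [], rows)
        with_metric = fit_continuity_stepwise(patients, ["density"], rows)
        assert with_metric.aic <= controls_only.aic

    def test_screening_feeds_selection(self, planted_density_study):
        patients, rows = planted_density_study
        cands = screen_candidates(patients, ["density", "dissimilarity_index"], rows)
        assert "density" in cands
        res = fit_continuity_stepwise(patients, cands, rows)
        assert set(res.selected) <= set(cands)

    def test_selection_power_for_planted_effect(self):
        # planted 0.2-SD effect vs a null metric: the planted one should be
        # selected in >= 90% of replicate studies
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            cfg = SimulationConfig(continuity_effects={"density": 0.2}, six_effects={}, seed=20_000 + rep)
            patients, rows = fit_inputs(generate_study(cfg))
            res = fit_continuity_stepwise(patients, ["density", "dissimilarity_index"], rows)
            hits += "density" in res.selected
        assert hits >= 0.90 * n_reps


class TestSixModel:
    def test_null_effects_give_odds_ratios_near_one(self):
        # no planted effects and no between-network outcome variance: the
        # estimate is pure patient-level sampling noise around OR = 1
        ors = []
        for rep in range(3):
            cfg = SimulationConfig(
                continuity_effects={},
                six_effects={},
                six_network_intercept_sd=0.0,
                seed=31_000 + rep,
            )
            patients, rows = fit_inputs(generate_study(cfg))
            res = fit_six_model(patients, ["density"], rows, "bivariate")
            ors.append(res.estimates["density"])
        assert 0.9 <= np.mean(ors) <= 1.1

    def test_bivariate_requires_single_metric(self, planted_density_study):
        patients, rows = planted_density_study
        with pytest.raises(ValueError, match="exactly one"):
            fit_six_model(patients, ["density", "clustering"], rows, "bivariate")

    def test_odds_ratios_positive_and_icc_in_range(self, planted_density_study):
        patients, rows = planted_density_study
        res = fit_six_model(patients, ["density"], rows, "bivariate")
        assert all(v > 0 for v in res.estimates.values())
        assert 0.0 <= res.icc <= 1.0
        assert res.kind == "ordinal"

    def test_multivariate_forces_all_metrics(self, planted_density_study):
        patients, rows = planted_density_study
        res = fit_six_model(patients, ["density", "clustering"], rows, "multivariate")
        assert res.selected == ["density", "clustering"]
        assert "density" in res.estimates and "clustering" in res.estimates

    def test_multinomial_check_model_runs(self, planted_density_study):
        patients, rows = planted_density_study
        table = fit_six_multinomial(patients, ["density"], rows)
        assert np.isfinite(table.to_numpy()).all()
        assert (table.to_numpy() > 0).all()


class TestRendering:
    def test_csv_round_trip_preserves_numbers(self, tmp_path, planted_density_study):
        patients, rows = planted_density_study
        r1 = fit_continuity_bivariate(patients, "density", rows)
        r2 = fit_continuity_stepwise(patients, ["density"], rows)
        table, text = render_model_tables([r1, r2])
        path = tmp_path / "models.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table)
        assert "std beta" in text and "ICC" in text

    def test_footer_rows_present_per_model(self, planted_density_study):
        patients, rows = planted_density_study
        table, _ = render_model_tables([fit_continuity_bivariate(patients, "density", rows)])
        assert set(table[table["row"].isin(["icc", "aic"])]["row"]) == {"icc", "aic"}
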