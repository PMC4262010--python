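"""Mixed-model toolkit: fitting, LRT, structure selection, simplification, stages."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quantweb import (
    GeneratorConfig,
    ModelSpec,
    backward_simplify,
    collection_metrics,
    fit_lmm,
    generate_collection,
    lrt,
    residualise,
    select_random_structure,
    stage1_size_regressions,
)
from quantweb.inference import metric_transform


def simulate_lmm(n_studies=12, n_per=6, beta=1.0, intercept_sd=0.3, noise_sd=0.3,
                 slope_sd=0.0, seed=0):
    """Draw observations from y = 1 + beta*logm + b_study(+ s_study*logm) + eps."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_studies):
        b = rng.normal(0, intercept_sd)
        sl = rng.normal(0, slope_sd)
        for k in range(n_per):
            logm = rng.uniform(1, 8)
            y = 1.0 + beta * logm + b + sl * logm + rng.normal(0, noise_sd)
            rows.append({"study_id": f"s{s}", "network_id": f"s{s}_n{k}",
                         "logm": logm, "y": y})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_constant_response(self):
        df = simulate_lmm(beta=0.0, intercept_sd=0.0, noise_sd=0.0)
        df["y"] = 3.0
        fit = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        assert fit.params["logm"] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.resid_conditional, 0.0, atol=1e-6)

    def test_slope_recovery(self):
        df = simulate_lmm(n_studies=30, n_per=5, beta=1.0, seed=42)
        fit = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        assert fit.params["logm"] == pytest.approx(1.0, abs=0.1)

    def test_aicc_exceeds_aic(self):
        df = simulate_lmm(seed=1)
        fit = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        assert fit.aicc > fit.aic
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.k_params)

    def test_residuals_centred(self):
        df = simulate_lmm(seed=2)
        fit = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        assert abs(np.mean(fit.resid_marginal)) < 1e-6 * np.std(df["y"])

    def test_single_group_falls_back_to_ols(self):
        df = simulate_lmm(n_studies=1, seed=3)
        with pytest.warns(UserWarning, match="one level"):
            fit = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        assert fit.spec.random == "none"


class TestSelectRandomStructure:
    def test_prefers_simple_when_no_slope_variance(self):
        df = simulate_lmm(slope_sd=0.0, seed=4)
        structure, _ = select_random_structure(df, ModelSpec(response="y", fixed=["logm"]))
        assert structure == "intercept"

    def test_detects_strong_random_slopes(self):
        df = simulate_lmm(n_studies=20, n_per=8, slope_sd=0.8, noise_sd=0.2, seed=5)
        structure, _ = select_random_structure(df, ModelSpec(response="y", fixed=["logm"]))
        assert structure == "slope"

    def test_parsimony_on_identical_models(self):
        # with no group structure at all, the slope model cannot beat the
        # intercept model by more than 1 AIC unit
        df = simulate_lmm(intercept_sd=0.0, slope_sd=0.0, seed=6)
        structure, _ = select_random_structure(df, ModelSpec(response="y", fixed=["logm"]))
        assert structure == "intercept"


class TestLrt:
    def test_identical_loglik_gives_p_one(self):
        df = simulate_lmm(seed=7)
        full = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        reduced_same = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
        reduced_same.k_fe -= 1  # declare nesting with equal fit
        chi2, df_, p = lrt(full, reduced_same)
        assert chi2 == 0.0 and p == 1.0

    def test_chi_square_quantile_identity(self):
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_reml_refused(self):
        df = simulate_lmm(seed=8)
        full = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="REML")
        reduced = fit_lmm(df, ModelSpec(response="y", fixed=[]), method="REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(full, reduced)

    def test_type_one_error_calibration(self):
        """Null rejections of the logm LRT at alpha=.05 stay near nominal."""
        rejections = 0
        n_sim = 120
        for s in range(n_sim):
            df = simulate_lmm(n_studies=10, n_per=5, beta=0.0, seed=1000 + s)
            full = fit_lmm(df, ModelSpec(response="y", fixed=["logm"]), method="ML")
            reduced = fit_lmm(df, ModelSpec(response="y", fixed=[]), method="ML")
            _, _, p = lrt(full, reduced)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_sim <= 0.12


class TestBackwardSimplify:
    def _data_with_terms(self, beta_x=0.0, beta_z=0.0, beta_xz=0.0, seed=0, n=150):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "x": rng.uniform(-1, 1, n),
            "z": rng.uniform(-1, 1, n),
            "study_id": [f"s{i % 10}" for i in range(n)],
        })
        b = {g: rng.normal(0, 0.2) for g in df["study_id"].unique()}
        df["y"] = (beta_x * df["x"] + beta_z * df["z"] + beta_xz * df["x"] * df["z"]
                   + df["study_id"].map(b) + rng.normal(0, 0.3, n))
        return df

    def test_null_terms_all_removed(self):
        df = self._data_with_terms(seed=1)
        spec = ModelSpec(response="y", fixed=["x", "z", "x:z"])
        res = backward_simplify(df, spec)
        assert res.retained_terms == []
        assert res.final_reml.method == "REML"

    def test_strong_term_retained(self):
        df = self._data_with_terms(beta_x=2.0, seed=2)
        res = backward_simplify(df, ModelSpec(response="y", fixed=["x", "z", "x:z"]))
        assert "x" in res.retained_terms
        assert "z" not in res.retained_terms

    def test_marginality_keeps_parents_of_interaction(self):
        df = self._data_with_terms(beta_xz=3.0, seed=3)
        res = backward_simplify(df, ModelSpec(response="y", fixed=["x", "z", "x:z"]))
        assert "x:z" in res.retained_terms
        assert {"x", "z"} <= set(res.retained_terms)

    def test_removal_path_is_logged(self):
        df = self._data_with_terms(seed=4)
        res = backward_simplify(df, ModelSpec(response="y", fixed=["x", "z", "x:z"]))
        assert any(e["removed"] for e in res.path)
        assert all({"term", "chi2", "df", "p"} <= set(e) for e in res.path)


class TestTransforms:
    @pytest.mark.parametrize(
        "stage,metric,expected",
        [(1, "h2prime", "identity"), (1, "modularity", "log"),
         (2, "modularity", "identity"), (3, "h2prime", "identity"),
         (4, "connectance", "identity"), (4, "generality", "log")],
    )
    def test_per_stage_rules(self, stage, metric, expected):
        assert metric_transform(stage, metric) == expected


@pytest.fixture(scope="module")
def sampling_collection_metrics():
    cfg = GeneratorConfig(seed=21, shared_structure=True, n_studies=10,
                          networks_per_study=(3, 6), m_range=(20, 5000))
    coll, _, _ = generate_collection(cfg)
    return collection_metrics(coll)


class TestStage1:
    def test_size_effect_on_generality_recovered(self, sampling_collection_metrics):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage1_size_regressions(sampling_collection_metrics).table
        row = rep[rep["metric"] == "generality"].iloc[0]
        assert row["direction"] == "+"
        assert row["p"] < 0.05

    def test_report_covers_available_metrics(self, sampling_collection_metrics):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage1_size_regressions(sampling_collection_metrics).table
        assert {"linkage_density", "connectance", "generality",
                "vulnerability", "h2prime"} <= set(rep["metric"])
        assert (rep["df"] >= 1).all()
        assert (rep["chi2"] >= 0).all()

    def test_single_study_falls_back(self):
        cfg = GeneratorConfig(seed=22, n_studies=1, networks_per_study=(6, 6))
        coll, _, _ = generate_collection(cfg)
        df = collection_metrics(coll)
        with pytest.warns(UserWarning, match="one level"):
            rep = stage1_size_regressions(df).table
        assert (rep["random_structure"] == "none").all()


class TestResidualise:
    def test_constant_metric_gives_zero_residuals(self):
        df = simulate_lmm(seed=9).rename(columns={"y": "generality"})
        df["generality"] = 2.0
        df["m"] = np.exp(df.pop("logm"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = residualise(df, "generality")
        assert np.allclose(out["resid"], 0.0, atol=1e-6)

    def test_residuals_uncorrelated_with_logm(self):
        df = simulate_lmm(n_studies=20, n_per=6, beta=0.8, seed=10)
        df["generality"] = np.exp(df["y"])
        df["m"] = np.exp(df["logm"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = residualise(df, "generality")
        r = stats.pearsonr(out["logm"], out["resid"]).statistic
        assert abs(r) < 0.05
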