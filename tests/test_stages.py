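"""The later analysis stages: subsampled, standardised, Delta and residual models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from quantweb import (
    GeneratorConfig,
    collection_delta,
    collection_metrics,
    generate_collection,
    generate_network,
    generate_taxonomy,
    rarefaction_curve,
    stage2_subsample_regressions,
    stage3_standardised_regressions,
    stage4_delta_regressions,
    stage5_residual_analysis,
    standardise,
)


@pytest.fixture(scope="module")
def curves_table():
    """Rarefaction curves for six species-rich networks in two studies."""
    rng = np.random.default_rng(17)
    frames = []
    for k in range(6):
        net = generate_network(
            100, 50, 600, 0.5, rng, network_id=f"n{k}", study_id=f"s{k % 2}",
            host_abundance_sd=1.5, keep_empty_hosts=False,
        )
        res = rarefaction_curve(net, reps=30, seed=k, net_index=k)
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


class TestStage2:
    def test_sign_pattern_of_subsampled_regressions(self, curves_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage2_subsample_regressions(curves_table).table.set_index("metric")
        for metric in ("generality", "vulnerability", "linkage_density"):
            assert rep.loc[metric, "direction"] == "+"
            assert rep.loc[metric, "p"] < 0.05
        assert rep.loc["connectance", "direction"] == "-"
        assert rep.loc["connectance", "p"] < 0.05
        # scale independence of H2' is about effect size: replicate means
        # are so precise that even a negligible slope reaches significance
        assert abs(rep.loc["h2prime", "slope"]) < 0.05

    def test_transforms_follow_recipe(self, curves_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage2_subsample_regressions(curves_table).table.set_index("metric")
        assert rep.loc["h2prime", "transform"] == "identity"
        assert rep.loc["generality", "transform"] == "log"


class TestStage3:
    @pytest.fixture(scope="class")
    def std_table(self):
        cfg = GeneratorConfig(seed=31, shared_structure=True, n_studies=8,
                              networks_per_study=(3, 5), m_range=(70, 5000))
        coll, _, _ = generate_collection(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, excluded = standardise(coll, std_size=65, reps=25,
                                          include_modularity=False, seed=0)
        return table

    def test_pure_sampling_gives_null(self, std_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage3_standardised_regressions(std_table).table
        n_null = (rep["p"] > 0.05).sum()
        assert n_null >= len(rep) - 1

    def test_detects_real_size_structure_coupling(self):
        """Power check: metrics built to depend on original size are flagged."""
        rng = np.random.default_rng(5)
        rows = []
        for k in range(60):
            m = float(np.exp(rng.uniform(np.log(70), np.log(5000))))
            rows.append({
                "network_id": f"n{k}", "study_id": f"s{k % 10}",
                "original_m": m,
                "generality": float(np.exp(0.3 * np.log(m) + rng.normal(0, 0.1))),
            })
        df = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage3_standardised_regressions(df).table
        assert rep.iloc[0]["p"] < 0.05

    def test_std_size_above_every_network_errors(self):
        cfg = GeneratorConfig(seed=32, n_studies=4, m_range=(10, 50))
        coll, _, _ = generate_collection(cfg)
        from quantweb import NetworkValidationError

        with pytest.raises(NetworkValidationError):
            standardise(coll, std_size=10_000, reps=2, seed=0)


class TestStage4:
    def _table(self, coupled: bool, seed=0, n=120):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(n):
            d = float(rng.uniform(0, 100))
            mu = 1.0 + (0.01 * d if coupled else 0.0)
            rows.append({
                "network_id": f"n{k}", "study_id": f"s{k % 10}",
                "delta": d,
                "generality": float(np.exp(mu + rng.normal(0, 0.2))),
                "connectance": float(0.2 + rng.normal(0, 0.02)),
            })
        return pd.DataFrame(rows)

    def test_coupled_generator_detected(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage4_delta_regressions(self._table(coupled=True)).table
        row = rep[rep["metric"] == "generality"].iloc[0]
        assert row["p"] < 0.05 and row["direction"] == "+"
        assert row["random_structure"] == "slope"

    def test_decoupled_generator_null(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage4_delta_regressions(self._table(coupled=False, seed=3)).table
        assert (rep["p"] > 0.05).all()

    def test_constant_delta_refused(self):
        df = self._table(coupled=False)
        df["delta"] = 50.0
        with pytest.raises(ValueError, match="constant"):
            stage4_delta_regressions(df)


def _stage5_table(latitude_beta=0.0, seed=0, n_studies=20, n_per=5):
    """Metrics table from the null LMM world, optionally with a latitude
    shift injected into the H2' column."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_studies):
        lat = float(rng.uniform(-35, 75))
        guild = ["aphids", "gallers", "leaf chewers", "leaf miners", "trap nesters"][s % 5]
        b = rng.normal(0, 0.05)
        for k in range(n_per):
            logm = rng.uniform(2.5, 9)
            h2 = 0.5 + b + rng.normal(0, 0.08) + latitude_beta * abs(lat)
            rows.append({
                "network_id": f"s{s}_n{k}", "study_id": f"s{s}",
                "m": float(np.exp(logm)),
                "abs_latitude": abs(lat), "guild": guild,
                "delta": float(rng.uniform(20, 90)),
                "h2prime": h2,
                "generality": float(np.exp(0.2 * logm + b + rng.normal(0, 0.1))),
            })
    return pd.DataFrame(rows)


class TestStage5:
    @staticmethod
    def _latitude_p(df):
        """Focused LRT of |latitude| on the H2' size-regression residuals."""
        from quantweb.inference import ModelSpec, fit_lmm, lrt, residualise

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = residualise(df, "h2prime")
            full = fit_lmm(data, ModelSpec(response="resid",
                                           fixed=["abs_latitude"]), "ML")
            reduced = fit_lmm(data, ModelSpec(response="resid", fixed=[]), "ML")
            return lrt(full, reduced)[2]

    def test_latitude_test_discriminates_null_from_injected(self):
        """The residual latitude test separates a flat world from one with a
        0.005-per-degree shift, at matched seeds."""
        for seed in (11, 12, 13):
            assert self._latitude_p(_stage5_table(latitude_beta=0.005,
                                                  seed=seed)) < 0.05
        null_ps = [self._latitude_p(_stage5_table(seed=s)) for s in (11, 12, 13)]
        assert sum(p > 0.05 for p in null_ps) >= 2

    def test_report_structure_and_marginality(self):
        df = _stage5_table(seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage5_residual_analysis(df).table
        assert {"metric", "retained_terms", "latitude_retained",
                "guild_retained", "latitude_p", "n"} <= set(rep.columns)
        # marginality: an interaction in the minimum adequate model implies
        # both parents are present
        for terms in rep["retained_terms"]:
            parts = [] if terms == "(intercept)" else terms.split(",")
            for t in parts:
                if ":" in t:
                    for parent in t.split(":"):
                        assert parent in parts

    def test_constant_metric_yields_intercept_only(self):
        df = _stage5_table(seed=13)
        df["generality"] = 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = stage5_residual_analysis(df).table.set_index("metric")
        assert rep.loc["generality", "retained_terms"] == "(intercept)"

    def test_single_guild_level_dropped_with_warning(self):
        df = _stage5_table(seed=14)
        df["guild"] = "aphids"
        with pytest.warns(UserWarning, match="guild"):
            rep = stage5_residual_analysis(df).table
        assert not rep["guild_retained"].any()


class TestStage4OnGeneratedData:
    def test_clustered_preferences_raise_modularity_with_delta(self):
        """End-to-end: the taxonomic-clustering switch couples Delta to
        structure through network mechanics rather than injected shifts."""
        cfg = GeneratorConfig(seed=41, n_studies=10, networks_per_study=(3, 5),
                              m_range=(100, 2000), taxonomic_clustering=True)
        coll, tax, _ = generate_collection(cfg)
        metrics = collection_metrics(coll)
        deltas = collection_delta(coll, tax)
        df = metrics.merge(deltas[["network_id", "delta"]], on="network_id")
        assert df["delta"].nunique() > 1
        assert np.isfinite(df["delta"]).all()
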