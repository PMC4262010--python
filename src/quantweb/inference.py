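"""Linear mixed-model machinery for cross-network comparisons.

Five analysis stages share one toolkit: Gaussian linear mixed models
with study-level random intercepts (optionally random slopes on log
matrix size, or network-within-study variance components), maximum
likelihood for all model comparisons, likelihood-ratio tests for fixed
effects, AIC/AICc selection of the random structure (the simpler
structure wins unless the richer one improves the criterion by more
than 1), backward elimination of non-significant fixed effects
respecting marginality, and a final REML refit of the minimum adequate
model.

The stages:

1. each metric (log-transformed except H2') against log matrix size
   across original networks;
2. replicate-mean metrics of subsampled networks against log subsample
   size, network nested within study (random slope for modularity);
3. metrics standardised to a common subsample size against log
   *original* size — the null expectation under pure sampling effects;
4. metrics against host taxonomic diversity Delta;
5. residuals of the size regressions against guild, absolute latitude,
   Delta and their two-way interactions, backward-simplified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .metrics import METRIC_NAMES

__all__ = [
    "ModelSpec",
    "LmmFit",
    "AnalysisReport",
    "fit_lmm",
    "select_random_structure",
    "lrt",
    "backward_simplify",
    "residualise",
    "stage1_size_regressions",
    "stage2_subsample_regressions",
    "stage3_standardised_regressions",
    "stage4_delta_regressions",
    "stage5_residual_analysis",
]


class FitError(RuntimeError):
    """A mixed-model fit could not be completed."""


@dataclass
class ModelSpec:
    """Description of one mixed model: response, fixed terms, random structure.

    ``random`` is ``"intercept"``, ``"slope"`` (random intercept and
    slope on ``slope_var`` per group) or ``"none"`` (plain OLS
    fallback when only one group exists).  ``nested`` adds a variance
    component for that identifier within the group.
    """

    response: str
    fixed: list[str] = field(default_factory=list)
    group: str = "study_id"
    random: str = "intercept"
    slope_var: str = "logm"
    nested: str | None = None

    def formula(self) -> str:
        rhs = " + ".join(["1"] + list(self.fixed))
        return f"{self.response} ~ {rhs}"

    def without(self, term: str) -> "ModelSpec":
        return ModelSpec(
            response=self.response,
            fixed=[t for t in self.fixed if t != term],
            group=self.group,
            random=self.random,
            slope_var=self.slope_var,
            nested=self.nested,
        )


@dataclass
class LmmFit:
    """A fitted mixed model with the bookkeeping the pipeline needs."""

    spec: ModelSpec
    method: str  # "ML" or "REML"
    llf: float
    k_params: int  # fixed + covariance + residual variance
    k_fe: int
    n_obs: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    singular: bool
    resid_conditional: np.ndarray
    resid_marginal: np.ndarray

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.n_obs
        if n - k - 1 <= 0:
            return float("inf")
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def criterion(self, name: str) -> float:
        return self.aic if name.lower() == "aic" else self.aicc


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, method: str = "ML") -> LmmFit:
    """Fit one Gaussian mixed model (or OLS when ``spec.random == 'none'``).

    Non-convergence or a singular covariance estimate is flagged on the
    returned fit, never silently dropped.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be ML or REML, got {method!r}")
    data = data.reset_index(drop=True)
    if spec.random != "none" and data[spec.group].nunique() < 2:
        warnings.warn(
            f"only one level of {spec.group!r}: falling back to a fixed-effects fit"
        )
        spec = ModelSpec(**{**spec.__dict__, "random": "none", "fixed": list(spec.fixed)})
    if spec.random == "none":
        res = smf.ols(spec.formula(), data).fit()
        resid = np.asarray(res.resid)
        return LmmFit(
            spec=spec,
            method=method,
            llf=float(res.llf),
            k_params=len(res.params) + 1,
            k_fe=len(res.params),
            n_obs=int(res.nobs),
            params=res.params,
            bse=res.bse,
            converged=True,
            singular=False,
            resid_conditional=resid,
            resid_marginal=resid,
        )
    re_formula = "1" if spec.random == "intercept" else f"1 + {spec.slope_var}"
    vc_formula = None
    if spec.nested is not None:
        vc_formula = {spec.nested: f"0 + C({spec.nested})"}
    model = smf.mixedlm(
        spec.formula(), data, groups=spec.group,
        re_formula=re_formula, vc_formula=vc_formula,
    )
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = None
        last_exc: Exception | None = None
        for optimizer in (None, "powell", "nm"):
            try:
                if optimizer is None:
                    res = model.fit(reml=(method == "REML"))
                else:
                    res = model.fit(reml=(method == "REML"), method=optimizer)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if res is None:
            raise FitError(f"mixed-model fit failed: {last_exc}") from last_exc
        for w in caught:
            msg = str(w.message).lower()
            if "boundary" in msg or "singular" in msg or "positive definite" in msg:
                singular = True
    fitted_marginal = np.asarray(model.exog @ res.fe_params)
    endog = np.asarray(model.endog)
    return LmmFit(
        spec=spec,
        method=method,
        llf=float(res.llf),
        k_params=model.k_fe + model.k_re2 + model.k_vc + 1,
        k_fe=model.k_fe,
        n_obs=len(endog),
        params=res.fe_params,
        bse=res.bse[: model.k_fe],
        converged=bool(res.converged),
        singular=singular,
        resid_conditional=np.asarray(res.resid),
        resid_marginal=endog - fitted_marginal,
    )


def select_random_structure(
    data: pd.DataFrame,
    spec: ModelSpec,
    criterion: str = "aic",
) -> tuple[str, LmmFit]:
    """Choose between random intercept and random intercept + slope.

    The richer structure is kept only if it beats the simpler one by
    more than 1 criterion unit; ties and near-ties go to the simpler
    model (parsimony).  If one candidate fails to converge the other is
    returned with a warning.
    """
    simple = ModelSpec(**{**spec.__dict__, "random": "intercept", "fixed": list(spec.fixed)})
    complex_ = ModelSpec(**{**spec.__dict__, "random": "slope", "fixed": list(spec.fixed)})
    try:
        fit_simple = fit_lmm(data, simple, method="ML")
    except FitError:
        fit_simple = None
    try:
        fit_complex = fit_lmm(data, complex_, method="ML")
    except FitError:
        fit_complex = None
    if fit_complex is None or not fit_complex.converged:
        if fit_simple is None:
            raise FitError("neither random structure could be fitted")
        if fit_complex is not None and not fit_complex.converged:
            warnings.warn("random-slope candidate did not converge; using intercept")
        return "intercept", fit_simple
    if fit_simple is None or not fit_simple.converged:
        warnings.warn("random-intercept candidate did not converge; using slope")
        return "slope", fit_complex
    if fit_simple.criterion(criterion) - fit_complex.criterion(criterion) > 1.0:
        return "slope", fit_complex
    return "intercept", fit_simple


def lrt(full: LmmFit, reduced: LmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p).

    Refuses REML fits — fixed-effect comparisons require ML.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("likelihood-ratio tests on fixed effects require ML fits")
    df = full.k_fe - reduced.k_fe
    if df < 1:
        raise ValueError("the reduced model must drop at least one fixed parameter")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _parents(term: str) -> set[str]:
    return set(term.split(":")) if ":" in term else set()


def _removable(fixed: list[str]) -> list[str]:
    """Terms whose removal respects marginality (interactions go first)."""
    locked: set[str] = set()
    for t in fixed:
        locked |= _parents(t)
    return [t for t in fixed if t not in locked]


@dataclass
class SimplificationResult:
    """Backward-elimination outcome: final fits and the full removal path."""

    final_ml: LmmFit
    final_reml: LmmFit
    path: list[dict]  # one entry per elimination round per candidate

    @property
    def retained_terms(self) -> list[str]:
        return list(self.final_ml.spec.fixed)


def backward_simplify(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> SimplificationResult:
    """Backward-eliminate fixed effects until a minimum adequate model.

    At each round the removable term (marginality respected: no main
    effect leaves while its interaction remains) with the largest LRT
    p-value >= ``alpha`` is dropped and the model refitted; the
    minimum adequate model is refitted with REML for reporting.
    """
    current = fit_lmm(data, spec, method="ML")
    path: list[dict] = []
    while True:
        candidates = _removable(current.spec.fixed)
        if not candidates:
            break
        tested = []
        for term in candidates:
            try:
                reduced = fit_lmm(data, current.spec.without(term), method="ML")
            except FitError:
                warnings.warn(f"reduced model without {term!r} failed to fit; kept")
                continue
            chi2, df, p = lrt(current, reduced)
            tested.append((term, reduced, chi2, df, p))
        if not tested:
            break
        for term, reduced, chi2, df, p in tested:
            path.append(
                {"term": term, "chi2": chi2, "df": df, "p": p,
                 "n_terms": len(current.spec.fixed), "removed": False}
            )
        term, reduced, chi2, df, p = max(tested, key=lambda t: t[4])
        if p >= alpha:
            path[-len(tested) + [t[0] for t in tested].index(term)]["removed"] = True
            current = reduced
        else:
            break
    try:
        final_reml = fit_lmm(data, current.spec, method="REML")
    except FitError:
        warnings.warn("REML refit of the minimum adequate model failed; reporting ML")
        final_reml = current
    return SimplificationResult(final_ml=current, final_reml=final_reml, path=path)


# ---------------------------------------------------------------------------
# per-stage model recipes
# ---------------------------------------------------------------------------

#: metrics never log-transformed, per analysis stage
_IDENTITY_METRICS = {
    1: {"h2prime"},
    2: {"h2prime", "modularity"},
    3: {"h2prime", "modularity"},
    4: {"h2prime", "connectance"},
}

#: information criterion used for random-structure selection per stage
_STAGE_CRITERION = {1: "aic", 2: "aic", 3: "aicc", 4: "aic", 5: "aicc"}


def metric_transform(stage: int, metric: str) -> str:
    """'log' or 'identity' for a metric response at a given stage."""
    return "identity" if metric in _IDENTITY_METRICS.get(stage, set()) else "log"


@dataclass
class AnalysisReport:
    """Per-metric LRT results for one analysis stage."""

    stage: int
    table: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnalysisReport(stage={self.stage})\n{self.table}"


def _prepare_response(
    df: pd.DataFrame, metric: str, stage: int
) -> tuple[pd.DataFrame, str]:
    """Add a transformed response column, dropping undefined/invalid rows."""
    out = df[np.isfinite(df[metric])].copy()
    transform = metric_transform(stage, metric)
    if transform == "log":
        bad = out[metric] <= 0
        if bad.any():
            warnings.warn(
                f"{metric}: dropping {int(bad.sum())} non-positive value(s) "
                "before log transform"
            )
            out = out[~bad]
        out["y"] = np.log(out[metric])
    else:
        out["y"] = out[metric]
    return out, transform


def _available_metrics(df: pd.DataFrame) -> list[str]:
    return [m for m in METRIC_NAMES if m in df.columns and np.isfinite(df[m]).sum() >= 3]


def _size_regression_row(
    df: pd.DataFrame,
    metric: str,
    stage: int,
    size_column: str,
    group: str = "study_id",
    nested: str | None = None,
    force_random: str | None = None,
) -> dict:
    """Fit metric ~ log(size) with the stage's recipe; report the LRT."""
    sub, transform = _prepare_response(df, metric, stage)
    sub["logm"] = np.log(sub[size_column].astype(float))
    spec = ModelSpec(response="y", fixed=["logm"], group=group, nested=nested)
    criterion = _STAGE_CRITERION[stage]
    if sub[group].nunique() < 2:
        warnings.warn(
            f"{metric}: only one level of {group}; random effects dropped, "
            "fixed-effects fit reported"
        )
        structure = "none"
        full = fit_lmm(sub, ModelSpec(**{**spec.__dict__, "random": "none",
                                         "fixed": ["logm"]}), method="ML")
    elif force_random is not None:
        structure = force_random
        full = fit_lmm(sub, ModelSpec(**{**spec.__dict__, "random": force_random,
                                         "fixed": ["logm"]}), method="ML")
    else:
        structure, full = select_random_structure(sub, spec, criterion=criterion)
    reduced = fit_lmm(sub, full.spec.without("logm"), method="ML")
    chi2, dof, p = lrt(full, reduced)
    slope = float(full.params.get("logm", np.nan))
    return {
        "metric": metric,
        "transform": transform,
        "random_structure": structure,
        "n": full.n_obs,
        "chi2": chi2,
        "df": dof,
        "p": p,
        "slope": slope,
        "direction": "+" if slope > 0 else ("-" if slope < 0 else "0"),
        "converged": full.converged and reduced.converged,
    }


def stage1_size_regressions(metrics_df: pd.DataFrame) -> AnalysisReport:
    """Each metric against log matrix size across the original networks.

    Expects one row per network with columns ``study_id``, ``m`` and the
    metric columns; the random structure is selected per metric by AIC.
    """
    rows = [
        _size_regression_row(metrics_df, metric, stage=1, size_column="m")
        for metric in _available_metrics(metrics_df)
    ]
    return AnalysisReport(stage=1, table=pd.DataFrame(rows))


def stage2_subsample_regressions(curves_df: pd.DataFrame) -> AnalysisReport:
    """Replicate-mean metrics against log subsample size, within networks.

    Expects the long table from rarefaction curves: one row per
    (network, size) with columns ``study_id``, ``network_id``, ``size``
    and metric means.  Networks are nested within studies; modularity
    uses a random intercept and slope.
    """
    rows = []
    for metric in _available_metrics(curves_df):
        force = "slope" if metric == "modularity" else "intercept"
        rows.append(
            _size_regression_row(
                curves_df, metric, stage=2, size_column="size",
                nested="network_id", force_random=force,
            )
        )
    return AnalysisReport(stage=2, table=pd.DataFrame(rows))


def stage3_standardised_regressions(std_df: pd.DataFrame) -> AnalysisReport:
    """Standardised-size metrics against log *original* matrix size.

    Under pure sampling effects the standardised metrics carry no
    information about the original size, so the expectation is a null
    result for every metric.  Structure selection uses AICc (small
    samples).
    """
    rows = [
        _size_regression_row(std_df, metric, stage=3, size_column="original_m")
        for metric in _available_metrics(std_df)
    ]
    return AnalysisReport(stage=3, table=pd.DataFrame(rows))


def stage4_delta_regressions(metrics_df: pd.DataFrame,
                             delta_column: str = "delta") -> AnalysisReport:
    """Each metric against host taxonomic diversity Delta.

    Random intercept for every metric except generality, which gets a
    random intercept and slope (on Delta).  Connectance and H2' stay
    untransformed.
    """
    if metrics_df[delta_column].nunique() <= 1:
        raise ValueError(
            "Delta is constant across networks; its effect is not estimable"
        )
    rows = []
    for metric in _available_metrics(metrics_df):
        sub, transform = _prepare_response(metrics_df, metric, stage=4)
        sub = sub[np.isfinite(sub[delta_column])]
        structure = "slope" if metric == "generality" else "intercept"
        spec = ModelSpec(response="y", fixed=[delta_column], random=structure,
                         slope_var=delta_column)
        full = fit_lmm(sub, spec, method="ML")
        reduced = fit_lmm(sub, spec.without(delta_column), method="ML")
        chi2, dof, p = lrt(full, reduced)
        slope = float(full.params.get(delta_column, np.nan))
        rows.append(
            {"metric": metric, "transform": transform,
             "random_structure": structure, "n": full.n_obs,
             "chi2": chi2, "df": dof, "p": p, "slope": slope,
             "direction": "+" if slope > 0 else ("-" if slope < 0 else "0"),
             "converged": full.converged and reduced.converged}
        )
    return AnalysisReport(stage=4, table=pd.DataFrame(rows))


def residualise(
    metrics_df: pd.DataFrame,
    metric: str,
    resid_type: str = "marginal",
    method: str = "ML",
    size_column: str = "m",
) -> pd.DataFrame:
    """Residuals of one metric's size regression, attached to the table.

    The metric is transformed as in stage 1, regressed on log matrix
    size with the AIC-selected random structure, and the conditional
    (default) or marginal residuals are returned in a ``resid`` column.
    """
    sub, _ = _prepare_response(metrics_df, metric, stage=1)
    sub["logm"] = np.log(sub[size_column].astype(float))
    spec = ModelSpec(response="y", fixed=["logm"])
    if sub["study_id"].nunique() < 2:
        fit = fit_lmm(sub, ModelSpec(**{**spec.__dict__, "random": "none",
                                        "fixed": ["logm"]}), method=method)
    else:
        structure, fit = select_random_structure(sub, spec)
        if method.upper() == "REML":
            fit = fit_lmm(sub, fit.spec, method="REML")
    resid = fit.resid_conditional if resid_type == "conditional" else fit.resid_marginal
    out = sub.copy()
    out["resid"] = resid
    return out


def stage5_residual_analysis(
    metrics_df: pd.DataFrame,
    delta_column: str = "delta",
    latitude_column: str = "abs_latitude",
    guild_column: str = "guild",
    alpha: float = 0.05,
    resid_type: str = "marginal",
) -> AnalysisReport:
    """Latitude / guild / Delta analysis of size-adjusted metrics.

    For each metric: residualise against log matrix size (stage-1
    recipe), then model the residuals as guild + |latitude| + Delta +
    all two-way interactions with a study random intercept, backward-
    simplifying to the minimum adequate model.  Reports which terms
    survive and the LRT p of latitude and guild at their removal (or
    final retention) point.
    """
    rows = []
    for metric in _available_metrics(metrics_df)[:]:
        data = residualise(metrics_df, metric, resid_type=resid_type)
        data = data[np.isfinite(data[delta_column])]
        lat, dlt = latitude_column, delta_column
        guild_ok = data[guild_column].nunique() >= 2
        if not guild_ok:
            warnings.warn(
                f"{metric}: guild has a single level; guild terms dropped"
            )
        if np.var(data["resid"].to_numpy()) < 1e-14:
            # a constant metric leaves nothing to model
            rows.append(
                {"metric": metric, "retained_terms": "(intercept)",
                 "latitude_retained": False, "guild_retained": False,
                 "delta_retained": False, "latitude_p": float("nan"),
                 "guild_p": float("nan"), "n": len(data), "converged": True}
            )
            continue
        g = f"C({guild_column})"
        terms = [lat, dlt, f"{lat}:{dlt}"]
        if guild_ok:
            terms = [g, lat, dlt, f"{g}:{lat}", f"{g}:{dlt}", f"{lat}:{dlt}"]
        spec = ModelSpec(response="resid", fixed=terms, random="intercept")
        simp = backward_simplify(data, spec, alpha=alpha)
        retained = simp.retained_terms

        def last_p(stem: str) -> float:
            # prefer the main-effect test; fall back to any term containing it
            exact = [e for e in simp.path if e["term"] == stem or e["term"] == f"C({stem})"]
            if exact:
                return exact[-1]["p"]
            entries = [e for e in simp.path if stem in e["term"]]
            return entries[-1]["p"] if entries else float("nan")

        rows.append(
            {
                "metric": metric,
                "retained_terms": ",".join(retained) if retained else "(intercept)",
                "latitude_retained": any(lat in t for t in retained),
                "guild_retained": any(guild_column in t for t in retained),
                "delta_retained": any(dlt in t for t in retained),
                "latitude_p": last_p(lat),
                "guild_p": last_p(guild_column) if guild_ok else float("nan"),
                "n": simp.final_ml.n_obs,
                "converged": simp.final_ml.converged,
            }
        )
    return AnalysisReport(stage=5, table=pd.DataFrame(rows))
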