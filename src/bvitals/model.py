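"""Linear mixed-effects models with simultaneous between/within terms.

For each summary feature, the repeatedly measured PHQ-8 score is regressed
on the participant's global feature level (between-person term, "who is at
risk") and the weekly deviation from it (within-person term, "when is a
person at risk"), adjusting for age, gender, occupation, living status,
treatment arm, √week and treatment×√week, with a per-participant random
intercept and random slope on √week (unstructured 2×2 covariance) and
Gaussian residuals.  Estimation is REML via statsmodels MixedLM with fixed
optimizer settings; confidence intervals are Wald (estimate ± 1.96 SE).

Marginal R² follows the Nakagawa–Schielzeth variance decomposition with
the random-slope extension: the fixed-effect predictor variance over the
sum of fixed, random (mean of zᵢ'Gzᵢ over observations) and residual
variances.  ΔR² is the increment of marginal R² from adding the feature
block to the covariate-only model on the identical rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregate import SUMMARY_FEATURES, summary_key

FEATURE_TERMS = ("x_between", "x_within")
COVARIATE_TERMS = (
    "age",
    "female",
    "employed",
    "alone",
    "treatment",
    "sqrt_week",
    "treat_sqrt_week",
)
Z_95 = 1.96


class DesignError(ValueError):
    """Raised when no usable rows remain for a model."""


def build_design(
    triples: pd.DataFrame,
    covariates: pd.DataFrame,
    phq: pd.DataFrame,
    feature: str,
    statistic: str,
) -> pd.DataFrame:
    """Model-ready table for one summary feature.

    One row per participant-wave with the outcome, the between term
    (global feature), the within term (weekly deviation) and coded
    covariates.  Reference levels: male_or_other, not_employed,
    with_others, control.  Rows with any missing value are dropped; the
    count of dropped rows is attached as ``.attrs["n_dropped"]``.
    """
    tri = triples[(triples["feature"] == feature) & (triples["statistic"] == statistic)]
    data = phq.merge(
        tri[["participant_id", "week", "x_global", "x_dev"]],
        on=["participant_id", "week"],
        how="inner",
    ).merge(covariates, on="participant_id", how="inner")
    data = data.rename(columns={"x_global": "x_between", "x_dev": "x_within"})
    data["sqrt_week"] = np.sqrt(data["week"].astype(float))
    data["treat_sqrt_week"] = data["treatment"] * data["sqrt_week"]
    used = ["phq8", *FEATURE_TERMS, *COVARIATE_TERMS]
    n0 = len(data)
    data = data.dropna(subset=used).reset_index(drop=True)
    if len(data) == 0:
        raise DesignError(f"no usable rows for {summary_key(feature, statistic)}")
    data.attrs["n_dropped"] = n0 - len(data)
    data.attrs["summary"] = summary_key(feature, statistic)
    return data


@dataclass
class ModelFit:
    """Fixed effects with Wald CIs plus variance components and fit indices."""

    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    cov_re: np.ndarray
    scale: float
    converged: bool
    fallback: str | None
    n_obs: int
    n_groups: int
    llf: float
    var_fixed: float
    var_random: float
    row_key: tuple = field(repr=False, default=())

    @property
    def random_structure(self) -> str:
        return {0: "none", 1: "intercept", 2: "intercept+slope"}[len(self.cov_re)]


def _wald(params, bse):
    lo = {k: params[k] - Z_95 * bse[k] for k in params}
    hi = {k: params[k] + Z_95 * bse[k] for k in params}
    return lo, hi


def _fit_ols(endog, exog, names, data) -> ModelFit:
    res = sm.OLS(endog, exog).fit()
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    lo, hi = _wald(params, bse)
    fe = exog @ res.params
    return ModelFit(
        terms=tuple(names),
        params=params,
        bse=bse,
        ci_low=lo,
        ci_high=hi,
        cov_re=np.zeros((0, 0)),
        scale=float(res.scale),
        converged=True,
        fallback="ols",
        n_obs=len(endog),
        n_groups=int(data["participant_id"].nunique()),
        llf=float(res.llf),
        var_fixed=float(np.var(fe)),
        var_random=0.0,
        row_key=_row_key(data),
    )


def _row_key(data: pd.DataFrame) -> tuple:
    return tuple(zip(data["participant_id"].tolist(), data["week"].tolist()))


def fit_mixed_model(
    data: pd.DataFrame,
    feature_terms: tuple[str, ...] = FEATURE_TERMS,
    reml: bool = True,
    warm_start: ModelFit | None = None,
) -> ModelFit:
    """REML fit of the mixed model on a design table from :func:`build_design`.

    The random structure starts as intercept + √week slope with free 2×2
    covariance.  A fit whose random-effect covariance is estimated at the
    zero boundary (singular) is reduced — slope first, then intercept; with
    no random effects left the model is estimated by OLS, to which the
    mixed model degenerates exactly.  Non-convergence after reduction is
    flagged and no estimates are reported.
    """
    names = ["const", *feature_terms, *COVARIATE_TERMS]
    exog = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in names[1:]])
    endog = data["phq8"].to_numpy(dtype=float)
    groups = data["participant_id"].to_numpy()
    sqrt_week = data["sqrt_week"].to_numpy(dtype=float)

    structures = [
        np.column_stack([np.ones(len(data)), sqrt_week]),
        np.ones((len(data), 1)),
    ]
    fallback = None
    for i, exog_re in enumerate(structures):
        start = None
        if (
            warm_start is not None
            and warm_start.cov_re.shape == (exog_re.shape[1], exog_re.shape[1])
            and warm_start.scale > 0
        ):
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            start = MixedLMParams.from_components(
                fe_params=np.array([warm_start.params.get(k, 0.0) for k in names]),
                cov_re=warm_start.cov_re / warm_start.scale,
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
                res = md.fit(
                    reml=reml, method="lbfgs", maxiter=500, disp=False,
                    start_params=start,
                )
        except (np.linalg.LinAlgError, ValueError):
            fallback = "intercept-only"
            continue
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        eig = np.linalg.eigvalsh(cov_re)
        boundary = eig.min() < 1e-8 * max(res.scale, 1e-12)
        # the boundary stratum with no random effects is part of the REML
        # parameter space; if it achieves at least the same restricted
        # likelihood the optimizer stopped on a flat ridge and the model
        # degenerates to OLS exactly
        try:
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            ols_res = sm.OLS(endog, exog).fit()
            # small positive ridge keeps the likelihood evaluation stable;
            # it upper-bounds the true zero-RE restricted likelihood
            p0 = MixedLMParams.from_components(
                fe_params=ols_res.params, cov_re=np.eye(exog_re.shape[1]) * 1e-8
            )
            ll_zero = md.loglike(p0)
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            ll_zero = -np.inf
        if np.isfinite(ll_zero) and ll_zero >= res.llf - 1e-6:
            return _fit_ols(endog, exog, names, data)
        if boundary and i == 0:
            # singular slope: drop it and refit
            fallback = "intercept-only"
            continue
        if boundary and i == 1:
            # the whole random part is at zero: the model is OLS
            return _fit_ols(endog, exog, names, data)
        if not res.converged:
            fallback = "intercept-only"
            continue
        params = dict(zip(names, res.fe_params))
        bse = dict(zip(names, res.bse_fe))
        lo, hi = _wald(params, bse)
        fe = exog @ res.fe_params
        zgz = np.einsum("ij,jk,ik->i", exog_re, cov_re, exog_re)
        return ModelFit(
            terms=tuple(names),
            params=params,
            bse=bse,
            ci_low=lo,
            ci_high=hi,
            cov_re=cov_re,
            scale=float(res.scale),
            converged=True,
            fallback=fallback if i > 0 else None,
            n_obs=len(endog),
            n_groups=int(pd.Series(groups).nunique()),
            llf=float(res.llf),
            var_fixed=float(np.var(fe)),
            var_random=float(zgz.mean()),
            row_key=_row_key(data),
        )
    # last resort: OLS keeps the screen going but is flagged as such
    try:
        fit = _fit_ols(endog, exog, names, data)
        fit.converged = False
        return fit
    except Exception as exc:  # pragma: no cover
        raise DesignError(f"model could not be fit: {exc}")


def marginal_r2(fit: ModelFit) -> float:
    """Nakagawa–Schielzeth marginal R² of a fitted model."""
    total = fit.var_fixed + fit.var_random + fit.scale
    if total <= 0:
        return float("nan")
    return float(fit.var_fixed / total)


def delta_r2(full_fit: ModelFit, reduced_fit: ModelFit) -> float:
    """Marginal-R² increment of the feature block (full − covariate-only).

    Both fits must be on the identical observation set; may be slightly
    negative in finite samples.
    """
    if full_fit.row_key != reduced_fit.row_key:
        raise ValueError("fits are not on the identical observation set")
    return float(marginal_r2(full_fit) - marginal_r2(reduced_fit))


def run_feature_screen(
    triples: pd.DataFrame,
    covariates: pd.DataFrame,
    phq: pd.DataFrame,
    features: tuple[tuple[str, str], ...] = SUMMARY_FEATURES,
) -> pd.DataFrame:
    """Fit one model per summary feature and tabulate between/within rows.

    Each feature contributes two rows (between and within term) with the
    estimate, Wald 95% CI, ΔR², observation counts and convergence status.
    No multiple-comparison adjustment is applied.  Per-feature failures
    are recorded and the screen continues.
    """
    rows = []
    for feature, stat in features:
        key = summary_key(feature, stat)
        try:
            data = build_design(triples, covariates, phq, feature, stat)
            full = fit_mixed_model(data)
            reduced = fit_mixed_model(data, feature_terms=())
            dr2 = delta_r2(full, reduced)
        except (DesignError, ValueError) as exc:
            for term in ("between", "within"):
                rows.append(
                    {
                        "feature": feature,
                        "statistic": stat,
                        "summary": key,
                        "term": term,
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "delta_r2": np.nan,
                        "marginal_r2_full": np.nan,
                        "marginal_r2_covariates": np.nan,
                        "n_obs": 0,
                        "n_participants": 0,
                        "converged": False,
                        "note": str(exc),
                    }
                )
            continue
        for term, col in (("between", "x_between"), ("within", "x_within")):
            rows.append(
                {
                    "feature": feature,
                    "statistic": stat,
                    "summary": key,
                    "term": term,
                    "estimate": full.params[col],
                    "se": full.bse[col],
                    "ci_low": full.ci_low[col],
                    "ci_high": full.ci_high[col],
                    "delta_r2": dr2,
                    "marginal_r2_full": marginal_r2(full),
                    "marginal_r2_covariates": marginal_r2(reduced),
                    "n_obs": full.n_obs,
                    "n_participants": full.n_groups,
                    "converged": full.converged,
                    "note": full.fallback or "",
                }
            )
    return pd.DataFrame(rows)


def format_screen(screen: pd.DataFrame) -> pd.DataFrame:
    """Screen table at reporting precision: B and CI to 2 dp, ΔR² to 3 dp."""
    out = screen.copy()
    for c in ("estimate", "se", "ci_low", "ci_high"):
        out[c] = out[c].round(2)
    out["delta_r2"] = out["delta_r2"].round(3)
    return out
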