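"""Mixed-effects models of SES along the dominant-species cover gradient.

For each trait set, SES is regressed on the focal species' percent cover
with a linear and a quadratic mixed model.  Site type (two levels,
distinguished by their subordinate species) enters as a random grouping
factor carrying a random intercept and a random cover slope.  The linear
and quadratic forms are compared by AIC under maximum likelihood; the
chosen form is refit by REML for the reported coefficients.  Explained
variance is summarized with marginal R^2 (fixed effects only) and
conditional R^2 (fixed plus random effects), following the
Nakagawa-Schielzeth variance decomposition.

Cover is centered and scaled to unit variance before the quadratic term
is formed, so reported coefficients are on the standardized cover axis.
A grouping factor with only two levels makes the random-slope fit
fragile; singular or non-converged fits fall back to a random intercept
only (logged).  Fixed-effect p-values use the normal approximation on
the t-ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_data import ValidationError

logger = logging.getLogger("fdgradient")

TABLE_ORDER = ["H", "LDMC", "LA", "SM", "PCGO", "LS", "NCO", "LHS", "Multiple"]


@dataclass
class GradientModelFit:
    """One trait set's fitted gradient model."""

    trait_set: str
    chosen_form: str  # linear | quadratic
    beta_linear: float
    se_linear: float
    p_linear: float
    beta_quadratic: float  # nan when the linear form is chosen
    se_quadratic: float
    p_quadratic: float
    var_fixed: float
    var_random: float
    var_residual: float
    aic_ml: float
    aic_ml_linear: float
    aic_ml_quadratic: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    random_structure: str  # intercept_slope | intercept | fixed_interaction
    conf_int: dict = field(default_factory=dict)  # term -> (lo, hi), 95%, REML fit


def nakagawa_r2(
    var_fixed: float, var_random: float, var_residual: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 from a variance decomposition.

    r2_marginal = s2_f / (s2_f + s2_r + s2_e);
    r2_conditional = (s2_f + s2_r) / (s2_f + s2_r + s2_e).
    ``var_fixed`` is the variance of the fixed-effect linear predictor
    over the data.
    """
    if min(var_fixed, var_random, var_residual) < 0:
        raise ValidationError("variance components must be >= 0")
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise ValidationError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random) / total


def _is_singular(res, exog_re_dim: int) -> bool:
    if not np.isfinite(res.llf):
        return True
    cov = np.atleast_2d(np.asarray(res.cov_re))
    if cov.shape[0] != exog_re_dim:
        return True
    eig = np.linalg.eigvalsh(cov)
    return bool(eig.min() < 1e-8 * max(res.scale, 1e-12))


def _fit_mixed(y, X, groups, exog_re, reml):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = None
        for method in (None, "lbfgs"):
            try:
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=reml, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res is not None and np.isfinite(res.llf):
                return res
    return res if res is not None and np.isfinite(res.llf) else None


def _fit_with_fallback(y, X, groups, Z_full):
    """ML+REML pair with fallback to random intercept on singular fits."""
    structure = "intercept_slope"
    Z = Z_full
    res_ml = _fit_mixed(y, X, groups, Z, reml=False)
    if res_ml is None or _is_singular(res_ml, Z.shape[1]):
        logger.warning("singular random-slope fit; falling back to random intercept")
        structure = "intercept"
        Z = Z_full[:, :1]
        res_ml = _fit_mixed(y, X, groups, Z, reml=False)
    if res_ml is None:
        raise ValidationError("mixed model failed to fit")
    res_reml = _fit_mixed(y, X, groups, Z, reml=True)
    if res_reml is None:
        res_reml = res_ml
    return res_ml, res_reml, Z, structure


def _variance_components(res_reml, X, Z):
    fe = np.asarray(res_reml.fe_params)
    pred = X @ fe
    var_fixed = float(np.var(pred))
    cov_re = np.atleast_2d(np.asarray(res_reml.cov_re))
    var_random = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
    var_residual = float(res_reml.scale)
    return var_fixed, var_random, var_residual


def _assemble(ses_table: pd.DataFrame, focal_cover: pd.Series, plot_meta: pd.DataFrame,
              trait_set: str) -> pd.DataFrame:
    sub = ses_table[ses_table["trait_set"] == trait_set]
    sub = sub[np.isfinite(sub["ses"])]
    if "degenerate" in sub.columns:
        sub = sub[~sub["degenerate"].astype(bool)]
    df = sub.set_index("plot_id")[["ses"]].copy()
    df["cover"] = focal_cover.reindex(df.index).astype(float)
    df["site_type"] = plot_meta.reindex(df.index)["site_type"]
    df = df.dropna()
    if df.empty:
        raise ValidationError(f"no usable SES values for trait set {trait_set!r}")
    return df


def fit_gradient_model(
    ses_table: pd.DataFrame,
    focal_cover: pd.Series,
    plot_meta: pd.DataFrame,
    trait_set: str,
    random_structure: str = "intercept_slope",
) -> GradientModelFit:
    """Fit linear and quadratic mixed models for one trait set's SES.

    Model choice is by ML-AIC with a parsimony tie-break: the quadratic
    form is chosen only when its AIC undercuts the linear form's by more
    than 2.  Reported coefficients, variance components and R^2 come from
    the REML refit of the chosen form.  ``random_structure
    ="fixed_interaction"`` replaces the random effects with fixed
    cover x site-type interaction terms (OLS), as a robustness variant.
    """
    df = _assemble(ses_table, focal_cover, plot_meta, trait_set)
    if df["site_type"].nunique() < 2 and random_structure != "fixed_interaction":
        raise ValidationError("need >= 2 site-type levels for the random grouping")
    y = df["ses"].to_numpy(dtype=float)
    if np.var(y) <= 0:
        raise ValidationError(f"SES response for {trait_set!r} has zero variance")
    c_raw = df["cover"].to_numpy(dtype=float)
    c = (c_raw - c_raw.mean()) / c_raw.std(ddof=1)

    X_lin = np.column_stack([np.ones_like(c), c])
    X_quad = np.column_stack([np.ones_like(c), c, c**2])

    if random_structure == "fixed_interaction":
        return _fit_fixed_interaction(df, y, c, trait_set)

    groups = df["site_type"].to_numpy()
    Z_full = np.column_stack([np.ones_like(c), c])

    ml_lin, reml_lin, Z_lin, struct_lin = _fit_with_fallback(y, X_lin, groups, Z_full)
    ml_quad, reml_quad, Z_quad, struct_quad = _fit_with_fallback(y, X_quad, groups, Z_full)
    aic_lin, aic_quad = float(ml_lin.aic), float(ml_quad.aic)

    if aic_lin - aic_quad > 2.0:
        chosen, res, Z, structure, aic = "quadratic", reml_quad, Z_quad, struct_quad, aic_quad
        X = X_quad
    else:
        chosen, res, Z, structure, aic = "linear", reml_lin, Z_lin, struct_lin, aic_lin
        X = X_lin

    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    pv = np.asarray(res.pvalues)[: len(fe)]
    ci_half = 1.959963984540054 * se
    conf = {
        "linear": (float(fe[1] - ci_half[1]), float(fe[1] + ci_half[1])),
    }
    if chosen == "quadratic":
        conf["quadratic"] = (float(fe[2] - ci_half[2]), float(fe[2] + ci_half[2]))

    var_f, var_r, var_e = _variance_components(res, X, Z)
    r2m, r2c = nakagawa_r2(var_f, var_r, var_e)
    return GradientModelFit(
        trait_set=trait_set,
        chosen_form=chosen,
        beta_linear=float(fe[1]),
        se_linear=float(se[1]),
        p_linear=float(pv[1]),
        beta_quadratic=float(fe[2]) if chosen == "quadratic" else float("nan"),
        se_quadratic=float(se[2]) if chosen == "quadratic" else float("nan"),
        p_quadratic=float(pv[2]) if chosen == "quadratic" else float("nan"),
        var_fixed=var_f,
        var_random=var_r,
        var_residual=var_e,
        aic_ml=aic,
        aic_ml_linear=aic_lin,
        aic_ml_quadratic=aic_quad,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(y),
        random_structure=structure,
        conf_int=conf,
    )


def _fit_fixed_interaction(df, y, c, trait_set):
    """OLS robustness variant: SES ~ cover * site_type (no random effects)."""
    t = (df["site_type"] == sorted(df["site_type"].unique())[-1]).to_numpy(float)
    X_lin = np.column_stack([np.ones_like(c), c, t, c * t])
    X_quad = np.column_stack([np.ones_like(c), c, c**2, t, c * t])
    res_lin = sm.OLS(y, X_lin).fit()
    res_quad = sm.OLS(y, X_quad).fit()
    aic_lin, aic_quad = float(res_lin.aic), float(res_quad.aic)
    if aic_lin - aic_quad > 2.0:
        chosen, res, X = "quadratic", res_quad, X_quad
        qidx = 2
    else:
        chosen, res, X = "linear", res_lin, X_lin
        qidx = None
    var_f = float(np.var(X @ res.params))
    var_e = float(res.mse_resid)
    r2m, r2c = nakagawa_r2(var_f, 0.0, var_e)
    ci = res.conf_int()
    conf = {"linear": (float(ci[1][0]), float(ci[1][1]))}
    if qidx is not None:
        conf["quadratic"] = (float(ci[qidx][0]), float(ci[qidx][1]))
    return GradientModelFit(
        trait_set=trait_set,
        chosen_form=chosen,
        beta_linear=float(res.params[1]),
        se_linear=float(res.bse[1]),
        p_linear=float(res.pvalues[1]),
        beta_quadratic=float(res.params[qidx]) if qidx else float("nan"),
        se_quadratic=float(res.bse[qidx]) if qidx else float("nan"),
        p_quadratic=float(res.pvalues[qidx]) if qidx else float("nan"),
        var_fixed=var_f,
        var_random=0.0,
        var_residual=var_e,
        aic_ml=float(res.aic),
        aic_ml_linear=aic_lin,
        aic_ml_quadratic=aic_quad,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(y),
        random_structure="fixed_interaction",
        conf_int=conf,
    )


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def run_all_models(
    ses_table: pd.DataFrame,
    focal_cover: pd.Series,
    plot_meta: pd.DataFrame,
    trait_sets: list[str] | None = None,
    random_structure: str = "intercept_slope",
) -> tuple[list[GradientModelFit], pd.DataFrame]:
    """Fit the gradient model for every trait set and format the summary.

    Returns the fits plus a table with one row per trait set (canonical
    order) holding the linear and quadratic terms with significance
    stars, marginal and conditional R^2 and the ML AIC of the chosen
    form.
    """
    if trait_sets is None:
        present = list(ses_table["trait_set"].unique())
        trait_sets = [t for t in TABLE_ORDER if t in present] + [
            t for t in present if t not in TABLE_ORDER
        ]
    fits = [
        fit_gradient_model(ses_table, focal_cover, plot_meta, ts, random_structure)
        for ts in trait_sets
    ]
    rows = []
    for f in fits:
        rows.append(
            {
                "trait_set": f.trait_set,
                "chosen_form": f.chosen_form,
                "linear_term": f.beta_linear,
                "linear_sig": significance_stars(f.p_linear),
                "quadratic_term": f.beta_quadratic,
                "quadratic_sig": significance_stars(f.p_quadratic),
                "r2_marginal": f.r2_marginal,
                "r2_conditional": f.r2_conditional,
                "aic_ml": f.aic_ml,
                "random_structure": f.random_structure,
            }
        )
    return fits, pd.DataFrame(rows)
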