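"""Dose-response GLMs: gamma startle-magnitude models, logistic
startle-occurrence models, AICc model selection and prediction curves.

Startle magnitude (p-p VeDBA or max norm jerk, both strictly positive
and right-skewed) is modelled with gamma-family GLMs under a log,
inverse (hyperbolic) or identity link; binary video-scored startle
occurrence with a binomial GLM under a logit link.  Received level (or
rise time) is always retained as the primary predictor; playback
session, trial number or its natural logarithm (within-session
habituation), and focal/other-animal echolocation activity enter as
optional terms subject to data-availability rules.  Among the candidate
models the one with the lowest small-sample-corrected AIC (AICc) is
selected; non-significant terms are retained, not pruned.

Trial tables are plain :class:`pandas.DataFrame` objects with (a subset
of) the columns ``animal, session, trial, frequency_khz, rise_time_ms,
RL, is_control, FA_clicks, OA_clicks, pp_vedba, max_norm_jerk,
video_binary``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.genmod.families import links as sml

__all__ = [
    "ModelSpec",
    "FittedGlm",
    "PredictionCurve",
    "GlmConvergenceError",
    "fit_glm",
    "aicc",
    "select_model",
    "predict_with_intervals",
    "nagelkerke_r2",
]


class GlmConvergenceError(RuntimeError):
    """IRLS failed to converge, or the fit is degenerate (e.g. complete
    separation in a logistic model, non-positive gamma fitted values)."""


_LINKS = {
    "log": sml.Log,
    "inverse": sml.InversePower,
    "identity": sml.Identity,
    "logit": sml.Logit,
}

# term name -> how to build its design column(s)
_COVARIATES = {"RL", "rise_time", "trial", "ln_trial", "FA_clicks", "OA_clicks"}


@dataclass(frozen=True)
class ModelSpec:
    """A GLM specification: family, link, response column and terms.

    The intercept is always included.  ``session`` enters as a factor
    (treatment-coded against the first level); all other terms are
    covariates.  ``trial`` and ``ln_trial`` are mutually exclusive.
    """

    family: str  # {"gamma", "binomial"}
    link: str  # {"log", "inverse", "identity", "logit"}
    response: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.family == "binomial" and self.link != "logit":
            raise ValueError("binomial models use the logit link")
        if self.family == "gamma" and self.link == "logit":
            raise ValueError("logit link requires a binomial family")
        if "trial" in self.terms and "ln_trial" in self.terms:
            raise ValueError("trial and ln_trial are mutually exclusive")


@dataclass
class FittedGlm:
    """A fitted GLM with the quantities the analysis reports.

    ``params`` are coefficients on the link scale; ``exp_params`` their
    response-scale multipliers (exp(beta)) for log/logit links.  Wald
    95% intervals are beta +- 1.96 SE.  ``k`` counts estimated
    parameters including the gamma dispersion (the MuMIn convention),
    and feeds the AICc.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    wald_ci: pd.DataFrame  # columns lo, hi
    p_values: pd.Series
    dispersion: float
    llf: float
    n: int
    k: int
    aic: float
    aicc: float
    converged: bool
    result: object = field(repr=False, default=None)  # statsmodels result
    design_info: dict = field(repr=False, default_factory=dict)

    @property
    def exp_params(self) -> pd.Series:
        return np.exp(self.params)

    def to_dict(self) -> dict:
        """JSON-serialisable summary."""
        return {
            "family": self.spec.family,
            "link": self.spec.link,
            "response": self.spec.response,
            "terms": list(self.spec.terms),
            "coefficients": self.params.to_dict(),
            "exp_coefficients": self.exp_params.to_dict(),
            "se": self.bse.to_dict(),
            "wald_ci_lo": self.wald_ci["lo"].to_dict(),
            "wald_ci_hi": self.wald_ci["hi"].to_dict(),
            "p_values": self.p_values.to_dict(),
            "dispersion": self.dispersion,
            "log_likelihood": self.llf,
            "n": self.n,
            "k": self.k,
            "aicc": self.aicc,
            "converged": self.converged,
        }


@dataclass
class PredictionCurve:
    """Response-scale predictions over a fine predictor grid."""

    var: str
    grid: np.ndarray
    fitted: np.ndarray
    interval_lo: np.ndarray
    interval_hi: np.ndarray
    held_at: dict

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("empty prediction grid")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Build the design matrix (with intercept) for the given terms."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    for term in terms:
        if term == "session":
            levels = sorted(pd.unique(data["session"]))
            for lev in levels[1:]:
                cols[f"session[{lev}]"] = (data["session"] == lev).astype(float).to_numpy()
        elif term == "ln_trial":
            cols["ln_trial"] = np.log(data["trial"].to_numpy(dtype=float))
        elif term in _COVARIATES:
            src = "rise_time_ms" if term == "rise_time" and "rise_time_ms" in data else term
            cols[term] = data[src].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=data.index)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: AIC + 2k(k+1)/(n-k-1), with
    AIC = -2 logL + 2k.  Undefined (infinite) when n <= k+1, which
    excludes the model from selection."""
    if n <= k + 1:
        return np.inf
    aic = -2.0 * log_likelihood + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _gamma_llf(y: np.ndarray, mu: np.ndarray, deviance: float) -> float:
    """Gamma log-likelihood at the deviance-based dispersion estimate
    (shape = n / deviance), the convention R's ``logLik.glm`` uses and
    hence the one AICc-based selection in this field is calibrated to."""
    n = len(y)
    disp = deviance / n
    shape = 1.0 / disp
    return float(np.sum(scipy.stats.gamma.logpdf(y, shape, scale=mu * disp)))


def fit_glm(spec: ModelSpec, data: pd.DataFrame, maxiter: int = 200) -> FittedGlm:
    """Fit a GLM by IRLS and package coefficients, Wald intervals,
    dispersion and AICc.

    Gamma responses must be strictly positive; identity-link gamma fits
    with any non-positive fitted value raise :class:`GlmConvergenceError`,
    as does complete separation in a logistic fit.
    """
    y = data[spec.response].to_numpy(dtype=float)
    X = _design_matrix(data, spec.terms)
    p = X.shape[1]
    n = len(y)
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} coefficients")
    if spec.family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma response values must be strictly positive")

    link = _LINKS[spec.link]()
    if spec.family == "gamma":
        family = sm.families.Gamma(link)
    else:
        family = sm.families.Binomial(link)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=family)
        try:
            res = model.fit(maxiter=maxiter)
        except Exception as exc:
            raise GlmConvergenceError(f"IRLS failed: {exc}") from exc

    # statsmodels' relative-deviance criterion cannot flag convergence on
    # (near-)perfect fits where the deviance is ~0; accept those.
    converged = bool(res.converged) or float(res.deviance) < 1e-8
    if not converged:
        raise GlmConvergenceError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(spec={spec.link}/{'+'.join(spec.terms)})"
        )
    mu = res.fittedvalues
    if spec.family == "gamma" and np.any(mu <= 0):
        raise GlmConvergenceError("gamma fit produced non-positive fitted values")
    if spec.family == "binomial" and len(spec.terms) > 0:
        # no finite MLE exists under (quasi-)complete separation; IRLS
        # then wanders toward infinite coefficients instead of failing
        eta = np.asarray(res.predict(X, which="linear"))
        if y.min() == y.max():
            raise GlmConvergenceError("degenerate response: all 0 or all 1")
        if np.all((mu > 0.5) == (y > 0.5)) or np.max(np.abs(eta)) > 25:
            raise GlmConvergenceError(
                "logistic fit is degenerate (complete or quasi-complete "
                "separation: effectively infinite coefficients)"
            )

    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    ci = pd.DataFrame(
        {"lo": params - 1.96 * bse, "hi": params + 1.96 * bse}, index=X.columns
    )
    pvals = pd.Series(res.pvalues, index=X.columns)

    if spec.family == "gamma":
        dispersion = float(res.pearson_chi2 / res.df_resid)  # Pearson chi2/(n-p)
        llf = _gamma_llf(y, mu, float(res.deviance))
        k = p + 1  # + dispersion parameter
    else:
        dispersion = 1.0
        llf = float(res.llf)
        k = p

    return FittedGlm(
        spec=spec,
        params=params,
        bse=bse,
        wald_ci=ci,
        p_values=pvals,
        dispersion=dispersion,
        llf=llf,
        n=n,
        k=k,
        aic=-2 * llf + 2 * k,
        aicc=aicc(llf, k, n),
        converged=converged,
        result=res,
        design_info={"columns": list(X.columns), "terms": spec.terms},
    )


def candidate_terms(
    primary: str,
    data: pd.DataFrame,
    context: dict | None = None,
) -> list[tuple[str, ...]]:
    """Enumerate admissible term sets.

    The primary predictor (RL or rise_time) is always included.
    Optional terms: ``session`` (only if >1 session present), one of
    ``trial``/``ln_trial`` (never both), ``OA_clicks`` (only with a full
    acoustic + accelerometry record from >= 2 playback sessions) and
    ``FA_clicks`` (additionally, only if the focal animal clicked in
    more than 2 trials).
    """
    context = context or {}
    optional: list[list[tuple[str, ...]]] = []
    if "session" in data and data["session"].nunique() > 1:
        optional.append([(), ("session",)])
    optional.append([(), ("trial",), ("ln_trial",)])
    full_sessions = context.get("n_sessions_with_full_records", 0)
    if full_sessions >= 2 and "OA_clicks" in data:
        optional.append([(), ("OA_clicks",)])
    if (
        full_sessions >= 2
        and context.get("FA_click_trial_count", 0) > 2
        and "FA_clicks" in data
    ):
        optional.append([(), ("FA_clicks",)])
    out = []
    for combo in itertools.product(*optional):
        terms = (primary,) + tuple(t for group in combo for t in group)
        out.append(terms)
    return out


def select_model(
    data: pd.DataFrame,
    response: str,
    primary: str = "RL",
    links: tuple[str, ...] = ("log", "inverse"),
    context: dict | None = None,
    family: str = "gamma",
) -> tuple[FittedGlm, pd.DataFrame]:
    """Fit every candidate term set under every candidate link and
    return the fit with the lowest AICc plus the full candidate table.

    AICc ties closer than 0.01 are broken toward fewer parameters.
    Non-significant variables in the winning model are retained.
    """
    if family == "binomial":
        links = ("logit",)
    rows = []
    fits: list[FittedGlm] = []
    for terms in candidate_terms(primary, data, context):
        for link in links:
            spec = ModelSpec(family=family, link=link, response=response, terms=terms)
            try:
                fit = fit_glm(spec, data)
            except (GlmConvergenceError, ValueError) as exc:
                rows.append(
                    {"link": link, "terms": "+".join(terms), "k": np.nan,
                     "aicc": np.inf, "converged": False, "note": str(exc)}
                )
                continue
            fits.append(fit)
            rows.append(
                {"link": link, "terms": "+".join(terms), "k": fit.k,
                 "aicc": fit.aicc, "converged": True, "note": ""}
            )
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    if not fits:
        raise GlmConvergenceError("no candidate model converged")
    best_aicc = min(f.aicc for f in fits)
    near = [f for f in fits if f.aicc - best_aicc < 0.01]
    best = min(near, key=lambda f: (f.k, f.aicc))
    return best, table


def _held_value(term_col: str, held_at: dict, terms: tuple[str, ...]) -> float:
    """Design-column value for a held-fixed covariate."""
    if term_col.startswith("session["):
        lev = term_col[len("session[") : -1]
        held = str(held_at.get("session", ""))
        return 1.0 if held == lev else 0.0
    if term_col == "ln_trial":
        return float(np.log(held_at.get("trial", 6.5)))
    if term_col == "trial":
        return float(held_at.get("trial", 6.5))
    return float(held_at.get(term_col, 0.0))


def predict_with_intervals(
    fit: FittedGlm,
    grid_spec: dict,
    held_at: dict | None = None,
) -> PredictionCurve:
    """Response-scale predictions with 95% intervals on a fine grid.

    ``grid_spec`` is ``{"var": name, "lo": x0, "hi": x1, "step": 0.1}``.
    Other covariates are held at ``held_at`` (trial defaults to the
    intermediate value 6.5 when trial/ln_trial is in the model; factors
    default to their reference level).  Intervals are
    eta +- t(n-k, 0.975) * SE(eta) on the link scale, back-transformed
    through the inverse link; for the inverse link the linear predictor
    must stay positive over the whole grid.
    """
    held_at = dict(held_at or {})
    var = grid_spec["var"]
    step = grid_spec.get("step", 0.1)
    ngrid = int(round((grid_spec["hi"] - grid_spec["lo"]) / step))
    grid = grid_spec["lo"] + step * np.arange(ngrid + 1)

    cols = fit.design_info["columns"]
    var_cols = {var}
    if var == "rise_time":
        var_cols.add("rise_time_ms")
    if not var_cols & set(cols):
        raise ValueError(f"grid variable {var!r} is not a term of the model")

    X = np.empty((len(grid), len(cols)))
    for j, col in enumerate(cols):
        if col == "intercept":
            X[:, j] = 1.0
        elif col in var_cols:
            X[:, j] = grid
        else:
            X[:, j] = _held_value(col, held_at, fit.spec.terms)

    beta = fit.params.to_numpy()
    cov = np.asarray(fit.result.cov_params())
    eta = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    tq = scipy.stats.t.ppf(0.975, fit.n - fit.k)

    linkname = fit.spec.link
    if linkname == "log":
        inv = np.exp
    elif linkname == "inverse":
        if np.any(eta <= 0) or np.any(eta - tq * se <= 0):
            raise ValueError(
                "inverse-link linear predictor crosses zero on the grid; "
                "the mean is singular there"
            )
        inv = lambda e: 1.0 / e
    elif linkname == "identity":
        inv = lambda e: e
    else:  # logit
        inv = lambda e: 1.0 / (1.0 + np.exp(-e))

    lo = inv(eta - tq * se)
    hi = inv(eta + tq * se)
    fitted = inv(eta)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return PredictionCurve(
        var=var, grid=grid, fitted=fitted, interval_lo=lo, interval_hi=hi,
        held_at=held_at,
    )


def mc_prediction_intervals(
    fit: FittedGlm,
    grid_spec: dict,
    held_at: dict | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> PredictionCurve:
    """Monte-Carlo analogue of :func:`predict_with_intervals`: sample
    t-distributed deviates on the link scale and take empirical 2.5/97.5
    percentiles after back-transforming.  Provided for fidelity checks;
    the analytic quantile version is equivalent in distribution."""
    base = predict_with_intervals(fit, grid_spec, held_at)
    held_at = dict(held_at or {})
    cols = fit.design_info["columns"]
    var_cols = {base.var, "rise_time_ms" if base.var == "rise_time" else base.var}
    X = np.empty((len(base.grid), len(cols)))
    for j, col in enumerate(cols):
        if col == "intercept":
            X[:, j] = 1.0
        elif col in var_cols:
            X[:, j] = base.grid
        else:
            X[:, j] = _held_value(col, held_at, fit.spec.terms)
    eta = X @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, np.asarray(fit.result.cov_params()), X))
    rng = np.random.default_rng(seed)
    draws = eta[None, :] + se[None, :] * rng.standard_t(fit.n - fit.k, (n_draws, 1))
    inv = {"log": np.exp, "identity": lambda e: e,
           "inverse": lambda e: 1.0 / e,
           "logit": lambda e: 1.0 / (1.0 + np.exp(-e))}[fit.spec.link]
    resp = inv(draws)
    lo, hi = np.percentile(resp, [2.5, 97.5], axis=0)
    return PredictionCurve(
        var=base.var, grid=base.grid, fitted=base.fitted,
        interval_lo=lo, interval_hi=hi, held_at=held_at,
    )


def nagelkerke_r2(fit: FittedGlm, null_fit: FittedGlm) -> float:
    """Nagelkerke pseudo R-squared:
    [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)], clamped to [0, 1].

    ``null_fit`` must be the intercept-only model on the same data.
    """
    if null_fit.n != fit.n:
        raise ValueError("null model must be fitted to the same data")
    n = fit.n
    ll0, ll1 = null_fit.llf, fit.llf
    if ll1 < ll0:
        import warnings

        warnings.warn("full model has lower likelihood than null; returning 0")
        return 0.0
    num = 1.0 - np.exp(2.0 / n * (ll0 - ll1))
    den = 1.0 - np.exp(2.0 / n * ll0)
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def fit_null(fit_or_spec, data: pd.DataFrame) -> FittedGlm:
    """Intercept-only companion fit for pseudo-R2 computation."""
    spec = fit_or_spec.spec if isinstance(fit_or_spec, FittedGlm) else fit_or_spec
    link = "log" if spec.family == "gamma" else "logit"
    null_spec = ModelSpec(spec.family, link, spec.response, ())
    return fit_glm(null_spec, data)
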