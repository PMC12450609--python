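"""Multilevel random-effects meta-analysis of dominance-discovery correlations.

Each effect is a Spearman rank correlation r_s between a dominance metric
and discovery ability within one ant community, carried on the Fisher-Z
scale (z = atanh r_s) with known sampling variance v.  Two variance
conventions are supported: the Fisher default 1/(n - 3) and the
Spearman-adjusted 1.06/(n - 3).  Effects from the same study share a
study-level random intercept:

    z_i = x_i' beta + u_study(i) + e_i,
    u ~ Normal(0, sigma2_study),  e_i ~ Normal(0, v_i).

sigma2_study and beta are estimated by restricted maximum likelihood
(variance on the log scale with multi-start, plus an explicit boundary
check at zero).  The moderator model has the three dominance-type means
fitted without an intercept plus species number as a covariate, so the
type coefficients are directly the predicted mean effects per type
(back-transformed with tanh for reporting on the r scale).

Diagnostics: a modified Egger regression of the meta-model residuals on
the effect standard errors (a nonzero intercept signals funnel-plot
asymmetry), and a multilevel I2 using the typical within-study variance
s2 = (k - 1) sum(w) / ((sum w)^2 - sum(w^2)), w_i = 1/v_i.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectRecord",
    "MetaFit",
    "BiasDiagnostics",
    "make_effect",
    "effects_frame",
    "fit_multilevel",
    "egger_test",
    "i2_multilevel",
]

log = logging.getLogger(__name__)

DOM_TYPES = ("behavioral", "numerical", "ecological")
VARIANCE_CONVENTIONS = {"fisher": 1.0, "spearman_adjusted": 1.06}


@dataclass(frozen=True)
class EffectRecord:
    """One study x community x dominance-type correlation on the z scale."""

    study: str
    response: str
    dom_type: str
    n_species: int
    r_s: float
    z: float
    v: float

    def __post_init__(self) -> None:
        if self.dom_type not in DOM_TYPES:
            raise ValueError(f"unknown dominance type {self.dom_type!r}")
        if self.v <= 0:
            raise ValueError("sampling variance must be positive")


def make_effect(
    study: str,
    response: str,
    dom_type: str,
    r_s: float,
    n_species: int,
    variance_convention: str = "fisher",
) -> EffectRecord:
    """Fisher-Z transform one Spearman correlation into a meta-analysis effect.

    z = atanh(r_s); v = c/(n - 3) with c = 1 (fisher) or 1.06
    (spearman_adjusted).  Correlations from fewer than four taxa are
    unreliable and rejected; |r_s| = 1 has infinite z and is rejected.
    """
    if variance_convention not in VARIANCE_CONVENTIONS:
        raise ValueError(f"unknown variance convention {variance_convention!r}")
    if n_species < 4:
        raise ValueError(
            f"effect {study}/{response} excluded: fewer than four unique ant taxa "
            f"(n = {n_species})"
        )
    if abs(r_s) >= 1.0:
        raise ValueError(f"|r_s| = 1 gives an infinite Fisher-Z value ({study}/{response})")
    c = VARIANCE_CONVENTIONS[variance_convention]
    return EffectRecord(study, response, dom_type, n_species, r_s,
                        float(np.arctanh(r_s)), c / (n_species - 3))


def effects_frame(effects: list[EffectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"study": e.study, "response": e.response, "dom_type": e.dom_type,
             "n_species": e.n_species, "r_s": e.r_s, "z": e.z, "v": e.v}
            for e in effects
        ]
    )


@dataclass
class MetaFit:
    mu: float  # pooled mean (z scale); for the moderator model, NaN
    se_mu: float
    ci_z: tuple[float, float]
    ci_r: tuple[float, float]
    sigma2_study: float
    k: int
    coefficients: pd.DataFrame  # term, estimate, se, ci_lo, ci_hi (z scale)
    cov_coef: np.ndarray
    QM: dict[str, dict[str, float]] = field(default_factory=dict)
    X: np.ndarray | None = None
    z: np.ndarray | None = None
    v: np.ndarray | None = None
    studies: np.ndarray | None = None
    moderators: str = "none"

    def type_means(self) -> pd.DataFrame:
        """Back-transformed predicted mean correlation per dominance type."""
        rows = []
        for _, row in self.coefficients.iterrows():
            if row["term"].startswith("dom_type:"):
                rows.append(
                    {
                        "dom_type": row["term"].split(":", 1)[1],
                        "r": float(np.tanh(row["estimate"])),
                        "ci_lo": float(np.tanh(row["ci_lo"])),
                        "ci_hi": float(np.tanh(row["ci_hi"])),
                    }
                )
        return pd.DataFrame(rows)


def _design(df: pd.DataFrame, moderators: str) -> tuple[np.ndarray, list[str]]:
    if moderators == "none":
        return np.ones((len(df), 1)), ["intercept"]
    if moderators == "dom_type":
        cols = [(df["dom_type"] == t).to_numpy(float) for t in DOM_TYPES]
        X = np.column_stack(cols + [df["n_species"].to_numpy(float)])
        return X, [f"dom_type:{t}" for t in DOM_TYPES] + ["n_species"]
    raise ValueError(f"unknown moderator set {moderators!r}")


def _profile_beta(sigma2: float, X: np.ndarray, z: np.ndarray, v: np.ndarray,
                  Zs: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """GLS beta, its covariance, and the REML log-likelihood at sigma2."""
    V = sigma2 * (Zs @ Zs.T) + np.diag(v)
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    M = XtVi @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ (XtVi @ z)
    resid = z - X @ beta
    sign, logdetV = np.linalg.slogdet(V)
    sign2, logdetM = np.linalg.slogdet(M)
    ll = -0.5 * (logdetV + logdetM + resid @ Vi @ resid)
    return beta, Minv, float(ll)


def fit_multilevel(
    effects: list[EffectRecord] | pd.DataFrame, moderators: str = "none"
) -> MetaFit:
    """REML fit of the study-level random-effects model.

    ``moderators`` is "none" (intercept-only pooled mean) or "dom_type"
    (three type means without intercept + species number).  Wald 95%
    intervals use normal quantiles on the z scale and are back-transformed
    with tanh.
    """
    df = effects if isinstance(effects, pd.DataFrame) else effects_frame(effects)
    if df.empty:
        raise ValueError("no effects supplied")
    z = df["z"].to_numpy(float)
    v = df["v"].to_numpy(float)
    k = len(df)
    studies, study_idx = np.unique(df["study"].to_numpy(), return_inverse=True)
    Zs = np.zeros((k, len(studies)))
    Zs[np.arange(k), study_idx] = 1.0

    X, terms = _design(df, moderators)
    if moderators == "dom_type":
        counts = df["dom_type"].value_counts()
        missing = [t for t in DOM_TYPES if counts.get(t, 0) == 0]
        if missing:
            raise ValueError(f"no effects for dominance type(s) {missing}")

    if k == 1:
        log.warning("single effect: sigma2_study fixed at 0, CI from sampling variance only")
        sigma2, beta, covb = 0.0, np.array([z[0]]), np.array([[v[0]]])
    else:
        def neg_ll(log_s2) -> float:
            return -_profile_beta(float(np.exp(np.asarray(log_s2).item())), X, z, v, Zs)[2]

        best_s2, best_val = 0.0, -_profile_beta(0.0, X, z, v, Zs)[2]
        for start in (0.001, 0.05, 0.5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = optimize.minimize(
                    neg_ll, x0=[np.log(start)], method="L-BFGS-B",
                    bounds=[(np.log(1e-10), np.log(1e3))], tol=1e-10,
                )
            if not res.success and not np.isfinite(res.fun):
                raise RuntimeError(f"REML optimization failed: {res.message}")
            if res.fun < best_val - 1e-12:
                best_val, best_s2 = float(res.fun), float(np.exp(res.x[0]))
        sigma2 = 0.0 if best_s2 < 1e-8 else best_s2
        beta, covb, _ = _profile_beta(sigma2, X, z, v, Zs)

    if len(studies) == 1 and k > 1:
        log.warning("all effects from one study: study intercept is confounded "
                    "with the mean; sigma2_study is not identifiable")

    se = np.sqrt(np.diag(covb))
    zcrit = stats.norm.ppf(0.975)
    coef = pd.DataFrame(
        {"term": terms, "estimate": beta, "se": se,
         "ci_lo": beta - zcrit * se, "ci_hi": beta + zcrit * se}
    )

    QM: dict[str, dict[str, float]] = {}
    if moderators == "dom_type":
        # joint Wald chi-square of the three type means (df = 3)
        sel = np.arange(3)
        b3 = beta[sel]
        q3 = float(b3 @ np.linalg.solve(covb[np.ix_(sel, sel)], b3))
        QM["dom_type"] = {"stat": q3, "df": 3, "p": float(stats.chi2.sf(q3, 3))}
        qn = float(beta[3] ** 2 / covb[3, 3])
        QM["n_species"] = {"stat": qn, "df": 1, "p": float(stats.chi2.sf(qn, 1))}
        mu, se_mu = np.nan, np.nan
        ci_z = ci_r = (np.nan, np.nan)
    else:
        mu, se_mu = float(beta[0]), float(se[0])
        ci_z = (mu - zcrit * se_mu, mu + zcrit * se_mu)
        ci_r = (float(np.tanh(ci_z[0])), float(np.tanh(ci_z[1])))

    return MetaFit(mu, se_mu, ci_z, ci_r, sigma2, k, coef, covb,
                   QM, X, z, v, df["study"].to_numpy(), moderators)


@dataclass(frozen=True)
class BiasDiagnostics:
    egger_intercept: float
    egger_t: float
    egger_p: float
    i2_total: float


def egger_test(fit: MetaFit) -> tuple[float, float, float]:
    """Modified Egger regression: meta-model residuals on effect SEs.

    Residuals are marginal (random effects at zero): z_i - x_i' beta.
    Returns (intercept, t, two-sided p); a nonzero intercept signals
    funnel asymmetry, i.e. possible publication bias.
    """
    if fit.k < 3:
        raise ValueError("Egger regression needs >= 3 effects")
    se_i = np.sqrt(fit.v)
    if np.ptp(se_i) == 0:
        raise ValueError("effect standard errors are constant: Egger predictor degenerate")
    resid = fit.z - fit.X @ fit.coefficients["estimate"].to_numpy()
    Xe = np.column_stack([np.ones_like(se_i), se_i])
    coef, *_ = np.linalg.lstsq(Xe, resid, rcond=None)
    fitted = Xe @ coef
    dof = fit.k - 2
    s2 = float((resid - fitted) @ (resid - fitted)) / dof
    cov = s2 * np.linalg.inv(Xe.T @ Xe)
    t = coef[0] / np.sqrt(cov[0, 0])
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(coef[0]), float(t), float(p)


def i2_multilevel(fit: MetaFit) -> float:
    """Multilevel I2: percent of total variance beyond sampling error.

    Uses the typical within-study variance
    s2 = (k - 1) sum(w) / ((sum w)^2 - sum(w^2)) with w_i = 1/v_i.
    """
    if fit.k < 2:
        raise ValueError("I2 needs >= 2 effects")
    w = 1.0 / fit.v
    s2 = (fit.k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    return float(100.0 * fit.sigma2_study / (fit.sigma2_study + s2))


def bias_diagnostics(fit: MetaFit) -> BiasDiagnostics:
    intercept, t, p = egger_test(fit)
    return BiasDiagnostics(intercept, t, p, i2_multilevel(fit))
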