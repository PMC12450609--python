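"""Linear mixed models and estimated marginal means for site metrics.

Every dominance/discovery metric is compared across taxa on a common
currency: the estimated marginal mean (EMM) per taxon from a linear
mixed model.  The model for a metric has taxon (and optionally
competitor identity) as fixed factors, sampling effort in hours as a
covariate, and site (optionally bait nested within site) as random
intercepts; fitting is by REML.

The EMM reference grid is the conventional one: predictions are averaged
with equal weight over the observed levels of the other fixed factors,
covariates are held at their grand mean, and random effects are set to
zero.  Standard errors come from the fixed-effect covariance matrix via
the averaged design row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["ModelSpec", "fit_emm"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure for one metric's mixed model.

    ``fixed`` lists categorical fixed factors and must include "taxon";
    ``covariates`` are numeric columns (typically "effort_h");
    ``random_intercepts`` may be ["site"] or ["site", "bait"] (bait is
    nested within site); ``transform`` is "identity" or "log" on the
    response.
    """

    response: str
    fixed: tuple[str, ...] = ("taxon",)
    covariates: tuple[str, ...] = ()
    random_intercepts: tuple[str, ...] = ("site",)
    transform: str = "identity"

    def __post_init__(self) -> None:
        if "taxon" not in self.fixed:
            raise ValueError("'taxon' must be among the fixed factors")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.random_intercepts and self.random_intercepts[0] != "site":
            raise ValueError("random intercepts must start with 'site'")


def _formula(spec: ModelSpec) -> str:
    terms = [f"C({f})" for f in spec.fixed] + list(spec.covariates)
    return f"value ~ {' + '.join(terms)}"


def fit_emm(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fit the metric's mixed model and return per-taxon EMMs.

    ``data`` is a long site-metric table with columns ``value``, ``site``,
    ``taxon`` and whatever ``spec`` references.  Returns a frame with
    columns ``taxon``, ``estimate``, ``se``, ``df`` and ``n_obs``
    (``df`` is the residual degrees-of-freedom proxy n - rank(X)).

    Degenerate random-effect variances (zero between-group variance) are
    retained and logged, never silently re-specified.  Taxa observed only
    once are kept and flagged in the log.
    """
    df = data.copy()
    needed = {"value", *spec.fixed, *spec.covariates, *spec.random_intercepts}
    missing = needed - set(df.columns)
    if missing:
        raise KeyError(f"data lacks columns {sorted(missing)}")
    df = df.dropna(subset=["value"])
    if df["taxon"].nunique() < 2:
        raise ValueError("need data on at least two taxa")
    if spec.transform == "log":
        if (df["value"] <= 0).any():
            raise ValueError("log transform requires strictly positive responses")
        df["value"] = np.log(df["value"])

    singletons = df["taxon"].value_counts()
    for taxon in singletons[singletons == 1].index:
        log.warning("taxon %r has a single observation; EMM will be imprecise", taxon)

    formula = _formula(spec)
    if spec.random_intercepts:
        vc = None
        if "bait" in spec.random_intercepts:
            # bait ids repeat across sites; nest explicitly
            df["bait_in_site"] = df["site"].astype(str) + ":" + df["bait"].astype(str)
            vc = {"bait": "0 + C(bait_in_site)"}
        model = smf.mixedlm(formula, df, groups=df["site"], re_formula="1", vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = model.fit(reml=True)
        if fit.cov_re.size and float(fit.cov_re.iloc[0, 0]) <= 1e-10:
            log.warning(
                "%s: site random-intercept variance estimated at boundary (0)", spec.response
            )
        design_info = model.data.design_info
        params = fit.fe_params
        cov = fit.cov_params().loc[params.index, params.index]
        n, rank = model.exog.shape[0], np.linalg.matrix_rank(model.exog)
    else:
        model = smf.ols(formula, df)
        fit = model.fit()
        design_info = model.data.design_info
        params = fit.params
        cov = fit.cov_params()
        n, rank = model.exog.shape[0], np.linalg.matrix_rank(model.exog)

    emm_rows = _emm_rows(df, spec, design_info)
    beta = params.to_numpy()
    V = cov.to_numpy()
    out = []
    for taxon, L in emm_rows:
        est = float(L @ beta)
        # boundary fits can leave tiny negative quadratic forms
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        out.append({"taxon": taxon, "estimate": est, "se": se, "df": n - rank,
                    "n_obs": int((df["taxon"] == taxon).sum())})
    return pd.DataFrame(out)


def _emm_rows(
    df: pd.DataFrame, spec: ModelSpec, design_info: patsy.DesignInfo
) -> list[tuple[str, np.ndarray]]:
    """Averaged design row per taxon over the EMM reference grid."""
    other_factors = [f for f in spec.fixed if f != "taxon"]
    grand_means = {c: df[c].mean() for c in spec.covariates}
    rows = []
    for taxon in sorted(df["taxon"].unique()):
        grid = {"taxon": [taxon]}
        for f in other_factors:
            grid[f] = sorted(df[f].dropna().unique())
        ref = pd.DataFrame(
            [
                {**{k: v for k, v in zip(grid.keys(), combo)}, **grand_means}
                for combo in _product(list(grid.values()))
            ]
        )
        (X,) = patsy.build_design_matrices([design_info], ref)
        rows.append((taxon, np.asarray(X).mean(axis=0)))
    return rows


def _product(levels: list[list]) -> list[tuple]:
    out: list[tuple] = [()]
    for lv in levels:
        out = [c + (x,) for c in out for x in lv]
    return out
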