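"""Cross-metric correlations, the trade-off axis, and trait associations.

Dominance metrics and discovery ability are compared across taxa with
Pearson correlations (sensitive to magnitudes, not just ranks).  The
dominance-discovery trade-off is summarized by the first principal
component of the two standardized vectors: for two variables with
correlation r, PC1 explains (1 + |r|) / 2 of the variance and its
loadings are +/- 1/sqrt(2).  The axis is oriented so the dominance
loading is positive, making PC1 a deterministic trade-off score that
increases with behavioral dominance and decreases with discovery
ability when the two trade off.

Sign convention: discovery *ability* is the negated discovery-time EMM,
so larger = faster discoverer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "TradeoffAxis", "pearson_with_test", "tradeoff_axis",
           "correlation_matrix", "trait_associations"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float
    n: int
    perfect: bool = False  # |r| = 1: t is infinite, p reported as 0


@dataclass(frozen=True)
class TradeoffAxis:
    scores: pd.Series  # taxon -> PC1 coordinate
    loadings: tuple[float, float]  # (dominance, discovery)
    var_share: float  # fraction of variance on PC1, in [0.5, 1]
    r: float  # correlation of the two inputs


def _paired(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat({"x": x, "y": y}, axis=1).dropna()
    return joined["x"].to_numpy(float), joined["y"].to_numpy(float)


def pearson_with_test(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson correlation with the exact t test on n - 2 df.

    Pairwise-complete observations are used; n >= 3 and non-constant
    vectors are required.  For |r| = 1 the t statistic is infinite and
    p is reported as 0 with the ``perfect`` flag set.
    """
    xv, yv = _paired(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-14:
        sign = 1.0 if r > 0 else -1.0
        return CorrelationResult(sign, sign * np.inf, df, 0.0, n, perfect=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r, float(t), df, float(p), n)


def tradeoff_axis(dominance: pd.Series, discovery: pd.Series) -> TradeoffAxis:
    """PC1 of standardized behavioral dominance and discovery ability.

    Both vectors are standardized to zero mean and unit variance (the
    correlation-matrix PCA); PC1 of a 2x2 correlation matrix has
    eigenvalue 1 + |r| and loadings (1, sign(r)) / sqrt(2).  The sign is
    fixed so the dominance loading is positive.
    """
    joined = pd.concat({"dom": dominance, "disc": discovery}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 taxa with both metrics")
    for col in ("dom", "disc"):
        if np.ptp(joined[col].to_numpy()) == 0:
            raise ValueError("constant metric vector: PCA undefined")
    z = (joined - joined.mean()) / joined.std(ddof=1)
    r = float(np.corrcoef(z["dom"], z["disc"])[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    w = np.array([1.0, sign]) / np.sqrt(2.0)
    scores = pd.Series(z.to_numpy() @ w, index=joined.index, name="pc1")
    return TradeoffAxis(scores, (float(w[0]), float(w[1])), (1.0 + abs(r)) / 2.0, r)


def correlation_matrix(metrics: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson tests among metric columns (taxa as rows)."""
    rows = []
    cols = list(metrics.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            res = pearson_with_test(metrics[a], metrics[b])
            rows.append(
                {"metric_x": a, "metric_y": b, "r": res.r, "t": res.t,
                 "df": res.df, "p": res.p, "n": res.n}
            )
    return pd.DataFrame(rows)


def trait_associations(pc1: pd.Series, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson tests of the trade-off axis against each trait column."""
    rows = []
    for trait in traits.columns:
        res = pearson_with_test(pc1, traits[trait])
        rows.append({"trait": trait, "r": res.r, "t": res.t, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)
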