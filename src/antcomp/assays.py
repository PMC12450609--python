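"""One-on-one aggression assays: scoring, pairwise tallies, and Colley ratings.

Staged encounters between worker pairs are scored on a 4-point aggression
scale (1 = touch, 2 = avoid, 3 = brief aggression, 4 = prolonged fight).
A trial's winner is the ant showing strictly more aggressive behaviors
(scores 3-4); with equal aggression, the ant showing strictly fewer
avoidance behaviors (score 2) wins; otherwise the trial is a tie
(including trials where the ants only ever touched).  Trials with no
interaction at all are excluded.

Win/loss/tie records accumulate into a pairwise tally from which two
dominance scores are derived per taxon:

* the *raw* score, (wins + ties/2) / interactions, which is biased by
  unequal numbers of trials per pair, and
* the *Colley* rating, the solution of the strictly diagonally dominant
  linear system ``(2 + n_i) r_i - sum_j n_ij r_j = 1 + (w_i - l_i)/2``,
  which adjusts each taxon's score for the strength of its opponents.
  Ratings always average 0.5 (they sum to T/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayTrial",
    "InteractionRecord",
    "PairwiseTally",
    "score_assay",
    "build_tally",
    "colley_ratings",
    "dominance_table",
]

#: behavior codes, in order of increasing aggression
TOUCH, AVOID, AGGRESSION, FIGHT = 1, 2, 3, 4


@dataclass(frozen=True)
class AssayTrial:
    """A single staged encounter between one worker of each of two taxa.

    ``counts_a``/``counts_b`` map behavior score (1-4) to the number of
    times that behavior was recorded for the respective ant.
    """

    site: str
    taxon_a: str
    taxon_b: str
    counts_a: Mapping[int, int] = field(default_factory=dict)
    counts_b: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError(f"assay requires two distinct taxa, got {self.taxon_a!r} twice")
        for counts in (self.counts_a, self.counts_b):
            for score, n in counts.items():
                if score not in (TOUCH, AVOID, AGGRESSION, FIGHT):
                    raise ValueError(f"unknown behavior score {score!r}")
                if n < 0:
                    raise ValueError(f"negative behavior count {n} for score {score}")


@dataclass(frozen=True)
class InteractionRecord:
    """Outcome of one scored interaction (assay trial or bait replacement).

    For a tie, ``winner``/``loser`` simply hold the unordered pair.
    """

    context: str  # "assay" or "bait"
    site: str
    winner: str
    loser: str
    is_tie: bool = False
    bait: str | None = None

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise ValueError("winner and loser must differ")
        if self.context not in ("assay", "bait"):
            raise ValueError(f"unknown interaction context {self.context!r}")


def _n_aggr(counts: Mapping[int, int]) -> int:
    return counts.get(AGGRESSION, 0) + counts.get(FIGHT, 0)


def score_assay(trial: AssayTrial) -> InteractionRecord | None:
    """Score one assay trial into a win/loss/tie record.

    Returns ``None`` for trials in which no interactions occurred (all
    behavior counts zero); such trials are excluded from analysis.
    """
    total = sum(trial.counts_a.values()) + sum(trial.counts_b.values())
    if total == 0:
        return None

    aggr_a, aggr_b = _n_aggr(trial.counts_a), _n_aggr(trial.counts_b)
    if aggr_a != aggr_b:
        winner, loser = (
            (trial.taxon_a, trial.taxon_b) if aggr_a > aggr_b else (trial.taxon_b, trial.taxon_a)
        )
        return InteractionRecord("assay", trial.site, winner, loser)

    # equal aggression: fewer avoidance events wins; equal again (incl.
    # touch-only trials) is a tie
    avoid_a = trial.counts_a.get(AVOID, 0)
    avoid_b = trial.counts_b.get(AVOID, 0)
    if avoid_a != avoid_b:
        winner, loser = (
            (trial.taxon_a, trial.taxon_b) if avoid_a < avoid_b else (trial.taxon_b, trial.taxon_a)
        )
        return InteractionRecord("assay", trial.site, winner, loser)
    return InteractionRecord("assay", trial.site, trial.taxon_a, trial.taxon_b, is_tie=True)


@dataclass
class PairwiseTally:
    """Win and tie count matrices over an ordered taxon registry.

    ``wins[i, j]`` counts interactions in which taxon ``i`` beat taxon
    ``j``; ``ties`` is symmetric; both diagonals are zero.
    """

    taxa: list[str]
    wins: np.ndarray
    ties: np.ndarray

    @property
    def n_games(self) -> np.ndarray:
        """Pairwise interaction counts (wins either way + ties)."""
        return self.wins + self.wins.T + self.ties

    def n_interactions(self, taxon: str) -> int:
        i = self.taxa.index(taxon)
        return int(self.n_games[i].sum())

    def validate(self) -> None:
        T = len(self.taxa)
        if self.wins.shape != (T, T) or self.ties.shape != (T, T):
            raise ValueError("tally matrices must be square over the taxon registry")
        if not np.array_equal(self.ties, self.ties.T):
            raise ValueError("tie matrix must be symmetric")
        if np.any(np.diag(self.wins)) or np.any(np.diag(self.ties)):
            raise ValueError("tally diagonals must be zero")
        if (self.wins < 0).any() or (self.ties < 0).any():
            raise ValueError("tally counts must be non-negative")


def build_tally(
    records: Iterable[InteractionRecord], taxa: Sequence[str] | None = None
) -> PairwiseTally:
    """Accumulate interaction records into a pairwise win/tie tally.

    ``taxa`` fixes the registry (and its order); by default the registry
    is the sorted set of taxa appearing in the records.  A record naming
    a taxon outside an explicit registry raises ``KeyError``.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a tally from an empty record list")
    if taxa is None:
        taxa = sorted({t for r in records for t in (r.winner, r.loser)})
    index = {t: i for i, t in enumerate(taxa)}
    T = len(taxa)
    wins = np.zeros((T, T), dtype=int)
    ties = np.zeros((T, T), dtype=int)
    for r in records:
        try:
            i, j = index[r.winner], index[r.loser]
        except KeyError as exc:
            raise KeyError(f"taxon {exc.args[0]!r} not in registry {list(taxa)}") from None
        if r.is_tie:
            ties[i, j] += 1
            ties[j, i] += 1
        else:
            wins[i, j] += 1
    tally = PairwiseTally(list(taxa), wins, ties)
    tally.validate()
    return tally


def raw_scores(tally: PairwiseTally) -> pd.Series:
    """Raw dominance: (wins + ties/2) / interactions per taxon.

    Taxa with no interactions get NaN (no information, not 0).
    """
    tally.validate()
    n = tally.n_games.sum(axis=1).astype(float)
    points = tally.wins.sum(axis=1) + 0.5 * tally.ties.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n > 0, points / np.where(n > 0, n, 1.0), np.nan)
    return pd.Series(vals, index=tally.taxa, name="raw")


def colley_ratings(tally: PairwiseTally, tie_mode: str = "half-win") -> pd.Series:
    """Colley bias-free ratings from a pairwise tally.

    Solves ``C r = b`` with ``C[i,i] = 2 + n_i``, ``C[i,j] = -n_ij`` and
    ``b[i] = 1 + (w_i - l_i) / 2``.  A tie counts as half a win and half
    a loss for each side: it increments the game counts but leaves
    ``w - l`` unchanged.  Taxa with no interactions are excluded from the
    system (their rating is NaN in the returned series) rather than pinned
    at 0.5.

    The system matrix is strictly diagonally dominant, hence always
    nonsingular; ratings lie in (0, 1) and sum to T/2 over the included
    taxa.
    """
    if tie_mode != "half-win":
        raise ValueError(f"unsupported tie_mode {tie_mode!r}")
    tally.validate()
    if len(tally.taxa) < 2:
        raise ValueError("Colley ratings need at least two taxa")

    games = tally.n_games
    played = games.sum(axis=1) > 0
    out = pd.Series(np.nan, index=tally.taxa, name="colley")
    if played.sum() == 0:
        # no interactions anywhere: every taxon is uninformative but the
        # full system still has the uniform solution
        return pd.Series(0.5, index=tally.taxa, name="colley")

    idx = np.flatnonzero(played)
    g = games[np.ix_(idx, idx)]
    w = tally.wins[np.ix_(idx, idx)].sum(axis=1)
    l = tally.wins[np.ix_(idx, idx)].T.sum(axis=1)
    C = -g.astype(float)
    np.fill_diagonal(C, 2.0 + g.sum(axis=1))
    b = 1.0 + (w - l) / 2.0
    r = np.linalg.solve(C, b)
    out.iloc[idx] = r
    return out


def dominance_table(tally: PairwiseTally) -> pd.DataFrame:
    """Per-taxon dominance summary: raw score, Colley rating, interaction count."""
    raw = raw_scores(tally)
    colley = colley_ratings(tally)
    n = pd.Series(tally.n_games.sum(axis=1), index=tally.taxa, name="n_interactions")
    return pd.DataFrame({"raw": raw, "colley": colley, "n_interactions": n}).rename_axis("taxon")
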