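"""Synthetic ant-community generator with known latent structure.

Emulates the field design end to end — staged one-on-one assays, honey
baits observed on a discrete schedule at gridded stations, pitfall traps
with heterogeneous deployment times, and a per-taxon trait table — from a
community with explicit latent parameters:

* ``alpha``   latent aggressiveness, driving both assay outcomes and
  bait-takeover (Bradley-Terry) probabilities;
* ``lam``     colony density (colonies per site), driving pitfall capture,
  recruitment, and part of the bait-discovery hazard;
* ``delta``   discovery efficiency; the per-taxon bait arrival hazard is
  proportional to lam * delta;
* ``rho``     the target latent correlation between alpha and log(delta) —
  negative rho builds in a dominance-discovery trade-off, positive rho a
  discovery-defense community.

Body mass increases with alpha (dominants are bigger) with noise, and
head width scales allometrically with mass.  Bait state is sampled only
at the observation schedule, so discovery times are right-censored
exactly as in the field.  All draws flow from one seed via independent
sub-streams per table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assays as asy
from .baits import BaitSeries, BaitObservation, PitfallRecord

__all__ = ["CommunityTruth", "SyntheticBundle", "simulate_community", "default_schedule",
           "recovery_report"]


@dataclass(frozen=True)
class CommunityTruth:
    """Latent per-taxon parameters of a simulated community."""

    taxa: tuple[str, ...]
    alpha: tuple[float, ...]
    lam: tuple[float, ...]
    delta: tuple[float, ...]
    mass_mg: tuple[float, ...]
    head_width_mm: tuple[float, ...]
    rho: float
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": self.taxa, "alpha": self.alpha, "lam": self.lam,
             "delta": self.delta, "mass_mg": self.mass_mg,
             "head_width_mm": self.head_width_mm}
        )


@dataclass
class SyntheticBundle:
    assays: pd.DataFrame
    baits: pd.DataFrame
    pitfalls: pd.DataFrame
    traits: pd.DataFrame
    truth: CommunityTruth

    def bait_series(self) -> list[BaitSeries]:
        return baits_to_series(self.baits)

    def pitfall_records(self) -> list[PitfallRecord]:
        return pitfalls_to_records(self.pitfalls)


def default_schedule(duration_h: float) -> list[float]:
    """Half-hourly checks for the first 1.5 h, then daily until collection."""
    sched = [0.5, 1.0, 1.5, 3.0, 6.0]
    day = 24.0
    while day <= duration_h:
        sched.append(day)
        day += 24.0
    return [t for t in sched if t <= duration_h]


# -- generator defaults: the study conditions ------------------------------
SD_ALPHA = 1.3        # spread of latent aggressiveness across taxa
SD_LOG_DELTA = 0.9    # spread of log discovery efficiency
SD_LOG_LAM = 0.3      # spread of log colony density
MEAN_LAM = 2.0        # colonies per site
ARRIVAL_RATE = 0.05   # bait arrival hazard per (lam * delta) unit, per hour
MEAN_STAY_H = 12.0    # mean bait occupancy bout before abandonment
TIE_PROB = 0.25       # failed challenger co-occupies instead of retreating
RECRUIT_RATE = 2.0    # recruitment intensity per unit colony density
PITFALL_RATE = 0.010  # capture hazard per (lam * hour)
MASS_BASE_MG = 1.5    # body mass at alpha = 0
MASS_SLOPE = 0.55     # log-mass increase per unit alpha
SD_LOG_MASS = 0.20


def simulate_community(
    T: int = 5,
    S: int = 16,
    B: int = 10,
    P: int = 10,
    n_assays: int = 200,
    rho: float = -0.9,
    seed: int = 0,
    bait_durations: tuple[float, ...] = (48.0, 72.0, 96.0, 120.0),
    pitfall_duration_range: tuple[float, float] = (26.0, 72.0),
    alpha_discovery_decoupled: bool = False,
) -> SyntheticBundle:
    """Simulate a community and its full sampling campaign.

    Defaults mirror the field design: 5 taxa, 16 sites, 10 baits and 10
    pitfall traps per site on the same grid, ~200 one-on-one assays, with
    per-site heterogeneity in deployment duration (hence sampling
    effort).  ``rho`` sets the latent dominance-discovery correlation;
    ``alpha_discovery_decoupled`` re-draws the assay aggressiveness
    independently of the bait-contest aggressiveness (a robustness
    switch separating individual- from colony-level dominance).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if T < 2:
        raise ValueError("need at least two taxa")
    ss = np.random.SeedSequence(seed)
    r_truth, r_assay, r_bait, r_pit = [np.random.default_rng(c) for c in ss.spawn(4)]

    taxa = tuple(f"T{i+1:02d}" for i in range(T))
    cov = np.array([[SD_ALPHA**2, rho * SD_ALPHA * SD_LOG_DELTA],
                    [rho * SD_ALPHA * SD_LOG_DELTA, SD_LOG_DELTA**2]])
    draw = r_truth.multivariate_normal(np.zeros(2), cov, size=T, method="svd")
    alpha, log_delta = draw[:, 0], draw[:, 1]
    lam = np.exp(np.log(MEAN_LAM) + r_truth.normal(0.0, SD_LOG_LAM, T))
    mass = np.exp(np.log(MASS_BASE_MG) + MASS_SLOPE * alpha
                  + r_truth.normal(0.0, SD_LOG_MASS, T))
    head = 0.9 * mass ** (1 / 3) * np.exp(r_truth.normal(0.0, 0.05, T))
    contest_alpha = alpha
    if alpha_discovery_decoupled:
        contest_alpha = r_truth.normal(0.0, SD_ALPHA, T)

    truth = CommunityTruth(taxa, tuple(alpha), tuple(lam), tuple(np.exp(log_delta)),
                           tuple(mass), tuple(head), rho, seed)
    sites = [f"S{i+1:02d}" for i in range(S)]

    assays_df = _simulate_assays(r_assay, taxa, alpha, sites, n_assays)
    baits_df = _simulate_baits(r_bait, taxa, contest_alpha, lam, np.exp(log_delta),
                               sites, B, bait_durations)
    pitfalls_df = _simulate_pitfalls(r_pit, taxa, lam, sites, P, pitfall_duration_range)
    traits_df = pd.DataFrame(
        {"taxon": taxa, "head_width_mm": np.round(head, 3),
         "body_mass_mg": np.round(mass, 4)}
    )
    return SyntheticBundle(assays_df, baits_df, pitfalls_df, traits_df, truth)


def _simulate_assays(rng, taxa, alpha, sites, n_assays) -> pd.DataFrame:
    """Behavior tallies per staged pair: aggression ~ Poisson(exp(alpha)),
    avoidance ~ Poisson(exp(-alpha)), plus incidental touches."""
    T = len(taxa)
    pairs = [(i, j) for i in range(T) for j in range(i + 1, T)]
    rows = []
    for trial in range(n_assays):
        i, j = pairs[rng.integers(len(pairs))]
        site = sites[rng.integers(len(sites))]
        row = {"site": site, "trial_id": f"A{trial+1:04d}",
               "taxon_a": taxa[i], "taxon_b": taxa[j]}
        for who, idx in (("a", i), ("b", j)):
            aggr = rng.poisson(np.exp(alpha[idx]))
            fight = rng.binomial(aggr, 0.3)
            row[f"{who}_touch"] = int(rng.poisson(0.8))
            row[f"{who}_avoid"] = int(rng.poisson(np.exp(-alpha[idx])))
            row[f"{who}_aggr"] = int(aggr - fight)
            row[f"{who}_fight"] = int(fight)
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_baits(rng, taxa, alpha, lam, delta, sites, B, durations) -> pd.DataFrame:
    """Continuous-time bait dynamics sampled at the observation schedule.

    Arrivals per taxon are Poisson with hazard ARRIVAL_RATE * lam * delta;
    the first arrival claims the bait; a challenger displaces the current
    holder with Bradley-Terry probability on the contest aggressiveness,
    else co-occupies with probability TIE_PROB; occupancy bouts end by
    abandonment after an exponential stay.
    """
    T = len(taxa)
    hazard = ARRIVAL_RATE * lam * delta
    rows = []
    for s_i, site in enumerate(sites):
        duration = float(durations[s_i % len(durations)])
        schedule = default_schedule(duration)
        for b in range(B):
            bait = f"B{b+1:02d}"
            events = []  # (time, taxon index)
            for t_i in range(T):
                n = rng.poisson(hazard[t_i] * duration)
                for t_arr in np.sort(rng.uniform(0.0, duration, n)):
                    events.append((float(t_arr), t_i))
            events.sort()
            # occupants: taxon -> (arrival order stamp, departure time)
            occupants: dict[int, float] = {}
            order: list[int] = []
            samples: dict[float, dict[int, int]] = {t: {} for t in schedule}
            ev = 0
            for t_obs in schedule:
                while ev < len(events) and events[ev][0] <= t_obs:
                    t_arr, tx = events[ev]
                    ev += 1
                    _prune(occupants, order, t_arr)
                    stay = rng.exponential(MEAN_STAY_H)
                    if tx in occupants:
                        occupants[tx] = max(occupants[tx], t_arr + stay)
                    elif not occupants:
                        occupants[tx] = t_arr + stay
                        order.append(tx)
                    else:
                        holder = order[0]
                        p_win = np.exp(alpha[tx]) / (np.exp(alpha[tx]) + np.exp(alpha[holder]))
                        u = rng.uniform()
                        if u < p_win:
                            occupants.clear()
                            order.clear()
                            occupants[tx] = t_arr + stay
                            order.append(tx)
                        elif u < p_win + (1 - p_win) * TIE_PROB and len(order) < 2:
                            occupants[tx] = t_arr + stay
                            order.append(tx)
                _prune(occupants, order, t_obs)
                for tx in order:
                    samples[t_obs][tx] = 1 + int(rng.poisson(RECRUIT_RATE * lam[tx]))
            for t_obs in schedule:
                present = samples[t_obs]
                if not present:
                    rows.append({"site": site, "bait": bait, "duration_h": duration,
                                 "obs_time_h": t_obs, "taxon": "", "workers": 0})
                else:
                    for tx, workers in sorted(present.items()):
                        rows.append({"site": site, "bait": bait, "duration_h": duration,
                                     "obs_time_h": t_obs, "taxon": taxa[tx],
                                     "workers": workers})
    return pd.DataFrame(rows)


def _prune(occupants: dict[int, float], order: list[int], t: float) -> None:
    gone = [tx for tx, dep in occupants.items() if dep <= t]
    for tx in gone:
        del occupants[tx]
        order.remove(tx)


def _simulate_pitfalls(rng, taxa, lam, sites, P, duration_range) -> pd.DataFrame:
    rows = []
    lo, hi = duration_range
    for site in sites:
        duration = float(np.round(rng.uniform(lo, hi), 1))
        for p in range(P):
            trap = f"P{p+1:02d}"
            caught = [taxa[i] for i in range(len(taxa))
                      if rng.uniform() < 1.0 - np.exp(-PITFALL_RATE * lam[i] * duration)]
            if not caught:
                rows.append({"site": site, "trap": trap, "duration_h": duration, "taxon": ""})
            for tx in caught:
                rows.append({"site": site, "trap": trap, "duration_h": duration, "taxon": tx})
    return pd.DataFrame(rows)


def baits_to_series(baits: pd.DataFrame) -> list[BaitSeries]:
    """Group a long bait table into per-bait observation series."""
    out = []
    for (site, bait), grp in baits.groupby(["site", "bait"], sort=True):
        duration = float(grp["duration_h"].iloc[0])
        schedule = sorted(grp["obs_time_h"].unique())
        obs = [
            BaitObservation(site, bait, float(r.obs_time_h), str(r.taxon), int(r.workers))
            for r in grp.itertuples()
            if isinstance(r.taxon, str) and r.taxon != ""
        ]
        out.append(BaitSeries(site, bait, duration, schedule, obs))
    return out


def pitfalls_to_records(pitfalls: pd.DataFrame) -> list[PitfallRecord]:
    out = []
    for (site, trap), grp in pitfalls.groupby(["site", "trap"], sort=True):
        duration = float(grp["duration_h"].iloc[0])
        taxa = frozenset(t for t in grp["taxon"] if isinstance(t, str) and t != "")
        out.append(PitfallRecord(site, trap, duration, taxa))
    return out


def recovery_report(bundle: SyntheticBundle, pipeline: dict) -> dict[str, float]:
    """Compare pipeline estimates against the community's latent truth.

    ``pipeline`` is the dict returned by ``workbench.run_pipeline``.
    Reports Spearman correlations of Colley ratings vs alpha and of
    pitfall numerical-dominance EMMs vs lam, and the sign of the
    estimated dominance-discovery correlation next to the latent rho.
    """
    from scipy import stats as sps

    truth = bundle.truth.frame().set_index("taxon")
    report: dict[str, float] = {}

    dom = pipeline.get("dominance_individual")
    if dom is None:
        raise KeyError("pipeline output lacks 'dominance_individual'")
    joined = dom.join(truth, how="inner")
    report["spearman_colley_alpha"] = float(
        sps.spearmanr(joined["colley"], joined["alpha"]).statistic
    )

    emm_pit = pipeline.get("emm_prop_pitfalls")
    if emm_pit is not None:
        j = emm_pit.set_index("taxon").join(truth, how="inner")
        report["spearman_numerical_lam"] = float(
            sps.spearmanr(j["estimate"], j["lam"]).statistic
        )

    corr = pipeline.get("dominance_discovery_r")
    if corr is not None:
        report["dominance_discovery_r"] = float(corr)
        report["tradeoff_sign_matches_rho"] = float(
            np.sign(corr) == np.sign(bundle.truth.rho)
        )
    return report
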