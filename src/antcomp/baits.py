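"""Bait time series and pitfall records: replacements, occupancy, discovery.

Sugar baits are observed at discrete times after deployment; each
observation records which taxa are present and how many workers each has
recruited.  Pitfall traps record which taxa were captured over a known
deployment duration.  From these, four site-level quantities are derived:

* colony-level behavioral dominance — a taxon wins an interaction when it
  replaces another taxon previously occupying a bait between consecutive
  occupied observations; a pair co-occurring at two or more consecutive
  observations of the same bait ties;
* numerical dominance — the proportion of baits (or pitfall traps)
  occupied at least once per site;
* ecological dominance — baits occupied divided by pitfall traps occupied
  per site (foraging success relative to environmental abundance);
* discovery ability — the time at which a taxon is first observed at a
  bait, right-censored by the observation schedule.

An intervening empty observation breaks a replacement chain: displacement
cannot be distinguished from abandonment across a gap, so no interaction
is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assays import InteractionRecord

__all__ = [
    "BaitObservation",
    "BaitSeries",
    "PitfallRecord",
    "detect_replacements",
    "prop_won_rows",
    "occupancy_proportions",
    "ecological_ratio",
    "discovery_times",
    "recruitment_biomass",
]

log = logging.getLogger(__name__)

METRICS = ("prop_baits", "prop_pitfalls", "eco_ratio", "discovery_h", "prop_won")

#: columns of the long-format site-metric table shared by all downstream models
METRIC_COLUMNS = [
    "site",
    "taxon",
    "metric",
    "value",
    "effort_h",
    "bait",
    "competitor",
    "n_occupied",
    "n_stations",
]


@dataclass(frozen=True)
class BaitObservation:
    site: str
    bait: str
    t: float  # hours since deployment
    taxon: str
    workers: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("observation time must be >= 0 h")
        if self.workers < 1:
            raise ValueError("a presence row needs >= 1 worker")


@dataclass
class BaitSeries:
    """All observations of one bait, on a strictly increasing schedule.

    ``schedule`` lists every observation time, including times when the
    bait was empty (an empty observation carries information: it breaks
    replacement chains).
    """

    site: str
    bait: str
    duration_h: float
    schedule: list[float]
    observations: list[BaitObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        sched = list(self.schedule)
        if sched and sched[0] < 0:
            raise ValueError(
                f"bait {self.site}/{self.bait}: observation times must be >= 0 h"
            )
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError(
                f"bait {self.site}/{self.bait}: schedule must be strictly increasing"
            )
        if sched and sched[-1] > self.duration_h + 1e-9:
            raise ValueError("schedule extends past the deployment duration")
        times = set(sched)
        for obs in self.observations:
            if obs.t not in times:
                raise ValueError(
                    f"observation at t={obs.t} h not on the schedule of bait "
                    f"{self.site}/{self.bait}"
                )

    def occupants(self) -> list[tuple[float, dict[str, int]]]:
        """Taxon -> worker count per schedule time (empty dict = empty bait)."""
        by_time: dict[float, dict[str, int]] = {t: {} for t in self.schedule}
        for obs in self.observations:
            by_time[obs.t][obs.taxon] = obs.workers
        return [(t, by_time[t]) for t in self.schedule]


@dataclass(frozen=True)
class PitfallRecord:
    site: str
    trap: str
    duration_h: float
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("pitfall duration must be positive")


def detect_replacements(
    series: BaitSeries, taxa: Sequence[str] | None = None
) -> list[InteractionRecord]:
    """Score bait takeovers and ties from one bait's observation series.

    Between consecutive non-empty observations, every taxon that left is
    scored as beaten by every taxon present at the later observation
    (one record per winner-loser pair; multiple replacements at the same
    bait are separate interactions).  An unordered pair present together
    at >= 2 consecutive observations yields exactly one tie for that bait.
    No interaction is scored across an empty observation.
    """
    if taxa is not None:
        known = set(taxa)
        for obs in series.observations:
            if obs.taxon not in known:
                raise KeyError(f"taxon {obs.taxon!r} not in registry")

    records: list[InteractionRecord] = []
    tied_pairs: set[frozenset[str]] = set()
    occ = series.occupants()
    for (_, prev), (_, cur) in zip(occ, occ[1:]):
        p, c = set(prev), set(cur)
        if not p or not c:
            continue
        for loser in sorted(p - c):
            for winner in sorted(c):
                records.append(
                    InteractionRecord("bait", series.site, winner, loser, bait=series.bait)
                )
        for a in sorted(p & c):
            for b in sorted(p & c):
                if a < b and frozenset((a, b)) not in tied_pairs:
                    tied_pairs.add(frozenset((a, b)))
                    records.append(
                        InteractionRecord(
                            "bait", series.site, a, b, is_tie=True, bait=series.bait
                        )
                    )
    return records


def prop_won_rows(all_series: Iterable[BaitSeries]) -> pd.DataFrame:
    """Proportion of interactions won per taxon x competitor x bait.

    The unit of analysis for colony-level behavioral dominance: within
    each bait, for every interacting pair, each taxon's
    (wins + ties/2) / interactions against that competitor.  The two
    rows of a pair sum to 1.
    """
    rows = []
    for series in all_series:
        recs = detect_replacements(series)
        pairs: dict[tuple[str, str], dict[str, float]] = {}
        for r in recs:
            key = tuple(sorted((r.winner, r.loser)))
            d = pairs.setdefault(key, {key[0]: 0.0, key[1]: 0.0, "n": 0.0})
            d["n"] += 1
            if r.is_tie:
                d[key[0]] += 0.5
                d[key[1]] += 0.5
            else:
                d[r.winner] += 1.0
        for (a, b), d in pairs.items():
            for taxon, comp in ((a, b), (b, a)):
                rows.append(
                    {
                        "site": series.site,
                        "taxon": taxon,
                        "metric": "prop_won",
                        "value": d[taxon] / d["n"],
                        "effort_h": series.duration_h,
                        "bait": series.bait,
                        "competitor": comp,
                        "n_occupied": np.nan,
                        "n_stations": np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def _site_effort(durations: dict[str, list[float]]) -> dict[str, float]:
    return {site: float(sum(d)) for site, d in durations.items()}


def occupancy_proportions(
    records: Sequence[BaitSeries] | Sequence[PitfallRecord],
    kind: str,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per site x taxon proportion of stations occupied at least once.

    ``kind`` selects the station type ("baits" or "pitfalls") and the
    metric name of the output rows.  Every registry taxon gets a row in
    every site, including zeros: absence is data.  ``effort_h`` is the
    total deployment time (hours) of all stations in the site.
    """
    if kind not in ("baits", "pitfalls"):
        raise ValueError(f"kind must be 'baits' or 'pitfalls', got {kind!r}")
    records = list(records)
    if not records:
        raise ValueError("no stations supplied")

    # site -> station -> set of taxa observed there
    present: dict[str, dict[str, set[str]]] = {}
    durations: dict[str, list[float]] = {}
    seen: set[str] = set()
    for rec in records:
        if kind == "baits":
            assert isinstance(rec, BaitSeries)
            station, taxa_here = rec.bait, {o.taxon for o in rec.observations}
        else:
            assert isinstance(rec, PitfallRecord)
            station, taxa_here = rec.trap, set(rec.taxa)
        present.setdefault(rec.site, {})[station] = taxa_here
        durations.setdefault(rec.site, []).append(rec.duration_h)
        seen |= taxa_here

    registry = list(taxa) if taxa is not None else sorted(seen)
    unknown = seen - set(registry)
    if unknown:
        raise KeyError(f"taxa {sorted(unknown)} not in registry")

    effort = _site_effort(durations)
    metric = "prop_baits" if kind == "baits" else "prop_pitfalls"
    rows = []
    for site, stations in present.items():
        n_stations = len(stations)
        for taxon in registry:
            n_occ = sum(taxon in occ for occ in stations.values())
            rows.append(
                {
                    "site": site,
                    "taxon": taxon,
                    "metric": metric,
                    "value": n_occ / n_stations,
                    "effort_h": effort[site],
                    "bait": None,
                    "competitor": None,
                    "n_occupied": n_occ,
                    "n_stations": n_stations,
                }
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def ecological_ratio(bait_occ: pd.DataFrame, pitfall_occ: pd.DataFrame) -> pd.DataFrame:
    """Ecological dominance: baits occupied / pitfall traps occupied per site x taxon.

    Cells with zero pitfall occupancy are excluded (the ratio is
    undefined) and logged.  Effort is the summed bait + pitfall
    deployment hours of the site.
    """
    b = bait_occ.set_index(["site", "taxon"])
    p = pitfall_occ.set_index(["site", "taxon"])
    common = b.index.intersection(p.index)
    rows = []
    n_excluded = 0
    for site, taxon in common:
        nb, npf = b.loc[(site, taxon), "n_occupied"], p.loc[(site, taxon), "n_occupied"]
        if npf == 0:
            if nb > 0:
                n_excluded += 1
            continue
        rows.append(
            {
                "site": site,
                "taxon": taxon,
                "metric": "eco_ratio",
                "value": nb / npf,
                "effort_h": b.loc[(site, taxon), "effort_h"] + p.loc[(site, taxon), "effort_h"],
                "bait": None,
                "competitor": None,
                "n_occupied": np.nan,
                "n_stations": np.nan,
            }
        )
    if n_excluded:
        log.warning(
            "ecological_ratio: excluded %d site x taxon cells with bait presence "
            "but zero pitfall occupancy (ratio undefined)",
            n_excluded,
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def discovery_times(series: BaitSeries) -> pd.DataFrame:
    """Time of first observation of each taxon at one bait.

    Values are right-censored by the schedule: a taxon first seen at the
    48-h check may have arrived any time since the previous check.  Taxa
    never observed at the bait yield no row (missing, not zero).
    """
    first: dict[str, float] = {}
    for t, occ in series.occupants():
        for taxon in occ:
            first.setdefault(taxon, t)
    rows = [
        {
            "site": series.site,
            "taxon": taxon,
            "metric": "discovery_h",
            "value": t,
            "effort_h": series.duration_h,
            "bait": series.bait,
            "competitor": None,
            "n_occupied": np.nan,
            "n_stations": np.nan,
        }
        for taxon, t in sorted(first.items())
    ]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def recruitment_biomass(
    all_series: Sequence[BaitSeries], traits: pd.DataFrame
) -> pd.DataFrame:
    """Recruitment rate and recruited worker biomass per taxon.

    Recruitment rate is the mean worker count over observations where the
    taxon was present, first per bait, then averaged over baits; recruit
    biomass is body mass x recruitment rate.  ``traits`` must carry
    ``taxon``, ``head_width_mm`` and ``body_mass_mg`` columns.
    """
    mass = traits.set_index("taxon")["body_mass_mg"]
    head = traits.set_index("taxon")["head_width_mm"]
    per_bait: dict[str, list[float]] = {}
    for series in all_series:
        counts: dict[str, list[int]] = {}
        for _, occ in series.occupants():
            for taxon, workers in occ.items():
                counts.setdefault(taxon, []).append(workers)
        for taxon, ws in counts.items():
            per_bait.setdefault(taxon, []).append(float(np.mean(ws)))
    rows = []
    for taxon, rates in sorted(per_bait.items()):
        if taxon not in mass.index:
            raise KeyError(f"no body mass available for taxon {taxon!r}")
        rate = float(np.mean(rates))
        rows.append(
            {
                "taxon": taxon,
                "head_width_mm": float(head[taxon]),
                "body_mass_mg": float(mass[taxon]),
                "recruitment_rate": rate,
                "recruit_biomass_mg": float(mass[taxon]) * rate,
            }
        )
    return pd.DataFrame(rows)
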