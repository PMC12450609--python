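"""I/O, configuration, and the end-to-end analysis pipeline.

Stage order mirrors the analysis: assay scoring -> bait/pitfall metrics
-> mixed-model EMMs -> cross-metric correlation matrix -> trade-off axis
-> trait associations -> (optional) meta-analysis of a curated effect
table.  Every run writes its tables as CSV plus a ``manifest.json`` with
the configuration hash and seed so identical manifests reproduce
identical outputs.

Input schemas (all CSV):
  assays.csv    site, trial_id, taxon_a, taxon_b, a_touch, a_avoid,
                a_aggr, a_fight, b_touch, b_avoid, b_aggr, b_fight
  baits.csv     site, bait, duration_h, obs_time_h, taxon, workers
                (empty observation = row with an empty taxon field)
  pitfalls.csv  site, trap, duration_h, taxon (empty trap = empty taxon)
  traits.csv    taxon, head_width_mm, body_mass_mg
  effects.csv   study, response, dom_type, n_species, spearman_r
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays as asy
from . import baits as bp
from . import meta as mt
from . import tradeoff as to
from .emm import ModelSpec, fit_emm
from .simulate import SyntheticBundle, baits_to_series, pitfalls_to_records

__all__ = ["read_assays", "read_baits", "read_pitfalls", "read_traits", "read_effects",
           "assay_records", "run_pipeline", "write_outputs", "load_config"]

log = logging.getLogger(__name__)

REQUIRED = {
    "assays": ["site", "trial_id", "taxon_a", "taxon_b", "a_touch", "a_avoid",
               "a_aggr", "a_fight", "b_touch", "b_avoid", "b_aggr", "b_fight"],
    "baits": ["site", "bait", "duration_h", "obs_time_h", "taxon", "workers"],
    "pitfalls": ["site", "trap", "duration_h", "taxon"],
    "traits": ["taxon", "head_width_mm", "body_mass_mg"],
    "effects": ["study", "response", "dom_type", "n_species", "spearman_r"],
}

#: default mixed-model structure per metric
DEFAULT_SPECS = {
    "prop_won": ModelSpec("prop_won", fixed=("taxon", "competitor"),
                          random_intercepts=("site", "bait")),
    "prop_baits": ModelSpec("prop_baits", covariates=("effort_h",)),
    "prop_pitfalls": ModelSpec("prop_pitfalls", covariates=("effort_h",)),
    "eco_ratio": ModelSpec("eco_ratio", covariates=("effort_h",)),
    "discovery_h": ModelSpec("discovery_h", covariates=("effort_h",)),
}


def _read_csv(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in REQUIRED[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED[kind]]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, extra)
    return df[REQUIRED[kind]]


def read_assays(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, "assays")


def read_baits(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "baits")
    for col in ("duration_h", "obs_time_h"):
        df[col] = df[col].astype(float)
    df["workers"] = pd.to_numeric(df["workers"]).fillna(0).astype(int)
    before = len(df)
    df = df.drop_duplicates(subset=["site", "bait", "obs_time_h", "taxon"])
    if len(df) < before:
        log.warning("baits: dropped %d duplicated observation rows", before - len(df))
    return df


def read_pitfalls(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "pitfalls")
    df["duration_h"] = df["duration_h"].astype(float)
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "traits")
    for col in ("head_width_mm", "body_mass_mg"):
        df[col] = df[col].astype(float)
    return df


def read_effects(path: str | Path, variance_convention: str = "fisher") -> list[mt.EffectRecord]:
    """Load a curated effect table, excluding (with a notice) effects from
    fewer than four taxa."""
    df = _read_csv(path, "effects")
    effects = []
    for row in df.itertuples():
        try:
            effects.append(
                mt.make_effect(str(row.study), str(row.response), str(row.dom_type),
                               float(row.spearman_r), int(row.n_species),
                               variance_convention)
            )
        except ValueError as exc:
            log.warning("effects: %s", exc)
    return effects


def assay_records(assays: pd.DataFrame) -> list[asy.InteractionRecord]:
    """Score every assay row; no-contact trials are excluded."""
    records = []
    for row in assays.itertuples():
        trial = asy.AssayTrial(
            site=str(row.site), taxon_a=str(row.taxon_a), taxon_b=str(row.taxon_b),
            counts_a={1: int(row.a_touch), 2: int(row.a_avoid),
                      3: int(row.a_aggr), 4: int(row.a_fight)},
            counts_b={1: int(row.b_touch), 2: int(row.b_avoid),
                      3: int(row.b_aggr), 4: int(row.b_fight)},
        )
        rec = asy.score_assay(trial)
        if rec is not None:
            records.append(rec)
    log.info("assays: %d of %d trials had contact", len(records), len(assays))
    return records


def run_pipeline(
    assays: pd.DataFrame,
    baits: pd.DataFrame,
    pitfalls: pd.DataFrame,
    traits: pd.DataFrame,
    effects: list[mt.EffectRecord] | None = None,
    taxa: list[str] | None = None,
    specs: dict[str, ModelSpec] | None = None,
) -> dict:
    """Run all analysis stages on in-memory tables; returns a result dict.

    Keys: ``dominance_individual``, ``interactions``, ``site_metrics``,
    ``emm_<metric>`` per metric, ``correlations``, ``tradeoff_axis``,
    ``trait_assoc``, ``traits_derived``, ``metric_vectors``,
    ``dominance_discovery_r``, and (if effects given) ``meta``.
    """
    specs = {**DEFAULT_SPECS, **(specs or {})}
    results: dict = {}

    # -- stage 1: individual-level behavioral dominance --------------------
    records = assay_records(assays)
    tally = asy.build_tally(records, taxa)
    dom = asy.dominance_table(tally)
    results["dominance_individual"] = dom
    registry = taxa if taxa is not None else sorted(
        set(tally.taxa)
        | set(t for t in baits["taxon"] if t) | set(t for t in pitfalls["taxon"] if t)
    )

    # -- stage 2: bait/pitfall metrics --------------------------------------
    series = baits_to_series(baits)
    traps = pitfalls_to_records(pitfalls)
    bait_records = [r for s in series for r in bp.detect_replacements(s, registry)]
    results["interactions"] = pd.DataFrame(
        [{"context": r.context, "site": r.site, "bait": r.bait,
          "winner": r.winner, "loser": r.loser, "is_tie": r.is_tie}
         for r in records + bait_records]
    )
    prop_won = bp.prop_won_rows(series)
    bait_occ = bp.occupancy_proportions(series, "baits", registry)
    pit_occ = bp.occupancy_proportions(traps, "pitfalls", registry)
    eco = bp.ecological_ratio(bait_occ, pit_occ)
    disc_parts = [d for s in series if len(d := bp.discovery_times(s))]
    parts = [p for p in (prop_won, bait_occ, pit_occ, eco, *disc_parts) if len(p)]
    site_metrics = pd.concat(parts, ignore_index=True)
    results["site_metrics"] = site_metrics
    results["traits_derived"] = bp.recruitment_biomass(series, traits)
    log.info("stage baits: %d interactions, %d metric rows", len(bait_records),
             len(site_metrics))

    # -- stage 3: EMMs -------------------------------------------------------
    for metric, spec in specs.items():
        data = site_metrics[site_metrics["metric"] == metric]
        if data["taxon"].nunique() < 2:
            log.warning("metric %s: fewer than two taxa with data, EMM skipped", metric)
            continue
        results[f"emm_{metric}"] = fit_emm(data, spec)

    # -- stage 4: metric vectors and correlations ---------------------------
    vectors = {"behavioral_individual": dom["colley"]}
    emm_to_vector = {
        "prop_won": "behavioral_colony",
        "prop_baits": "numerical_baits",
        "prop_pitfalls": "numerical_pitfalls",
        "eco_ratio": "ecological",
    }
    for metric, name in emm_to_vector.items():
        emm = results.get(f"emm_{metric}")
        if emm is not None:
            vectors[name] = emm.set_index("taxon")["estimate"]
    emm_disc = results.get("emm_discovery_h")
    if emm_disc is not None:
        # discovery ability: larger = faster, hence the negated time EMM
        vectors["discovery_ability"] = -emm_disc.set_index("taxon")["estimate"]
    metric_vectors = pd.DataFrame(vectors)
    results["metric_vectors"] = metric_vectors
    results["correlations"] = to.correlation_matrix(metric_vectors)

    # -- stage 5: trade-off axis and traits ---------------------------------
    if "discovery_ability" in metric_vectors:
        axis = to.tradeoff_axis(metric_vectors["behavioral_individual"],
                                metric_vectors["discovery_ability"])
        results["tradeoff"] = axis
        results["tradeoff_axis"] = axis.scores.rename_axis("taxon").reset_index()
        results["dominance_discovery_r"] = to.pearson_with_test(
            metric_vectors["behavioral_individual"],
            metric_vectors["discovery_ability"],
        ).r
        td = results["traits_derived"].set_index("taxon")
        try:
            results["trait_assoc"] = to.trait_associations(axis.scores, td)
        except ValueError as exc:
            log.warning("trait associations skipped: %s", exc)

    # -- stage 6: meta-analysis ---------------------------------------------
    if effects:
        overall = mt.fit_multilevel(effects, moderators="none")
        moderated = mt.fit_multilevel(effects, moderators="dom_type")
        results["meta"] = {
            "overall": overall,
            "moderated": moderated,
            "bias_overall": mt.bias_diagnostics(overall),
            "bias_moderated": mt.bias_diagnostics(moderated),
        }
    else:
        log.info("no effect table supplied: meta-analysis stage skipped")
    return results


def run_pipeline_on_bundle(bundle: SyntheticBundle, **kwargs) -> dict:
    return run_pipeline(bundle.assays, bundle.baits, bundle.pitfalls, bundle.traits,
                        taxa=list(bundle.truth.taxa), **kwargs)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def write_outputs(results: dict, out_dir: str | Path, config: dict | None = None,
                  seed: int | None = None) -> None:
    """Write all tabular results as CSV plus a manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            path = out / f"{key}.csv"
            val.to_csv(path, index=isinstance(val.index, pd.Index) and val.index.name is not None)
            written[key] = path.name
        elif isinstance(val, pd.Series):
            (out / f"{key}.csv").write_text(val.to_csv())
            written[key] = f"{key}.csv"
    meta_res = results.get("meta")
    if meta_res:
        summary = meta_summary(meta_res)
        (out / "meta_summary.json").write_text(json.dumps(summary, indent=2))
        written["meta"] = "meta_summary.json"
    manifest = {
        "seed": seed,
        "config": config or {},
        "outputs": written,
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def meta_summary(meta_res: dict) -> dict:
    """Flatten the meta-analysis fits into a JSON-friendly summary."""
    overall, moderated = meta_res["overall"], meta_res["moderated"]
    bo, bm = meta_res["bias_overall"], meta_res["bias_moderated"]
    return {
        "pooled_r": float(np.tanh(overall.mu)),
        "pooled_ci_r": list(overall.ci_r),
        "sigma2_study": overall.sigma2_study,
        "k": overall.k,
        "type_means": moderated.type_means().to_dict(orient="records"),
        "QM": moderated.QM,
        "i2_overall": bo.i2_total,
        "i2_moderated": bm.i2_total,
        "egger_overall": {"intercept": bo.egger_intercept, "t": bo.egger_t, "p": bo.egger_p},
        "egger_moderated": {"intercept": bm.egger_intercept, "t": bm.egger_t, "p": bm.egger_p},
    }
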