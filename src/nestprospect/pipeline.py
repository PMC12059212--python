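"""End-to-end pipeline: simulate -> process -> home ranges -> permutation
tests -> autocorrelation -> settlement models.

Each stage is a thin orchestration over the library modules and writes its
outputs (CSV tables, a JSON manifest, diagnostic figures) under an output
directory.  Every stochastic stage derives its seed from the run seed, so a
run is reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autocorr import morans_i, temporal_acf
from .data import Dataset, write_tables
from .detections import (classify_status, count_floaters, dedupe_visits,
                         eligible_broods, filter_bouts, provisioning_rate)
from .glmm import ModelSpec, Term, fit_glmm, fit_hurdle
from .homerange import summarize_prospecting
from .permutation import perm_in_area, perm_mean_distance
from .settlement import (attach_owner_traits, body_condition, body_size_pca,
                         build_candidate_set, corrected_feed_rate,
                         fit_settlement_models)
from .simulate import GroundTruth, SimConfig, generate_dataset

__all__ = ["run_pipeline", "process_detections", "prospect_and_settle"]


def process_detections(ds: Dataset) -> dict:
    """Bout filtering, dedup, status scoring, floater counts, feed rates."""
    bouts, bout_stats = filter_bouts(ds.bouts)
    events = dedupe_visits(ds.detections)
    sex_map = dict(zip(ds.individuals["tag_id"], ds.individuals["sex"]))
    statuses = []
    for year in sorted(ds.breeding["year"].unique()):
        st = classify_status(ds.breeding, int(year),
                             tags=list(ds.individuals["tag_id"]))
        st["year"] = int(year)
        statuses.append(st)
    statuses = pd.concat(statuses, ignore_index=True)
    visit_counts = count_floaters(events, bouts, ds.breeding, statuses, sex_map)
    eligible = eligible_broods(visit_counts, ds.breeding)
    rates = provisioning_rate(events, bouts, ds.breeding)
    return {"bouts": bouts, "bout_stats": bout_stats, "events": events,
            "statuses": statuses, "visit_counts": visit_counts,
            "eligible_counts": eligible, "feed_rates": rates,
            "sex_map": sex_map}


def _stage_models(visit_counts: pd.DataFrame, n_nodes: int = 15) -> dict:
    """Stage-pattern Poisson GLMM and nestling-stage hurdle model."""
    out: dict = {}
    vc = visit_counts.copy()
    if len(vc) == 0:
        return out
    vc["year"] = vc["year"].astype(str)
    terms = [Term("stage", ref="pre_laying")]
    if vc["wave"].nunique() > 1:
        terms.append(Term("wave", ref="first"))
    if vc["year"].nunique() > 1:
        terms.append(Term("year"))
    if vc["stage"].nunique() > 1:
        spec = ModelSpec("n_floaters", "poisson", terms, offset="hours",
                         groups=["box_id"])
        out["stage_poisson"] = fit_glmm(spec, vc, n_nodes=n_nodes)

    nest = vc[vc["stage"].str.startswith("nestling")].dropna(
        subset=["nestling_age"]).copy()
    if len(nest) and (nest["n_floaters"] == 0).any() and (nest["n_floaters"] > 0).any():
        terms = [Term("nestling_age", degree=2, standardize=True),
                 Term("parent_visits"), Term("n_chicks")]
        if nest["wave"].nunique() > 1:
            terms.append(Term("wave", ref="first"))
        if nest["year"].nunique() > 1:
            terms.append(Term("year"))
        spec = ModelSpec("n_floaters", "ztpoisson", terms, offset="hours",
                         groups=["box_id"])
        out["nestling_hurdle"] = fit_hurdle(spec, nest, n_nodes=n_nodes)
    return out


def prospect_and_settle(ds: Dataset, processed: dict, truth: GroundTruth,
                        B: int = 10_000, seed: int = 0, n_nodes: int = 15
                        ) -> dict:
    """Home ranges, permutation tests, and settlement models."""
    events = processed["events"]
    statuses = processed["statuses"]
    # floater visits: detections of tags with floater status in that year
    ev = events.copy()
    ev["year"] = ev["timestamp"].dt.year
    floater_keys = {(r["tag_id"], r["year"]) for _, r in statuses.iterrows()
                    if r["status"] != "breeder"}
    sex_map = processed["sex_map"]
    mask = [(t, y) in floater_keys and sex_map.get(t) == "M"
            for t, y in zip(ev["tag_id"], ev["year"])]
    visits = ev[mask][["tag_id", "year", "box_id"]]
    summaries = summarize_prospecting(visits, ds.boxes)

    out: dict = {"summaries": summaries}
    if not summaries:
        return out
    median_area = float(np.median([s.area_m2 for s in summaries]))
    out["median_mcp_ha"] = median_area / 10_000.0

    settle = truth.settlements.set_index("tag_id")
    coords = ds.boxes.set_index("box_id")[["x", "y"]]
    anchors, settled, centers, radii = [], [], [], []
    kept = []
    for s in summaries:
        if s.tag_id not in settle.index:
            continue
        box = settle.loc[s.tag_id, "box_id"]
        anchors.append(s.centroid)
        settled.append(coords.loc[box].to_numpy())
        centers.append(s.centroid)
        radii.append(s.circle_radius_m)
        kept.append(s)
    if kept:
        anchors = np.array(anchors)
        settled = np.array(settled)
        out["perm_distance"] = perm_mean_distance(
            anchors, settled, ds.boxes, B=B, seed=seed)
        out["perm_in_area"] = perm_in_area(
            np.array(centers), np.array(radii), settled, ds.boxes,
            B=B, seed=seed + 1)

    # settlement covariates
    morph = ds.morphometrics
    owner_traits = None
    if morph is not None and len(morph) >= 3:
        pca = body_size_pca(morph)
        out["pca"] = pca
        cond = body_condition(morph, pca.scores)
        traits = morph[["tag_id", "year"]].copy()
        traits["ornament"] = morph[["throat1", "throat2", "throat3"]].mean(axis=1)
        traits["condition"] = cond
        rates = processed["feed_rates"]
        males = rates[rates["parent"] == "male"].reset_index(drop=True)
        if len(males) >= 5 and males["brood_size"].nunique() > 1:
            males["feed_rate_corrected"] = corrected_feed_rate(males)
            # join corrected feed rate by the male owner of that brood
            owner_rate = males.merge(
                ds.breeding[["box_id", "year", "wave", "male_owner"]],
                on=["box_id", "year", "wave"], how="left")
            owner_rate = owner_rate.dropna(subset=["male_owner"])
            owner_rate = owner_rate.groupby(["male_owner", "year"])[
                "feed_rate_corrected"].mean().reset_index()
            owner_rate.columns = ["tag_id", "year", "feed_rate_corrected"]
            traits = traits.merge(owner_rate, on=["tag_id", "year"], how="left")
        owner_traits = traits

    birth_years = None
    if ds.individuals is not None:
        birth_years = {r["tag_id"]: r["birth_year"]
                       for _, r in ds.individuals.iterrows()
                       if pd.notna(r["birth_year"])}
    cand = build_candidate_set(kept or summaries, ds.boxes,
                               truth.settlements, ds.breeding)
    if len(cand):
        cand = attach_owner_traits(cand, owner_year_traits=owner_traits,
                                   detections=ds.detections,
                                   breeding=ds.breeding,
                                   birth_years=birth_years)
        out["candidates"] = cand
        out["settlement_models"] = fit_settlement_models(cand, n_nodes=n_nodes)
    return out


def run_pipeline(config: SimConfig, out_dir: str | Path, B: int = 10_000,
                 n_nodes: int = 15, max_lag: int = 3,
                 make_figures: bool = True) -> dict:
    """Run every stage on a freshly simulated colony; write a report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()
                                 if not isinstance(v, dict)}}

    ds, truth = generate_dataset(config)
    write_tables(ds, out_dir / "tables")
    truth.settlements.to_csv(out_dir / "tables" / "settlements.csv", index=False)
    manifest["row_counts"] = ds.counts()

    processed = process_detections(ds)
    manifest["bout_filter"] = processed["bout_stats"]
    manifest["n_visit_count_rows"] = len(processed["visit_counts"])
    processed["visit_counts"].to_csv(out_dir / "visit_counts.csv", index=False)

    models = _stage_models(processed["eligible_counts"], n_nodes=n_nodes)
    results: dict = {"dataset": ds, "truth": truth, "processed": processed,
                     "stage_models": models}
    if "stage_poisson" in models:
        models["stage_poisson"].summary_frame().to_csv(
            out_dir / "stage_model.csv", index=False)

    # temporal + spatial autocorrelation of fledging success
    br = ds.breeding[(ds.breeding["wave"] == "first") & (~ds.breeding["manipulated"])]
    annual = br.groupby(["box_id", "year"])["fledged"].sum().reset_index()
    acf = temporal_acf(annual, max_lag=max_lag)
    results["temporal_acf"] = acf
    mean_fledged = annual.groupby("box_id")["fledged"].mean()
    coords = ds.boxes.set_index("box_id").loc[mean_fledged.index, ["x", "y"]]
    moran = morans_i(mean_fledged.to_numpy(), coords.to_numpy(),
                     lag_width=100.0, seed=config.seed + 1)
    results["morans_i"] = moran
    pd.DataFrame([{"lag": b.lag, "estimate": b.estimate, "p": b.p_value,
                   "n_pairs": b.n_pairs} for b in acf + moran]).to_csv(
        out_dir / "correlograms.csv", index=False)

    settled = prospect_and_settle(ds, processed, truth, B=B,
                                  seed=config.seed + 2, n_nodes=n_nodes)
    results.update(settled)
    if "settlement_models" in settled:
        settled["settlement_models"].to_csv(
            out_dir / "settlement_models.csv", index=False)
    for key in ("perm_distance", "perm_in_area"):
        if key in settled:
            r = settled[key]
            manifest[key] = {"observed": r.observed_stat, "p": r.p_value,
                             "B": r.B, "permuted_mean": r.permuted_mean}

    if make_figures:
        _figures(results, out_dir)
    manifest["n_prospect_summaries"] = len(settled.get("summaries", []))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _figures(results: dict, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vc = results["processed"]["visit_counts"]
    nest = vc[vc["stage"].str.startswith("nestling")].dropna(subset=["nestling_age"])
    if len(nest):
        fig, ax = plt.subplots(figsize=(6, 4))
        ages = sorted(nest["nestling_age"].unique())
        ax.boxplot([nest.loc[nest["nestling_age"] == a, "n_floaters"] for a in ages],
                   positions=ages, widths=0.6)
        ax.set_xlabel("nestling age (d)")
        ax.set_ylabel("male floaters per box-day")
        fig.tight_layout()
        fig.savefig(out_dir / "floaters_by_nestling_age.png", dpi=120)
        plt.close(fig)

    if "perm_distance" in results:
        r = results["perm_distance"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot([r.permuted_stats], positions=[1], widths=0.5)
        ax.scatter([1], [r.observed_stat], color="goldenrod", zorder=3,
                   label="observed mean")
        ax.set_xticks([1])
        ax.set_xticklabels(["permuted"])
        ax.set_ylabel("mean centroid-to-nest distance (m)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "distance_permutation.png", dpi=120)
        plt.close(fig)
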