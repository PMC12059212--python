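"""From raw RFID reads to analysis tables.

The processing chain is: keep only recording bouts with at least 120 min of
coverage; collapse bursts of reads with an 8-second filter; classify each
(box, date) into a breeding stage; score per-year breeding status of every
tag; count distinct male floaters per box-day; and compute parental
provisioning rates during chick rearing.

Breeding stages partition the nesting cycle into pre-laying (the 14 days
before the first egg), laying (one egg per day until clutch completion),
incubation (clutch completion to hatching), and four nestling-age bins
(ages 1-7, 8-14, 15-18, and >18 days up to fledging at ~22-23 days).

A bird's yearly status: breeding in the first clutch wave makes it a breeder
for the whole season; breeding only in a later wave makes it a transitioning
floater up to that lay date and a breeder afterwards; never breeding makes
it a floater throughout.  The two floater classes are pooled in all counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_LABELS",
    "MIN_BOUT_MINUTES",
    "DEDUPE_WINDOW_S",
    "filter_bouts",
    "dedupe_visits",
    "classify_stage",
    "assign_ownership",
    "classify_status",
    "count_floaters",
    "provisioning_rate",
    "eligible_broods",
]

STAGE_LABELS = ["pre_laying", "laying", "incubation", "nestling_1_7",
                "nestling_8_14", "nestling_15_18", "nestling_gt18"]
NESTLING_STAGES = STAGE_LABELS[3:]

MIN_BOUT_MINUTES = 120.0
DEDUPE_WINDOW_S = 8.0
PRE_LAYING_DAYS = 14
MAX_NESTLING_AGE = 22  # fledging window closes
FEED_SHARE_THRESHOLD = 0.20  # male feeds >= 20% of female feeds to qualify


def filter_bouts(bouts: pd.DataFrame, min_minutes: float = MIN_BOUT_MINUTES
                 ) -> tuple[pd.DataFrame, dict]:
    """Drop bouts shorter than ``min_minutes``; report retained coverage."""
    if len(bouts) == 0:
        return bouts.copy(), {"n_in": 0, "n_kept": 0}
    kept = bouts[bouts["minutes_recorded"] >= min_minutes].reset_index(drop=True)
    stats = {"n_in": len(bouts), "n_kept": len(kept)}
    if len(kept):
        stats.update(min=float(kept["minutes_recorded"].min()),
                     max=float(kept["minutes_recorded"].max()),
                     mean=float(kept["minutes_recorded"].mean()))
    return kept, stats


def dedupe_visits(events: pd.DataFrame, window_s: float = DEDUPE_WINDOW_S
                  ) -> pd.DataFrame:
    """Collapse repeat reads: within each (tag, box), drop a detection less
    than ``window_s`` seconds after the last *retained* detection.

    Anchoring the window to the last retained read (not the last raw read)
    makes the filter idempotent.
    """
    if len(events) == 0:
        return events.copy()
    ev = events.sort_values(["tag_id", "box_id", "timestamp"], kind="stable")
    keep = np.ones(len(ev), dtype=bool)
    ts = ev["timestamp"].to_numpy()
    tags = ev["tag_id"].to_numpy()
    boxes = ev["box_id"].to_numpy()
    last_kept = np.datetime64("1900-01-01")
    prev_key = None
    window = np.timedelta64(int(window_s * 1e9), "ns")
    for i in range(len(ev)):
        key = (tags[i], boxes[i])
        if key != prev_key:
            prev_key = key
            last_kept = ts[i]
            continue
        if ts[i] - last_kept < window:
            keep[i] = False
        else:
            last_kept = ts[i]
    return ev[keep].reset_index(drop=True)


def classify_stage(record: pd.Series, date) -> str:
    """Breeding stage of one nesting attempt on ``date``; 'none' outside.

    Windows are closed on the left, open on the right.  Laying is modeled as
    one egg per day.  The hatch day itself (nestling age 0) falls between
    incubation and the first nestling bin and is excluded.
    """
    date = pd.Timestamp(date)
    lay = pd.Timestamp(record["lay_date"])
    if pd.isna(lay):
        return "none"
    if lay - pd.Timedelta(days=PRE_LAYING_DAYS) <= date < lay:
        return "pre_laying"
    laying_end = lay + pd.Timedelta(days=int(record["clutch_size"]))
    if lay <= date < laying_end:
        return "laying"
    hatch = pd.Timestamp(record["hatch_date"]) if pd.notna(record["hatch_date"]) else None
    if hatch is None:
        return "none"
    if laying_end <= date < hatch:
        return "incubation"
    age = (date - hatch).days
    if 1 <= age <= 7:
        return "nestling_1_7"
    if 8 <= age <= 14:
        return "nestling_8_14"
    if 15 <= age <= 18:
        return "nestling_15_18"
    if 18 < age <= MAX_NESTLING_AGE:
        return "nestling_gt18"
    return "none"


def assign_ownership(events: pd.DataFrame, breeding: pd.DataFrame,
                     sex_map: dict[str, str]) -> pd.DataFrame:
    """Identify the male owner of each (box, year, wave) from visit counts.

    The male owner is the most frequent male visitor during chick feeding
    whose feeding-visit count reaches at least 20% of the female owner's
    feeds.  A tie between two qualifying males is flagged as unresolved
    rather than broken silently.  Returns columns ``box_id, year, wave,
    male_owner, unresolved``.
    """
    ev = events.copy()
    ev["date"] = ev["timestamp"].dt.normalize()
    rows = []
    for _, rec in breeding.iterrows():
        stage = ev[ev["box_id"] == rec["box_id"]].copy()
        if len(stage):
            labels = stage["date"].map(lambda d: classify_stage(rec, d))
            feeding = stage[labels.isin(NESTLING_STAGES)]
        else:
            feeding = stage
        female = rec.get("female_owner")
        fem_feeds = int((feeding["tag_id"] == female).sum()) if pd.notna(female) else 0
        males = feeding[feeding["tag_id"].map(lambda t: sex_map.get(t) == "M")]
        counts = males.groupby("tag_id").size().sort_values(ascending=False)
        qualified = counts[counts >= FEED_SHARE_THRESHOLD * fem_feeds] if fem_feeds else counts
        owner, unresolved = None, False
        if len(qualified):
            top = qualified.iloc[0]
            tied = qualified[qualified == top]
            if len(tied) > 1:
                unresolved = True
            else:
                owner = qualified.index[0]
        rows.append({"box_id": rec["box_id"], "year": rec["year"],
                     "wave": rec["wave"], "male_owner": owner,
                     "unresolved": unresolved})
    return pd.DataFrame(rows)


def classify_status(breeding: pd.DataFrame, year: int,
                    tags: list[str] | None = None) -> pd.DataFrame:
    """Yearly breeding status per tag: breeder / transitioning_floater / floater.

    ``transition_date`` is the lay date of a later-wave breeding attempt;
    before it the bird counts as a (transitioning) floater, after it as a
    breeder.  Tags never seen breeding are floaters all season.
    """
    br = breeding[breeding["year"] == year]
    first = set()
    later: dict[str, pd.Timestamp] = {}
    for _, rec in br.iterrows():
        for owner in (rec["male_owner"], rec["female_owner"]):
            if pd.isna(owner) or owner is None:
                continue
            if rec["wave"] == "first":
                first.add(owner)
            else:
                lay = pd.Timestamp(rec["lay_date"])
                if owner not in later or lay < later[owner]:
                    later[owner] = lay
    all_tags = set(tags or []) | first | set(later)
    rows = []
    for tag in sorted(all_tags):
        if tag in first:
            rows.append({"tag_id": tag, "status": "breeder", "transition_date": pd.NaT})
        elif tag in later:
            rows.append({"tag_id": tag, "status": "transitioning_floater",
                         "transition_date": later[tag]})
        else:
            rows.append({"tag_id": tag, "status": "floater", "transition_date": pd.NaT})
    return pd.DataFrame(rows)


def _is_floater_on(status_row, date) -> bool:
    if status_row is None:
        return True  # untracked tags are never recorded breeding
    if status_row["status"] == "floater":
        return True
    if status_row["status"] == "transitioning_floater":
        return date < status_row["transition_date"]
    return False


def count_floaters(events: pd.DataFrame, bouts: pd.DataFrame,
                   breeding: pd.DataFrame, statuses: pd.DataFrame,
                   sex_map: dict[str, str]) -> pd.DataFrame:
    """Per (box, day) count of distinct male floater visitors.

    ``events`` must already be deduplicated and ``bouts`` filtered.  Days
    with several bouts at a box pool their hours.  The box's own owners are
    excluded whatever their status elsewhere.  Output columns: box_id, date,
    year, wave, stage, nestling_age, n_chicks, n_floaters, parent_visits,
    hours.
    """
    ev = events.copy()
    ev["date"] = ev["timestamp"].dt.normalize()
    bt = bouts.copy()
    bt["date"] = pd.to_datetime(bt["date"]).dt.normalize()
    hours = bt.groupby(["box_id", "date"])["minutes_recorded"].sum() / 60.0
    status_idx = {(int(y), t): row
                  for y, grp in statuses.groupby("year")
                  for t, row in grp.set_index("tag_id").iterrows()} \
        if "year" in statuses.columns else None
    ev_by_boxday = dict(tuple(ev.groupby(["box_id", "date"])))
    hours_by_box: dict[str, list] = {}
    for (b, date), hrs in hours.items():
        hours_by_box.setdefault(b, []).append((date, hrs))

    rows = []
    for _, rec in breeding.iterrows():
        box = rec["box_id"]
        for date, hrs in hours_by_box.get(box, []):
            stage = classify_stage(rec, date)
            if stage == "none":
                continue
            day_ev = ev_by_boxday.get((box, date))
            owners = {o for o in (rec["male_owner"], rec["female_owner"])
                      if pd.notna(o) and o is not None}
            n_floaters = 0
            parent_visits = 0
            if day_ev is not None:
                parent_visits = int(day_ev["tag_id"].isin(owners).sum())
                cand = day_ev[~day_ev["tag_id"].isin(owners)]
                for tag in cand["tag_id"].unique():
                    if sex_map.get(tag) != "M":
                        continue
                    if status_idx is not None:
                        srow = status_idx.get((int(rec["year"]), tag))
                    else:
                        s = statuses[statuses["tag_id"] == tag]
                        srow = s.iloc[0] if len(s) else None
                    if _is_floater_on(srow, date):
                        n_floaters += 1
            age = np.nan
            if pd.notna(rec["hatch_date"]):
                age = (pd.Timestamp(date) - pd.Timestamp(rec["hatch_date"])).days
            rows.append({"box_id": box, "date": date, "year": int(rec["year"]),
                         "wave": rec["wave"], "stage": stage,
                         "nestling_age": age if stage in NESTLING_STAGES else np.nan,
                         "n_chicks": rec.get("n_chicks", rec["fledged"]),
                         "n_floaters": n_floaters,
                         "parent_visits": parent_visits,
                         "hours": float(hrs)})
    return pd.DataFrame(rows)


def provisioning_rate(events: pd.DataFrame, bouts: pd.DataFrame,
                      breeding: pd.DataFrame) -> pd.DataFrame:
    """Parental feeds/hour during the nestling period, per (box, brood, parent).

    Entries are deduplicated detections of the male or female owner at their
    own box on nestling-stage days covered by a retained bout.  Broods with
    zero recorded hours are excluded.  Output: box_id, year, wave, parent,
    entries, hours, rate, brood_size.
    """
    ev = events.copy()
    ev["date"] = ev["timestamp"].dt.normalize()
    bt = bouts.copy()
    bt["date"] = pd.to_datetime(bt["date"]).dt.normalize()
    hours = bt.groupby(["box_id", "date"])["minutes_recorded"].sum() / 60.0
    hours_by_box: dict[str, dict] = {}
    for (b, date), hrs in hours.items():
        hours_by_box.setdefault(b, {})[date] = hrs

    rows = []
    for _, rec in breeding.iterrows():
        box = rec["box_id"]
        box_hours = hours_by_box.get(box, {})
        nest_days = [d for d in box_hours
                     if classify_stage(rec, d) in NESTLING_STAGES]
        if not nest_days:
            continue
        total_h = float(sum(box_hours[d] for d in nest_days))
        if total_h <= 0:
            continue
        day_ev = ev[(ev["box_id"] == box) & (ev["date"].isin(nest_days))]
        for parent, owner in (("male", rec["male_owner"]),
                              ("female", rec["female_owner"])):
            if pd.isna(owner) or owner is None:
                continue
            entries = int((day_ev["tag_id"] == owner).sum())
            rows.append({"box_id": box, "year": int(rec["year"]),
                         "wave": rec["wave"], "parent": parent,
                         "entries": entries, "hours": total_h,
                         "rate": entries / total_h,
                         "brood_size": rec.get("n_chicks", rec["fledged"])})
    return pd.DataFrame(rows)


def eligible_broods(visit_counts: pd.DataFrame, breeding: pd.DataFrame,
                    min_nestling_days: int = 8) -> pd.DataFrame:
    """Broods admissible for the stage models: both parents tagged and at
    least ``min_nestling_days`` recorded days in the nestling period."""
    ok = []
    for _, rec in breeding.iterrows():
        if pd.isna(rec["male_owner"]) or pd.isna(rec["female_owner"]):
            continue
        vc = visit_counts[(visit_counts["box_id"] == rec["box_id"])
                          & (visit_counts["year"] == rec["year"])
                          & (visit_counts["wave"] == rec["wave"])]
        if (vc["stage"].isin(NESTLING_STAGES)).sum() >= min_nestling_days:
            ok.append((rec["box_id"], rec["year"], rec["wave"]))
    key = pd.MultiIndex.from_tuples(ok, names=["box_id", "year", "wave"]) if ok \
        else pd.MultiIndex.from_arrays([[], [], []], names=["box_id", "year", "wave"])
    mask = visit_counts.set_index(["box_id", "year", "wave"]).index.isin(key)
    return visit_counts[mask].reset_index(drop=True)
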