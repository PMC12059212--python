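"""Synthetic nest-box colony with known ground truth.

Generates the full input bundle the pipeline consumes — boxes, breeding
records, RFID detections, recording bouts, morphometrics — with the
statistical structure the analysis assumes, so every downstream stage can be
checked against planted parameters:

* a fully occupied colony (every box breeds every year) of ``n_boxes``
  uniformly placed on a square of ``area_ha`` hectares;
* male owners surviving year-to-year with probability ``owner_survival``;
  a box whose owner disappears is a *vacancy*;
* per-box fledging success driven by a latent AR(1) box-quality process so
  success is temporally autocorrelated at a planted lag-1 level;
* male floaters prospecting boxes drawn around a personal center with a
  Gaussian distance kernel, detected at readers at ``detection_rate`` reads
  per hour, with visitation inflated during the nestling weeks;
* settlement the following year by a multinomial logit over all boxes with
  log-odds  -d(box, centroid)/distance_decay + vacancy_logOR * 1[owner died],
  the two effects the settlement analysis is meant to recover.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
single component can be regenerated without disturbing the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_colony",
    "simulate_breeding",
    "simulate_floaters",
    "simulate_settlement",
    "simulate_morphometrics",
    "generate_dataset",
    "simulate_fledged_series",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic colony.

    Defaults mirror the study system: 246 boxes on ~80 ha, modal clutch of
    4 eggs, ~12-day incubation, fledging around day 23, male owner survival
    0.54-0.60, floaters visiting 5-46 distinct boxes (mean ~15).
    """

    n_boxes: int = 246
    area_ha: float = 80.0
    n_years: int = 3
    start_year: int = 2011
    n_floaters_per_year: int = 60
    boxes_visited_range: tuple[int, int] = (5, 46)
    prospect_kernel_sd: float = 150.0  # m
    owner_survival: float = 0.57
    vacancy_logOR: float = math.log(2.0)
    distance_decay: float = 100.0  # m per unit of settlement log-odds
    mean_clutch: float = 4.0
    incubation_days: int = 12
    fledge_age: int = 23
    #: reads/hour per floater at a visited box at multiplier 1.  Counts of
    #: *distinct* floaters saturate once rate x hours x multiplier >> 1, so
    #: the default keeps single-read probability low at baseline stages and
    #: high during the nestling weeks, reproducing the observed contrast.
    detection_rate: float = 0.05
    #: visitation multipliers: pre-laying, laying, incubation, then the four
    #: nestling-age bins (weeks) in order
    stage_multipliers: dict = field(default_factory=lambda: {
        "pre_laying": 1.0, "laying": 1.0, "incubation": 1.0,
        "nestling_1_7": 3.0, "nestling_8_14": 6.0,
        "nestling_15_18": 7.0, "nestling_gt18": 6.0})
    success_lag1_corr: float = 0.25
    #: share of box-quality variance carried by a smooth spatial field with
    #: an exponential correlogram of the given range; keeps the proximal-lag
    #: spatial autocorrelation of fledging success weakly positive, as in
    #: saturated colonies where box quality differences are small
    spatial_quality_share: float = 0.2
    spatial_quality_range_m: float = 100.0
    fledged_sd: float = 1.5
    second_wave_prob: float = 0.3
    bout_coverage: float = 0.3  # probability a box-day gets a recording bout
    short_bout_prob: float = 0.1  # fraction of bouts under the 120-min cutoff
    female_feed_rate: float = 2.0  # feeds / chick / hour
    male_feed_rate: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.n_boxes < 2:
            raise ValueError("a colony needs at least 2 boxes")
        for name in ("owner_survival", "second_wave_prob", "bout_coverage",
                     "short_bout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.boxes_visited_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid boxes_visited_range")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())]))


@dataclass
class GroundTruth:
    """Planted quantities returned for recovery tests."""

    centroids: pd.DataFrame  # tag_id, year, cx, cy (true prospecting centers)
    settlements: pd.DataFrame  # tag_id, year, box_id, owner_died
    survival: pd.DataFrame  # tag_id, year, survived
    vacancy_logOR: float
    distance_decay: float


def generate_colony(config: SimConfig) -> pd.DataFrame:
    """Uniformly place ``n_boxes`` boxes on a square of ``area_ha`` hectares."""
    rng = config.rng("colony")
    side = math.sqrt(config.area_ha * 10_000.0)
    width = len(str(config.n_boxes))
    return pd.DataFrame({
        "box_id": [f"B{i + 1:0{width}d}" for i in range(config.n_boxes)],
        "x": rng.uniform(0, side, config.n_boxes),
        "y": rng.uniform(0, side, config.n_boxes),
    })


def _truncated_poisson_clutch(rng, mean, size):
    """Clutch sizes ~ Poisson(mean) conditioned on >= 1."""
    c = rng.poisson(mean, size)
    while (c == 0).any():
        c[c == 0] = rng.poisson(mean, int((c == 0).sum()))
    return c


def simulate_breeding(boxes: pd.DataFrame, config: SimConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fully-occupied breeding histories plus male-owner survival outcomes.

    Every box hosts a first-wave attempt each year; a random subset also
    hosts a second-wave attempt.  Fledged counts follow a latent per-box
    AR(1) quality process (stationary lag-1 correlation
    ``success_lag1_corr``) mapped to integers and clipped to [0, clutch].
    Each male owner survives to the next year with probability
    ``owner_survival``; survivors keep their box (owners are philopatric),
    casualties are replaced by fresh recruits.
    """
    rng = config.rng("breeding")
    n = len(boxes)
    years = range(config.start_year, config.start_year + config.n_years)
    rho = config.success_lag1_corr

    # quality innovations: independent noise plus an optional smooth spatial
    # field (exponential correlogram), unit marginal variance either way
    share = config.spatial_quality_share
    if share > 0:
        xy = boxes[["x", "y"]].to_numpy()
        dmat = np.hypot(xy[:, 0, None] - xy[None, :, 0],
                        xy[:, 1, None] - xy[None, :, 1])
        corr = np.exp(-dmat / config.spatial_quality_range_m)
        chol = np.linalg.cholesky(corr + 1e-9 * np.eye(n))

        def innovate():
            return (math.sqrt(1 - share) * rng.normal(size=n)
                    + math.sqrt(share) * chol @ rng.normal(size=n))
    else:
        def innovate():
            return rng.normal(size=n)

    quality = innovate()  # stationary N(0, 1) start
    owners_m = np.array([f"M{config.start_year}_{i}" for i in range(n)], dtype=object)
    owners_f = np.array([f"X{config.start_year}_{i}" for i in range(n)], dtype=object)
    recruit_counter = n
    records, survival_rows = [], []
    for year in years:
        clutch = _truncated_poisson_clutch(rng, config.mean_clutch, n)
        latent = (config.mean_clutch - 1.0) + config.fledged_sd * quality
        fledged = np.clip(np.round(latent + rng.normal(0, 0.3, n)), 0, clutch
                          ).astype(int)
        lay = pd.Timestamp(year=year, month=4, day=1) + pd.to_timedelta(
            rng.integers(-7, 8, n), unit="D")
        for i in range(n):
            hatch = lay[i] + pd.Timedelta(days=int(clutch[i]) + config.incubation_days)
            records.append({
                "box_id": boxes["box_id"].iat[i], "year": year, "wave": "first",
                "lay_date": lay[i], "hatch_date": hatch,
                "clutch_size": int(clutch[i]), "fledged": int(fledged[i]),
                "male_owner": owners_m[i], "female_owner": owners_f[i],
                "manipulated": False,
            })
        second = rng.random(n) < config.second_wave_prob
        clutch2 = _truncated_poisson_clutch(rng, config.mean_clutch, n)
        fledged2 = np.clip(np.round(latent + rng.normal(0, 0.5, n)) - 1, 0, clutch2
                           ).astype(int)
        for i in np.flatnonzero(second):
            lay2 = lay[i] + pd.Timedelta(days=45)
            hatch2 = lay2 + pd.Timedelta(days=int(clutch2[i]) + config.incubation_days)
            records.append({
                "box_id": boxes["box_id"].iat[i], "year": year, "wave": "second",
                "lay_date": lay2, "hatch_date": hatch2,
                "clutch_size": int(clutch2[i]), "fledged": int(fledged2[i]),
                "male_owner": owners_m[i], "female_owner": owners_f[i],
                "manipulated": False,
            })
        # advance the quality process and the ownership roster
        quality = rho * quality + math.sqrt(1 - rho**2) * innovate()
        survived = rng.random(n) < config.owner_survival
        for i in range(n):
            survival_rows.append({"tag_id": owners_m[i], "year": year,
                                  "survived": bool(survived[i])})
        next_m = owners_m.copy()
        for i in np.flatnonzero(~survived):
            next_m[i] = f"M{year + 1}_r{recruit_counter}"
            recruit_counter += 1
        owners_m = next_m
    return pd.DataFrame(records), pd.DataFrame(survival_rows)


def _draw_n_visited(rng, config) -> int:
    lo, hi = config.boxes_visited_range
    # right-skewed around a mean of ~15 distinct boxes
    return int(np.clip(lo + rng.poisson(10), lo, hi))


def simulate_floaters(boxes: pd.DataFrame, breeding: pd.DataFrame,
                      config: SimConfig, years: list[int] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                 pd.DataFrame]:
    """Floater prospecting detections, recording bouts, and true centers.

    Each floater has a personal home-range center uniform over the colony;
    the set of boxes it visits is drawn without replacement with probability
    proportional to a Gaussian kernel exp(-d^2 / (2 sd^2)) of the distance
    to that center.  Detections at a visited box during a recording bout are
    Poisson with rate ``detection_rate * hours`` times the breeding-stage
    multiplier; owner provisioning visits are generated alongside so that
    ownership criteria and feed rates are exercised.

    Returns (detections, bouts, centroids, individuals).
    """
    from .detections import classify_stage

    rng = config.rng("floaters")
    if years is None:
        years = sorted(breeding["year"].unique())
    xy = boxes[["x", "y"]].to_numpy()
    side = math.sqrt(config.area_ha * 10_000.0)

    bouts_rows, det_rows, centroid_rows, indiv_rows = [], [], [], []
    seen_tags: set[str] = set()
    for year in years:
        br_year = breeding[breeding["year"] == year]
        # recording bouts: a subset of active box-days, 07:00 onward
        active: dict[tuple[str, pd.Timestamp], tuple] = {}
        for _, rec in br_year.iterrows():
            start = rec["lay_date"] - pd.Timedelta(days=14)
            end = rec["hatch_date"] + pd.Timedelta(days=config.fledge_age)
            for d in pd.date_range(start, end):
                stage = classify_stage(rec, d)
                if stage != "none":
                    active[(rec["box_id"], d)] = (stage, rec)
        box_day_bouts = {}
        for (box, day), (stage, rec) in active.items():
            if rng.random() >= config.bout_coverage:
                continue
            if rng.random() < config.short_bout_prob:
                minutes = float(rng.uniform(30, 119))
            else:
                minutes = float(rng.uniform(120, 361))
            bouts_rows.append({"box_id": box, "date": day,
                               "minutes_recorded": minutes})
            box_day_bouts[(box, day)] = (minutes, stage, rec)

        # owner provisioning + presence reads
        for (box, day), (minutes, stage, rec) in box_day_bouts.items():
            hours = minutes / 60.0
            start_ts = day + pd.Timedelta(hours=7)
            if stage.startswith("nestling"):
                n_chicks = max(int(rec["fledged"]), 1)
                for tag, rate in ((rec["female_owner"], config.female_feed_rate),
                                  (rec["male_owner"], config.male_feed_rate)):
                    k = rng.poisson(rate * n_chicks * hours)
                    for s in np.sort(rng.uniform(0, minutes * 60, k)):
                        det_rows.append({"tag_id": tag, "box_id": box,
                                         "timestamp": start_ts + pd.Timedelta(seconds=float(s))})
            elif stage in ("pre_laying", "incubation"):
                for tag in (rec["male_owner"], rec["female_owner"]):
                    k = rng.poisson(0.5 * hours)
                    for s in np.sort(rng.uniform(0, minutes * 60, k)):
                        det_rows.append({"tag_id": tag, "box_id": box,
                                         "timestamp": start_ts + pd.Timedelta(seconds=float(s))})

        # floaters
        for i in range(config.n_floaters_per_year):
            tag = f"F{year}_{i}"
            center = rng.uniform(0, side, 2)
            d2 = ((xy - center) ** 2).sum(axis=1)
            # shift by the minimum so a narrow kernel keeps relative weights
            w = np.exp(-(d2 - d2.min()) / (2 * config.prospect_kernel_sd**2))
            m = min(_draw_n_visited(rng, config), len(boxes))
            if (w > 0).sum() >= m:
                visited_idx = rng.choice(len(boxes), size=m, replace=False,
                                         p=w / w.sum())
            else:  # kernel so tight it degenerates to the m nearest boxes
                visited_idx = np.argsort(d2)[:m]
            visited = set(boxes["box_id"].iloc[visited_idx])
            centroid_rows.append({"tag_id": tag, "year": year,
                                  "cx": center[0], "cy": center[1]})
            indiv_rows.append({"tag_id": tag, "sex": "M",
                               "birth_year": year - 1, "natal_box": pd.NA})
            seen_tags.add(tag)
            for (box, day), (minutes, stage, rec) in box_day_bouts.items():
                if box not in visited:
                    continue
                hours = minutes / 60.0
                mult = config.stage_multipliers.get(stage, 1.0)
                k = rng.poisson(config.detection_rate * hours * mult)
                if k == 0:
                    continue
                start_ts = day + pd.Timedelta(hours=7)
                for s in np.sort(rng.uniform(0, minutes * 60, k)):
                    det_rows.append({"tag_id": tag, "box_id": box,
                                     "timestamp": start_ts + pd.Timedelta(seconds=float(s))})

    # owners: birth year known only for the fraction ringed as nestlings
    for tag in pd.unique(breeding["male_owner"]):
        first_year = int(str(tag)[1:5])
        birth = first_year - int(rng.integers(2, 6)) if rng.random() < 0.4 else pd.NA
        indiv_rows.append({"tag_id": tag, "sex": "M", "birth_year": birth,
                           "natal_box": pd.NA})
    for tag in pd.unique(breeding["female_owner"]):
        indiv_rows.append({"tag_id": tag, "sex": "F", "birth_year": pd.NA,
                           "natal_box": pd.NA})
    detections = pd.DataFrame(det_rows, columns=["tag_id", "box_id", "timestamp"])
    detections = detections.sort_values(["tag_id", "box_id", "timestamp"]
                                        ).reset_index(drop=True)
    bouts = pd.DataFrame(bouts_rows, columns=["box_id", "date", "minutes_recorded"])
    centroids = pd.DataFrame(centroid_rows, columns=["tag_id", "year", "cx", "cy"])
    individuals = pd.DataFrame(indiv_rows).drop_duplicates("tag_id"
                                                           ).reset_index(drop=True)
    return detections, bouts, centroids, individuals


def simulate_settlement(centroids: pd.DataFrame, breeding: pd.DataFrame,
                        survival: pd.DataFrame, boxes: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """Each floater settles the year after floating by multinomial logit.

    log-odds(box) = -d(box, centroid) / distance_decay
                    + vacancy_logOR * 1[male owner of the previous year died].
    Choices are independent across floaters (no exclusion), so the planted
    coefficients are exactly the data-generating ones.
    Returns tag_id, year (settlement year), box_id, owner_died.
    """
    rng = config.rng("settlement")
    xy = boxes[["x", "y"]].to_numpy()
    died = {}
    for _, row in survival.iterrows():
        died[(row["year"], row["tag_id"])] = not row["survived"]
    rows = []
    for _, fl in centroids.iterrows():
        year = int(fl["year"])
        br = breeding[(breeding["year"] == year) & (breeding["wave"] == "first")]
        owner_of = dict(zip(br["box_id"], br["male_owner"]))
        owner_died = np.array([
            bool(died.get((year, owner_of.get(b)), False))
            for b in boxes["box_id"]])
        d = np.hypot(xy[:, 0] - fl["cx"], xy[:, 1] - fl["cy"])
        logits = -d / config.distance_decay + config.vacancy_logOR * owner_died
        p = np.exp(logits - logits.max())
        p /= p.sum()
        j = rng.choice(len(boxes), p=p)
        rows.append({"tag_id": fl["tag_id"], "year": year + 1,
                     "box_id": boxes["box_id"].iat[j],
                     "owner_died": bool(owner_died[j])})
    return pd.DataFrame(rows, columns=["tag_id", "year", "box_id", "owner_died"])


def simulate_morphometrics(individuals: pd.DataFrame, config: SimConfig,
                           years: list[int] | None = None) -> pd.DataFrame:
    """Per-capture morphometrics with a common latent size axis.

    Beak, wing and tarsus load on one latent size factor (so a
    correlation-matrix PCA has a dominant first axis with all-positive
    loadings); mass responds to size plus capture time/date, a year effect
    and an individual effect.  Throat-feather ornament is measured three
    times around a per-bird true length.
    """
    rng = config.rng("morphometrics")
    if years is None:
        years = list(range(config.start_year, config.start_year + config.n_years))
    males = individuals[individuals["sex"] == "M"]
    rows = []
    for _, ind in males.iterrows():
        size = rng.normal()
        ind_eff = rng.normal(0, 2.0)
        ornament_true = 24.0 + rng.normal(0, 2.5)
        for year in years:
            if rng.random() < 0.5:  # not every bird is caught every year
                continue
            t = rng.uniform(8.0, 12.0)  # capture hour
            day = int(rng.integers(0, 30))  # days since 1 March
            year_eff = rng.normal(0, 1.0)
            mass = (80.0 + 3.0 * size - 0.4 * (t - 10.0) + 0.05 * day
                    + year_eff + ind_eff + rng.normal(0, 1.5))
            rows.append({
                "tag_id": ind["tag_id"], "year": year,
                "mass": round(mass, 1),
                "tarsus": round(30.0 + 1.0 * size + rng.normal(0, 0.6), 2),
                "beak": round(25.0 + 0.8 * size + rng.normal(0, 0.5), 2),
                "wing": round(130.0 + 3.0 * size + rng.normal(0, 2.0), 1),
                "throat1": round(ornament_true + rng.normal(0, 0.4), 2),
                "throat2": round(ornament_true + rng.normal(0, 0.4), 2),
                "throat3": round(ornament_true + rng.normal(0, 0.4), 2),
                "capture_time": round(t, 2),
                "capture_date": pd.Timestamp(year=year, month=3, day=1)
                + pd.Timedelta(days=day),
            })
    return pd.DataFrame(rows)


def generate_dataset(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Full synthetic bundle: all tables plus the planted ground truth."""
    boxes = generate_colony(config)
    breeding, survival = simulate_breeding(boxes, config)
    float_years = sorted(breeding["year"].unique())[:-1] or \
        sorted(breeding["year"].unique())
    detections, bouts, centroids, individuals = simulate_floaters(
        boxes, breeding, config, years=float_years)
    settlements = simulate_settlement(centroids, breeding, survival, boxes, config)
    morph = simulate_morphometrics(individuals, config)
    ds = Dataset(boxes=boxes, individuals=individuals, detections=detections,
                 bouts=bouts, breeding=breeding, morphometrics=morph)
    truth = GroundTruth(centroids, settlements, survival,
                        config.vacancy_logOR, config.distance_decay)
    return ds, truth


def simulate_fledged_series(n_boxes: int, n_years: int, lag1_corr: float,
                            mean: float = 3.0, sd: float = 1.5,
                            seed: int = 0) -> pd.DataFrame:
    """Per-box annual fledged counts with a planted lag-1 autocorrelation.

    A stationary AR(1) latent series per box (lag-1 correlation
    ``lag1_corr``) is shifted/scaled to the count range and rounded.
    Rounding attenuates the realized Pearson correlation slightly (by the
    factor sd^2 / (sd^2 + 1/12)); with sd >= 1.5 that attenuation is < 0.01.
    """
    rng = np.random.default_rng(seed)
    z = np.empty((n_boxes, n_years))
    z[:, 0] = rng.normal(size=n_boxes)
    for t in range(1, n_years):
        z[:, t] = lag1_corr * z[:, t - 1] + \
            math.sqrt(1 - lag1_corr**2) * rng.normal(size=n_boxes)
    counts = np.clip(np.round(mean + sd * z), 0, None).astype(int)
    box_ids = [f"B{i + 1:03d}" for i in range(n_boxes)]
    return pd.DataFrame({
        "box_id": np.repeat(box_ids, n_years),
        "year": np.tile(np.arange(2011, 2011 + n_years), n_boxes),
        "fledged": counts.ravel(),
    })
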