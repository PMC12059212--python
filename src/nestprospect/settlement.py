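"""Settlement-choice analysis: does a floater's next nest depend on what it
could have learned while prospecting?

For every floater-year with a prospected circle, the candidate set is the
boxes inside that circle plus the box actually chosen (union rule: the chosen
box is kept even when it falls outside the circle).  Each candidate box
carries predictors from its most recent breeding attempt in the year before
settlement — the last owner's reproductive output, age, ornament size, body
condition, provisioning rate, and whether that owner was ever detected again
in the settlement year.  One univariate binomial GLMM per predictor (floater
identity and year as crossed random intercepts) mirrors a
one-chosen-among-many design; missing owner data shrinks each model's sample
independently.

Covariate construction helpers:

* :func:`body_size_pca` — PC1 of the beak/wing/tarsus correlation matrix.
* :func:`body_condition` — residual mass after size, capture time and date
  (year and individual as random effects).
* :func:`corrected_feed_rate` — provisioning rate residualized on brood size
  (year random).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import ModelSpec, Term, fit_glmm, fit_lmm, odds_ratio, wald_type3
from .homerange import ProspectSummary, boxes_in_circle

__all__ = [
    "build_candidate_set",
    "attach_owner_traits",
    "body_size_pca",
    "body_condition",
    "corrected_feed_rate",
    "fit_settlement_models",
    "PCAResult",
    "SETTLEMENT_PREDICTORS",
]

#: Predictors of the univariate settlement models, in reporting order.
SETTLEMENT_PREDICTORS = [
    "annual_fledged_prev",
    "second_brood_fledged_prev",
    "second_brood_failed_prev",
    "owner_age",
    "owner_ornament",
    "owner_condition",
    "owner_feed_rate_corrected",
    "owner_not_returned",
]


@dataclass
class PCAResult:
    scores: pd.Series  # PC1 score per input row
    loadings: np.ndarray  # (3,) loadings on beak, wing, tarsus
    eigenvalue: float
    variance_share: float


def _last_attempt(breeding: pd.DataFrame, box: str, year: int):
    """Latest breeding attempt of ``box`` in ``year`` (second wave beats first)."""
    att = breeding[(breeding["box_id"] == box) & (breeding["year"] == year)]
    if len(att) == 0:
        return None
    order = {"first": 0, "second": 1}
    return att.iloc[att["wave"].map(order).to_numpy().argmax()]


def build_candidate_set(summaries: list[ProspectSummary], boxes: pd.DataFrame,
                        settlements: pd.DataFrame, breeding: pd.DataFrame,
                        ) -> pd.DataFrame:
    """One row per (floater, candidate box) with previous-year predictors.

    ``settlements`` gives the box each floater chose (columns tag_id, year,
    box_id; year is the settlement year, predictors come from year - 1).
    Floaters without a settlement record are skipped.  Reproductive
    predictors: total young fledged across the previous year's attempts,
    young fledged in the second brood (0 when no second attempt), and
    whether the second brood failed (no young fledged).
    """
    settle_idx = {(r["tag_id"]): r for _, r in settlements.iterrows()}
    by_boxyear = dict(tuple(breeding.groupby(["box_id", "year"])))
    rows = []
    for s in summaries:
        settle = settle_idx.get(s.tag_id)
        if settle is None:
            continue
        year = int(settle["year"])
        prev = year - 1
        chosen = settle["box_id"]
        cand = boxes_in_circle(s.centroid, s.circle_radius_m, boxes)
        cand = sorted(cand | {chosen})
        for box in cand:
            att = by_boxyear.get((box, prev))
            if att is None:
                continue
            annual = int(att["fledged"].sum())
            second = att[att["wave"] == "second"]
            second_fledged = int(second["fledged"].sum()) if len(second) else 0
            order = {"first": 0, "second": 1}
            last = att.iloc[att["wave"].map(order).to_numpy().argmax()]
            rows.append({
                "tag_id": s.tag_id, "box_id": box, "year": year,
                "chosen": int(box == chosen),
                "annual_fledged_prev": annual,
                "second_brood_fledged_prev": second_fledged,
                "second_brood_failed_prev": int(second_fledged == 0),
                "last_owner": last["male_owner"],
            })
    return pd.DataFrame(rows)


def attach_owner_traits(candidates: pd.DataFrame,
                        owner_year_traits: pd.DataFrame | None = None,
                        detections: pd.DataFrame | None = None,
                        breeding: pd.DataFrame | None = None,
                        birth_years: dict | None = None) -> pd.DataFrame:
    """Join last-owner covariates onto the candidate table.

    ``owner_year_traits`` carries per (tag_id, year) columns among
    ``ornament``, ``condition``, ``feed_rate_corrected`` measured in the
    pre-settlement year.  ``owner_not_returned`` is 1 when the owner tag
    appears nowhere in the settlement year's detections nor as an owner in
    that year's breeding records.  ``owner_age`` is settlement year minus
    birth year (minimum age when only a first-capture year is known).
    Missing owners propagate missing values.
    """
    out = candidates.copy()
    for col in ["owner_age", "owner_ornament", "owner_condition",
                "owner_feed_rate_corrected", "owner_not_returned"]:
        out[col] = np.nan

    if owner_year_traits is not None:
        traits = owner_year_traits.set_index(["tag_id", "year"])
        for i, row in out.iterrows():
            owner = row["last_owner"]
            if pd.isna(owner):
                continue
            key = (owner, row["year"] - 1)
            if key in traits.index:
                tr = traits.loc[key]
                if isinstance(tr, pd.DataFrame):
                    tr = tr.iloc[0]
                for src, dst in (("ornament", "owner_ornament"),
                                 ("condition", "owner_condition"),
                                 ("feed_rate_corrected", "owner_feed_rate_corrected")):
                    if src in tr.index and pd.notna(tr[src]):
                        out.at[i, dst] = tr[src]

    if detections is not None or breeding is not None:
        seen_by_year: dict[int, set] = {}
        if detections is not None:
            det = detections.copy()
            det["year"] = pd.to_datetime(det["timestamp"]).dt.year
            for y, grp in det.groupby("year"):
                seen_by_year.setdefault(int(y), set()).update(grp["tag_id"])
        if breeding is not None:
            for y, grp in breeding.groupby("year"):
                owners = set(grp["male_owner"].dropna()) | set(grp["female_owner"].dropna())
                seen_by_year.setdefault(int(y), set()).update(owners)
        for i, row in out.iterrows():
            owner = row["last_owner"]
            if pd.isna(owner):
                continue
            seen = seen_by_year.get(int(row["year"]), set())
            out.at[i, "owner_not_returned"] = float(owner not in seen)

    if birth_years is not None:
        for i, row in out.iterrows():
            owner = row["last_owner"]
            by = birth_years.get(owner)
            if owner is not None and pd.notna(owner) and by is not None:
                out.at[i, "owner_age"] = row["year"] - 1 - int(by)
    return out


def body_size_pca(morph: pd.DataFrame) -> PCAResult:
    """First principal component of the beak/wing/tarsus correlation matrix.

    Traits are standardized, so the eigenvalues sum to 3 and the variance
    share is eigenvalue / 3.  The component sign is chosen to make all
    loadings non-negative when possible (larger birds score higher).
    """
    traits = morph[["beak", "wing", "tarsus"]].astype(float)
    if len(traits) < 3:
        raise ValueError("need at least 3 complete morphometric records")
    if (traits.std(ddof=0) == 0).any():
        raise ValueError("constant trait; correlation-matrix PCA undefined")
    z = (traits - traits.mean()) / traits.std(ddof=0)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    v1 = vecs[:, -1]
    if (v1 <= 0).all() or (v1 < 0).sum() > (v1 > 0).sum():
        v1 = -v1
    scores = pd.Series(z.to_numpy() @ v1, index=morph.index, name="pc1")
    return PCAResult(scores, v1, float(vals[-1]), float(vals[-1] / 3.0))


def body_condition(morph: pd.DataFrame, pc1: pd.Series | None = None
                   ) -> pd.Series:
    """Mass residuals after size, capture time and date (condition index).

    The model is mass ~ PC1 + capture_time + capture_day with year and
    individual identity as crossed random intercepts; conditional residuals
    (fixed + predicted random effects subtracted) are returned, so a
    positive value means heavier than predicted for that bird's size,
    capture moment, and year.
    """
    if pc1 is None:
        pc1 = body_size_pca(morph).scores
    df = morph.copy()
    df["pc1"] = np.asarray(pc1, dtype=float)
    dates = pd.to_datetime(df["capture_date"])
    season_start = pd.to_datetime({"year": dates.dt.year, "month": 3, "day": 1})
    df["capture_day"] = (dates - season_start).dt.days.astype(float)
    df["capture_time"] = df["capture_time"].astype(float)
    spec = ModelSpec("mass", "gaussian",
                     [Term("pc1"), Term("capture_time"), Term("capture_day")],
                     groups=["year", "tag_id"])
    _, resid = fit_lmm(spec, df)
    return pd.Series(resid, index=morph.index, name="condition")


def corrected_feed_rate(rates: pd.DataFrame) -> pd.Series:
    """Provisioning rate residualized on brood size, year random intercept.

    ``rates`` needs columns rate, brood_size, year (one row per male-brood).
    """
    df = rates.copy().reset_index(drop=True)
    terms = [Term("brood_size")] if df["brood_size"].nunique() > 1 else []
    groups = ["year"] if df["year"].nunique() > 1 else []
    spec = ModelSpec("rate", "gaussian", terms, groups=groups)
    _, resid = fit_lmm(spec, df)
    return pd.Series(resid, index=rates.index, name="feed_rate_corrected")


def fit_settlement_models(candidates: pd.DataFrame,
                          predictors: list[str] | None = None,
                          n_nodes: int = 15) -> pd.DataFrame:
    """Univariate binomial settlement GLMMs, one per predictor.

    Each model regresses chosen (0/1) on a single predictor with floater
    identity and year as random intercepts, on the rows where that predictor
    is observed.  Output mirrors a results table: predictor, beta, se,
    odds_ratio, ci_lo, ci_hi, chi2, p, n_males, n_obs, plus convergence and
    separation flags.  Complete separation (runaway coefficient) is flagged
    and the estimate withheld.
    """
    predictors = predictors or [p for p in SETTLEMENT_PREDICTORS
                                if p in candidates.columns]
    rows = []
    for pred in predictors:
        sub = candidates.dropna(subset=[pred]).copy()
        sub[pred] = sub[pred].astype(float)
        n_males = sub["tag_id"].nunique()
        row = {"predictor": pred, "n_males": n_males, "n_obs": len(sub),
               "beta": np.nan, "se": np.nan, "odds_ratio": np.nan,
               "ci_lo": np.nan, "ci_hi": np.nan, "chi2": np.nan,
               "p": np.nan, "converged": False, "separated": False}
        if len(sub) == 0 or sub[pred].std() == 0 or sub["chosen"].nunique() < 2:
            rows.append(row)
            continue
        groups = [g for g in ("tag_id", "year") if sub[g].nunique() >= 2]
        spec = ModelSpec("chosen", "binomial", [Term(pred)], groups=groups)
        fit = fit_glmm(spec, sub, n_nodes=n_nodes)
        beta = fit.coef(pred)
        se = fit.coef_se(pred)
        if abs(beta) > 10 or not np.isfinite(se) or se > 50:
            row["separated"] = True
            rows.append(row)
            continue
        orr, (lo, hi) = odds_ratio(fit, pred)
        chi2, _, p = wald_type3(fit, pred)
        row.update(beta=beta, se=se, odds_ratio=orr, ci_lo=lo, ci_hi=hi,
                   chi2=chi2, p=p, converged=fit.converged)
        rows.append(row)
    return pd.DataFrame(rows)
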