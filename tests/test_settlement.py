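import numpy as np
import pandas as pd
import pytest

from nestprospect.homerange import ProspectSummary
from nestprospect.settlement import (body_condition, body_size_pca,
                                     build_candidate_set, corrected_feed_rate,
                                     fit_settlement_models)


def _summary(tag, centroid, radius):
    return ProspectSummary(tag, 2019, frozenset(), np.empty((0, 2)), 1e4,
                           centroid, radius)


def _grid_colony(n_side=6, spacing=50.0):
    rows = []
    for i in range(n_side):
        for j in range(n_side):
            rows.append({"box_id": f"B{i}{j}", "x": i * spacing,
                         "y": j * spacing})
    return pd.DataFrame(rows)


def _breeding_for(boxes, year=2019):
    rows = []
    for k, b in enumerate(boxes["box_id"]):
        rows.append({"box_id": b, "year": year, "wave": "first",
                     "lay_date": pd.Timestamp(f"{year}-04-01"),
                     "hatch_date": pd.Timestamp(f"{year}-04-17"),
                     "clutch_size": 4, "fledged": k % 5,
                     "male_owner": f"m_{b}", "female_owner": f"f_{b}",
                     "manipulated": False})
    return pd.DataFrame(rows)


class TestCandidateSet:
    def test_circle_union_chosen_inside(self):
        boxes = _grid_colony()
        breeding = _breeding_for(boxes)
        s = _summary("fl1", (100.0, 100.0), 75.0)
        inside = {b for _, r in boxes.iterrows()
                  if np.hypot(r["x"] - 100, r["y"] - 100) <= 75
                  for b in [r["box_id"]]}
        chosen = sorted(inside)[0]
        settle = pd.DataFrame({"tag_id": ["fl1"], "year": [2020],
                               "box_id": [chosen]})
        cand = build_candidate_set([s], boxes, settle, breeding)
        assert len(cand) == len(inside)
        assert cand["chosen"].sum() == 1
        assert set(cand["box_id"]) == inside

    def test_chosen_outside_circle_is_appended(self):
        boxes = _grid_colony()
        breeding = _breeding_for(boxes)
        s = _summary("fl1", (100.0, 100.0), 75.0)
        inside = {b for _, r in boxes.iterrows()
                  if np.hypot(r["x"] - 100, r["y"] - 100) <= 75
                  for b in [r["box_id"]]}
        settle = pd.DataFrame({"tag_id": ["fl1"], "year": [2020],
                               "box_id": ["B55"]})  # far corner
        assert "B55" not in inside
        cand = build_candidate_set([s], boxes, settle, breeding)
        assert len(cand) == len(inside) + 1
        assert cand.loc[cand["box_id"] == "B55", "chosen"].iloc[0] == 1

    def test_floater_without_settlement_is_skipped(self):
        boxes = _grid_colony()
        breeding = _breeding_for(boxes)
        s = _summary("ghost", (100.0, 100.0), 75.0)
        cand = build_candidate_set([s], boxes, pd.DataFrame(
            {"tag_id": [], "year": [], "box_id": []}), breeding)
        assert len(cand) == 0

    def test_second_brood_predictors(self):
        boxes = _grid_colony(2)
        breeding = _breeding_for(boxes)
        extra = breeding.iloc[[0]].assign(wave="second", fledged=2)
        breeding = pd.concat([breeding, extra], ignore_index=True)
        s = _summary("fl1", (25.0, 25.0), 1000.0)
        settle = pd.DataFrame({"tag_id": ["fl1"], "year": [2020],
                               "box_id": ["B00"]})
        cand = build_candidate_set([s], boxes, settle, breeding
                                   ).set_index("box_id")
        # box with a second attempt: annual total pools both waves
        assert cand.loc["B00", "annual_fledged_prev"] == 0 + 2
        assert cand.loc["B00", "second_brood_fledged_prev"] == 2
        assert cand.loc["B00", "second_brood_failed_prev"] == 0
        assert cand.loc["B01", "second_brood_failed_prev"] == 1
        # last owner of B00 comes from the second-wave attempt
        assert cand.loc["B00", "last_owner"] == "m_B00"


class TestBodySizePCA:
    def test_perfectly_correlated_traits(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        morph = pd.DataFrame({"beak": base, "wing": 2 * base + 1,
                              "tarsus": 0.5 * base - 3})
        res = body_size_pca(morph)
        assert res.variance_share == pytest.approx(1.0)
        assert np.abs(res.loadings) == pytest.approx([1 / np.sqrt(3)] * 3,
                                                     abs=1e-9)

    def test_uncorrelated_traits_share_one_third(self):
        rng = np.random.default_rng(2)
        morph = pd.DataFrame({"beak": rng.normal(size=4000),
                              "wing": rng.normal(size=4000),
                              "tarsus": rng.normal(size=4000)})
        res = body_size_pca(morph)
        assert res.eigenvalue == pytest.approx(1.0, abs=0.1)
        assert res.variance_share == pytest.approx(1 / 3, abs=0.04)

    def test_scores_match_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=200)
        morph = pd.DataFrame({
            "beak": 25 + 0.8 * latent + rng.normal(0, 0.5, 200),
            "wing": 130 + 3 * latent + rng.normal(0, 2, 200),
            "tarsus": 30 + latent + rng.normal(0, 0.6, 200)})
        res = body_size_pca(morph)
        z = (morph - morph.mean()) / morph.std(ddof=0)
        vals, vecs = np.linalg.eigh(np.corrcoef(z.to_numpy(), rowvar=False))
        v = vecs[:, np.argmax(vals)]
        v = v if v.sum() > 0 else -v
        expected = z.to_numpy() @ v
        assert np.asarray(res.scores) == pytest.approx(expected, abs=1e-9)
        assert (res.loadings >= 0).all()

    def test_constant_trait_raises(self):
        morph = pd.DataFrame({"beak": [1.0, 1.0, 1.0],
                              "wing": [1, 2, 3.0], "tarsus": [2, 3, 4.0]})
        with pytest.raises(ValueError):
            body_size_pca(morph)


class TestCondition:
    def _morph(self, n=300, seed=5):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        years = rng.integers(2018, 2021, n)
        year_eff = {2018: -1.0, 2019: 0.5, 2020: 0.5}
        df = pd.DataFrame({
            "tag_id": [f"m{i % 150}" for i in range(n)],
            "year": years,
            "beak": 25 + 0.8 * latent + rng.normal(0, 0.5, n),
            "wing": 130 + 3 * latent + rng.normal(0, 2, n),
            "tarsus": 30 + latent + rng.normal(0, 0.6, n),
            "capture_time": rng.uniform(8, 12, n),
            "capture_date": pd.to_datetime([f"{y}-03-{d:02d}" for y, d in
                                            zip(years, rng.integers(1, 29, n))]),
        })
        df["mass"] = (80 + 3 * latent + [year_eff[y] for y in years]
                      + rng.normal(0, 1.5, n))
        return df

    def test_residuals_uncorrelated_with_size(self):
        morph = self._morph(1000)
        pca = body_size_pca(morph)
        cond = body_condition(morph, pca.scores)
        r = np.corrcoef(pca.scores, cond)[0, 1]
        assert abs(r) < 0.05

    def test_heavier_bird_has_positive_residual(self):
        morph = self._morph(200)
        morph.loc[0, "mass"] += 25.0  # one artificially heavy bird
        cond = body_condition(morph)
        assert cond.iloc[0] > 0


class TestCorrectedFeedRate:
    def test_rate_proportional_to_brood_size_centers_to_zero(self):
        df = pd.DataFrame({"rate": [2.0, 4.0, 6.0, 8.0] * 5,
                           "brood_size": [1, 2, 3, 4] * 5,
                           "year": [2019, 2019, 2020, 2020] * 5})
        resid = corrected_feed_rate(df)
        assert np.allclose(resid, 0.0, atol=1e-5)

    def test_symmetric_deviations_preserved(self):
        df = pd.DataFrame({"rate": [3.0, 5.0] * 10,
                           "brood_size": [2, 2] * 10,
                           "year": [2019] * 20})
        resid = corrected_feed_rate(df)
        assert resid.to_numpy() == pytest.approx([-1.0, 1.0] * 10, abs=1e-6)


class TestSettlementModels:
    def _candidates(self, n_floaters=60, seed=4):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_floaters):
            k = rng.integers(8, 15)
            chosen = rng.integers(0, k)
            for j in range(k):
                rows.append({
                    "tag_id": f"fl{i}", "year": 2019 + int(rng.integers(0, 2)),
                    "box_id": f"B{i}_{j}", "chosen": int(j == chosen),
                    "noise": rng.normal(),
                    "partial": rng.normal() if rng.random() < 0.6 else np.nan})
        return pd.DataFrame(rows)

    def test_each_floater_one_positive_row(self):
        cand = self._candidates()
        assert (cand.groupby("tag_id")["chosen"].sum() == 1).all()

    def test_noise_predictor_near_null(self):
        cand = self._candidates(n_floaters=120)
        res = fit_settlement_models(cand, predictors=["noise"]).iloc[0]
        assert res["n_obs"] == len(cand)
        assert abs(res["beta"]) < 2.5 * res["se"]
        assert 0.6 < res["odds_ratio"] < 1.6

    def test_missingness_shrinks_only_that_model(self):
        cand = self._candidates()
        res = fit_settlement_models(cand, predictors=["noise", "partial"])
        res = res.set_index("predictor")
        assert res.loc["partial", "n_obs"] < res.loc["noise", "n_obs"]
        assert res.loc["noise", "n_obs"] == len(cand)

    def test_monotone_in_planted_vacancy_effect(self):
        """Estimated vacancy OR increases with the planted log-odds."""
        from nestprospect.simulate import (SimConfig, generate_colony,
                                           simulate_breeding,
                                           simulate_settlement)
        ors = []
        for logor in (0.0, np.log(2), np.log(5)):
            cfg = SimConfig(n_boxes=80, area_ha=25, n_years=2,
                            vacancy_logOR=logor, distance_decay=1e12, seed=21)
            boxes = generate_colony(cfg)
            breeding, survival = simulate_breeding(boxes, cfg)
            rng = cfg.rng("centers")
            side = np.sqrt(cfg.area_ha * 1e4)
            cent = pd.DataFrame({
                "tag_id": [f"F{i}" for i in range(250)],
                "year": cfg.start_year,
                "cx": rng.uniform(0, side, 250),
                "cy": rng.uniform(0, side, 250)})
            settle = simulate_settlement(cent, breeding, survival, boxes, cfg)
            summaries = [ProspectSummary(r.tag_id, cfg.start_year, frozenset(),
                                         np.empty((0, 2)), 1e4, (r.cx, r.cy),
                                         150.0)
                         for r in cent.itertuples()]
            cand = build_candidate_set(summaries, boxes, settle, breeding)
            died = {(r.year, r.tag_id): not r.survived
                    for r in survival.itertuples()}
            cand["owner_not_returned"] = [
                float(died.get((y - 1, o), np.nan))
                for y, o in zip(cand["year"], cand["last_owner"])]
            res = fit_settlement_models(cand, predictors=["owner_not_returned"])
            ors.append(res["odds_ratio"].iloc[0])
        assert ors[0] < ors[1] < ors[2]
        assert 0.7 < ors[0] < 1.4
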