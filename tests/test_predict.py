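"""Prediction surfaces, effect translations, triage classes, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from stonewort import model, predict
from stonewort.errors import SchemaError


def make_surface(lake_draws: dict[str, np.ndarray]) -> predict.PredictionSurface:
    """Surface built directly from per-lake draw matrices (draws x points)."""
    tables = []
    blocks = []
    for lake_id, draws in lake_draws.items():
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
        tables.append(
            pd.DataFrame(
                {
                    "point_id": [f"{lake_id}-p{i}" for i in range(draws.shape[1])],
                    "lake_id": lake_id,
                    "x": np.arange(draws.shape[1], dtype=float),
                    "y": 0.0,
                    "median": med,
                    "lower": lo,
                    "upper": hi,
                    "width": hi - lo,
                    "ever_detected": False,
                }
            )
        )
        blocks.append(draws)
    return predict.PredictionSurface(
        table=pd.concat(tables, ignore_index=True),
        draws=np.concatenate(blocks, axis=1),
        year=2021,
    )


@pytest.fixture(scope="module")
def fitted(small_sim):
    mc = model.MCMCSettings(n_chains=2, n_iter=1500, burn_in=500, thin=5)
    return model.fit(small_sim.design, mcmc=mc, seed=21)


class TestPredictSurface:
    def test_constant_draws_give_zero_width(self, fitted, small_sim):
        s = fitted
        collapsed = model.PosteriorSamples(
            beta=np.broadcast_to(s.beta[:1, :1], s.beta.shape).copy(),
            beta_names=s.beta_names,
            alpha=s.alpha, alpha_names=s.alpha_names,
            gamma=np.broadcast_to(s.gamma[:1, :1], s.gamma.shape).copy(),
            lake_ids=s.lake_ids,
            w=np.broadcast_to(s.w[:1, :1], s.w.shape).copy(),
            point_ids=s.point_ids,
            phi=s.phi, sigma2=s.sigma2, sigma2_lake=s.sigma2_lake,
            z_mean=s.z_mean, settings=s.settings, spec=s.spec, seed=s.seed,
            phi_bounds=s.phi_bounds,
        )
        surf = predict.predict_surface(collapsed, small_sim.design, 2021)
        np.testing.assert_allclose(surf.table["width"], 0.0, atol=1e-12)
        np.testing.assert_allclose(surf.table["median"], surf.table["lower"])

    def test_quantiles_match_sort_based_oracle(self, fitted, small_sim):
        surf = predict.predict_surface(fitted, small_sim.design, 2021)
        draws = surf.draws[:, 17]
        row = surf.table.iloc[17]
        srt = np.sort(draws)

        def quantile(p):  # linear-interpolation percentile, independently
            h = (len(srt) - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert row["median"] == pytest.approx(quantile(0.5), rel=1e-12)
        assert row["lower"] == pytest.approx(quantile(0.025), rel=1e-12)
        assert row["upper"] == pytest.approx(quantile(0.975), rel=1e-12)

    def test_monotone_in_the_occupancy_intercept(self, fitted, small_sim):
        surf0 = predict.predict_surface(fitted, small_sim.design, 2021)
        import dataclasses

        shifted = dataclasses.replace(fitted, beta=fitted.beta.copy())
        shifted.beta[:, :, fitted.beta_names.index("intercept")] += 1.0
        surf1 = predict.predict_surface(shifted, small_sim.design, 2021)
        assert (surf1.table["median"] >= surf0.table["median"] - 1e-12).all()

    def test_psi_reduces_to_inverse_logit_of_linear_predictor(self, fitted, small_sim):
        surf = predict.predict_surface(fitted, small_sim.design, 2021)
        # recompute one point's draws by hand
        i = 3
        x = small_sim.design.occupancy_row(i, 2021)
        beta = fitted.beta.reshape(-1, len(fitted.beta_names))
        lake = small_sim.design.point_table["lake_id"].iloc[i]
        g = fitted.gamma.reshape(-1, len(fitted.lake_ids))[
            :, fitted.lake_ids.index(lake)
        ]
        w = fitted.w.reshape(-1, len(fitted.point_ids))[:, i]
        np.testing.assert_allclose(surf.draws[:, i], expit(beta @ x + w + g))

    def test_unknown_lake_requires_marginal_flag(self, fitted, small_sim):
        import dataclasses

        stripped = dataclasses.replace(fitted, lake_ids=["nope", "nah"])
        with pytest.raises(Exception, match="lake"):
            predict.predict_surface(stripped, small_sim.design, 2021)
        surf = predict.predict_surface(
            stripped, small_sim.design, 2021, marginal_lakes=True
        )
        assert len(surf.table) == small_sim.design.n_points


class TestSignificance:
    def _samples_with_beta(self, draws: np.ndarray, fitted) -> model.PosteriorSamples:
        import dataclasses

        beta = fitted.beta.copy()
        flat = np.resize(draws, beta.shape[0] * beta.shape[1])
        beta[:, :, 0] = flat.reshape(beta.shape[0], beta.shape[1])
        return dataclasses.replace(fitted, beta=beta)

    def test_all_positive_draws_significant(self, fitted):
        s = self._samples_with_beta(np.linspace(0.1, 2.0, 400), fitted)
        sig, (lo, hi) = predict.significance(s, "intercept")
        assert sig and lo > 0

    def test_symmetric_draws_not_significant(self, fitted, rng):
        s = self._samples_with_beta(rng.standard_normal(400), fitted)
        sig, (lo, hi) = predict.significance(s, "intercept")
        assert not sig and lo < 0 < hi

    def test_just_under_2p5_percent_mass_below_zero_is_significant(self, fitted):
        # 2.4% of the draws below zero: the 2.5% quantile still sits above 0
        n = fitted.beta.shape[0] * fitted.beta.shape[1]
        n_neg = int(np.floor(0.024 * n))
        draws = np.concatenate(
            [-np.linspace(0.01, 0.5, n_neg), np.linspace(0.01, 2, n - n_neg)]
        )
        s = self._samples_with_beta(draws, fitted)
        sig, (lo, hi) = predict.significance(s, "intercept")
        assert sig and lo > 0


class TestEffectTranslations:
    def test_detection_intercept_translates_to_63_percent(self):
        assert round(predict.detection_at_mean(0.534)) == 63

    def test_zero_intercept_is_a_coin_flip(self):
        assert predict.detection_at_mean(0.0) == pytest.approx(50.0)

    def test_abundant_plants_scenario_reaches_38_percent(self):
        # +2 SD on both density covariates with the reported coefficients
        eta = 0.534 + 2 * (-0.348) + 2 * (-0.165)
        assert round(predict.detection_at_mean(eta)) == 38

    @pytest.mark.parametrize(
        "coef,expected", [(-0.165, 4.1), (-0.348, 8.7), (0.0, 0.0)]
    )
    def test_quarter_rule_translations(self, coef, expected):
        assert predict.max_prob_change_per_sd(coef) == expected

    @pytest.mark.parametrize("p0", [0.05, 0.2, 0.5, 0.8, 0.95])
    @pytest.mark.parametrize("coef", [-2.0, -0.165, 0.3, 1.5])
    def test_quarter_rule_is_an_upper_bound(self, p0, coef):
        moved = expit(logit(p0) + coef)
        bound = predict.max_prob_change_per_sd(coef) / 100.0
        # reporting rounds to 0.1%, so allow that much slack on top
        assert abs(moved - p0) <= bound + 0.0005 + 1e-12


class TestLakeClassification:
    def exemplar_surface(self, rng) -> predict.PredictionSurface:
        n_draws, n_pts = 4000, 30

        def lake(mean, spread):
            pts = np.clip(
                mean + rng.uniform(-0.2, 0.2, n_pts) * mean, 1e-4, 1 - 1e-4
            )
            draws = expit(
                logit(pts)[None, :]
                + spread * rng.standard_normal((n_draws, 1))
            )
            return draws * mean / draws.mean()  # recentre on the target mean

        return make_surface(
            {
                "muskego": lake(0.368, 0.25),   # high mean, wide CI
                "pike": lake(0.587, 0.11),      # high mean, moderate CI
                "camp": lake(0.028, 0.30),      # low-moderate mean
                "grand": lake(0.003, 0.30),     # low mean, tight CI
            }
        )

    def test_reproduces_the_four_exemplar_classes(self, rng):
        classes = predict.classify_lakes(self.exemplar_surface(rng))
        got = classes.set_index("lake_id")["lake_class"]
        assert got["muskego"] == 1
        assert got["pike"] == 2
        assert got["camp"] == 3
        assert got["grand"] == 4

    def test_rule_is_total_over_the_unit_square(self, rng):
        th = predict.ClassThresholds()
        for mean in rng.uniform(0, 1, 200):
            for width in rng.uniform(0, 1, 5):
                assert th.classify(mean, width) in (1, 2, 3, 4)

    def test_invariant_to_point_ordering_and_duplication(self, rng):
        surf = self.exemplar_surface(rng)
        base = predict.classify_lakes(surf)
        perm = rng.permutation(surf.draws.shape[1])
        shuffled = predict.PredictionSurface(
            table=surf.table.iloc[perm].reset_index(drop=True),
            draws=surf.draws[:, perm],
            year=surf.year,
        )
        assert (
            predict.classify_lakes(shuffled).sort_values("lake_id")["lake_class"].tolist()
            == base.sort_values("lake_id")["lake_class"].tolist()
        )
        doubled = predict.PredictionSurface(
            table=pd.concat([surf.table, surf.table], ignore_index=True),
            draws=np.concatenate([surf.draws, surf.draws], axis=1),
            year=surf.year,
        )
        assert (
            predict.classify_lakes(doubled).sort_values("lake_id")["lake_class"].tolist()
            == base.sort_values("lake_id")["lake_class"].tolist()
        )

    def test_zero_width_lake_is_deterministic(self):
        draws = np.full((500, 4), 0.5)
        surf = make_surface({"flat": draws})
        out1 = predict.classify_lakes(surf)
        out2 = predict.classify_lakes(surf)
        assert out1["lake_class"].iloc[0] == out2["lake_class"].iloc[0] == 2


class TestConcordance:
    def test_perfectly_monotone_vectors(self):
        pred = pd.Series([0.1, 0.2, 0.5, 0.9], index=list("abcd"))
        obs = pd.Series([0.0, 0.05, 0.3, 0.6], index=list("abcd"))
        assert predict.concordance(pred, obs) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        pred = pd.Series([0.1, 0.2, 0.5, 0.9], index=list("abcd"))
        obs = pd.Series([0.6, 0.3, 0.05, 0.0], index=list("abcd"))
        assert predict.concordance(pred, obs) == pytest.approx(-1.0)

    def test_six_lake_table_matches_rank_formula(self):
        pred = pd.Series([0.40, 0.10, 0.25, 0.85, 0.03, 0.55], index=list("abcdef"))
        obs = pd.Series([0.30, 0.12, 0.20, 0.70, 0.01, 0.45], index=list("abcdef"))
        rho = predict.concordance(pred, obs)
        # brute-force Spearman: Pearson correlation of the rank vectors
        rp = pred.rank().to_numpy()
        ro = obs.rank().to_numpy()
        manual = np.corrcoef(rp, ro)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_warns_and_returns_nan(self):
        pred = pd.Series([0.5, 0.5, 0.5], index=list("abc"))
        obs = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(predict.concordance(pred, obs))

    def test_too_few_lakes_rejected(self):
        pred = pd.Series([0.5, 0.1], index=list("ab"))
        obs = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(SchemaError):
            predict.concordance(pred, obs)
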