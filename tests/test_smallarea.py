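"""Cluster predictions, shrinkage behaviour and district aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import distprev as dp
from distprev.hierlogit import ModelData, PosteriorDraws

from conftest import make_outcome_table


def constant_draws(beta0, n_clusters=3, m=10):
    """PosteriorDraws with all residual means at zero."""
    table = make_outcome_table([1, 0] * n_clusters,
                               np.repeat(np.arange(n_clusters), 2))
    data = ModelData.from_table(table)
    return PosteriorDraws(
        beta0=np.full(m, beta0),
        sigma2_u=np.full(m, 0.1), sigma2_v=np.full(m, 0.1),
        sigma2_f=np.full(m, 0.1),
        u=np.zeros((m, data.n_clusters)),
        v=np.zeros((m, data.n_districts)),
        f=np.zeros((m, data.n_states)),
        data=data,
    )


class TestClusterPredictions:
    @pytest.mark.parametrize("beta0,expected", [(0.0, 0.5), (-2.2, expit(-2.2))])
    def test_plugin_with_zero_residuals(self, beta0, expected):
        preds = dp.cluster_predictions(constant_draws(beta0))
        assert np.allclose(preds["prob"], expected)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            dp.cluster_predictions(constant_draws(0.0), mode="map")

    def test_probabilities_strictly_inside_unit_interval(self, small_fit):
        _, _, draws = small_fit
        for mode in ("plugin", "draws"):
            p = dp.cluster_predictions(draws, mode)["prob"]
            assert ((p > 0) & (p < 1)).all()

    def test_small_cluster_shrinks_more(self):
        # two clusters with the same raw elevated prevalence but sizes 5 vs
        # 50, against a low-prevalence background: the size-5 cluster's
        # posterior-mean residual must be pulled harder toward zero
        rng = np.random.default_rng(4)
        background = [make_outcome_table(rng.binomial(1, 0.15, 40),
                                         cluster_id=c) for c in range(12)]
        status_small = [1, 1, 1, 0, 0]                  # 60% of 5
        status_big = [1] * 30 + [0] * 20               # 60% of 50
        rows = []
        for c, tab in enumerate(background):
            rows.append(tab)
        rows.append(make_outcome_table(status_small, cluster_id=100))
        rows.append(make_outcome_table(status_big, cluster_id=101))
        table = pd.concat(rows, ignore_index=True)
        table["person_id"] = np.arange(len(table))
        draws = dp.gibbs_fit(ModelData.from_table(table),
                             dp.MCMCConfig(burn_in=300, monitoring=2000, seed=6))
        u_mean = draws.u.mean(axis=0)
        pos = {cid: i for i, cid in enumerate(draws.data.cluster_ids)}
        assert abs(u_mean[pos[100]]) < abs(u_mean[pos[101]])

    def test_plugin_and_draw_averaged_agree_when_concentrated(self):
        # large clusters make the per-cluster linear predictor posterior
        # tight, so the Jensen gap between the two prediction modes shrinks
        cfg = dp.SimConfig(n_states=3, districts_per_state=3,
                           clusters_per_district=4,
                           mean_persons_per_cluster=150, seed=31)
        frame = dp.generate_frame(cfg)
        eff = dp.draw_random_effects(frame, cfg)
        persons = dp.simulate_individuals(frame, eff, cfg)
        table, _ = dp.build_outcome_table(persons, "hypertension")
        draws = dp.gibbs_fit(ModelData.from_table(table),
                             dp.MCMCConfig(burn_in=300, monitoring=3000,
                                           seed=32))
        p1 = dp.cluster_predictions(draws, "plugin")["prob"]
        p2 = dp.cluster_predictions(draws, "draws")["prob"]
        assert np.max(np.abs(p1 - p2)) < 0.005  # 0.5 percentage points


class TestDistrictPrevalence:
    def test_simple_average(self):
        preds = pd.DataFrame({"cluster_id": [1, 2, 3], "district_id": 7,
                              "prob": [0.10, 0.20, 0.30]})
        est = dp.district_prevalence(preds)
        assert est["prevalence"].iloc[0] == pytest.approx(20.0)
        assert est["n_clusters"].iloc[0] == 3

    def test_single_cluster_district(self):
        preds = pd.DataFrame({"cluster_id": [1], "district_id": 1, "prob": [0.07]})
        assert dp.district_prevalence(preds)["prevalence"].iloc[0] == pytest.approx(7.0)

    def test_permutation_invariance(self):
        preds = pd.DataFrame({"cluster_id": [1, 2, 3, 4],
                              "district_id": [0, 1, 0, 1],
                              "prob": [0.1, 0.2, 0.3, 0.4]})
        a = dp.district_prevalence(preds)
        b = dp.district_prevalence(preds.iloc[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_prevalence_within_cluster_range(self, small_fit):
        _, _, draws = small_fit
        preds = dp.cluster_predictions(draws)
        est = dp.district_prevalence(preds)
        lims = preds.groupby("district_id")["prob"].agg(["min", "max"])
        merged = est.merge(lims, on="district_id")
        assert (merged["prevalence"] >= 100 * merged["min"] - 1e-9).all()
        assert (merged["prevalence"] <= 100 * merged["max"] + 1e-9).all()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            dp.district_prevalence(pd.DataFrame(columns=["district_id", "prob"]))


class TestDistributionSummary:
    def test_known_quartiles(self):
        s = dp.distribution_summary(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert s["median"] == 3.0 and s["iqr"] == 2.0

    def test_constant_estimates(self):
        s = dp.distribution_summary(np.full(10, 7.0))
        assert s["iqr"] == 0.0 and s["n_outliers"] == 0

    def test_uniform_median_near_centre(self):
        # median of 720 uniform(5,15) draws: SE ~= 1.2533 * sd / sqrt(n)
        rng = np.random.default_rng(99)
        x = rng.uniform(5, 15, size=720)
        s = dp.distribution_summary(x)
        # order-statistic SE for the median of uniform(5,15):
        # 1 / (2 f(m) sqrt(n)) with density f = 1/10
        se = 10 / (2 * np.sqrt(720))
        assert abs(s["median"] - 10.0) < 3 * se

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dp.distribution_summary(np.array([]))
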