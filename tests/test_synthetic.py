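"""Generator invariants: nesting structure, seeding, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import distprev as dp
from distprev.config import ConfigurationError


@pytest.mark.parametrize("n_states,dps,cpd", [(2, 2, 2), (15, 8, 1), (3, 5, 4)])
def test_frame_counts_and_nesting(n_states, dps, cpd):
    cfg = dp.SimConfig(n_states=n_states, districts_per_state=dps,
                       clusters_per_district=cpd, seed=1)
    frame = dp.generate_frame(cfg)
    assert frame.n_districts == n_states * dps
    assert frame.n_clusters == n_states * dps * cpd
    # every cluster one district, every district one state
    assert frame.clusters.groupby("cluster_id")["district_id"].nunique().eq(1).all()
    assert frame.districts.groupby("district_id")["state_id"].nunique().eq(1).all()
    assert (frame.clusters["target_size"] >= 1).all()


def test_frame_seeded_determinism(small_config):
    f1 = dp.generate_frame(small_config)
    f2 = dp.generate_frame(small_config)
    pd.testing.assert_frame_equal(f1.clusters, f2.clusters)


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        dp.SimConfig(n_states=0)
    with pytest.raises(ConfigurationError):
        dp.SimConfig(sigma2_u=-0.1)
    with pytest.raises(ConfigurationError):
        dp.SimConfig(missing_rate=1.5)


def test_zero_variance_effects_are_zero(small_config):
    import dataclasses
    cfg = dataclasses.replace(small_config, sigma2_u=0.0, sigma2_v=0.0,
                              sigma2_f=0.0)
    frame = dp.generate_frame(cfg)
    eff = dp.draw_random_effects(frame, cfg)
    assert np.all(eff.u == 0) and np.all(eff.v == 0) and np.all(eff.f == 0)


def test_effect_sample_variance_matches_sigma2():
    # 10,000 clusters: sample variance of u must sit inside the chi^2
    # interval for a normal variance at that n (alpha = 0.002)
    cfg = dp.SimConfig(n_states=1, districts_per_state=1,
                       clusters_per_district=10000, sigma2_u=0.3, seed=9)
    frame = dp.generate_frame(cfg)
    eff = dp.draw_random_effects(frame, cfg)
    s2 = eff.u.var(ddof=1)
    n = 10000
    lo = 0.3 * stats.chi2.ppf(0.001, n - 1) / (n - 1)
    hi = 0.3 * stats.chi2.ppf(0.999, n - 1) / (n - 1)
    assert lo < s2 < hi


def test_true_probability_is_inverse_logit(small_config):
    import dataclasses
    for b0, expected in ((0.0, 0.5), (-2.2, expit(-2.2))):
        cfg = dataclasses.replace(small_config, beta0=(b0, b0), sigma2_u=0.0,
                                  sigma2_v=0.0, sigma2_f=0.0)
        frame = dp.generate_frame(cfg)
        eff = dp.draw_random_effects(frame, cfg)
        persons = dp.simulate_individuals(frame, eff, cfg)
        assert np.allclose(persons["true_p"], expected)


def test_person_conservation_and_ranges(small_config):
    frame = dp.generate_frame(small_config)
    eff = dp.draw_random_effects(frame, small_config)
    persons = dp.simulate_individuals(frame, eff, small_config)
    assert len(persons) == frame.clusters["target_size"].sum()
    assert persons["age"].between(15, 49).all()
    assert (persons["weight"] > 0).all()
    assert persons["y"].notna().all()  # missing_rate = 0


def test_missing_rate_zero_means_no_missing_biomarkers():
    cfg = dp.SimConfig(n_states=2, districts_per_state=2,
                       clusters_per_district=2, biomarker_mode="biomarker",
                       missing_rate=0.0, seed=5)
    frame = dp.generate_frame(cfg)
    eff = dp.draw_random_effects(frame, cfg)
    persons = dp.simulate_individuals(frame, eff, cfg)
    bio = ["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3", "glucose"]
    assert persons[bio].notna().all().all()
    assert (persons[bio] > 0).all().all()


@pytest.mark.parametrize("outcome", ["hypertension", "diabetes"])
def test_biomarker_calibration(outcome):
    # classified prevalence over >=100k persons within 3 MC standard
    # errors of the mean true probability
    cfg = dp.SimConfig(n_states=15, districts_per_state=10,
                       clusters_per_district=15, mean_persons_per_cluster=45,
                       biomarker_mode="biomarker", outcome=outcome, seed=21)
    frame = dp.generate_frame(cfg)
    eff = dp.draw_random_effects(frame, cfg)
    persons = dp.simulate_individuals(frame, eff, cfg)
    assert len(persons) >= 100_000
    table, _ = dp.build_outcome_table(persons, outcome)
    p_true = persons["true_p"].to_numpy()
    mc_se = np.sqrt(np.sum(p_true * (1 - p_true))) / len(p_true)
    assert abs(table["status"].mean() - p_true.mean()) < 3 * mc_se


def test_zero_variance_district_homogeneity():
    # with all variance components at zero, district prevalences differ
    # only by binomial noise: chi^2 homogeneity test must not reject
    cfg = dp.SimConfig(n_states=5, districts_per_state=6,
                       clusters_per_district=6, sigma2_u=0.0, sigma2_v=0.0,
                       sigma2_f=0.0, seed=13)
    frame = dp.generate_frame(cfg)
    eff = dp.draw_random_effects(frame, cfg)
    persons = dp.simulate_individuals(frame, eff, cfg)
    counts = persons.groupby("district_id")["y"].agg(["sum", "count"])
    table = np.column_stack([counts["sum"], counts["count"] - counts["sum"]])
    _, pval, _, _ = stats.chi2_contingency(table)
    assert pval > 0.01


def test_two_waves_identity_crosswalk_without_splits(small_config):
    import dataclasses
    cfg = dataclasses.replace(small_config, split_fraction=0.0)
    w1, w2, xwalk = dp.emit_two_waves(cfg)
    xw1 = xwalk[xwalk["wave"] == 1]
    orig = w1.drop_duplicates("cluster_id")[["cluster_id", "district_id"]]
    merged = orig.merge(xw1, on="cluster_id", suffixes=("", "_target"))
    assert (merged["district_id"] == merged["district_id_target"]).all()


def test_full_split_doubles_districts():
    # 13 districts fully split -> 26 target districts
    cfg = dp.SimConfig(n_states=1, districts_per_state=13,
                       clusters_per_district=2, split_fraction=1.0, seed=3)
    w1, w2, xwalk = dp.emit_two_waves(cfg)
    assert xwalk["district_id"].nunique() == 26
    assert w2["district_id"].nunique() == 26


def test_every_wave1_cluster_in_crosswalk_once(small_config):
    import dataclasses
    cfg = dataclasses.replace(small_config, split_fraction=0.3)
    w1, w2, xwalk = dp.emit_two_waves(cfg)
    xw1 = xwalk[xwalk["wave"] == 1]
    assert not xw1["cluster_id"].duplicated().any()
    assert set(w1["cluster_id"]) == set(xw1["cluster_id"])
    # seeded reproducibility of the whole two-wave emission
    w1b, w2b, xwb = dp.emit_two_waves(cfg)
    pd.testing.assert_frame_equal(w1, w1b)
    pd.testing.assert_frame_equal(w2, w2b)
    pd.testing.assert_frame_equal(xwalk, xwb)
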