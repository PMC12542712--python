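"""Synthetic two-stage cluster survey generator with known ground truth.

Emulates an NFHS/DHS-style design: states contain districts, districts
contain clusters (primary sampling units, selected in the field with
probability proportional to size), clusters contain individuals aged 15-49.
Each individual's true outcome probability is

    p = inverse-logit(beta0 + u_cluster + v_district + f_state)

with independent zero-mean normal random intercepts at each level. In
``binary`` mode the outcome indicator is drawn directly; in ``biomarker``
mode the generator emits three systolic/diastolic blood-pressure readings
and a random glucose reading whose WHO-cutoff classification recovers an
outcome with exactly that probability (the per-person mean shift solving
the threshold-crossing equation is computed numerically).

A two-wave emitter additionally splits a configurable fraction of wave-1
districts in two for wave 2 and returns the cluster -> target-district
crosswalk, mirroring real inter-round boundary changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri

from .config import ConfigurationError, SimConfig

# biomarker population parameters (marginals are stipulated, not estimated
# from any survey): systolic/diastolic in mmHg, glucose in mg/dL
SBP_MEAN, SBP_SD = 118.0, 12.0
DBP_MEAN, DBP_SD = 76.0, 9.0
BP_CORR = 0.7
READING_SD = 4.0          # independent per-reading device noise
FIRST_READING_SHIFT = 3.0  # known first-reading elevation artifact
GLUCOSE_LOG_MEAN = np.log(110.0)
GLUCOSE_LOG_SD = 0.30
SBP_CUTOFF, DBP_CUTOFF, GLUCOSE_CUTOFF = 140.0, 90.0, 200.0

PERSON_COLUMNS = [
    "person_id", "wave", "state_id", "district_id", "cluster_id",
    "age", "sex", "weight",
    "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3", "glucose",
    "y", "true_p",
]


@dataclass
class SurveyFrame:
    """Complete nesting: every cluster has one district, every district one state."""

    states: np.ndarray              # state ids
    districts: pd.DataFrame         # district_id, state_id
    clusters: pd.DataFrame          # cluster_id, district_id, state_id, target_size

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_districts(self) -> int:
        return len(self.districts)


@dataclass
class EffectSet:
    """Random-intercept draws aligned with a SurveyFrame, plus generating variances."""

    u: np.ndarray  # per cluster
    v: np.ndarray  # per district
    f: np.ndarray  # per state
    sigma2_u: float
    sigma2_v: float
    sigma2_f: float


def _cluster_sizes(n: int, mean_size: int, rng: np.random.Generator) -> np.ndarray:
    # log-normal size measure mimicking PPS heterogeneity; truncated to
    # [10, 60] at the default mean of 30, bounds relaxed only for tiny configs
    sigma = 0.4
    median = mean_size / np.exp(sigma ** 2 / 2)
    raw = np.rint(rng.lognormal(np.log(median), sigma, size=n)).astype(int)
    lo = max(1, min(10, mean_size))
    hi = max(60, 2 * mean_size)
    return np.clip(raw, lo, hi)


def generate_frame(config: SimConfig, seed: int | None = None) -> SurveyFrame:
    """Build the nested sampling frame with per-cluster target sizes."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    states = np.arange(config.n_states)
    n_districts = config.n_states * config.districts_per_state
    districts = pd.DataFrame({
        "district_id": np.arange(n_districts),
        "state_id": np.repeat(states, config.districts_per_state),
    })
    n_clusters = n_districts * config.clusters_per_district
    clusters = pd.DataFrame({
        "cluster_id": np.arange(n_clusters),
        "district_id": np.repeat(districts["district_id"].to_numpy(),
                                 config.clusters_per_district),
        "state_id": np.repeat(districts["state_id"].to_numpy(),
                              config.clusters_per_district),
        "target_size": _cluster_sizes(n_clusters, config.mean_persons_per_cluster, rng),
    })
    return SurveyFrame(states=states, districts=districts, clusters=clusters)


def draw_random_effects(frame: SurveyFrame, config: SimConfig,
                        seed: int | None = None) -> EffectSet:
    """Independent zero-mean normal intercepts per cluster/district/state."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    return EffectSet(
        u=rng.normal(0.0, np.sqrt(config.sigma2_u), size=frame.n_clusters),
        v=rng.normal(0.0, np.sqrt(config.sigma2_v), size=frame.n_districts),
        f=rng.normal(0.0, np.sqrt(config.sigma2_f), size=len(frame.states)),
        sigma2_u=config.sigma2_u, sigma2_v=config.sigma2_v, sigma2_f=config.sigma2_f,
    )


def _hypertension_shift_interpolator() -> tuple[np.ndarray, np.ndarray]:
    """Tabulate P(classified hypertensive | mean shift delta) on a dense grid.

    The combined (mean of 2nd & 3rd readings) SBP/DBP pair is bivariate
    normal; the per-person shift moves the SBP mean by delta and the DBP
    mean along the population regression of DBP on SBP. Returns (p_grid,
    delta_grid) suitable for monotone interpolation of delta given p.
    """
    var_s = SBP_SD ** 2 + READING_SD ** 2 / 2
    var_d = DBP_SD ** 2 + READING_SD ** 2 / 2
    cov = BP_CORR * SBP_SD * DBP_SD
    rho_c = cov / np.sqrt(var_s * var_d)
    gamma = BP_CORR * DBP_SD / SBP_SD
    delta = np.linspace(-90.0, 110.0, 1601)
    zs = (SBP_CUTOFF - SBP_MEAN - delta) / np.sqrt(var_s)
    zd = (DBP_CUTOFF - DBP_MEAN - gamma * delta) / np.sqrt(var_d)
    bvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho_c], [rho_c, 1.0]])
    p = 1.0 - bvn.cdf(np.column_stack([zs, zd]))
    # enforce strict monotonicity for inversion
    p = np.maximum.accumulate(p)
    return p, delta


_HT_GRID: tuple[np.ndarray, np.ndarray] | None = None


def _hypertension_shift(p: np.ndarray) -> np.ndarray:
    global _HT_GRID
    if _HT_GRID is None:
        _HT_GRID = _hypertension_shift_interpolator()
    p_grid, delta_grid = _HT_GRID
    return np.interp(p, p_grid, delta_grid)


def _glucose_shift(p: np.ndarray) -> np.ndarray:
    # closed form: P(lognormal >= cutoff) = p  =>  shift of the log-mean
    return np.log(GLUCOSE_CUTOFF) - GLUCOSE_LOG_MEAN - GLUCOSE_LOG_SD * ndtri(1.0 - p)


def simulate_individuals(frame: SurveyFrame, effects: EffectSet, config: SimConfig,
                         wave: int = 1, seed: int | None = None) -> pd.DataFrame:
    """Draw one person-level table for a wave.

    Each person's true probability is inverse-logit(beta0 + u + v + f); the
    individual level contributes the logistic distribution's fixed variance
    of pi^2/3 (3.29) implicitly through the Bernoulli-logit draw.
    """
    if len(effects.u) != frame.n_clusters or len(effects.v) != frame.n_districts \
            or len(effects.f) != len(frame.states):
        raise ConfigurationError("effects are not aligned with the survey frame")
    rng = np.random.default_rng(config.seed + 2 + wave if seed is None else seed)
    sizes = frame.clusters["target_size"].to_numpy()
    n = int(sizes.sum())
    cluster_row = np.repeat(np.arange(frame.n_clusters), sizes)
    cluster_id = frame.clusters["cluster_id"].to_numpy()[cluster_row]
    district_id = frame.clusters["district_id"].to_numpy()[cluster_row]
    state_id = frame.clusters["state_id"].to_numpy()[cluster_row]

    state_pos = {s: i for i, s in enumerate(frame.states)}
    district_pos = {d: i for i, d in enumerate(frame.districts["district_id"])}
    eta = (config.beta0[wave - 1]
           + effects.u[cluster_row]
           + effects.v[[district_pos[d] for d in district_id]]
           + effects.f[[state_pos[s] for s in state_id]])
    true_p = expit(eta)

    df = pd.DataFrame({
        "person_id": np.arange(n),
        "wave": wave,
        "state_id": state_id,
        "district_id": district_id,
        "cluster_id": cluster_id,
        "age": rng.integers(15, 50, size=n),
        "sex": config.sex,
        "weight": rng.lognormal(-0.3 ** 2 / 2, 0.3, size=n),
        "true_p": true_p,
    })

    for col in ("sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3", "glucose", "y"):
        df[col] = np.nan

    if config.biomarker_mode == "binary":
        df["y"] = rng.binomial(1, true_p).astype(float)
        if config.missing_rate > 0:
            df.loc[rng.random(n) < config.missing_rate, "y"] = np.nan
    else:
        _draw_biomarkers(df, true_p, config, rng)
    df["person_id"] = df["person_id"].astype(int)
    return df[PERSON_COLUMNS]


def _draw_biomarkers(df: pd.DataFrame, true_p: np.ndarray, config: SimConfig,
                     rng: np.random.Generator) -> None:
    n = len(df)
    # the configured outcome's biomarkers are calibrated so classification
    # recovers true_p; the other family is drawn at the population baseline
    delta_bp = _hypertension_shift(true_p) if config.outcome == "hypertension" \
        else np.zeros(n)
    delta_gl = _glucose_shift(true_p) if config.outcome == "diabetes" \
        else np.zeros(n)

    gamma = BP_CORR * DBP_SD / SBP_SD
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    latent_s = SBP_MEAN + delta_bp + SBP_SD * z1
    latent_d = (DBP_MEAN + gamma * delta_bp
                + DBP_SD * (BP_CORR * z1 + np.sqrt(1 - BP_CORR ** 2) * z2))
    for r in (1, 2, 3):
        shift = FIRST_READING_SHIFT if r == 1 else 0.0
        df[f"sbp{r}"] = np.maximum(latent_s + shift + rng.normal(0, READING_SD, n), 1.0)
        df[f"dbp{r}"] = np.maximum(latent_d + shift + rng.normal(0, READING_SD, n), 1.0)
    df["glucose"] = np.exp(GLUCOSE_LOG_MEAN + delta_gl
                           + GLUCOSE_LOG_SD * rng.standard_normal(n))

    if config.missing_rate > 0:
        bp_cols = ["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]
        df.loc[rng.random(n) < config.missing_rate, bp_cols] = np.nan
        df.loc[rng.random(n) < config.missing_rate, "glucose"] = np.nan


def emit_two_waves(config: SimConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate both waves plus the cluster -> target-district crosswalk.

    Wave 1 uses the original district frame. A ``split_fraction`` share of
    districts (rounded) is split into two districts for wave 2; the target
    frame is the wave-2 geography, and the crosswalk maps every cluster of
    both waves onto it. Effects and persons are drawn fresh per wave with
    the per-wave intercept.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(7)]

    frame1 = generate_frame(config, seed=seeds[0])
    eff1 = draw_random_effects(frame1, config, seed=seeds[1])
    w1 = simulate_individuals(frame1, eff1, config, wave=1, seed=seeds[2])

    rng = np.random.default_rng(seeds[3])
    d1 = frame1.districts
    n_split = int(round(config.split_fraction * len(d1)))
    split_ids = np.sort(rng.choice(d1["district_id"].to_numpy(), size=n_split,
                                   replace=False))
    next_id = int(d1["district_id"].max()) + 1

    # target frame: unsplit districts keep their id; split district d maps
    # to two children (d stays as child A, a fresh id is child B)
    child_of = {}
    rows = []
    for _, row in d1.iterrows():
        d = int(row["district_id"])
        if d in set(split_ids):
            child_of[d] = (d, next_id)
            rows.append({"district_id": d, "state_id": int(row["state_id"])})
            rows.append({"district_id": next_id, "state_id": int(row["state_id"])})
            next_id += 1
        else:
            rows.append({"district_id": d, "state_id": int(row["state_id"])})
    target_districts = pd.DataFrame(rows, columns=["district_id", "state_id"])

    # wave-2 frame: fresh clusters drawn in the target geography
    frame2 = SurveyFrame(
        states=frame1.states,
        districts=target_districts,
        clusters=pd.DataFrame({
            "cluster_id": frame1.n_clusters + np.arange(
                len(target_districts) * config.clusters_per_district),
            "district_id": np.repeat(target_districts["district_id"].to_numpy(),
                                     config.clusters_per_district),
            "state_id": np.repeat(target_districts["state_id"].to_numpy(),
                                  config.clusters_per_district),
            "target_size": _cluster_sizes(
                len(target_districts) * config.clusters_per_district,
                config.mean_persons_per_cluster,
                np.random.default_rng(seeds[4])),
        }),
    )
    eff2 = draw_random_effects(frame2, config, seed=seeds[5])
    w2 = simulate_individuals(frame2, eff2, config, wave=2, seed=seeds[6])

    # crosswalk: wave-1 clusters of split districts are divided between the
    # two children; everything else maps identically
    xw_rows = []
    for d, grp in frame1.clusters.groupby("district_id", sort=True):
        cids = grp["cluster_id"].to_numpy()
        sid = int(grp["state_id"].iloc[0])
        if int(d) in child_of:
            perm = rng.permutation(len(cids))
            half = len(cids) // 2
            a, b = child_of[int(d)]
            for i, c in enumerate(cids[perm]):
                xw_rows.append((1, int(c), a if i < half else b, sid))
        else:
            for c in cids:
                xw_rows.append((1, int(c), int(d), sid))
    for _, row in frame2.clusters.iterrows():
        xw_rows.append((2, int(row["cluster_id"]), int(row["district_id"]),
                        int(row["state_id"])))
    xwalk = pd.DataFrame(xw_rows,
                         columns=["wave", "cluster_id", "district_id", "state_id"])
    return w1, w2, xwalk
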