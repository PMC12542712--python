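"""Four-level random-intercept Bayesian logistic regression via Gibbs sampling.

Model, for person i in cluster j, district k, state l:

    y_ijkl ~ Bernoulli(p_ijkl),  logit(p_ijkl) = beta0 + u_jkl + v_kl + f_l
    u ~ N(0, sigma2_u),  v ~ N(0, sigma2_v),  f ~ N(0, sigma2_f)

The individual level carries the logistic distribution's fixed variance of
pi^2/3 (3.29) implicitly. Pólya-Gamma data augmentation makes every full
conditional exact: one auxiliary omega_i ~ PG(1, eta_i) per person turns the
Bernoulli-logit likelihood Gaussian in the linear predictor, so the
intercept and each residual block are drawn from closed-form normals and
each variance from its inverse-gamma full conditional. No tuning, no
Metropolis step.

Update order within an iteration is fixed (omega, beta0, u, v, f,
variances) so seeded runs are bit-reproducible. Persons are canonically
ordered by ID when the design is built, which makes results invariant to
the input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logit

from ._pg import draw_pg
from .config import MCMCConfig

#: fixed level-1 (individual) variance implied by the logistic link, pi^2/3
LOGISTIC_LEVEL1_VARIANCE = np.pi ** 2 / 3


@dataclass
class ModelData:
    """Binary responses plus dense nesting indices, canonically ordered."""

    y: np.ndarray                 # {0,1}, one per person
    cluster_idx: np.ndarray       # person -> cluster position
    district_idx: np.ndarray      # person -> district position
    state_idx: np.ndarray         # person -> state position
    cluster_ids: np.ndarray       # position -> original cluster id
    district_ids: np.ndarray
    state_ids: np.ndarray
    cluster_district: np.ndarray  # cluster position -> district position
    district_state: np.ndarray    # district position -> state position

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ModelData":
        """Build from a classified outcome table (needs person_id, status,
        cluster_id, district_id, state_id)."""
        t = table.sort_values("person_id", kind="mergesort")
        y = t["status"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        cluster_ids, cluster_idx = np.unique(t["cluster_id"].to_numpy(),
                                             return_inverse=True)
        district_ids, district_idx = np.unique(t["district_id"].to_numpy(),
                                               return_inverse=True)
        state_ids, state_idx = np.unique(t["state_id"].to_numpy(),
                                         return_inverse=True)
        cluster_district = np.full(len(cluster_ids), -1, dtype=int)
        cluster_district[cluster_idx] = district_idx
        district_state = np.full(len(district_ids), -1, dtype=int)
        district_state[district_idx] = state_idx
        # nesting must be strict: one parent per unit
        if len(set(zip(cluster_idx.tolist(), district_idx.tolist()))) != len(cluster_ids):
            raise ValueError("a cluster maps to more than one district")
        if len(set(zip(district_idx.tolist(), state_idx.tolist()))) != len(district_ids):
            raise ValueError("a district maps to more than one state")
        return cls(y.astype(np.int8), cluster_idx, district_idx, state_idx,
                   cluster_ids, district_ids, state_ids,
                   cluster_district, district_state)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in Gibbs draws for every model parameter."""

    beta0: np.ndarray     # (M,)
    sigma2_u: np.ndarray  # (M,)
    sigma2_v: np.ndarray
    sigma2_f: np.ndarray
    u: np.ndarray         # (M, n_clusters)
    v: np.ndarray         # (M, n_districts)
    f: np.ndarray         # (M, n_states)
    data: ModelData

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    def scalar_summary(self) -> pd.DataFrame:
        rows = []
        for name in ("beta0", "sigma2_u", "sigma2_v", "sigma2_f"):
            x = getattr(self, name)
            rows.append({"parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                         "q2.5": np.quantile(x, 0.025),
                         "q97.5": np.quantile(x, 0.975)})
        return pd.DataFrame(rows)


def initialize(data: ModelData, config: MCMCConfig,
               user_state: dict | None = None) -> dict:
    """Starting state: intercept at the (clamped) empirical log-odds,
    residuals at zero, variances at 0.1 — an approximate-mode start whose
    influence is confined to burn-in."""
    ybar = float(data.y.mean())
    if ybar in (0.0, 1.0):
        edge = 1.0 / (data.n + 1)
        b0 = float(logit(edge if ybar == 0.0 else 1.0 - edge))
        warnings.warn("all responses identical; intercept clamped", stacklevel=2)
    else:
        b0 = float(logit(ybar))
    state = {
        "beta0": b0,
        "u": np.zeros(data.n_clusters),
        "v": np.zeros(data.n_districts),
        "f": np.zeros(data.n_states),
        "sigma2_u": 0.1, "sigma2_v": 0.1, "sigma2_f": 0.1,
    }
    if config.init_mode == "zeros":
        state["beta0"] = 0.0
    elif config.init_mode == "user":
        if user_state is None:
            raise ValueError("init_mode 'user' requires a starting state")
        state.update(user_state)
    return state


def _draw_block(idx, n_units, kappa, omega, offset, sigma2, rng):
    """Gaussian full conditional for one residual block."""
    prec = 1.0 / sigma2 + np.bincount(idx, weights=omega, minlength=n_units)
    mean = np.bincount(idx, weights=kappa - omega * offset, minlength=n_units) / prec
    return mean + rng.standard_normal(n_units) / np.sqrt(prec)


def gibbs_fit(data: ModelData, config: MCMCConfig,
              user_state: dict | None = None) -> PosteriorDraws:
    """Run the Pólya-Gamma Gibbs sampler and return thinned retained draws."""
    if data.n == 0:
        raise ValueError("empty data")
    state = initialize(data, config, user_state)
    rng = np.random.default_rng(config.seed)
    a0, b0_hyper = config.prior.variance_a, config.prior.variance_b
    ci, di, si = data.cluster_idx, data.district_idx, data.state_idx
    kappa = data.y.astype(float) - 0.5
    n_keep = config.n_retained
    out = PosteriorDraws(
        beta0=np.empty(n_keep),
        sigma2_u=np.empty(n_keep), sigma2_v=np.empty(n_keep),
        sigma2_f=np.empty(n_keep),
        u=np.empty((n_keep, data.n_clusters)),
        v=np.empty((n_keep, data.n_districts)),
        f=np.empty((n_keep, data.n_states)),
        data=data,
    )
    beta0 = state["beta0"]
    u, v, f = state["u"].copy(), state["v"].copy(), state["f"].copy()
    s2u, s2v, s2f = state["sigma2_u"], state["sigma2_v"], state["sigma2_f"]

    kept = 0
    total = config.burn_in + config.monitoring
    for it in range(total):
        resid = u[ci] + v[di] + f[si]
        eta = beta0 + resid
        omega = draw_pg(eta, int(rng.integers(2 ** 31)))
        if not np.all(np.isfinite(omega)) or np.any(omega <= 0):
            omega = draw_pg(eta, int(rng.integers(2 ** 31)))  # one retry
            if not np.all(np.isfinite(omega)) or np.any(omega <= 0):
                raise FloatingPointError("degenerate Pólya-Gamma draw")

        # intercept (flat prior)
        prec0 = omega.sum()
        mean0 = np.sum(kappa - omega * resid) / prec0
        beta0 = mean0 + rng.standard_normal() / np.sqrt(prec0)

        u = _draw_block(ci, data.n_clusters, kappa, omega,
                        beta0 + v[di] + f[si], s2u, rng)
        v = _draw_block(di, data.n_districts, kappa, omega,
                        beta0 + u[ci] + f[si], s2v, rng)
        f = _draw_block(si, data.n_states, kappa, omega,
                        beta0 + u[ci] + v[di], s2f, rng)

        s2u = 1.0 / rng.gamma(a0 + data.n_clusters / 2.0,
                              1.0 / (b0_hyper + 0.5 * u @ u))
        s2v = 1.0 / rng.gamma(a0 + data.n_districts / 2.0,
                              1.0 / (b0_hyper + 0.5 * v @ v))
        s2f = 1.0 / rng.gamma(a0 + data.n_states / 2.0,
                              1.0 / (b0_hyper + 0.5 * f @ f))

        post = it - config.burn_in
        if post >= 0 and post % config.thin == 0 and kept < n_keep:
            out.beta0[kept] = beta0
            out.sigma2_u[kept], out.sigma2_v[kept], out.sigma2_f[kept] = s2u, s2v, s2f
            out.u[kept] = u
            out.v[kept] = v
            out.f[kept] = f
            kept += 1
    return out


@dataclass
class Diagnostics:
    table: pd.DataFrame  # parameter, ess, rhat, mcse, flagged

    @property
    def ok(self) -> bool:
        return not self.table["flagged"].any()


def diagnostics(draws: PosteriorDraws | dict[str, np.ndarray]) -> Diagnostics:
    """ESS (autocorrelation-time estimate), split-chain convergence statistic
    and Monte-Carlo standard error for each scalar parameter."""
    if isinstance(draws, PosteriorDraws):
        chains = {name: getattr(draws, name)
                  for name in ("beta0", "sigma2_u", "sigma2_v", "sigma2_f")}
    else:
        chains = dict(draws)
    rows = []
    for name, x in chains.items():
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("diagnostics require at least 2 retained draws")
        if np.allclose(x, x[0]):
            rows.append({"parameter": name, "ess": 0.0, "rhat": np.nan,
                         "mcse": np.nan, "flagged": True})
            continue
        half = x.size // 2
        split = np.stack([x[:half], x[half:2 * half]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(x[None, :]))
            rhat = float(az.rhat(split))
        mcse = float(x.std(ddof=1) / np.sqrt(ess)) if ess > 0 else np.nan
        rows.append({"parameter": name, "ess": ess, "rhat": rhat, "mcse": mcse,
                     "flagged": not (ess > 0) or rhat > 1.05})
    return Diagnostics(pd.DataFrame(rows))
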