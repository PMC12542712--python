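"""Independent brute-force oracles used only by the test suite.

The tiny-instance oracle integrates the exact posterior of the four-level
logistic model on a dense tensor-product grid, entirely independently of
the Gibbs implementation. With a single cluster/district/state the latent
space is (beta0, u, v, f); the inverse-gamma variance components are
marginalised analytically, which makes each residual's prior a scaled
Student-t:

    u | a, b  ~  t_{2a}(0, sqrt(b/a))

and leaves a 4-dimensional integral. Posterior variance means are
recovered from the conditional inverse-gamma mean,
E[s2 | u] = (b + u^2/2) / (a + 1/2 - 1), valid for a > 1/2.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _log_post(b0, u, v, f, k, n, df, scale):
    total = (b0[:, None, None, None] + u[None, :, None, None]
             + v[None, None, :, None] + f[None, None, None, :])
    ll = -k * np.logaddexp(0.0, -total) - (n - k) * np.logaddexp(0.0, total)
    lp = (stats.t.logpdf(u, df, scale=scale)[None, :, None, None]
          + stats.t.logpdf(v, df, scale=scale)[None, None, :, None]
          + stats.t.logpdf(f, df, scale=scale)[None, None, None, :])
    return ll + lp


def tiny_posterior_means(y, prior_a: float, prior_b: float,
                         n_grid: int = 51) -> dict[str, float]:
    """Posterior means of (beta0, sigma2_u, sigma2_v, sigma2_f) for a
    single-cluster/district/state dataset, by two-pass adaptive quadrature."""
    if prior_a <= 0.5:
        raise ValueError("variance posterior mean requires prior shape > 1/2")
    y = np.asarray(y)
    k, n = int(y.sum()), len(y)
    if k == 0 or k == n:
        raise ValueError("flat intercept prior needs both response values")
    df = 2.0 * prior_a
    scale = np.sqrt(prior_b / prior_a)

    grids = [np.linspace(-12, 12, n_grid)] + \
            [np.linspace(-8 * scale - 2, 8 * scale + 2, n_grid)] * 3
    for _ in range(2):  # refine around the bulk
        lp = _log_post(grids[0], grids[1], grids[2], grids[3], k, n, df, scale)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        new_grids = []
        for axis, g in enumerate(grids):
            marg = w.sum(axis=tuple(i for i in range(4) if i != axis))
            mu = float(np.sum(marg * g))
            sd = float(np.sqrt(np.sum(marg * (g - mu) ** 2)))
            new_grids.append(np.linspace(mu - 7 * sd, mu + 7 * sd, n_grid))
        grids = new_grids

    lp = _log_post(grids[0], grids[1], grids[2], grids[3], k, n, df, scale)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    means = {}
    marg_b0 = w.sum(axis=(1, 2, 3))
    means["beta0"] = float(np.sum(marg_b0 * grids[0]))
    denom = prior_a + 0.5 - 1.0
    for name, axis in (("sigma2_u", 1), ("sigma2_v", 2), ("sigma2_f", 3)):
        marg = w.sum(axis=tuple(i for i in range(4) if i != axis))
        e_sq = float(np.sum(marg * grids[axis] ** 2))
        means[name] = (prior_b + e_sq / 2.0) / denom
    return means
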