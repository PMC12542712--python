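"""Precision-weighted cluster predictions and district prevalence.

The posterior-mean residuals from the hierarchical fit are the
precision-weighted (shrunken) cluster estimates: each cluster's deviation
is pulled toward its district/state mean in proportion to its sampling
imprecision. District prevalence is the simple (unweighted) average of the
member clusters' predicted probabilities, in percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierlogit import PosteriorDraws


def cluster_predictions(draws: PosteriorDraws, mode: str = "plugin") -> pd.DataFrame:
    """Predicted probability per cluster.

    ``plugin`` (default): inverse-logit of the posterior-mean linear
    predictor, ilogit(b0 + u_j + v_k + f_l) with posterior-mean residuals.
    ``draws``: average of per-draw inverse-logits (the fully Bayesian
    posterior-mean probability). The two agree closely when the posterior
    is concentrated.
    """
    data = draws.data
    kd = data.cluster_district
    ls = data.district_state[kd]
    if mode == "plugin":
        eta = (draws.beta0.mean()
               + draws.u.mean(axis=0)
               + draws.v.mean(axis=0)[kd]
               + draws.f.mean(axis=0)[ls])
        p = expit(eta)
    elif mode == "draws":
        eta = (draws.beta0[:, None] + draws.u
               + draws.v[:, kd] + draws.f[:, ls])
        p = expit(eta).mean(axis=0)
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return pd.DataFrame({
        "cluster_id": data.cluster_ids,
        "district_id": data.district_ids[kd],
        "state_id": data.state_ids[ls],
        "prob": p,
    })


def district_prevalence(preds: pd.DataFrame, wave=None, sex=None, outcome=None
                        ) -> pd.DataFrame:
    """Simple average of member-cluster probabilities per district, in %."""
    if len(preds) == 0:
        raise ValueError("no cluster predictions")
    grouped = preds.groupby("district_id")
    out = pd.DataFrame({
        "district_id": grouped.size().index,
        "prevalence": 100.0 * grouped["prob"].mean().to_numpy(),
        "n_clusters": grouped.size().to_numpy(),
    })
    for name, value in (("wave", wave), ("sex", sex), ("outcome", outcome)):
        if value is not None:
            out[name] = value
    return out.reset_index(drop=True)


def distribution_summary(estimates: pd.DataFrame | np.ndarray) -> dict:
    """Box-plot summary of the district prevalence distribution.

    Quartiles use linear interpolation between order statistics; whisker
    fences sit at 1.5 x IQR beyond the quartiles, with values outside
    counted as outliers.
    """
    x = estimates["prevalence"].to_numpy() if isinstance(estimates, pd.DataFrame) \
        else np.asarray(estimates, dtype=float)
    if x.size == 0:
        raise ValueError("empty estimate set")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    return {
        "n": int(x.size),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "iqr": float(iqr),
        "mean": float(x.mean()),
        "lower_fence": float(lo_fence),
        "upper_fence": float(hi_fence),
        "n_outliers": int(np.sum((x < lo_fence) | (x > hi_fence))),
    }
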