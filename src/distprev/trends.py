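"""Between-wave comparative analytics over district prevalence tables.

Change is wave-2 minus wave-1 prevalence in percentage points. Banding uses
the +/-2.49 pp thresholds with an inclusive middle band. The quadrant
analysis crosses each district's wave-1 position relative to the unweighted
district mean with the direction of its change; exact-zero changes and
exactly-average baselines are tallied separately rather than silently
assigned to a side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STABLE_BAND = 2.49  # percentage points, inclusive


def compute_change(w1: pd.DataFrame, w2: pd.DataFrame) -> pd.DataFrame:
    """Per-district percentage-point change between waves.

    Districts present in only one wave are excluded (their IDs are
    reported in the ``dropped`` attribute of the result).
    """
    a = w1.set_index("district_id")["prevalence"]
    b = w2.set_index("district_id")["prevalence"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no districts shared between waves")
    out = pd.DataFrame({
        "district_id": shared,
        "prevalence_w1": a.loc[shared].to_numpy(),
        "prevalence_w2": b.loc[shared].to_numpy(),
    })
    out["change"] = out["prevalence_w2"] - out["prevalence_w1"]
    out["band"] = band_labels(out["change"].to_numpy())
    out.attrs["dropped"] = sorted(set(a.index).symmetric_difference(b.index))
    return out


def band_labels(change: np.ndarray) -> np.ndarray:
    change = np.asarray(change, dtype=float)
    labels = np.where(change > STABLE_BAND, "increase",
                      np.where(change < -STABLE_BAND, "decrease", "stable"))
    return labels


def band_changes(changes: pd.DataFrame | np.ndarray) -> dict[str, int]:
    """Counts of districts per change band."""
    arr = changes["change"].to_numpy() if isinstance(changes, pd.DataFrame) \
        else np.asarray(changes, dtype=float)
    labels = band_labels(arr)
    return {band: int(np.sum(labels == band))
            for band in ("decrease", "stable", "increase")}


def quadrant_analysis(w1: pd.DataFrame, changes: pd.DataFrame) -> dict:
    """Cross wave-1 baseline side (vs the unweighted district mean) with the
    direction of change. Returns the 2x2 counts plus explicit tallies for
    zero changes and exactly-average baselines."""
    base = w1.set_index("district_id")["prevalence"]
    chg = changes.set_index("district_id")["change"]
    if set(base.index) != set(chg.index):
        raise ValueError("quadrant analysis requires identical district sets")
    chg = chg.loc[base.index]
    mean_prev = float(base.mean())
    above = base.to_numpy() > mean_prev
    at_mean = base.to_numpy() == mean_prev
    up = chg.to_numpy() > 0
    zero = chg.to_numpy() == 0
    counts = {
        "baseline_mean": mean_prev,
        "above_increase": int(np.sum(above & up & ~zero)),
        "above_decrease": int(np.sum(above & ~up & ~zero)),
        "below_increase": int(np.sum(~above & ~at_mean & up & ~zero)),
        "below_decrease": int(np.sum(~above & ~at_mean & ~up & ~zero)),
        "zero_change": int(np.sum(zero)),
        "at_mean_baseline": int(np.sum(at_mean & ~zero)),
        "n_districts": int(len(base)),
    }
    counts["above_total"] = counts["above_increase"] + counts["above_decrease"]
    counts["below_total"] = counts["below_increase"] + counts["below_decrease"]
    return counts


def cross_outcome_correlation(est_a: pd.DataFrame, est_b: pd.DataFrame,
                              method: str = "pearson") -> tuple[float, int]:
    """District-level correlation between two outcomes' prevalence estimates
    over shared districts. Returns (r, n_shared)."""
    a = est_a.set_index("district_id")["prevalence"]
    b = est_b.set_index("district_id")["prevalence"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared districts")
    r = a.loc[shared].corr(b.loc[shared], method=method)
    return float(r), int(len(shared))
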