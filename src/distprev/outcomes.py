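"""WHO-cutoff classification, eligibility filtering and weighted prevalence.

Hypertension: combined systolic >= 140 mmHg and/or combined diastolic
>= 90 mmHg (cutoffs inclusive, no age/sex adjustment). Diabetes: random
blood glucose >= 200 mg/dL. Eligibility: ages 15-49 inclusive with the
required biomarkers present; exclusions are tallied by reason, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SBP_CUTOFF = 140.0
DBP_CUTOFF = 90.0
GLUCOSE_CUTOFF = 200.0
AGE_MIN, AGE_MAX = 15, 49

BP_RULES = ("mean23", "mean_all", "last")


def combine_bp_readings(df: pd.DataFrame, rule: str = "mean23") -> pd.DataFrame:
    """Collapse the three SBP/DBP readings into one value each.

    Default rule averages the 2nd and 3rd readings (the convention for the
    survey's portable monitor, whose first reading runs systematically
    high); alternatives average all three or take the last. Rows lacking
    the readings the rule needs come out NaN and are excluded downstream.
    """
    if rule not in BP_RULES:
        raise ValueError(f"unknown BP rule {rule!r}; expected one of {BP_RULES}")
    out = df.copy()
    for prefix in ("sbp", "dbp"):
        r1, r2, r3 = (out[f"{prefix}{i}"] for i in (1, 2, 3))
        if rule == "mean23":
            combined = (r2 + r3) / 2.0
        elif rule == "mean_all":
            combined = (r1 + r2 + r3) / 3.0
        else:  # last
            combined = r3
        out[prefix] = combined
    return out


def classify_hypertension(sbp, dbp):
    """1 iff SBP >= 140 or DBP >= 90 (inclusive); NaN where either is missing."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    status = ((sbp >= SBP_CUTOFF) | (dbp >= DBP_CUTOFF)).astype(float)
    status = np.where(np.isnan(sbp) | np.isnan(dbp), np.nan, status)
    return status


def classify_diabetes(glucose):
    """1 iff random glucose >= 200 mg/dL (inclusive); NaN where missing."""
    glucose = np.asarray(glucose, dtype=float)
    return np.where(np.isnan(glucose), np.nan, (glucose >= GLUCOSE_CUTOFF).astype(float))


def filter_eligible(persons: pd.DataFrame, outcome: str, bp_rule: str = "mean23"
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain persons aged 15-49 with the outcome's biomarkers present.

    Returns the retained rows (unaltered) and an exclusion tally by reason.
    Synthetic binary-mode tables (a ``y`` column, no biomarkers) are
    filtered on ``y`` presence instead.
    """
    tally: dict[str, int] = {}
    keep = (persons["age"] >= AGE_MIN) & (persons["age"] <= AGE_MAX)
    tally["age_out_of_range"] = int((~keep).sum())
    eligible = persons[keep]

    binary_mode = "y" in eligible.columns and eligible["y"].notna().any()
    if binary_mode:
        present = eligible["y"].notna()
        tally["missing_outcome"] = int((~present).sum())
    elif outcome == "hypertension":
        combined = combine_bp_readings(eligible, bp_rule)
        present = combined["sbp"].notna() & combined["dbp"].notna()
        tally["missing_bp"] = int((~present).sum())
    elif outcome == "diabetes":
        present = eligible["glucose"].notna()
        tally["missing_glucose"] = int((~present).sum())
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return eligible[present], tally


def build_outcome_table(persons: pd.DataFrame, outcome: str, bp_rule: str = "mean23"
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify eligible persons into a person-level binary outcome table."""
    retained, tally = filter_eligible(persons, outcome, bp_rule)
    out = retained.copy()
    if "y" in out.columns and out["y"].notna().any():
        status = out["y"].to_numpy(dtype=float)
    elif outcome == "hypertension":
        combined = combine_bp_readings(out, bp_rule)
        status = classify_hypertension(combined["sbp"], combined["dbp"])
    else:
        status = classify_diabetes(out["glucose"])
    out["outcome"] = outcome
    out["status"] = status.astype(int)
    cols = ["person_id", "wave", "state_id", "district_id", "cluster_id",
            "sex", "weight", "outcome", "status"]
    extra = [c for c in ("true_p",) if c in out.columns]
    return out[cols + extra].reset_index(drop=True), tally


@dataclass
class WeightedPrevalence:
    estimate: float   # percent
    ci_low: float     # percent
    ci_high: float    # percent
    n: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 100.0


def weighted_prevalence(table: pd.DataFrame, cluster_col: str = "cluster_id"
                        ) -> WeightedPrevalence:
    """Survey-weighted prevalence with a cluster-robust 95% CI.

    Point estimate 100 * sum(w*y)/sum(w); variance by first-stage PSU
    linearisation of the ratio estimator (between-cluster totals), normal
    interval clamped to [0, 100]. Degenerate all-0/all-1 tables return a
    zero-width interval at the boundary.
    """
    if len(table) == 0:
        raise ValueError("weighted_prevalence: empty outcome table")
    w = table["weight"].to_numpy(dtype=float)
    y = table["status"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    p_hat = float(np.sum(w * y) / np.sum(w))
    grouped = pd.DataFrame({"c": table[cluster_col], "wy": w * y, "w": w}).groupby("c")
    z_c = grouped["wy"].sum().to_numpy()
    w_c = grouped["w"].sum().to_numpy()
    n_psu = len(z_c)
    if n_psu > 1 and 0.0 < p_hat < 1.0:
        resid = z_c - p_hat * w_c
        var = n_psu / (n_psu - 1) * np.sum(resid ** 2) / np.sum(w) ** 2
        half = 1.959963984540054 * np.sqrt(var)
    else:
        half = 0.0
    lo = float(np.clip(p_hat - half, 0.0, 1.0))
    hi = float(np.clip(p_hat + half, 0.0, 1.0))
    return WeightedPrevalence(100.0 * p_hat, 100.0 * lo, 100.0 * hi, len(table))
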