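"""Reassign survey clusters to a common target district frame.

Both waves must be expressed over the same districts before changes can be
compared; the crosswalk table (wave, cluster -> target district/state) is
consumed as supplied — polygon intersection work lives upstream of this
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

XWALK_COLUMNS = ["wave", "cluster_id", "district_id", "state_id"]


class CrosswalkError(KeyError):
    """A cluster is missing from the crosswalk."""


def apply_crosswalk(table: pd.DataFrame, xwalk: pd.DataFrame, wave: int
                    ) -> pd.DataFrame:
    """Replace district/state IDs with target-frame IDs for one wave.

    Every cluster in ``table`` must appear in the crosswalk for that wave;
    absent clusters raise, naming the offenders. Row count is conserved.
    """
    xw = xwalk[xwalk["wave"] == wave]
    dup = xw["cluster_id"].duplicated()
    if dup.any():
        raise ValueError(f"crosswalk has duplicate clusters for wave {wave}: "
                         f"{sorted(xw.loc[dup, 'cluster_id'].unique().tolist())}")
    mapping = xw.set_index("cluster_id")[["district_id", "state_id"]]
    missing = set(table["cluster_id"].unique()) - set(mapping.index)
    if missing:
        raise CrosswalkError(f"clusters absent from crosswalk (wave {wave}): "
                             f"{sorted(missing)}")
    out = table.copy()
    out["district_id"] = mapping["district_id"].reindex(out["cluster_id"]).to_numpy()
    out["state_id"] = mapping["state_id"].reindex(out["cluster_id"]).to_numpy()
    return out


@dataclass
class CrosswalkReport:
    n_rows: int = 0
    district_count: int = 0
    duplicate_keys: list = field(default_factory=list)
    orphan_districts: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.duplicate_keys and not self.orphan_districts


def validate_crosswalk(xwalk: pd.DataFrame,
                       target_districts: pd.DataFrame | None = None
                       ) -> CrosswalkReport:
    """Report-only diagnostics: duplicates, orphan districts, frame size."""
    if len(xwalk) == 0:
        return CrosswalkReport()
    dup_mask = xwalk.duplicated(subset=["wave", "cluster_id"], keep=False)
    duplicates = sorted({(int(w), int(c)) for w, c in
                         xwalk.loc[dup_mask, ["wave", "cluster_id"]].itertuples(index=False)})
    # a district mapped to more than one state is malformed
    states_per_district = xwalk.groupby("district_id")["state_id"].nunique()
    orphans = sorted(states_per_district[states_per_district > 1].index.tolist())
    if target_districts is not None:
        known = set(target_districts["district_id"])
        orphans += sorted(set(xwalk["district_id"]) - known)
    return CrosswalkReport(
        n_rows=len(xwalk),
        district_count=int(xwalk["district_id"].nunique()),
        duplicate_keys=duplicates,
        orphan_districts=orphans,
    )
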