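"""End-to-end pipeline: simulate -> classify -> crosswalk -> fit -> estimate -> trends.

One independent model fit per (outcome x sex x wave) cell. The global seed
deterministically derives per-cell seeds through ``numpy.random.SeedSequence``
spawning in a fixed cell order (outcomes x sexes as configured, waves 1-2
within a cell), so cells are independent yet the whole run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import MCMCConfig, PipelineConfig
from .crosswalk import apply_crosswalk, validate_crosswalk
from .hierlogit import ModelData, gibbs_fit
from .io import write_crosswalk, write_estimates, write_survey_table
from .outcomes import build_outcome_table, weighted_prevalence
from .smallarea import cluster_predictions, district_prevalence
from .synthetic import emit_two_waves
from .trends import band_changes, compute_change, cross_outcome_correlation, \
    quadrant_analysis


def _cell_seeds(global_seed: int, n_cells: int) -> list[list[int]]:
    """Four sub-seeds per cell (simulate, fit wave 1, fit wave 2, spare)."""
    root = np.random.SeedSequence(global_seed)
    return [[int(c.generate_state(1)[0] % (2 ** 31)) for c in cell.spawn(4)]
            for cell in root.spawn(n_cells)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every cell and write district, change and summary tables.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = [(o, s) for o in config.outcomes for s in config.sexes]
    seeds = _cell_seeds(config.seed, len(cells))
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "global_seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "cells": {},
    }
    district_tables: dict[tuple, pd.DataFrame] = {}

    for (outcome, sex), cell_seed in zip(cells, seeds):
        cell_name = f"{outcome}_{sex}"
        try:
            sim = dataclasses.replace(config.sim, outcome=outcome, sex=sex,
                                      seed=cell_seed[0])
            w1, w2, xwalk = emit_two_waves(sim)
            report = validate_crosswalk(xwalk)
            if not report.ok:
                raise ValueError(f"invalid crosswalk: {report}")
            write_survey_table(out_dir / f"persons_{cell_name}_w1.csv", w1)
            write_survey_table(out_dir / f"persons_{cell_name}_w2.csv", w2)
            write_crosswalk(out_dir / f"crosswalk_{cell_name}.csv", xwalk)

            cell_info: dict = {"seeds": cell_seed, "waves": {}}
            for wave, persons in ((1, w1), (2, w2)):
                table, tally = build_outcome_table(persons, outcome, config.bp_rule)
                table = apply_crosswalk(table, xwalk, wave)
                wp = weighted_prevalence(table)
                data = ModelData.from_table(table)
                mcmc = dataclasses.replace(config.mcmc, seed=cell_seed[wave])
                draws = gibbs_fit(data, mcmc)
                preds = cluster_predictions(draws, config.prediction_mode)
                est = district_prevalence(preds, wave=wave, sex=sex,
                                          outcome=outcome)
                npersons = table.groupby("district_id").size()
                est["n_persons"] = npersons.reindex(est["district_id"]).to_numpy()
                write_estimates(
                    out_dir / f"district_{cell_name}_w{wave}.csv", est)
                district_tables[(outcome, sex, wave)] = est
                cell_info["waves"][wave] = {
                    "exclusions": tally,
                    "n_analysed": wp.n,
                    "weighted_prevalence": wp.estimate,
                    "ci": [wp.ci_low, wp.ci_high],
                    "n_districts": len(est),
                }

            chg = compute_change(district_tables[(outcome, sex, 1)],
                                 district_tables[(outcome, sex, 2)])
            write_estimates(out_dir / f"change_{cell_name}.csv", chg)
            cell_info["bands"] = band_changes(chg)
            cell_info["quadrants"] = quadrant_analysis(
                district_tables[(outcome, sex, 1)].loc[
                    lambda d: d["district_id"].isin(chg["district_id"])], chg)
            manifest["cells"][cell_name] = cell_info
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for cell {cell_name}: {exc}") from exc

    # cross-outcome district correlation per sex and wave
    correlations = {}
    for sex in config.sexes:
        if {"hypertension", "diabetes"} <= set(config.outcomes):
            for wave in (1, 2):
                r, n = cross_outcome_correlation(
                    district_tables[("hypertension", sex, wave)],
                    district_tables[("diabetes", sex, wave)])
                correlations[f"{sex}_w{wave}"] = {"r": r, "n": n}
    manifest["cross_outcome_correlation"] = correlations

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
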