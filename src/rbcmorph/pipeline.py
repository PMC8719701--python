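"""End-to-end experiment runs: simulate -> segment -> measure -> compare.

A run is declared by a config mapping (YAML on disk) listing solution
conditions; each condition is simulated, segmented and measured with its own
deterministic seed substream derived from the root seed and the condition
name, so adding or removing a condition never perturbs the others.  A fixed
number of cells per condition (default 40, the study's sampling depth) is
randomly selected for the group comparison against a designated reference
condition.  Re-running with the same config and seed reproduces every CSV
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, morphometry, segmentation, simulate
from .io import (
    LabelVolume,
    Tomogram,
    records_to_frame,
    write_cell_table,
    write_label_volume,
    write_tomogram,
)
from .solutions import ConditionPreset, SolutionSpec, named_preset, preset_from_solution
from .stats import GroupComparison, compare_groups

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "default_config", "validate_config", "run_experiment", "load_config"]

#: morphometric parameters compared across groups by default
DEFAULT_PARAMETERS = [
    "volume_fl",
    "surface_area_um2",
    "sphericity",
    "long_axis_um",
    "short_axis_um",
    "aspect_ratio",
]

_PRESET_OVERRIDES = (
    "volume_mean_fl",
    "volume_sd_fl",
    "s_mean",
    "s_sd",
    "cell_ri_mean",
    "cell_ri_sd",
    "medium_ri",
    "noise_sd",
)


class ConfigError(ValueError):
    """The run configuration is structurally invalid."""


def default_config() -> dict:
    """Three-medium design: plasma (reference), PBS, AS; 40 cells compared."""
    return {
        "reference": "plasma",
        "n_select": 40,
        "voxel_size": 0.1,
        "supersample": 3,
        "parameters": list(DEFAULT_PARAMETERS),
        "conditions": [
            {"name": "plasma", "medium": "plasma", "n_cells": 44},
            {"name": "PBS", "medium": "PBS", "n_cells": 44},
            {"name": "AS", "medium": "AS", "n_cells": 44},
        ],
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def validate_config(config: dict) -> dict:
    """Schema-style validation; returns the config with defaults filled in."""
    cfg = dict(default_config(), **config)
    problems: list[str] = []
    if not isinstance(cfg.get("conditions"), list) or not cfg["conditions"]:
        problems.append("'conditions' must be a non-empty list")
    else:
        names = []
        for i, cond in enumerate(cfg["conditions"]):
            if not isinstance(cond, dict) or "name" not in cond:
                problems.append(f"condition #{i} must be a mapping with a 'name'")
                continue
            names.append(cond["name"])
            if ("medium" in cond) == ("solution" in cond):
                problems.append(
                    f"condition {cond['name']!r} needs exactly one of 'medium' or 'solution'"
                )
            if "solution" in cond and not isinstance(cond["solution"], dict):
                problems.append(f"condition {cond['name']!r}: 'solution' must be a mapping")
            n = cond.get("n_cells", cfg["n_select"])
            if not isinstance(n, int) or n < 1:
                problems.append(f"condition {cond['name']!r}: n_cells must be a positive int")
        if len(set(names)) != len(names):
            problems.append("condition names must be unique")
        if cfg.get("reference") is not None and cfg["reference"] not in names:
            problems.append(f"reference {cfg['reference']!r} is not a condition name")
    if not isinstance(cfg.get("n_select"), int) or cfg["n_select"] < 2:
        problems.append("'n_select' must be an integer >= 2")
    if not (isinstance(cfg.get("voxel_size"), (int, float)) and cfg["voxel_size"] > 0):
        problems.append("'voxel_size' must be a positive number")
    unknown = set(cfg["parameters"]) - set(DEFAULT_PARAMETERS)
    if unknown:
        problems.append(f"unknown parameters {sorted(unknown)}")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    return cfg


def _condition_seed(root_seed: int, name: str, stage: str) -> int:
    """Deterministic per-condition, per-stage substream seed (< 2^31)."""
    key = f"{root_seed}:{name}:{stage}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _build_preset(cond: dict) -> ConditionPreset:
    overrides = {k: cond[k] for k in _PRESET_OVERRIDES if k in cond}
    if "medium" in cond:
        return named_preset(cond["medium"], name=cond["name"], **overrides)
    sol = SolutionSpec(**cond["solution"])
    return preset_from_solution(
        cond["name"], sol, measured_osmolality=cond.get("measured_osmolality"), **overrides
    )


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_condition(
    cond: dict, cfg: dict, root_seed: int, outdir: Path
) -> tuple[pd.DataFrame, dict]:
    """Simulate, segment and measure one condition; returns the selected-cell
    frame and the manifest entry."""
    name = cond["name"]
    preset = _build_preset(cond)
    n_cells = cond.get("n_cells", cfg["n_select"])
    sim_seed = _condition_seed(root_seed, name, "simulate")
    sel_seed = _condition_seed(root_seed, name, "select")

    tomo, truth = simulate.simulate_field(
        preset, n_cells=n_cells, seed=sim_seed,
        voxel_size=cfg["voxel_size"], supersample=cfg["supersample"],
    )
    tomo_path = outdir / f"{name}_field.tif"
    write_tomogram(tomo, tomo_path)
    truth_path = outdir / f"{name}_truth.csv"
    simulate.ground_truth_frame(truth).to_csv(truth_path, index=False, float_format="%.8g")

    threshold = cond.get(
        "threshold",
        cfg.get("threshold")
        or segmentation.midpoint_threshold(preset.medium_ri, preset.cell_ri_mean),
    )
    logger.info("condition %s: threshold %.4f, seed %d", name, threshold, sim_seed)
    mask = segmentation.binarize(tomo, threshold)
    labels = segmentation.label_components(mask, tomo.voxel_size)
    labels = segmentation.filter_cells(
        labels,
        min_volume_fl=cfg.get("min_volume_fl", segmentation.DEFAULT_MIN_VOLUME_FL),
        max_volume_fl=cfg.get("max_volume_fl", segmentation.DEFAULT_MAX_VOLUME_FL),
        exclude_border=cfg.get("exclude_border", True),
    )
    labels_path = outdir / f"{name}_labels.tif"
    write_label_volume(labels, labels_path)

    records, errors = morphometry.measure_all(tomo, labels, threshold)
    table_path = outdir / f"{name}_cells.csv"
    write_cell_table(records, table_path)

    n_select = min(cfg["n_select"], len(records))
    if n_select < cfg["n_select"]:
        logger.warning(
            "condition %s: only %d cells available for selection of %d",
            name, len(records), cfg["n_select"],
        )
    selected = segmentation.select_random_cells(records, n_select, seed=sel_seed)
    sel_path = outdir / f"{name}_cells_selected.csv"
    write_cell_table(selected, sel_path)

    manifest = {
        "condition": name,
        "preset": {
            **{k: v for k, v in asdict(preset).items() if not isinstance(v, SolutionSpec)},
            "solution": str(preset.solution),
        },
        "n_cells_simulated": n_cells,
        "n_cells_measured": len(records),
        "n_cells_selected": n_select,
        "measurement_errors": [str(e) for e in errors],
        "threshold": threshold,
        "seeds": {"simulate": sim_seed, "select": sel_seed},
        "files": {
            p.name: _md5(p)
            for p in (tomo_path, truth_path, labels_path, table_path, sel_path)
        },
    }
    return records_to_frame(selected), manifest


def _comparison_frames(
    comparisons: dict[str, GroupComparison]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sum_rows, pair_rows = [], []
    for param, comp in comparisons.items():
        for s in comp.summaries:
            sum_rows.append(
                {
                    "parameter": param, "group": s.name, "n": s.n,
                    "mean": s.mean, "sd": s.sd,
                    "anova_F": comp.anova.F, "anova_p": comp.anova.p,
                    "df_between": comp.anova.df_between, "df_within": comp.anova.df_within,
                }
            )
        for (a, b), p in comp.pairwise_p.items():
            pair_rows.append(
                {
                    "parameter": param, "group_a": a, "group_b": b,
                    "p_adjusted": p, "stars": comp.stars[(a, b)],
                }
            )
    return pd.DataFrame(sum_rows), pd.DataFrame(pair_rows)


def _text_report(comparisons: dict[str, GroupComparison], reference: str | None) -> str:
    lines = ["Group comparison report", "======================", ""]
    for param, comp in comparisons.items():
        lines.append(f"{param}:")
        for s in comp.summaries:
            lines.append(f"  {s.name}: {s.mean:.2f} +/- {s.sd:.2f} (n={s.n})")
        a = comp.anova
        lines.append(
            f"  ANOVA: F({a.df_between}, {a.df_within}) = {a.F:.3f}, p = {a.p:.3g}"
        )
        for (ga, gb), p in comp.pairwise_p.items():
            star = comp.stars[(ga, gb)] or "ns"
            mark = " (vs reference)" if reference in (ga, gb) else ""
            lines.append(f"  {ga} vs {gb}: p_adj = {p:.3g} {star}{mark}")
        lines.append("")
    return "\n".join(lines)


def run_experiment(config: dict, seed: int, outdir: str | Path) -> dict:
    """Run the full design; returns comparisons, per-condition tables and paths."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    selected_by_condition: dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "package_version": __version__,
        "root_seed": seed,
        "config": cfg,
        "conditions": [],
    }
    failures: dict[str, str] = {}
    for cond in cfg["conditions"]:
        try:
            frame, entry = run_condition(cond, cfg, seed, outdir)
            selected_by_condition[cond["name"]] = frame
            manifest["conditions"].append(entry)
        except Exception as exc:
            logger.error("condition %s failed: %s", cond["name"], exc)
            failures[cond["name"]] = str(exc)
    manifest["failed_conditions"] = failures

    comparisons: dict[str, GroupComparison] = {}
    if len(selected_by_condition) >= 2:
        for param in cfg["parameters"]:
            values = {
                name: frame[param].to_numpy() for name, frame in selected_by_condition.items()
            }
            comparisons[param] = compare_groups(values, param)
        summary_df, pairwise_df = _comparison_frames(comparisons)
        summary_df.to_csv(outdir / "comparison_summary.csv", index=False, float_format="%.8g")
        pairwise_df.to_csv(outdir / "comparison_pairwise.csv", index=False, float_format="%.8g")
        (outdir / "report.txt").write_text(_text_report(comparisons, cfg.get("reference")))

    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return {
        "comparisons": comparisons,
        "selected": selected_by_condition,
        "manifest": manifest,
        "outdir": outdir,
    }
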