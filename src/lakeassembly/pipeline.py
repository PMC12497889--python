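"""End-to-end pipeline: simulate (or load) -> NCM -> null models ->
stability -> PLS-PM, with a validated config and a reproducible manifest.

One root seed fans out to per-stage seeds through a deterministic
counter, so any stage can be re-run in isolation with the same stream.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AbundanceMatrix,
    aggregate_samples,
    read_abundance,
    richness,
    write_abundance,
)
from .exceptions import ConfigError
from .ncm import fit_ncm
from .phylonull import assembly_analysis
from .plspm import bootstrap_paths, default_block_spec, fit_plspm, indirect_effects
from .simulate import LakeScenario, monthly_dates, simulate_lake_timeseries, write_tree
from .stability import stability_series, write_series

_SCHEMA = {
    "seed": None,
    "output_dir": None,
    "input": {"counts": None, "tree": None, "metadata": None, "format": None},
    "simulate": {
        "lakes": None,
        "months": None,
        "start_month": None,
        "n_months": None,
        "depths": None,
        "fractions": None,
        "n_taxa": None,
        "community_size": None,
        "turnover": None,
        "salinity_amplitude": None,
        "selection_sigma": None,
    },
    "ncm": {"enabled": None, "n_bootstrap": None},
    "nullmodels": {"enabled": None, "n_null": None, "group_by": None, "weighted": None},
    "stability": {"enabled": None, "method": None, "group_by": None, "time_key": None},
    "plspm": {"enabled": None, "n_bootstrap": None, "alpha": None},
}

_STAGE_IDS = {"simulate": 1, "ncm": 2, "nullmodels": 3, "stability": 4, "plspm": 5}


def stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(root_seed) % (2**31), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] >> 1)  # < 2^31


def validate_config(config: dict) -> dict:
    """Validate the config document, reporting all failures at once."""
    errors = []
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key, val in config.items():
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
            continue
        sub_schema = _SCHEMA[key]
        if isinstance(sub_schema, dict):
            if not isinstance(val, dict):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub in val:
                if sub not in sub_schema:
                    errors.append(f"unknown key {key}.{sub}")
    if "seed" not in config:
        errors.append("missing required key 'seed'")
    if "input" not in config and "simulate" not in config:
        errors.append("need either an 'input' or a 'simulate' section")
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def demo_config(output_dir: str = "runs/demo", seed: int = 1) -> dict:
    """A small two-lake scenario exercising every stage in minutes."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "simulate": {
            "lakes": [
                {"name": "GRD", "regime": "gradient", "trophic": "mesotrophic"},
                {"name": "STB", "regime": "stable", "trophic": "oligotrophic"},
            ],
            "start_month": "2021-05",
            "n_months": 8,
            "depths": 2,
            "fractions": ["PA", "FL"],
            "n_taxa": 120,
            "community_size": 4000,
            "turnover": 0.3,
        },
        "ncm": {"n_bootstrap": 300},
        "nullmodels": {"n_null": 199, "group_by": ["lake", "fraction"]},
        "stability": {"method": "braycurtis", "group_by": ["lake", "fraction"]},
        "plspm": {"n_bootstrap": 199, "alpha": 0.1},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rows(path: Path) -> int:
    with path.open() as fh:
        return sum(1 for _ in fh) - 1  # minus header


def run_pipeline(config: dict | str | Path, output_dir: str | None = None) -> dict:
    """Execute all enabled stages and write a run manifest.

    Returns the manifest dict (also written as ``manifest.json`` in the
    run directory, last).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    seed = int(config["seed"])
    out = Path(output_dir or config.get("output_dir", "runs/run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": config,
        "version": __version__,
        "seeds": {},
        "inputs": {},
        "stages": {},
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- inputs -------------------------------------------------------
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        if "simulate" in config:
            sim_seed = stage_seed(seed, "simulate")
            manifest["seeds"]["simulate"] = sim_seed
            sim = dict(config["simulate"])
            months = sim.pop("months", None) or monthly_dates(
                sim.pop("start_month", "2021-05"), int(sim.pop("n_months", 8))
            )
            sim.pop("start_month", None)
            sim.pop("n_months", None)
            scenario = LakeScenario(months=months, **sim)
            matrix, metadata, tree = simulate_lake_timeseries(
                scenario, seed=sim_seed, return_tree=True
            )
            write_abundance(matrix, inputs_dir / "counts.tsv")
            write_tree(tree, inputs_dir / "tree.nwk")
            metadata.to_csv(inputs_dir / "metadata.csv", index=False)
        else:
            import shutil

            from skbio import TreeNode

            inp = config["input"]
            matrix = read_abundance(inp["counts"], format=inp.get("format", "tsv"))
            tree = TreeNode.read(inp["tree"])
            metadata = pd.read_csv(inp["metadata"])
            for src, dst in [
                (inp["counts"], "counts.tsv"),
                (inp["tree"], "tree.nwk"),
                (inp["metadata"], "metadata.csv"),
            ]:
                shutil.copy(src, inputs_dir / dst)
        for f in sorted(inputs_dir.iterdir()):
            manifest["inputs"][f.name] = _sha256(f)

        md_indexed = metadata.set_index("sample_id")

        # --- NCM ----------------------------------------------------------
        ncm_cfg = config.get("ncm", {})
        if ncm_cfg.get("enabled", True):
            ncm_seed = stage_seed(seed, "ncm")
            manifest["seeds"]["ncm"] = ncm_seed
            ncm_dir = out / "ncm"
            ncm_dir.mkdir(exist_ok=True)
            fit = fit_ncm(
                matrix, n_bootstrap=int(ncm_cfg.get("n_bootstrap", 1000)), seed=ncm_seed
            )
            fit.write_summary(ncm_dir / "summary.json")
            fit.write_table(ncm_dir / "taxa.tsv")
            manifest["stages"]["ncm"] = {
                "outputs": {
                    "ncm/summary.json": None,
                    "ncm/taxa.tsv": _rows(ncm_dir / "taxa.tsv"),
                }
            }

        # --- null models --------------------------------------------------
        nm_cfg = config.get("nullmodels", {})
        if nm_cfg.get("enabled", True):
            nm_seed = stage_seed(seed, "nullmodels")
            manifest["seeds"]["nullmodels"] = nm_seed
            nm_dir = out / "nullmodels"
            nm_dir.mkdir(exist_ok=True)
            pairs, summary = assembly_analysis(
                matrix,
                tree,
                metadata,
                group_keys=nm_cfg.get("group_by", ["lake", "fraction"]),
                n_null=int(nm_cfg.get("n_null", 999)),
                seed=nm_seed,
                weighted=bool(nm_cfg.get("weighted", True)),
            )
            pairs.to_csv(nm_dir / "pairs.tsv", sep="\t", index=False)
            summary.to_csv(nm_dir / "summary.tsv", sep="\t", index=False)
            manifest["stages"]["nullmodels"] = {
                "n_null": int(nm_cfg.get("n_null", 999)),
                "outputs": {
                    "nullmodels/pairs.tsv": _rows(nm_dir / "pairs.tsv"),
                    "nullmodels/summary.tsv": _rows(nm_dir / "summary.tsv"),
                },
            }

        # --- stability ----------------------------------------------------
        st_cfg = config.get("stability", {})
        series = None
        if st_cfg.get("enabled", True):
            st_dir = out / "stability"
            st_dir.mkdir(exist_ok=True)
            series = stability_series(
                matrix,
                metadata,
                group_keys=st_cfg.get("group_by", ["lake", "fraction"]),
                time_key=st_cfg.get("time_key", "month"),
                method=st_cfg.get("method", "braycurtis"),
            )
            write_series(series, st_dir / "series.tsv", st_dir / "summary.json")
            manifest["stages"]["stability"] = {
                "outputs": {"stability/series.tsv": _rows(st_dir / "series.tsv")}
            }

        # --- PLS-PM -------------------------------------------------------
        pm_cfg = config.get("plspm", {})
        if pm_cfg.get("enabled", True) and series is not None:
            pm_seed = stage_seed(seed, "plspm")
            manifest["seeds"]["plspm"] = pm_seed
            pm_dir = out / "plspm"
            pm_dir.mkdir(exist_ok=True)
            group_by = st_cfg.get("group_by", ["lake", "fraction"])
            time_key = st_cfg.get("time_key", "month")
            data = _plspm_table(matrix, md_indexed.reset_index(), series, group_by, time_key)
            spec = default_block_spec()
            result = fit_plspm(data, spec)
            paths = bootstrap_paths(
                data,
                spec,
                n_boot=int(pm_cfg.get("n_bootstrap", 1000)),
                seed=pm_seed,
                alpha=float(pm_cfg.get("alpha", 0.1)),
            )
            effects = indirect_effects(result)
            paths.to_csv(pm_dir / "paths.tsv", sep="\t", index=False)
            effects.to_csv(pm_dir / "effects.tsv", sep="\t", index=False)
            with open(pm_dir / "summary.json", "w") as fh:
                json.dump(
                    {
                        "gof": result.gof,
                        "r_squared": result.r_squared,
                        "communalities": {f"{lv}:{mv}": v for (lv, mv), v in result.communalities.items()},
                        "n_rows": int(len(data)),
                    },
                    fh,
                    indent=2,
                )
            manifest["stages"]["plspm"] = {
                "outputs": {
                    "plspm/paths.tsv": _rows(pm_dir / "paths.tsv"),
                    "plspm/effects.tsv": _rows(pm_dir / "effects.tsv"),
                    "plspm/summary.json": None,
                }
            }

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plspm_table(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    series,
    group_by,
    time_key: str,
) -> pd.DataFrame:
    """One row per (group, time point): depth-averaged environment,
    richness of the depth-aggregated community, and the stability of the
    transition ending at that time point."""
    env_cols = [
        "salinity",
        "conductivity",
        "temperature",
        "DO",
        "pH",
        "fDOM",
        "turbidity",
        "NO3",
        "PO4",
        "NH3",
        "SO4",
        "DOC",
    ]
    keys = list(group_by) + [time_key]
    agg_counts = aggregate_samples(matrix, metadata, keys)
    env = metadata.groupby(keys)[env_cols].mean().reset_index()
    env["_id"] = env[keys].astype(str).agg("|".join, axis=1)
    env = env.set_index("_id")
    rows = []
    for i, sid in enumerate(agg_counts.sample_ids):
        group, t = sid.rsplit("|", 1)
        if group not in series or t not in series[group].times:
            continue
        pos = series[group].times.index(t)
        row = env.loc[sid, env_cols].to_dict()
        row["richness"] = richness(agg_counts.counts[i])
        row["stability"] = float(series[group].values[max(pos - 1, 0)])
        rows.append(row)
    return pd.DataFrame(rows)
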