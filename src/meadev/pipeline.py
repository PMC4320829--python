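"""End-to-end orchestration: recordings -> features -> stats -> ML -> report.

A run is driven by one plain-text (YAML) config with flat, auditable
key names mirroring the analysis constants::

    simulate:                 # either this or `inputs: [file.h5, ...]`
      regions: {CTX: 10, HPC: 10}
      ages: [7, 14, 21, 28]
      n_electrodes: 59
      duration: 900
    seed: 1
    analysis:
      max_begin_isi: 0.1
      max_end_isi: 0.25
      min_ibi: 0.8
      min_duration: 0.05
      min_spikes: 6
      bin_width: 0.003
      ns_threshold: 10
      sttc_dt: 0.005
      min_isi: 10
    stats: {family: pooled}
    ml: {method: tree_ensemble, n_repeats: 500, n_trees: 500}

Outputs (``features.csv``, ``comparison.csv``, ``pca_div*.csv``,
``classification.json``, ``table1.csv``) land in the output directory
together with ``manifest.json`` recording versions, seeds, the config
echo and the status of every stage; a failed stage preserves the
outputs produced so far.
"""

from __future__ import annotations

import json
import os
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import meadev
from meadev.bursts import BurstParams
from meadev.features import FEATURE_NAMES, AnalysisConfig, features_table
from meadev.group_stats import comparison_table
from meadev.ml import evaluate, impute_median, incremental_performance, pca_project
from meadev.spike_io import read_recording
from meadev.synthetic_data import simulate_recording

__all__ = ["load_config", "analysis_config_from_dict", "run", "rank_features", "build_table1"]

_BURST_KEYS = ("max_begin_isi", "max_end_isi", "min_ibi", "min_duration", "min_spikes")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def analysis_config_from_dict(d: dict | None) -> AnalysisConfig:
    d = dict(d or {})
    burst_kwargs = {k: d.pop(k) for k in _BURST_KEYS if k in d}
    kwargs = {}
    for key in ("ibi_mode", "merge_before_filter", "bin_width", "ns_threshold", "sttc_dt", "min_isi"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "theta_band" in d:
        kwargs["theta_band"] = tuple(d.pop("theta_band"))
    if d:
        raise ValueError(f"unknown analysis config keys: {sorted(d)}")
    return AnalysisConfig(burst_params=BurstParams(**burst_kwargs), **kwargs)


def _validate(cfg: dict) -> None:
    if ("inputs" in cfg) == ("simulate" in cfg):
        raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
    if "inputs" in cfg:
        missing = [p for p in cfg["inputs"] if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"input file(s) not found: {missing}")
    if ("simulate" in cfg or "ml" in cfg) and "seed" not in cfg:
        raise ValueError("a 'seed' is required when simulation or ML is requested")
    analysis_config_from_dict(cfg.get("analysis"))


def _load_recordings(cfg: dict) -> list:
    if "inputs" in cfg:
        return [read_recording(p) for p in cfg["inputs"]]
    sim = cfg["simulate"]
    regions = sim.get("regions", {"CTX": 10, "HPC": 10})
    ages = sim.get("ages", [7, 14, 21, 28])
    recs = []
    counter = 0
    for age in ages:
        for region, n in sorted(regions.items()):
            for i in range(int(n)):
                recs.append(
                    simulate_recording(
                        region,
                        int(age),
                        n_electrodes=sim.get("n_electrodes"),
                        duration=sim.get("duration"),
                        seed=int(cfg["seed"]) * 1_000_003 + counter,
                    )
                )
                counter += 1
    return recs


def rank_features(df: pd.DataFrame, n_repeats: int, seed: int, n_trees: int) -> tuple[list[str], dict[str, float]]:
    """Rank features by forest Gini importance averaged over ages.

    Per-age importances (each max-normalised) are averaged, then
    re-normalised so the top feature scores 1.  Returns the ranking and
    the score mapping.
    """
    X_all = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    scores = np.zeros(len(FEATURE_NAMES))
    n_ages = 0
    for age in sorted(df["age_div"].unique()):
        sub = df[df["age_div"] == age]
        y = sub["region"].to_numpy()
        if np.unique(y).size < 2:
            continue
        res = evaluate(
            sub[list(FEATURE_NAMES)].to_numpy(dtype=float),
            y,
            method="tree_ensemble",
            n_repeats=n_repeats,
            seed=seed,
            n_trees=n_trees,
            age_div=int(age),
        )
        scores += np.asarray([res.importance_scores[f] for f in FEATURE_NAMES])
        n_ages += 1
    if n_ages == 0:
        raise ValueError("no age group contains both classes")
    scores /= n_ages
    scores /= scores.max()
    order = np.argsort(-scores, kind="mergesort")
    ranking = [FEATURE_NAMES[i] for i in order]
    return ranking, {FEATURE_NAMES[i]: float(scores[i]) for i in order}


def build_table1(
    df: pd.DataFrame,
    n_repeats: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    method: str = "tree_ensemble",
) -> pd.DataFrame:
    """Importance-ranked incremental-accuracy matrix (features x ages).

    Row *i* holds the ranked feature, its importance score, and the
    mean percent-correct at each age using only the top-*i* features.
    """
    ranking, scores = rank_features(df, n_repeats=n_repeats, seed=seed, n_trees=n_trees)
    ages = sorted(df["age_div"].unique())
    cols: dict[str, list] = {"feature": ranking, "score": [scores[f] for f in ranking]}
    for age in ages:
        sub = df[df["age_div"] == age]
        y = sub["region"].to_numpy()
        if np.unique(y).size < 2:
            cols[f"div{age}"] = [np.nan] * len(ranking)
            continue
        inc = incremental_performance(
            sub[list(FEATURE_NAMES)].to_numpy(dtype=float),
            y,
            ranking,
            method=method,
            n_repeats=n_repeats,
            seed=seed,
            n_trees=n_trees,
            age_div=int(age),
        )
        cols[f"div{age}"] = list(inc["accuracy"])
    return pd.DataFrame(cols)


def run(cfg: dict, out_dir) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": meadev.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": cfg,
        "stages": {},
    }

    def _finish():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest

    acfg = analysis_config_from_dict(cfg.get("analysis"))
    try:
        recs = _load_recordings(cfg)
        df = features_table(recs, acfg)
        df.to_csv(out / "features.csv", index=False)
        manifest["stages"]["features"] = {"status": "ok", "n_recordings": len(df)}
    except Exception as exc:  # noqa: BLE001 - manifest records the failure point
        manifest["stages"]["features"] = {"status": "failed", "error": repr(exc)}
        return _finish()

    try:
        table = comparison_table(df, family=cfg.get("stats", {}).get("family", "pooled"))
        table.to_csv(out / "comparison.csv", index=False)
        manifest["stages"]["group_stats"] = {"status": "ok", "n_tests": int(table["p_raw"].notna().sum())}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["group_stats"] = {"status": "failed", "error": repr(exc)}

    try:
        for age in sorted(df["age_div"].unique()):
            sub = df[df["age_div"] == age]
            if len(sub) < 3:
                continue
            X = impute_median(sub[list(FEATURE_NAMES)].to_numpy(dtype=float))
            res = pca_project(X)
            pcs = pd.DataFrame(
                res.projections[:, : min(2, res.projections.shape[1])],
                columns=["pc1", "pc2"][: min(2, res.projections.shape[1])],
            )
            pcs["region"] = sub["region"].to_numpy()
            pcs["array_id"] = sub["array_id"].to_numpy()
            pcs.to_csv(out / f"pca_div{age}.csv", index=False)
        manifest["stages"]["pca"] = {"status": "ok"}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["pca"] = {"status": "failed", "error": repr(exc)}

    ml_cfg = cfg.get("ml", {})
    method = ml_cfg.get("method", "tree_ensemble")
    n_repeats = int(ml_cfg.get("n_repeats", 500))
    n_trees = int(ml_cfg.get("n_trees", 500))
    seed = int(cfg.get("seed", 0))
    try:
        results = []
        for age in sorted(df["age_div"].unique()):
            sub = df[df["age_div"] == age]
            y = sub["region"].to_numpy()
            if np.unique(y).size < 2:
                continue
            res = evaluate(
                sub[list(FEATURE_NAMES)].to_numpy(dtype=float),
                y,
                method=method,
                n_repeats=n_repeats,
                seed=seed,
                n_trees=n_trees,
                age_div=int(age),
            )
            results.append(res.to_dict())
        with open(out / "classification.json", "w") as fh:
            json.dump(results, fh, indent=2)
        manifest["stages"]["classification"] = {"status": "ok", "n_models": len(results)}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["classification"] = {"status": "failed", "error": repr(exc)}

    try:
        t1 = build_table1(df, n_repeats=n_repeats, seed=seed, n_trees=n_trees)
        t1.to_csv(out / "table1.csv", index=False)
        manifest["stages"]["table1"] = {"status": "ok"}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["table1"] = {"status": "failed", "error": repr(exc)}

    return _finish()
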