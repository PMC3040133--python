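"""Dataset/report IO, run configuration, and the end-to-end pipeline.

The dataset interchange format is a plain CSV with columns
``dose_pmol, ratio_mean, ratio_se, n_replicates`` (``ratio_se`` and
``n_replicates`` optional). Reports mirror the shape of a model-comparison
table: one row per model with its fit error, leave-one-out prediction
error, both normalized against the worst model, and the fitted parameters
printed to 3 significant figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossval import LOOResult, loo_prediction_error, normalize_pe
from .fitting import (
    DoseResponseDataset,
    FitOptions,
    FitResult,
    compare_models,
    fit_model,
)
from .models import MODEL_IDS, SharedRates, make_params
from .synth import NoiseModel, generate_dataset, standard_dose_grid

__all__ = [
    "read_dataset",
    "write_dataset",
    "format_report",
    "report_frame",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("rnaifit")

_REQUIRED_COLUMNS = ("dose_pmol", "ratio_mean")
_KNOWN_COLUMNS = ("dose_pmol", "ratio_mean", "ratio_se", "n_replicates")


def read_dataset(path, level: str = "mRNA", label: str | None = None) -> DoseResponseDataset:
    """Read a dose-response CSV into a validated dataset.

    A missing ``ratio_se`` column yields a dataset without standard errors
    (weighted fitting is then unavailable; a notice is logged). Malformed
    rows are rejected with their line number; duplicate doses are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    # +2: header line plus 1-based numbering.
    for idx, row in df.iterrows():
        line = idx + 2
        if pd.isna(row["dose_pmol"]) or pd.isna(row["ratio_mean"]):
            raise ValueError(f"{path}, line {line}: missing dose or ratio")
        if row["dose_pmol"] < 0:
            raise ValueError(f"{path}, line {line}: negative dose")
        if row["ratio_mean"] <= 0:
            raise ValueError(f"{path}, line {line}: nonpositive ratio_mean")
    if df["dose_pmol"].duplicated().any():
        dupes = df.loc[df["dose_pmol"].duplicated(), "dose_pmol"].tolist()
        raise ValueError(f"{path}: duplicate doses {dupes}")
    df = df.sort_values("dose_pmol").reset_index(drop=True)
    ses = None
    if "ratio_se" in df.columns and not df["ratio_se"].isna().all():
        ses = df["ratio_se"].to_numpy(dtype=float)
    else:
        log.info("%s: no ratio_se column; weighted fitting disabled", path)
    n_rep = None
    if "n_replicates" in df.columns and not df["n_replicates"].isna().all():
        n_rep = df["n_replicates"].to_numpy(dtype=int)
    return DoseResponseDataset(
        doses=df["dose_pmol"].to_numpy(dtype=float),
        ratio_means=df["ratio_mean"].to_numpy(dtype=float),
        ratio_ses=ses,
        n_replicates=n_rep,
        level=level,
        label=label if label is not None else path.stem,
    )


def write_dataset(dataset: DoseResponseDataset, path) -> Path:
    """Write a dataset to the standard CSV layout (full float precision)."""
    path = Path(path)
    cols = {
        "dose_pmol": dataset.doses,
        "ratio_mean": dataset.ratio_means,
    }
    if dataset.ratio_ses is not None:
        cols["ratio_se"] = dataset.ratio_ses
    if dataset.n_replicates is not None:
        cols["n_replicates"] = dataset.n_replicates
    # Default float repr is the shortest round-tripping form, so reading
    # the file back reproduces the dataset bit-for-bit.
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def _sig3(x: float) -> str:
    return f"{x:.3g}"


def report_frame(
    fits: list[FitResult], loos: list[LOOResult] | None = None
) -> pd.DataFrame:
    """Model-comparison table as a DataFrame, one row per model."""
    pe_by_model = {r.model: r for r in loos} if loos else {}
    rows = []
    for fit in sorted(fits, key=lambda f: f.model):
        loo = pe_by_model.get(fit.model)
        row = {
            "model": fit.model,
            "fit_error": fit.raw_error,
            "norm_fit_error": fit.normalized_error,
            "pred_error": loo.prediction_error if loo else np.nan,
            "norm_pred_error": (loo.normalized_pe if loo else np.nan),
            "parameters": "; ".join(
                f"{k}={_sig3(v)}" for k, v in fit.params_dict.items()
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(fits: list[FitResult], loos: list[LOOResult] | None = None) -> str:
    """Plain-text model-comparison report, numbers at 3 significant figures."""
    df = report_frame(fits, loos)
    lines = [
        f"{'model':<8} {'fit err':>9} {'norm':>6} {'pred err':>9} "
        f"{'norm PE':>8}  parameters"
    ]
    for _, r in df.iterrows():
        norm = _sig3(r["norm_fit_error"]) if pd.notna(r["norm_fit_error"]) else "-"
        pe = _sig3(r["pred_error"]) if pd.notna(r["pred_error"]) else "-"
        npe = _sig3(r["norm_pred_error"]) if pd.notna(r["norm_pred_error"]) else "-"
        lines.append(
            f"{r['model']:<8} {_sig3(r['fit_error']):>9} {norm:>6} "
            f"{pe:>9} {npe:>8}  {r['parameters']}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Run configuration

_TOP_KEYS = {"seed", "output_dir", "shared", "dataset", "generate", "fit",
             "crossval", "models"}
_SHARED_KEYS = {"km", "dm", "kT", "dp"}
_GENERATE_KEYS = {"model", "params", "cv", "n_replicates", "doses", "level",
                  "label"}
_FIT_KEYS = {"restarts", "weighted", "constrain_h_ge_1", "bounds", "maxiter",
             "popsize", "tol"}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def load_config(path) -> dict:
    """Load and schema-check a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    _reject_unknown(cfg, _TOP_KEYS, "top level")
    if ("dataset" in cfg) == ("generate" in cfg):
        raise ValueError("config must have exactly one of 'dataset'/'generate'")
    if "shared" in cfg:
        _reject_unknown(cfg["shared"], _SHARED_KEYS, "shared")
    if "generate" in cfg:
        gen = cfg["generate"]
        _reject_unknown(gen, _GENERATE_KEYS, "generate")
        for key in ("model", "params"):
            if key not in gen:
                raise ValueError(f"generate block requires {key!r}")
    if "fit" in cfg:
        _reject_unknown(cfg["fit"], _FIT_KEYS, "fit")


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Fit all (or selected) models to a dataset, normalize, optionally LOO.

    ``config`` follows the schema of :func:`validate_config`: a dataset is
    either read from ``dataset`` (a CSV path) or generated from the
    ``generate`` block; all four models are fitted, errors normalized
    against the worst, and, when ``crossval`` is true, leave-one-out
    prediction errors are computed and normalized too. Writes
    ``report.csv``, ``report.txt`` and ``run_log.txt`` (plus
    ``dataset.csv`` when generated) to the output directory and returns
    the in-memory results.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(output_dir or config.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    shared = SharedRates(**config.get("shared", {}))

    if "dataset" in config:
        dataset = read_dataset(config["dataset"])
        generated = False
    else:
        gen = config["generate"]
        params = make_params(gen["model"], **gen["params"])
        noise = NoiseModel(
            cv=float(gen.get("cv", 0.1)),
            n_replicates=int(gen.get("n_replicates", 3)),
        )
        doses = gen.get("doses", standard_dose_grid())
        dataset = generate_dataset(
            gen["model"], params, shared, doses=doses, noise=noise,
            seed=seed, level=gen.get("level", "mRNA"),
            label=gen.get("label", ""),
        )
        write_dataset(dataset, out / "dataset.csv")
        generated = True

    fit_cfg = dict(config.get("fit", {}))
    if dataset.ratio_ses is None and fit_cfg.get("weighted", True):
        log.info("dataset has no SEs: falling back to unweighted fitting")
        fit_cfg["weighted"] = False
    if "bounds" in fit_cfg:
        fit_cfg["bounds"] = {
            k: tuple(v) for k, v in fit_cfg["bounds"].items()
        }
    options = FitOptions(seed=seed, **fit_cfg)

    models = config.get("models", list(MODEL_IDS))
    fits = [fit_model(m, dataset, shared, options) for m in models]
    if sorted(models) == sorted(MODEL_IDS):
        fits = compare_models(fits)

    loos: list[LOOResult] | None = None
    if config.get("crossval", False):
        loos = [loo_prediction_error(m, dataset, shared, options) for m in models]
        if sorted(models) == sorted(MODEL_IDS):
            loos = normalize_pe(loos)

    frame = report_frame(fits, loos)
    frame.to_csv(out / "report.csv", index=False, float_format="%.6g")
    text = format_report(fits, loos)
    (out / "report.txt").write_text(text)
    log_lines = [
        f"seed: {seed}",
        f"dataset: {'generated' if generated else config['dataset']} "
        f"({len(dataset)} doses, level={dataset.level}, "
        f"label={dataset.label!r})",
        f"weighted: {options.weighted}",
        f"restarts: {options.restarts}",
        f"constrain_h_ge_1: {options.constrain_h_ge_1}",
        f"models: {list(models)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "dataset": dataset,
        "fits": fits,
        "loos": loos,
        "report": frame,
        "report_text": text,
        "output_dir": out,
    }
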