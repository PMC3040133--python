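"""Leave-one-out prediction error for knockdown-model selection.

A model with more parameters can fit better without generalizing better.
To guard against that, each dose point is held out in turn, the model is
refitted on the remainder, and the held-out point is predicted; the
prediction error (PE) is the average of the per-point squared errors
(SE-weighted when the fit is weighted). PEs are then normalized across
models against the largest, exactly as fit errors are.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import DoseResponseDataset, FitOptions, fit_model
from .models import MODEL_IDS, SharedRates, knockdown_ratio

__all__ = ["LOOResult", "loo_prediction_error", "normalize_pe"]


@dataclass(frozen=True)
class LOOResult:
    """Per-fold predictions and the averaged leave-one-out error."""

    model: str
    doses: np.ndarray
    predictions: np.ndarray  # NaN where the fold fit failed
    fold_errors: np.ndarray  # per-point (weighted) squared errors
    prediction_error: float
    normalized_pe: float | None = None
    weighted: bool = True
    failed_folds: tuple[int, ...] = ()


def loo_prediction_error(
    model: str,
    dataset: DoseResponseDataset,
    shared: SharedRates,
    options: FitOptions | None = None,
) -> LOOResult:
    """Leave-one-out prediction error of one model on a dataset.

    For fold ``i`` the parameters are refitted on every point except
    ``i`` (with seed ``options.seed + i`` so each fold is reproducible),
    and the prediction at the held-out dose is scored by its squared
    error term — divided by that point's SE when ``options.weighted``.
    The PE is the mean over folds. The zero-dose point is held out like
    any other. A fold whose fit fails is flagged and excluded from the
    average with a warning.
    """
    options = options or FitOptions()
    n = len(dataset)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 dose points")
    predictions = np.full(n, np.nan)
    fold_errors = np.full(n, np.nan)
    failed: list[int] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = dataset.subset(keep)
        fold_options = dataclasses.replace(options, seed=options.seed + i)
        try:
            fit = fit_model(model, train, shared, fold_options)
        except Exception as exc:  # noqa: BLE001 - fold failures are reported
            warnings.warn(
                f"LOO fold {i} ({model}, dose {dataset.doses[i]} pmol) "
                f"failed: {exc}",
                stacklevel=2,
            )
            failed.append(i)
            continue
        pred = float(knockdown_ratio(model, fit.params, shared, dataset.doses[i]))
        predictions[i] = pred
        resid = pred - dataset.ratio_means[i]
        if options.weighted:
            resid /= dataset.ratio_ses[i]
        fold_errors[i] = resid * resid
    ok = ~np.isnan(fold_errors)
    if not ok.any():
        raise RuntimeError(f"all LOO folds failed for {model}")
    return LOOResult(
        model=model,
        doses=dataset.doses.copy(),
        predictions=predictions,
        fold_errors=fold_errors,
        prediction_error=float(np.mean(fold_errors[ok])),
        weighted=options.weighted,
        failed_folds=tuple(failed),
    )


def normalize_pe(loos: list[LOOResult]) -> list[LOOResult]:
    """Normalize prediction errors across the four models against the max."""
    models = sorted(r.model for r in loos)
    if models != sorted(MODEL_IDS):
        raise ValueError(
            f"normalize_pe needs exactly one result per model, got {models}"
        )
    max_pe = max(r.prediction_error for r in loos)
    if max_pe == 0:
        return [dataclasses.replace(r, normalized_pe=1.0) for r in loos]
    return [
        dataclasses.replace(r, normalized_pe=r.prediction_error / max_pe)
        for r in loos
    ]
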