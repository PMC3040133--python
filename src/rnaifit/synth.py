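"""Synthetic dose-response data with the structure of siRNA titration assays.

Emulates the design of a transfection dose series: a 14-dose grid from 0 to
200 pmol in a 2 mL well, biological triplicates per dose, and ratio-valued
readouts (treated over negative control). Replicate noise is multiplicative
lognormal — knockdown ratios are positive, fold-change-like quantities, so
their scatter is naturally proportional rather than additive. Also provides
the unit conversions (pmol-to-molar, half-life-to-rate) the dose bookkeeping
needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import DoseResponseDataset
from .models import ModelParams, SharedRates, knockdown_ratio

__all__ = [
    "NoiseModel",
    "standard_dose_grid",
    "generate_dataset",
    "generate_replicates",
    "pmol_to_molar",
    "halflife_to_rate",
    "WELL_VOLUME_L",
]

#: Transfection-well medium volume (liters) used for dose-concentration
#: conversion: 200 pmol in 2 mL is 100 nM.
WELL_VOLUME_L = 2e-3


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal replicate noise.

    ``cv`` is the coefficient of variation of a single replicate ratio
    around its true value (0.1 by default, resembling triplicate qPCR
    scatter); ``n_replicates`` biological replicates are drawn per dose.
    """

    cv: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")


def standard_dose_grid() -> np.ndarray:
    """The 14-dose transfection grid, 0 to 200 pmol per 2 mL well."""
    return np.array(
        [0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0, 20.0, 40.0, 60.0,
         80.0, 100.0, 200.0]
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    # Mean-1 lognormal: sigma^2 = ln(1 + cv^2), mu = -sigma^2 / 2.
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def generate_replicates(
    model: str,
    params: ModelParams,
    shared: SharedRates,
    doses,
    noise: NoiseModel,
    seed: int,
) -> np.ndarray:
    """Replicate-level ratios, shape (n_doses, n_replicates).

    Each replicate is the model's true knockdown ratio at that dose times
    an independent mean-1 lognormal factor with coefficient of variation
    ``noise.cv``. With ``cv=0`` every replicate equals the true ratio.
    """
    doses = np.asarray(doses, dtype=float)
    true = np.atleast_1d(knockdown_ratio(model, params, shared, doses))
    rng = np.random.default_rng(seed)
    factors = _lognormal_factors(rng, noise.cv, (doses.size, noise.n_replicates))
    return true[:, None] * factors


def generate_dataset(
    model: str,
    params: ModelParams,
    shared: SharedRates,
    doses=None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    level: str = "mRNA",
    label: str = "",
) -> DoseResponseDataset:
    """Generate a mean/SE dose-response dataset from a knockdown model.

    Per dose, ``noise.n_replicates`` noisy replicate ratios are drawn and
    summarized as their mean and standard error (sample SD over sqrt(n)).
    Protein-level generation uses the same ratio law as mRNA: the
    translation gain kT/dp cancels from the treated/control ratio.
    """
    if doses is None:
        doses = standard_dose_grid()
    noise = noise or NoiseModel()
    doses = np.asarray(doses, dtype=float)
    reps = generate_replicates(model, params, shared, doses, noise, seed)
    means = reps.mean(axis=1)
    if noise.cv == 0 or noise.n_replicates == 1:
        # Identical replicates: exactly zero spread, no roundoff residue.
        ses = np.zeros(doses.size)
    else:
        ses = reps.std(axis=1, ddof=1) / math.sqrt(noise.n_replicates)
    if not label:
        label = f"synthetic-{model}-{level}"
    return DoseResponseDataset(
        doses=doses,
        ratio_means=means,
        ratio_ses=ses,
        n_replicates=np.full(doses.size, noise.n_replicates),
        level=level,
        label=label,
    )


def pmol_to_molar(amount_pmol, volume_l: float = WELL_VOLUME_L):
    """Convert a pmol amount in a given volume (liters) to molar.

    200 pmol in 2 mL gives 1e-7 M (100 nM); 0.1 pmol gives 5e-11 M (50 pM).
    """
    if volume_l <= 0:
        raise ValueError("volume_l must be positive")
    amount = np.asarray(amount_pmol, dtype=float)
    if np.any(amount < 0):
        raise ValueError("amount_pmol must be nonnegative")
    out = amount * 1e-12 / volume_l
    return out if np.ndim(out) else float(out)


def halflife_to_rate(t_half_min: float) -> float:
    """First-order rate constant ln(2)/t_half (min^-1) from a half-life."""
    if not t_half_min > 0:
        raise ValueError("t_half_min must be positive")
    return math.log(2) / t_half_min
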