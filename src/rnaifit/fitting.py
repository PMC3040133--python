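"""SE-weighted global fitting of knockdown models to dose-response data.

Each model's free parameters are estimated by minimizing the weighted sum
of squared residuals between predicted and measured knockdown ratios,

    E = sum_i ((r_model(dose_i) - r_data_i) / SE_i)^2,

with an unweighted variant (no SE division) for datasets whose standard
errors are unreliable. Minimization is a seeded, population-based global
search (differential evolution) over log-scaled rate parameters, restarted
several times with a final local polish; errors across the four models are
then normalized against the largest so the worst model scores 1.

The basal degradation rate dm is an input, never a fitted quantity, and
the transcription rate km cancels from every ratio (model 3 retains it
only inside the clustered parameter c3/km), so fitted dimensionality is
1 (model1), 2 (model2, model3) and 3 (model4).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .models import (
    MODEL_IDS,
    ModelParams,
    SharedRates,
    knockdown_ratio,
    make_params,
)

__all__ = [
    "DoseResponseDataset",
    "FitOptions",
    "FitResult",
    "weighted_sse",
    "fit_model",
    "predict",
    "compare_models",
    "SE_FLOOR",
]

#: Standard errors below this are treated as degenerate in weighted mode.
SE_FLOOR = 1e-6


@dataclass(frozen=True)
class DoseResponseDataset:
    """A dose-response table of mean knockdown ratios.

    Doses are pmol per well, strictly increasing and unique. ``ratio_ses``
    is ``None`` when standard errors are unavailable (only unweighted
    fitting is then possible). ``level`` records whether ratios are mRNA
    (qPCR) or protein (FACS) measurements; both obey the same ratio model.
    """

    doses: np.ndarray
    ratio_means: np.ndarray
    ratio_ses: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    level: str = "mRNA"
    label: str = ""

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        means = np.asarray(self.ratio_means, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "ratio_means", means)
        if doses.ndim != 1 or doses.size == 0:
            raise ValueError("doses must be a nonempty 1-D array")
        if means.shape != doses.shape:
            raise ValueError("ratio_means length must match doses")
        if np.any(doses < 0):
            raise ValueError("doses must be nonnegative")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing and unique")
        if np.any(means <= 0) or np.any(~np.isfinite(means)):
            raise ValueError("ratio_means must be positive and finite")
        if self.ratio_ses is not None:
            ses = np.asarray(self.ratio_ses, dtype=float)
            object.__setattr__(self, "ratio_ses", ses)
            if ses.shape != doses.shape:
                raise ValueError("ratio_ses length must match doses")
            if np.any(ses < 0) or np.any(~np.isfinite(ses)):
                raise ValueError("ratio_ses must be nonnegative and finite")
        if self.n_replicates is not None:
            n = np.asarray(self.n_replicates, dtype=int)
            object.__setattr__(self, "n_replicates", n)
            if n.shape != doses.shape:
                raise ValueError("n_replicates length must match doses")
            if np.any(n < 1):
                raise ValueError("n_replicates must be positive integers")
        if self.level not in ("mRNA", "protein"):
            raise ValueError("level must be 'mRNA' or 'protein'")

    def __len__(self) -> int:
        return int(self.doses.size)

    def subset(self, keep: np.ndarray) -> "DoseResponseDataset":
        """Dataset restricted to boolean/index mask ``keep`` (dose order kept)."""
        return DoseResponseDataset(
            doses=self.doses[keep],
            ratio_means=self.ratio_means[keep],
            ratio_ses=None if self.ratio_ses is None else self.ratio_ses[keep],
            n_replicates=(
                None if self.n_replicates is None else self.n_replicates[keep]
            ),
            level=self.level,
            label=self.label,
        )


# Search space per model: (name, scale, (low, high)). Rate-like constants
# are searched on a log10 scale over ranges bracketing plausible fitted
# values by at least two orders of magnitude; Hill exponents are searched
# linearly. c3/km is a concentration-like ratio, not a rate, and large
# values (the near-mass-action regime) are physically meaningful, so its
# range extends much higher.
_SEARCH_SPACE: dict[str, tuple[tuple[str, str, tuple[float, float]], ...]] = {
    "model1": (("k1", "log", (1e-8, 1e2)),),
    "model2": (("k2", "log", (1e-8, 1e2)), ("h2", "lin", (0.05, 10.0))),
    "model3": (("k3h3", "log", (1e-8, 1e2)), ("c3_over_km", "log", (1e-4, 1e8))),
    "model4": (
        ("d4", "log", (1e-8, 1e2)),
        ("theta4", "log", (1e-4, 1e3)),
        ("h4", "lin", (0.05, 10.0)),
    ),
}


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the global fit.

    ``bounds`` overrides per-parameter search bounds (natural scale);
    ``restarts`` independent differential-evolution runs are performed and
    the best polished result kept. ``constrain_h_ge_1`` restricts the
    cooperativity exponent h2 to [1, high] so it keeps its interpretation
    as a number of binding sites. ``weighted`` selects SE-weighted vs
    plain squared error.
    """

    seed: int = 0
    restarts: int = 10
    weighted: bool = True
    constrain_h_ge_1: bool = False
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    maxiter: int = 250
    popsize: int = 18
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < math.inf):
                raise ValueError(
                    f"bounds for {name!r} must be finite, positive and ordered"
                )


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and error for one model on one dataset."""

    model: str
    params: ModelParams
    raw_error: float
    normalized_error: float | None = None
    weighted: bool = True
    n_restarts: int = 1
    dataset_label: str = ""

    @property
    def params_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self.params)


def weighted_sse(model_ratios, dataset: DoseResponseDataset, weighted: bool = True):
    """Squared-error objective between predicted and observed ratios.

    Weighted mode divides each residual by the point's standard error;
    a zero or near-zero SE (below ``SE_FLOOR``) makes the weight infinite
    and is rejected with instructions to fit unweighted or floor the SEs.
    """
    model_ratios = np.asarray(model_ratios, dtype=float)
    if model_ratios.shape != dataset.doses.shape:
        raise ValueError("model_ratios length must match dataset")
    resid = model_ratios - dataset.ratio_means
    if weighted:
        if dataset.ratio_ses is None:
            raise ValueError(
                "dataset has no standard errors; fit with weighted=False"
            )
        if np.any(dataset.ratio_ses < SE_FLOOR):
            raise ValueError(
                f"standard errors below {SE_FLOOR} present; use weighted=False "
                "or raise the SEs to a sensible floor before fitting"
            )
        resid = resid / dataset.ratio_ses
    return float(np.sum(resid * resid))


def _search_space(model: str, options: FitOptions):
    space = []
    for name, scale, (lo, hi) in _SEARCH_SPACE[model]:
        lo, hi = options.bounds.get(name, (lo, hi))
        if model == "model2" and name == "h2" and options.constrain_h_ge_1:
            lo = max(lo, 1.0)
        space.append((name, scale, (lo, hi)))
    return space


def _decode(theta: np.ndarray, space) -> dict[str, float]:
    out = {}
    for value, (name, scale, _) in zip(theta, space):
        out[name] = 10.0**value if scale == "log" else float(value)
    return out


def _encode_bounds(space):
    return [
        (math.log10(lo), math.log10(hi)) if scale == "log" else (lo, hi)
        for _, scale, (lo, hi) in space
    ]


def fit_model(
    model: str,
    dataset: DoseResponseDataset,
    shared: SharedRates,
    options: FitOptions | None = None,
) -> FitResult:
    """Globally fit one model's parameters to a dose-response dataset.

    Runs ``options.restarts`` independently seeded differential-evolution
    searches in the (log-scaled) parameter space, polishes the best
    candidate with a bounded local minimizer, and returns the overall best.
    Deterministic for a fixed ``options.seed``.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model id {model!r}")
    options = options or FitOptions()
    if options.weighted and dataset.ratio_ses is None:
        raise ValueError(
            "dataset has no standard errors; pass FitOptions(weighted=False)"
        )
    space = _search_space(model, options)
    box = _encode_bounds(space)
    doses = dataset.doses

    def objective(theta: np.ndarray) -> float:
        values = _decode(theta, space)
        try:
            params = make_params(model, **values)
        except ValueError:
            return float("inf")
        ratios = knockdown_ratio(model, params, shared, doses)
        return weighted_sse(ratios, dataset, weighted=options.weighted)

    seeds = np.random.SeedSequence(options.seed).generate_state(options.restarts)
    best_theta, best_err = None, float("inf")
    for run_seed in seeds:
        res = differential_evolution(
            objective,
            bounds=box,
            seed=int(run_seed % (2**31 - 1)),
            maxiter=options.maxiter,
            popsize=options.popsize,
            tol=options.tol,
            polish=False,
        )
        if res.fun < best_err:
            best_theta, best_err = res.x, float(res.fun)
    if best_theta is None:  # pragma: no cover - DE always returns a point
        raise RuntimeError(f"no candidate found fitting {model}")

    polished = minimize(
        objective, best_theta, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    if polished.fun <= best_err and all(
        lo <= v <= hi for v, (lo, hi) in zip(polished.x, box)
    ):
        best_theta, best_err = polished.x, float(polished.fun)

    params = make_params(model, **_decode(best_theta, space))
    return FitResult(
        model=model,
        params=params,
        raw_error=best_err,
        weighted=options.weighted,
        n_restarts=options.restarts,
        dataset_label=dataset.label,
    )


def predict(fit: FitResult, shared: SharedRates, doses) -> np.ndarray:
    """Knockdown ratios predicted by a fit at the given doses."""
    return np.atleast_1d(knockdown_ratio(fit.model, fit.params, shared, doses))


def compare_models(fits: list[FitResult]) -> list[FitResult]:
    """Normalize fit errors across the four models against the largest.

    The worst-fitting model receives a normalized error of exactly 1;
    ordering follows the raw errors. Requires exactly one fit per model.
    """
    models = sorted(f.model for f in fits)
    if models != sorted(MODEL_IDS):
        raise ValueError(
            f"compare_models needs exactly one fit per model, got {models}"
        )
    max_err = max(f.raw_error for f in fits)
    if max_err == 0:
        # All models interpolate the data; every normalized error is 1.
        return [dataclasses.replace(f, normalized_error=1.0) for f in fits]
    return [
        dataclasses.replace(f, normalized_error=f.raw_error / max_err)
        for f in fits
    ]
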