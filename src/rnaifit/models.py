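"""Kinetic models of siRNA-mediated mRNA knockdown.

A transcript produced at rate ``km`` and degraded at basal rate ``dm`` is
subject to an extra, siRNA-dependent degradation flux ``delta(Xm, Xs)``:

    dXm/dt = km - dm*Xm - delta(Xm, Xs)
    dXp/dt = kT*Xm - dp*Xp

Four candidate laws for ``delta`` are implemented, each a different
mechanistic picture of how the siRNA-loaded RISC engages its target:

``model1``
    Stoichiometric mass action, ``delta = k1*Xs*Xm``. Each silencing event
    consumes the siRNA-RISC complex.
``model2``
    Mass action with cooperativity, ``delta = k2*Xs**h2*Xm``, allowing for
    multiple siRNA binding sites on one transcript.
``model3``
    Enzymatic (catalytic RISC) model,
    ``delta = c3*k3h3*Xs*Xm / (c3 + k3h3*Xm)``. At fixed siRNA level this
    is a Michaelis-Menten law in the mRNA substrate, with ``Vm = c3*Xs``
    and ``Km = c3/k3h3`` (see :func:`michaelis_menten_view`). The four
    mechanistic constants are only identifiable from dose-response ratios
    through the two clusters ``k3h3 = k3*h3`` and ``c3_over_km = c3/km``,
    so those clusters are the parameters.
``model4``
    Phenomenological Hill law in the siRNA dose,
    ``delta = d4*Xs**h4/(theta4**h4 + Xs**h4) * Xm``: the RNAi-driven
    degradation rate saturates at ``d4``, with half-saturation at dose
    ``theta4``.

Doses ``Xs`` are expressed in pmol per transfection well; mRNA and protein
levels are in arbitrary units. Every model predicts the *knockdown ratio*
(steady-state level in treated cells over the level in negative-control
cells), which is the quantity the fitting layer works with: it is 1 at zero
dose and decreases as the dose grows.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Union

import numpy as np

__all__ = [
    "MODEL_IDS",
    "SharedRates",
    "Model1Params",
    "Model2Params",
    "Model3Params",
    "Model4Params",
    "ModelParams",
    "params_class",
    "make_params",
    "delta_rate",
    "knockdown_ratio",
    "steady_state_mrna",
    "protein_steady_state",
    "michaelis_menten_view",
]

#: The four recognised model identifiers, in canonical order.
MODEL_IDS = ("model1", "model2", "model3", "model4")

#: Basal mRNA degradation rate for a 40-minute half-life, ln(2)/40 (min^-1).
DEFAULT_DM = 0.0173


def _require_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not np.isfinite(value) or value <= 0:
            raise ValueError(
                f"{type(obj).__name__}.{name} must be strictly positive and "
                f"finite, got {value!r}"
            )


@dataclass(frozen=True)
class SharedRates:
    """Non-RNAi kinetic constants shared by all four models.

    Parameters
    ----------
    km : float
        Transcription rate (a.u. min^-1). Cancels out of knockdown ratios,
        so it defaults to 1.
    dm : float
        Basal mRNA degradation rate (min^-1). Defaults to ln(2)/40, i.e. a
        40-minute transcript half-life.
    kT : float
        Translation rate (min^-1).
    dp : float
        Basal protein degradation rate (min^-1).
    """

    km: float = 1.0
    dm: float = DEFAULT_DM
    kT: float = 1.0
    dp: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(self, "km", "dm", "kT", "dp")

    @property
    def control_mrna(self) -> float:
        """Steady-state mRNA level of the negative control, km/dm."""
        return self.km / self.dm

    @property
    def control_protein(self) -> float:
        """Steady-state protein level of the negative control, (kT/dp)(km/dm)."""
        return self.kT / self.dp * self.km / self.dm


@dataclass(frozen=True)
class Model1Params:
    """Stoichiometric model: ``k1`` in (pmol min)^-1."""

    k1: float

    def __post_init__(self) -> None:
        _require_positive(self, "k1")


@dataclass(frozen=True)
class Model2Params:
    """Cooperative stoichiometric model.

    ``k2`` in (pmol^h2 min)^-1; ``h2`` is the cooperativity exponent
    (number of siRNA binding sites when >= 1).
    """

    k2: float
    h2: float

    def __post_init__(self) -> None:
        _require_positive(self, "k2", "h2")


@dataclass(frozen=True)
class Model3Params:
    """Enzymatic model in its clustered, ratio-identifiable parametrization.

    ``k3h3`` is the product of the per-site complex-formation rate and the
    number of sites, in (pmol min)^-1; ``c3_over_km`` is the cleavage/
    dissociation rate divided by the transcription rate (a.u.). The raw
    constants k3, h3, c3 never appear individually.
    """

    k3h3: float
    c3_over_km: float

    def __post_init__(self) -> None:
        _require_positive(self, "k3h3", "c3_over_km")


@dataclass(frozen=True)
class Model4Params:
    """Hill model: maximal RNAi degradation rate ``d4`` (min^-1),
    half-maximal dose ``theta4`` (pmol), Hill coefficient ``h4``."""

    d4: float
    theta4: float
    h4: float

    def __post_init__(self) -> None:
        _require_positive(self, "d4", "theta4", "h4")


ModelParams = Union[Model1Params, Model2Params, Model3Params, Model4Params]

_PARAM_CLASSES = {
    "model1": Model1Params,
    "model2": Model2Params,
    "model3": Model3Params,
    "model4": Model4Params,
}


def _check_model(model: str) -> str:
    if model not in _PARAM_CLASSES:
        raise ValueError(f"unknown model id {model!r}; expected one of {MODEL_IDS}")
    return model


def params_class(model: str) -> type:
    """Return the parameter dataclass for a model id."""
    return _PARAM_CLASSES[_check_model(model)]


def param_names(model: str) -> tuple[str, ...]:
    """Fitted-parameter names of a model, in declaration order."""
    return tuple(f.name for f in fields(params_class(model)))


def make_params(model: str, **values: float) -> ModelParams:
    """Build the parameter object for ``model`` from keyword values."""
    return params_class(model)(**values)


def _check_pairing(model: str, params: ModelParams) -> None:
    expected = params_class(model)
    if not isinstance(params, expected):
        raise TypeError(
            f"model {model!r} requires {expected.__name__}, "
            f"got {type(params).__name__}"
        )


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError(f"{name} must be nonnegative, got {value!r}")
    return arr


def delta_rate(model: str, params: ModelParams, xm, xs, shared: SharedRates):
    """RNAi-induced mRNA degradation rate delta(Xm, Xs) in a.u. min^-1.

    ``xm`` (a.u.) and ``xs`` (pmol) may be scalars or arrays; the result
    broadcasts. The rate is zero whenever either level is zero.
    """
    _check_model(model)
    _check_pairing(model, params)
    xm = _check_nonnegative("xm", xm)
    xs = _check_nonnegative("xs", xs)
    if model == "model1":
        out = params.k1 * xs * xm
    elif model == "model2":
        out = params.k2 * xs**params.h2 * xm
    elif model == "model3":
        c3 = params.c3_over_km * shared.km
        kh = params.k3h3
        out = c3 * kh * xs * xm / (c3 + kh * xm)
    else:  # model4
        t_h = params.theta4**params.h4
        xs_h = xs**params.h4
        out = params.d4 * xs_h / (t_h + xs_h) * xm
    return out if np.ndim(out) else float(out)


def knockdown_ratio(model: str, params: ModelParams, shared: SharedRates, xs):
    """Steady-state knockdown ratio, treated over negative control, in (0, 1].

    Dividing the steady-state mRNA level by the control level km/dm makes
    the ratio independent of km for models 1, 2 and 4; for model 3 the
    ratio depends on km only through the clustered parameter c3/km, so it
    too is computable from the fitted parameters and dm alone.
    """
    _check_model(model)
    _check_pairing(model, params)
    xs = _check_nonnegative("xs", xs)
    dm = shared.dm
    if model == "model1":
        out = dm / (dm + params.k1 * xs)
    elif model == "model2":
        out = dm / (dm + params.k2 * xs**params.h2)
    elif model == "model3":
        out = _model3_ratio(params, dm, xs)
    else:  # model4
        t_h = params.theta4**params.h4
        xs_h = xs**params.h4
        out = dm * (t_h + xs_h) / (t_h * dm + (params.d4 + dm) * xs_h)
    return out if np.ndim(out) else float(out)


def _model3_ratio(params: Model3Params, dm: float, xs: np.ndarray):
    # Positive root of the steady-state quadratic, scaled by dm/km.
    # With a = c3/km and kh = k3*h3, dividing the quadratic through by km
    # gives ratio = (-b + sqrt(b^2 + 4*a*kh*dm)) / (2*kh),
    # b = a*dm + a*kh*xs - kh. The b >= 0 branch is rewritten to avoid
    # catastrophic cancellation between -b and the square root.
    a = params.c3_over_km
    kh = params.k3h3
    b = a * dm + a * kh * xs - kh
    disc = np.sqrt(b * b + 4.0 * a * kh * dm)
    safe = np.where(b >= 0, 2.0 * a * dm / (b + disc), (disc - b) / (2.0 * kh))
    # At xs = 0 the discriminant is a perfect square and the root is km/dm
    # exactly; pin the ratio to 1 so rounding in sqrt cannot perturb it.
    return np.where(xs == 0, 1.0, safe)


def steady_state_mrna(model: str, params: ModelParams, shared: SharedRates, xs):
    """Unique positive mRNA equilibrium of km - dm*Xm - delta(Xm, Xs) = 0.

    At ``xs = 0`` every model returns the control level km/dm. The closed
    forms are exact; the residual of the balance equation is zero to
    rounding for every model, including the quadratic root of model 3.
    """
    ratio = knockdown_ratio(model, params, shared, xs)
    return shared.control_mrna * ratio


def protein_steady_state(shared: SharedRates, xm_eq):
    """Equilibrium protein level (kT/dp) * Xm for a given mRNA equilibrium.

    Because the same kT/dp gain applies to treated and control cells, the
    protein-level knockdown ratio equals the mRNA-level one.
    """
    xm_eq = _check_nonnegative("xm_eq", xm_eq)
    out = shared.kT / shared.dp * xm_eq
    return out if np.ndim(out) else float(out)


def michaelis_menten_view(params: Model3Params, shared: SharedRates, xs):
    """Michaelis-Menten constants (Vm, Km) of the enzymatic model at dose xs.

    At a fixed siRNA level the enzymatic degradation law is
    ``delta = Vm*Xm/(Km + Xm)`` with ``Vm = c3*Xs`` and ``Km = c3/k3h3``,
    where ``c3`` is un-clustered via ``c3 = (c3/km)*km``. Vm is in
    a.u. min^-1, Km in a.u.
    """
    if not isinstance(params, Model3Params):
        raise TypeError("michaelis_menten_view requires Model3Params")
    xs = _check_nonnegative("xs", xs)
    c3 = params.c3_over_km * shared.km
    vm = c3 * xs
    km_const = c3 / params.k3h3
    return (vm if np.ndim(vm) else float(vm), float(km_const))
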