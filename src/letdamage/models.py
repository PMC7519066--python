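"""Evaluation of the analytical yield-vs-LET functions and derived quantities.

Units are fixed at the API boundary: LET in keV/µm, yields in Gy⁻¹ Gbp⁻¹,
dose in Gy, genome size in Gbp.

Decreasing form (strand breakage, SSB)::

    Y(L) = p1 - (p2 L)^p3 - p4 / (1 + ln²(L / p5))

Increasing form (DSB, DSB clusters, DSB sites)::

    Y(L) = (p1 + (p2 L)^p3) / (1 + (p4 L)^p5)

The logarithm is the natural logarithm.  Omitted terms (``None`` parameters)
contribute 0 to the decreasing form and 1 to the denominator of the
increasing form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .ions import IonSpecies, get_ion
from .params import (
    Channel,
    DamageClass,
    DamageSpec,
    ModelForm,
    ParamDB,
    YieldModelParams,
)

__all__ = [
    "YieldValue",
    "ValidityWindow",
    "DEFAULT_VALIDITY",
    "eval_eq1",
    "eval_eq2",
    "evaluate",
    "low_let_limit",
    "peak_yield",
    "PeakResult",
    "yield_table",
    "rbe",
    "ReferencePolicy",
    "per_cell_yield",
    "GENOME_SIZE_GBP",
    "ADDITIVITY_CEILING_GY",
]

#: DNA content of the modelled cell nucleus.
GENOME_SIZE_GBP = 6.6

#: Lower edge of the dose range beyond which damage additivity may fail.
ADDITIVITY_CEILING_GY = 100.0


@dataclass(frozen=True)
class ValidityWindow:
    """LET window (keV/µm) inside which a fit may be trusted."""

    let_min: float
    let_max: float

    def __post_init__(self) -> None:
        if not (0 < self.let_min < self.let_max):
            raise ValueError(f"invalid window [{self.let_min}, {self.let_max}]")

    def contains(self, let: float) -> bool:
        return self.let_min <= let <= self.let_max


# Approximate spans of the fitted LET points per ion.  The published work
# warns against extrapolating but does not tabulate per-ion ranges, so these
# defaults gate a warning flag only, never an error.
DEFAULT_VALIDITY: dict[str, ValidityWindow] = {
    "H": ValidityWindow(0.2, 100.0),
    "He": ValidityWindow(0.2, 160.0),
    "Li": ValidityWindow(0.2, 220.0),
    "Be": ValidityWindow(0.2, 280.0),
    "B": ValidityWindow(0.2, 340.0),
    "C": ValidityWindow(0.2, 400.0),
    "N": ValidityWindow(0.2, 460.0),
    "O": ValidityWindow(0.2, 530.0),
    "Ne": ValidityWindow(0.2, 600.0),
}


def default_window(ion: IonSpecies | str) -> ValidityWindow:
    symbol = ion if isinstance(ion, str) else ion.symbol
    return DEFAULT_VALIDITY[get_ion(symbol).symbol]


@dataclass(frozen=True)
class YieldValue:
    """A model evaluation plus validity/clamping flags."""

    value: float
    in_validity_range: bool = True
    clamped: bool = False

    def __float__(self) -> float:
        return self.value


def _check_let(let: float) -> float:
    let = float(let)
    if not (let > 0) or not math.isfinite(let):
        raise ValueError(f"LET must be positive and finite, got {let}")
    return let


def _window_for(params: YieldModelParams, window: ValidityWindow | None) -> ValidityWindow | None:
    if window is not None:
        return window
    if params.spec is not None:
        return default_window(params.spec.ion)
    return None


def _wrap(
    raw: float, let: float, params: YieldModelParams, window: ValidityWindow | None, clamp: bool
) -> YieldValue:
    win = _window_for(params, window)
    in_range = True if win is None else win.contains(let)
    if clamp and raw < 0:
        return YieldValue(0.0, in_range, True)
    return YieldValue(raw, in_range, False)


def eq1_raw(p1: float, p2: float | None, p3: float | None, p4: float | None, p5: float | None, let: float) -> float:
    """Decreasing form without any policy wrapping."""
    value = p1
    if p2 is not None:
        value -= (p2 * let) ** p3
    if p4 is not None:
        value -= p4 / (1.0 + math.log(let / p5) ** 2)
    return value


def eq2_raw(p1: float, p2: float, p3: float, p4: float | None, p5: float | None, let: float) -> float:
    """Increasing form without any policy wrapping."""
    num = p1 + (p2 * let) ** p3
    if p4 is not None:
        return num / (1.0 + (p4 * let) ** p5)
    return num


def eval_eq1(
    params: YieldModelParams,
    let: float,
    *,
    window: ValidityWindow | None = None,
    clamp: bool = False,
) -> YieldValue:
    """Evaluate the decreasing (SB/SSB) form at one LET value.

    The raw formula can go negative far outside the fitted range; by default
    the raw value is returned with ``in_validity_range`` cleared rather than
    silently altered.  Pass ``clamp=True`` to floor at 0 (sets ``clamped``).
    """
    if params.form is not ModelForm.EQ1_DECREASE:
        raise ValueError(f"eval_eq1 requires the decreasing form, got {params.form.value}")
    let = _check_let(let)
    raw = eq1_raw(params.p1, params.p2, params.p3, params.p4, params.p5, let)
    return _wrap(raw, let, params, window, clamp)


def eval_eq2(
    params: YieldModelParams,
    let: float,
    *,
    window: ValidityWindow | None = None,
    clamp: bool = False,
) -> YieldValue:
    """Evaluate the increasing (DSB-family) form at one LET value."""
    if params.form is not ModelForm.EQ2_INCREASE:
        raise ValueError(f"eval_eq2 requires the increasing form, got {params.form.value}")
    let = _check_let(let)
    raw = eq2_raw(params.p1, params.p2, params.p3, params.p4, params.p5, let)
    return _wrap(raw, let, params, window, clamp)


def evaluate(
    params: YieldModelParams,
    let: float,
    *,
    window: ValidityWindow | None = None,
    clamp: bool = False,
) -> YieldValue:
    """Form-dispatching evaluation; ``let == 0`` returns the analytic limit p1."""
    if let == 0:
        win = _window_for(params, window)
        return YieldValue(params.p1, win is None or win.let_min <= 0, False)
    if params.form is ModelForm.EQ1_DECREASE:
        return eval_eq1(params, let, window=window, clamp=clamp)
    return eval_eq2(params, let, window=window, clamp=clamp)


def low_let_limit(params: YieldModelParams) -> float:
    """The LET→0 limit of either form, which is exactly p1."""
    return params.p1


@dataclass(frozen=True)
class PeakResult:
    let_at_peak: float
    value: float
    at_boundary: bool


def peak_yield(
    params: YieldModelParams,
    window: ValidityWindow,
    *,
    grid_points: int = 1000,
    xatol: float = 1e-6,
) -> PeakResult:
    """Maximum of the increasing form over a LET window.

    A log-spaced coarse grid locates the mode, then bounded scalar
    minimization refines it to ``xatol`` (relative, in log-LET).  Ties break
    to the lowest LET.  ``at_boundary`` is set when the maximum sits at a
    window edge (e.g. fits without an overkill term, which are monotone).
    """
    if params.form is not ModelForm.EQ2_INCREASE:
        raise ValueError("peak_yield requires the increasing form")
    lo, hi = window.let_min, window.let_max
    if not (hi > lo):
        raise ValueError("degenerate window")

    def f(log_l: float) -> float:
        return -eq2_raw(params.p1, params.p2, params.p3, params.p4, params.p5, math.exp(log_l))

    grid = np.linspace(math.log(lo), math.log(hi), grid_points)
    values = [-f(x) for x in grid]
    i_best = int(np.argmax(values))  # argmax takes the first (lowest-LET) tie
    i_lo, i_hi = max(i_best - 1, 0), min(i_best + 1, grid_points - 1)
    res = minimize_scalar(
        f, bounds=(grid[i_lo], grid[i_hi]), method="bounded", options={"xatol": xatol}
    )
    candidates = [(float(-res.fun), float(math.exp(res.x)))]
    candidates.append((values[0], lo))
    candidates.append((values[-1], hi))
    value, let_at = max(candidates, key=lambda t: (t[0], -t[1]))
    edge_tol = 1e-9 * (hi - lo)
    at_boundary = let_at <= lo + edge_tol or let_at >= hi - edge_tol
    return PeakResult(let_at, value, at_boundary)


def yield_table(
    db: ParamDB,
    specs: Sequence[DamageSpec],
    let_grid: Iterable[float],
    *,
    clamp: bool = False,
) -> pd.DataFrame:
    """Rectangular table of yields: one row per LET, one column per spec."""
    lets = [float(v) for v in let_grid]
    data = {}
    for spec in specs:
        params = db[spec]
        data[spec.label()] = [evaluate(params, l, clamp=clamp).value for l in lets]
    frame = pd.DataFrame(data, index=pd.Index(lets, name="let_kev_um"))
    return frame


@dataclass(frozen=True)
class ReferencePolicy:
    """Reference yield used as the RBE denominator.

    Default: the low-LET limit (p1) of the same (damage class, channel) for
    hydrogen.  Setting ``at_let`` evaluates the hydrogen model at that LET
    instead; setting ``ion`` changes the reference species.
    """

    ion: str = "H"
    at_let: float | None = None

    def reference_yield(self, db: ParamDB, damage_class: DamageClass, channel: Channel) -> float:
        params = db.get(self.ion, damage_class, channel)
        if self.at_let is None:
            return low_let_limit(params)
        return evaluate(params, self.at_let).value


def rbe(
    db: ParamDB,
    spec: DamageSpec,
    let: float,
    reference: ReferencePolicy | None = None,
) -> float:
    """Ratio of the yield at ``let`` to the reference yield (same dose)."""
    reference = reference or ReferencePolicy()
    ref = reference.reference_yield(db, spec.damage_class, spec.channel)
    if ref == 0:
        raise ZeroDivisionError("reference yield is zero")
    return evaluate(db[spec], let).value / ref


def per_cell_yield(
    yield_per_gy_gbp: float, dose_gy: float, genome_size_gbp: float = GENOME_SIZE_GBP
) -> float:
    """Expected damage count per cell: yield × dose × genome size.

    Linear in dose; the linearity assumption holds only up to doses of order
    100–1000 Gy, which callers should respect (see
    :data:`ADDITIVITY_CEILING_GY`).
    """
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if genome_size_gbp <= 0:
        raise ValueError("genome size must be positive")
    return yield_per_gy_gbp * dose_gy * genome_size_gbp
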