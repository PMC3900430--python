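"""Single-compartment membrane models for horizontal LPTCs.

Spiking cells (H1, H2, Hu) follow type-I Morris-Lecar dynamics; graded
cells (HS, CH) are passive leak compartments.  Each cell is a cylinder;
specific parameters (per cm²) are converted to absolute quantities via
the lateral membrane area.

Unit conventions used throughout the package
--------------------------------------------
voltage mV, time ms, current nA, capacitance nF, conductance µS.
With these units ``C dV/dt = I`` is dimensionally consistent
(nF·mV/ms = nA).  Specific parameters are given per cm² as is customary
(µF/cm², S/cm²) and are multiplied by the membrane area in ``cell_rhs``
and the integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MLParams",
    "CellParams",
    "CellState",
    "SPIKING_CLASSES",
    "GRADED_CLASSES",
    "membrane_area",
    "m_inf",
    "w_inf",
    "tau_w",
    "cell_rhs",
    "resting_state",
    "integrate_cell",
    "fi_curve",
]

SPIKING_CLASSES = ("H1", "H2", "Hu")
GRADED_CLASSES = ("HS", "CH")


@dataclass(frozen=True)
class MLParams:
    """Type-I Morris-Lecar channel parameters.

    Reversal potentials in mV, conductances specific (S/cm²), ``phi`` in
    1/ms.  ``e_leak_ml`` is the leak reversal used by spiking cells.
    """

    e_fast: float = 120.0
    g_fast: float = 0.004
    e_slow: float = -84.0
    g_slow: float = 0.008
    e_leak_ml: float = -60.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.4
    phi: float = 0.066

    def __post_init__(self) -> None:
        if self.g_fast < 0 or self.g_slow < 0:
            raise ValueError("channel conductances must be non-negative")
        if self.v2 <= 0 or self.v4 <= 0:
            raise ValueError("v2 and v4 must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass(frozen=True)
class CellParams:
    """Geometry plus passive (and optionally active) membrane parameters.

    ``length``/``diameter`` in µm, ``c_m`` in µF/cm², ``g_leak`` in S/cm²,
    ``e_leak`` in mV.  Spiking classes carry ``ml``; graded classes do not.
    """

    cell_class: str
    length: float
    diameter: float
    c_m: float
    e_leak: float
    g_leak: float
    ml: MLParams | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("cell geometry must be positive")
        if self.c_m <= 0 or self.g_leak <= 0:
            raise ValueError("c_m and g_leak must be positive")
        if self.cell_class in SPIKING_CLASSES and self.ml is None:
            raise ValueError(f"{self.cell_class} is a spiking class and needs MLParams")
        if self.cell_class in GRADED_CLASSES and self.ml is not None:
            raise ValueError(f"{self.cell_class} is graded; it must not carry MLParams")

    @property
    def is_spiking(self) -> bool:
        return self.ml is not None

    # --- absolute electrical quantities -------------------------------
    @property
    def area_cm2(self) -> float:
        return membrane_area(self)

    @property
    def c_abs(self) -> float:
        """Absolute capacitance, nF."""
        return self.c_m * self.area_cm2 * 1e3

    @property
    def g_leak_abs(self) -> float:
        """Absolute leak conductance, µS."""
        return self.g_leak * self.area_cm2 * 1e6

    @property
    def g_fast_abs(self) -> float:
        return (self.ml.g_fast if self.ml else 0.0) * self.area_cm2 * 1e6

    @property
    def g_slow_abs(self) -> float:
        return (self.ml.g_slow if self.ml else 0.0) * self.area_cm2 * 1e6

    @property
    def e_leak_eff(self) -> float:
        """Leak reversal actually used: ML leak for spiking cells."""
        return self.ml.e_leak_ml if self.ml is not None else self.e_leak

    def scaled_length(self, factor: float) -> "CellParams":
        """Morphology variant with length scaled by ``factor``."""
        return CellParams(
            self.cell_class, self.length * factor, self.diameter,
            self.c_m, self.e_leak, self.g_leak, self.ml,
        )


@dataclass
class CellState:
    """Membrane potential (mV) and slow-channel open fraction."""

    v: float
    w: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("w must lie in [0, 1]")


# Table of default cell parameters (one row per class).  Lengths/diameters
# in µm; C_m µF/cm²; E_leak mV (spiking classes use the ML leak); g_leak S/cm².
DEFAULT_CELL_TABLE: dict[str, CellParams] = {
    "H1": CellParams("H1", 1000.0, 5.0, 20.0, -60.0, 0.002, MLParams()),
    "H2": CellParams("H2", 200.0, 5.0, 20.0, -60.0, 0.002, MLParams()),
    "Hu": CellParams("Hu", 200.0, 5.0, 20.0, -60.0, 0.002, MLParams()),
    "HS": CellParams("HS", 250.0, 15.0, 1.0, -50.0, 0.001),
    "CH": CellParams("CH", 250.0, 15.0, 1.0, -50.0, 0.001),
}


def membrane_area(params: CellParams) -> float:
    """Lateral (cylinder) membrane area in cm²: π·d·L, µm² → cm²."""
    if params.length <= 0 or params.diameter <= 0:
        raise ValueError("non-positive geometry")
    return math.pi * params.diameter * params.length * 1e-8


def m_inf(v, ml: MLParams):
    """Equilibrium open fraction of the fast channel."""
    return 0.5 * (1.0 + np.tanh((v - ml.v1) / ml.v2))


def w_inf(v, ml: MLParams):
    """Equilibrium open fraction of the slow channel."""
    return 0.5 * (1.0 + np.tanh((v - ml.v3) / ml.v4))


def tau_w(v, ml: MLParams):
    """Activation time constant of the slow channel (ms); maximal at v3."""
    return 1.0 / (ml.phi * np.cosh((v - ml.v3) / (2.0 * ml.v4)))


def cell_rhs(state: CellState, params: CellParams, i_total: float) -> tuple[float, float]:
    """Time derivatives (dV/dt mV/ms, dw/dt 1/ms) for one compartment.

    ``i_total`` is the summed stimulus + synaptic current in nA.  Graded
    cells reduce to the passive membrane equation (dw/dt = 0).
    """
    v = state.v
    c = params.c_abs
    i_ion = -params.g_leak_abs * (v - params.e_leak_eff)
    if params.ml is None:
        return ((i_ion + i_total) / c, 0.0)
    ml = params.ml
    i_ion -= params.g_fast_abs * m_inf(v, ml) * (v - ml.e_fast)
    i_ion -= params.g_slow_abs * state.w * (v - ml.e_slow)
    dv = (i_ion + i_total) / c
    dw = (w_inf(v, ml) - state.w) / tau_w(v, ml)
    return (dv, dw)


def resting_state(params: CellParams, i_dc: float = 0.0) -> CellState:
    """Numerical resting state at constant current ``i_dc`` (nA).

    For spiking cells the slow variable is slaved to its equilibrium curve
    (w = w_inf(V)) and the root of the resulting scalar current balance is
    found by bisection; below rheobase this root is the stable rest.
    """
    if params.ml is None:
        v = params.e_leak + i_dc / params.g_leak_abs
        return CellState(v=v, w=0.0)
    ml = params.ml

    def balance(v: float) -> float:
        i = -params.g_fast_abs * m_inf(v, ml) * (v - ml.e_fast)
        i -= params.g_slow_abs * w_inf(v, ml) * (v - ml.e_slow)
        i -= params.g_leak_abs * (v - ml.e_leak_ml)
        return i + i_dc

    grid = np.linspace(-100.0, 50.0, 601)
    vals = [balance(v) for v in grid]
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            v0 = grid[k]
            break
        if vals[k] * vals[k + 1] < 0:
            v0 = brentq(balance, grid[k], grid[k + 1])
            break
    else:
        raise ValueError("no resting state found (current above rheobase?)")
    return CellState(v=float(v0), w=float(w_inf(v0, ml)))


def integrate_cell(
    params: CellParams,
    current_trace: np.ndarray,
    dt: float,
    v0: float | None = None,
    w0: float | None = None,
) -> np.ndarray:
    """Integrate a single isolated compartment with forward Euler.

    ``current_trace`` holds the injected current (nA) at each step.
    Returns the voltage trace (same length).  Initial conditions default
    to the I=0 resting state.  Aborts on non-finite state.
    """
    if dt > 0.05:
        raise ValueError("dt must be ≤ 0.05 ms for a converged solution")
    from . import _core

    trace = np.ascontiguousarray(current_trace, dtype=np.float64)
    if v0 is None or w0 is None:
        rest = resting_state(params)
        v0 = rest.v if v0 is None else v0
        w0 = rest.w if w0 is None else w0
    ml = params.ml if params.ml is not None else MLParams(g_fast=0.0, g_slow=0.0)
    v = _core.integrate_single(
        trace, dt, float(v0), float(w0),
        params.c_abs, params.g_leak_abs, params.e_leak_eff,
        params.g_fast_abs, ml.e_fast, params.g_slow_abs, ml.e_slow,
        ml.v1, ml.v2, ml.v3, ml.v4, ml.phi, params.ml is not None,
    )
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise FloatingPointError(
            f"state blow-up in {params.cell_class} at t={bad * dt:.3f} ms"
        )
    return v


def fi_curve(
    params: CellParams,
    current_values: Sequence[float],
    t_sim: float = 5000.0,
    t_discard: float = 1000.0,
    dt: float = 0.025,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> np.ndarray:
    """Steady-state firing rate (Hz) for each noise-free DC current (nA)."""
    from .spike_analysis import detect_spikes

    n_steps = int(round(t_sim / dt))
    rates = np.empty(len(current_values))
    for k, i_dc in enumerate(current_values):
        trace = np.full(n_steps, float(i_dc))
        v = integrate_cell(params, trace, dt)
        train = detect_spikes(v, dt, threshold=threshold, refractory=refractory)
        n = np.count_nonzero(train.times >= t_discard)
        rates[k] = n / ((t_sim - t_discard) / 1000.0)
    return rates
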