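"""Eight-unit rate-model reduction of the bilateral LPTC network.

Each hemisphere is collapsed to four units — H1, H2, Hu and a single
HS/CH unit standing in for the five electrically coupled graded cells —
evolving under the continuous-time state-space equation

    τ ẋ = −x + W·f(x) + G-diffusive coupling + ξ(t) + noise,

with f the same sigmoidal transfer function used for the graded
synapses of the detailed model.  W carries the chemical couplings
(HS/CH inhibits ipsilateral H1/H2, excites ipsilateral Hu; H1 excites
and Hu inhibits the contralateral HS/CH), and G carries the two midline
electrical couplings H2 ↔ contralateral HS/CH in diffusive form.

The model exists as a robustness check: with noise, the windowed
activities of the six spiking units feed the same population-PCA
pipeline as the conductance-based network and should reproduce its
component identities in the connected and disconnected cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .population_pca import RateMatrix

__all__ = [
    "UNIT_ORDER",
    "ReducedParams",
    "build_matrices",
    "input_vector",
    "stim_input",
    "reduced_rhs",
    "simulate_reduced",
    "reduced_rate_matrix",
]

UNIT_ORDER = ("H1L", "H2L", "HuL", "HSCHL", "H1R", "H2R", "HuR", "HSCHR")
_IDX = {name: i for i, name in enumerate(UNIT_ORDER)}
SPIKING_IDX = np.array([_IDX[c] for c in
                        ("H1L", "H2L", "HuL", "H1R", "H2R", "HuR")])

_STIM_TO_KIND_S = {"C": ("rotation", +1), "CC": ("rotation", -1),
                   "FB": ("translation", +1), "BF": ("translation", -1)}


@dataclass(frozen=True)
class ReducedParams:
    """Rate-model parameters (time in ms; weights dimensionless)."""

    tau: float = 10.0
    w_exc: float = 1.0
    w_inh: float = 1.0
    g_elec: float = 1.0
    i_max: float = 1.0
    theta: float = 0.5
    slope: float = 0.25
    noise_sigma: float = 0.3
    input_amp: float = 1.0
    s_switch_period: float = 2000.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.w_exc <= 0 or self.w_inh <= 0 or self.g_elec < 0:
            raise ValueError("need w_exc, w_inh > 0 and g_elec ≥ 0")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def build_matrices(params: ReducedParams) -> tuple[np.ndarray, np.ndarray]:
    """Chemical coupling matrix W and electrical coupling matrix G.

    W[post, pre] weights f(x_pre); G[i, j] = g means a diffusive term
    g·(x_j − x_i) into unit i (entered symmetrically).  Both are
    invariant under the L↔R permutation.
    """
    w = np.zeros((8, 8))
    g = np.zeros((8, 8))
    for side, other in (("L", "R"), ("R", "L")):
        hsch, h1, h2, hu = (_IDX[f"HSCH{side}"], _IDX[f"H1{side}"],
                            _IDX[f"H2{side}"], _IDX[f"Hu{side}"])
        w[h1, hsch] = -params.w_inh
        w[h2, hsch] = -params.w_inh
        w[hu, hsch] = +params.w_exc
        w[_IDX[f"HSCH{other}"], h1] = +params.w_exc
        w[_IDX[f"HSCH{other}"], hu] = -params.w_inh
        g[h2, _IDX[f"HSCH{other}"]] = params.g_elec
        g[_IDX[f"HSCH{other}"], h2] = params.g_elec
    return w, g


def input_vector(kind: str, s: int, amp: float = 1.0) -> np.ndarray:
    """Rotation / translation input pattern over the 8 units; ξ(−s) = −ξ(s).

    s=+1 gives clockwise rotation or forward (front-to-back) translation.
    """
    if s not in (+1, -1):
        raise ValueError("s must be ±1")
    if kind == "rotation":
        base = np.array([+1.0, +1.0, -1.0, -1.0, -1.0, -1.0, +1.0, +1.0])
    elif kind == "translation":
        base = np.array([-1.0, -1.0, +1.0, +1.0, -1.0, -1.0, +1.0, +1.0])
    else:
        raise ValueError("kind must be 'rotation' or 'translation'")
    return amp * s * base


def stim_input(stim_type: str, params: ReducedParams) -> np.ndarray:
    """Input vector for one of the four binocular stimuli."""
    kind, s = _STIM_TO_KIND_S[stim_type]
    return input_vector(kind, s, params.input_amp)


def _sigmoid(x: np.ndarray, params: ReducedParams) -> np.ndarray:
    return params.i_max / (1.0 + np.exp(-(x - params.theta) / params.slope))


def reduced_rhs(x: np.ndarray, params: ReducedParams, xi: np.ndarray,
                matrices: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """dx/dt of the noise-free rate model."""
    w, g = matrices if matrices is not None else build_matrices(params)
    diffusive = g @ x - g.sum(axis=1) * x
    return (-x + w @ _sigmoid(x, params) + diffusive + xi) / params.tau


@njit(cache=True)
def _run(x0, w, g, g_row, xi, noise, dt, tau, i_max, theta, slope):  # pragma: no cover - jit
    n_steps = xi.shape[0]
    n = x0.shape[0]
    out = np.empty((n_steps, n))
    x = x0.copy()
    x_new = np.empty(n)
    f = np.empty(n)
    for k in range(n_steps):
        for i in range(n):
            z = (x[i] - theta) / slope
            if z > 35.0:
                f[i] = i_max
            elif z < -35.0:
                f[i] = 0.0
            else:
                f[i] = i_max / (1.0 + np.exp(-z))
        for i in range(n):
            drive = -x[i] + xi[k, i] - g_row[i] * x[i]
            for j in range(n):
                drive += w[i, j] * f[j] + g[i, j] * x[j]
            x_new[i] = x[i] + dt * drive / tau + noise[k, i]
        for i in range(n):
            x[i] = x_new[i]
        out[k] = x
    return out


def simulate_reduced(
    params: ReducedParams,
    stim_type: str,
    duration: float,
    dt: float = 0.5,
    seed: int = 0,
    connected: bool = True,
    switching: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama trajectories; returns (times ms, states n_steps × 8).

    ``stim_type`` is one of C/CC/FB/BF (fixed s), or 'rotation' /
    'translation' with ``switching=True`` to flip s every
    ``s_switch_period``.  ``connected=False`` zeroes W and G.
    """
    n_steps = int(round(duration / dt))
    if switching:
        if stim_type not in ("rotation", "translation"):
            raise ValueError("switching mode needs 'rotation' or 'translation'")
        xi = np.empty((n_steps, 8))
        for k in range(n_steps):
            s = +1 if int(k * dt // params.s_switch_period) % 2 == 0 else -1
            xi[k] = input_vector(stim_type, s, params.input_amp)
    else:
        xi = np.tile(stim_input(stim_type, params), (n_steps, 1))
    w, g = build_matrices(params)
    if not connected:
        w = np.zeros_like(w)
        g = np.zeros_like(g)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, 8))
    noise *= params.noise_sigma * np.sqrt(dt) / params.tau
    x0 = np.zeros(8)
    states = _run(x0, w, g, g.sum(axis=1), xi, noise, dt, params.tau,
                  params.i_max, params.theta, params.slope)
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("reduced-model state diverged")
    return np.arange(1, n_steps + 1) * dt, states


def reduced_rate_matrix(states: np.ndarray, dt: float, window: float = 150.0,
                        label: str = "", t_discard: float = 0.0) -> RateMatrix:
    """Windowed means of the six spiking units' activities (PCA input)."""
    k0 = int(round(t_discard / dt))
    x = states[k0:, SPIKING_IDX]
    per = int(round(window / dt))
    n = x.shape[0] // per
    if n < 1:
        raise ValueError("duration shorter than one window")
    mat = x[: n * per].reshape(n, per, len(SPIKING_IDX)).mean(axis=1)
    return RateMatrix(mat, window, np.full(n, label))
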