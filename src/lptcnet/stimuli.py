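"""Surrogate binocular motion stimuli.

Motion input from the earlier neuropils is mimicked by a per-cell DC
current (depolarizing when the stimulus moves in the cell's preferred
direction, hyperpolarizing otherwise) plus independent white noise.
Four binocular stimuli are modelled: clockwise (C) and counterclockwise
(CC) yaw rotations (in-phase) and front-to-back (FB) / back-to-front
(BF) translations (out-of-phase), plus a `spontaneous` condition with
zero DC everywhere.

Noise convention: a realized trace sample is ``DC + σ·√(t_ref/dt)·η``
with η standard normal per integration step, so the effective noise
power is independent of the step size (Euler–Maruyama).  σ is the RMS
noise current on the reference window t_ref = NOISE_REF_MS; the
continuum white-noise intensity is D = σ²·t_ref/2.  The signal-to-noise
ratio is SNR = A_PD²/σ².  t_ref calibrates where a quoted SNR puts the
network; the default (0.1 ms) keeps firing rates within the type-I
Morris-Lecar ceiling while all four stimuli remain responsive (see the
methods note).  When a target SNR is given, each stimulated cell
receives its own σ = A_PD/√SNR, so a single SNR value puts every cell
at the same operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CellId

__all__ = [
    "STIM_TYPES",
    "DEFAULT_AMPLITUDES",
    "POLARITY_TABLE",
    "StimulusSpec",
    "polarity",
    "dc_for_cell",
    "realize",
    "snr",
    "noise_for_snr",
]

STIM_TYPES = ("C", "CC", "FB", "BF", "spontaneous")

# reference window (ms) on which noise_sigma is defined; see module docstring
NOISE_REF_MS = 0.1

# A_PD / A_ND in nA per cell class.  The printed H1 and H2 amplitudes
# correspond to the same membrane current density (63.7 µA/cm²); Hu has
# no printed row and defaults to that same density, which for its
# geometry (identical to H2's) is the H2 amplitude pair.
DEFAULT_AMPLITUDES: dict[str, tuple[float, float]] = {
    "H1": (10.0, -1.0),
    "H2": (2.0, -0.2),
    "Hu": (2.0, -0.2),
    "HS": (3.6, -1.3),
}

# (cell class, side) -> P/N per stimulus, columns (C, CC, FB, BF)
POLARITY_TABLE: dict[tuple[str, str], tuple[str, str, str, str]] = {
    ("H1", "L"): ("P", "N", "N", "P"),
    ("H2", "L"): ("P", "N", "N", "P"),
    ("Hu", "L"): ("N", "P", "P", "N"),
    ("HS", "L"): ("N", "P", "P", "N"),
    ("H1", "R"): ("N", "P", "N", "P"),
    ("H2", "R"): ("N", "P", "N", "P"),
    ("Hu", "R"): ("P", "N", "P", "N"),
    ("HS", "R"): ("P", "N", "P", "N"),
}
_COLS = {"C": 0, "CC": 1, "FB": 2, "BF": 3}


def polarity(cell: CellId, stim_type: str) -> str:
    """'P' or 'N' for a directly stimulated cell under one stimulus."""
    if cell.cell_class == "CH":
        raise ValueError("CH cells receive no direct motion input")
    if stim_type not in _COLS:
        raise ValueError(f"no polarity defined for stimulus {stim_type!r}")
    return POLARITY_TABLE[(cell.cell_class, cell.side)][_COLS[stim_type]]


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus condition realized as per-cell current traces.

    Exactly one of ``noise_sigma`` (common σ, nA·√ms) or ``target_snr``
    should be given; with ``target_snr`` each cell's σ is derived from
    its own A_PD.
    """

    stim_type: str
    duration: float  # ms
    dt: float = 0.025  # ms
    seed: int = 0
    amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    noise_sigma: float | None = None
    target_snr: float | None = None

    def __post_init__(self) -> None:
        if self.stim_type not in STIM_TYPES:
            raise ValueError(f"unknown stimulus type {self.stim_type!r}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.noise_sigma is not None and self.target_snr is not None:
            raise ValueError("give either noise_sigma or target_snr, not both")
        for cls, (a_pd, a_nd) in self.amplitudes.items():
            if not (a_pd > 0 > a_nd):
                raise ValueError(f"{cls}: need a_pd > 0 > a_nd")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def sigma_for(self, cell_class: str) -> float:
        """Noise σ (nA·√ms) for one cell class."""
        if cell_class == "CH":
            return 0.0
        if self.target_snr is not None:
            return noise_for_snr(self.amplitudes[cell_class][0], self.target_snr)
        return float(self.noise_sigma or 0.0)


def dc_for_cell(spec: StimulusSpec, cell: CellId) -> float:
    """DC current (nA) injected into one cell under the spec's stimulus."""
    if cell.cell_class == "CH" or spec.stim_type == "spontaneous":
        return 0.0
    a_pd, a_nd = spec.amplitudes[cell.cell_class]
    return a_pd if polarity(cell, spec.stim_type) == "P" else a_nd


def realize(spec: StimulusSpec, cells: list[CellId]) -> np.ndarray:
    """Per-cell current traces, shape (n_steps, n_cells), in nA.

    Noise streams are independent per cell, derived from the spec seed;
    CH traces are identically zero.
    """
    n_steps = spec.n_steps
    out = np.empty((n_steps, len(cells)), dtype=np.float64)
    scale = np.sqrt(NOISE_REF_MS / spec.dt)
    streams = np.random.SeedSequence(spec.seed).spawn(len(cells))
    for j, cell in enumerate(cells):
        dc = dc_for_cell(spec, cell)
        sig = spec.sigma_for(cell.cell_class)
        if sig > 0.0:
            rng = np.random.default_rng(streams[j])
            col = rng.standard_normal(n_steps)
            col *= sig * scale
            col += dc
            out[:, j] = col
        else:
            out[:, j] = dc
    return out


def snr(a_pd: float, noise_sigma: float) -> float:
    """Signal-to-noise ratio A_PD²/σ²."""
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    return (a_pd / noise_sigma) ** 2


def noise_for_snr(a_pd: float, target_snr: float) -> float:
    """σ (nA·√ms) realizing a target SNR for the given PD amplitude."""
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    return a_pd / np.sqrt(target_snr)
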