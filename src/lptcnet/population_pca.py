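"""Population coding analysis: PCA of windowed firing-rate vectors.

Six-dimensional firing-rate vectors (one entry per spiking cell, 150 ms
non-overlapping windows) are decomposed by PCA of either the correlation
or the covariance matrix.  The cluster-geometry helpers quantify the two
qualitative regimes: four stimulus clusters in four quadrants of the
PC1–PC2 plane (isolated cells — PCs code monocular motion), versus
cluster pairs aligned with the PC axes (connected network — PC1/PC2
code in-phase and out-of-phase motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_analysis import SpikeTrain

__all__ = [
    "SPIKING_ORDER",
    "RateMatrix",
    "PCAResult",
    "rate_vectors",
    "run_pca",
    "cluster_geometry",
    "component_identity",
    "contribution_gap",
]

SPIKING_ORDER = ("H1L", "H2L", "HuL", "H1R", "H2R", "HuR")

# stimulus pairs sharing one eye's motion (see POLARITY_TABLE):
# C & BF share the left hemifield, C & FB share the right hemifield.
_AXIS_CONTRASTS = {
    "in_phase": ({"C"}, {"CC"}),
    "out_of_phase": ({"FB"}, {"BF"}),
    "left_monocular": ({"C", "BF"}, {"CC", "FB"}),
    "right_monocular": ({"C", "FB"}, {"CC", "BF"}),
}


@dataclass(frozen=True)
class RateMatrix:
    """N windows × 6 spiking cells of firing rates (Hz) with row labels."""

    rates: np.ndarray
    window: float  # ms
    labels: np.ndarray  # stimulus type per row

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        if r.ndim != 2 or r.shape[1] != len(SPIKING_ORDER):
            raise ValueError("rate matrix must be N × 6")
        if len(self.labels) != r.shape[0]:
            raise ValueError("one label per row required")


@dataclass(frozen=True)
class PCAResult:
    components: np.ndarray  # (6, 6), rows orthonormal, ordered by eigenvalue
    eigenvalues: np.ndarray
    contribution_ratios: np.ndarray
    projections: np.ndarray  # N × 2 scores on PC1/PC2
    labels: np.ndarray
    mode: str


def rate_vectors(trains: dict[str, SpikeTrain], window: float = 150.0,
                 label: str = "") -> RateMatrix:
    """Windowed six-cell firing-rate vectors from one condition's trains."""
    durations = {trains[c].duration for c in SPIKING_ORDER}
    if len(durations) != 1:
        raise ValueError("trains must cover equal durations")
    duration = durations.pop()
    n = int(duration // window)
    if n < 1:
        raise ValueError("duration shorter than one window")
    edges = np.arange(n + 1) * window
    mat = np.empty((n, len(SPIKING_ORDER)))
    for j, cell in enumerate(SPIKING_ORDER):
        counts, _ = np.histogram(trains[cell].times, bins=edges)
        mat[:, j] = counts / (window / 1000.0)
    return RateMatrix(mat, window, np.full(n, label))


def stack(matrices: list[RateMatrix]) -> RateMatrix:
    """Concatenate per-condition rate matrices (same window)."""
    if len({m.window for m in matrices}) != 1:
        raise ValueError("windows differ")
    return RateMatrix(
        np.vstack([m.rates for m in matrices]),
        matrices[0].window,
        np.concatenate([m.labels for m in matrices]),
    )


def run_pca(matrix: RateMatrix, mode: str = "correlation") -> PCAResult:
    """Eigendecomposition of the second-moment matrix of centered rates.

    mode='correlation' standardizes each cell's rate first (the default);
    mode='covariance' uses raw centered rates.  Component sign is fixed
    so each component's largest-magnitude element is positive.  A cell
    with zero variance forces a covariance fallback (with a warning).
    """
    if mode not in ("correlation", "covariance"):
        raise ValueError("mode must be 'correlation' or 'covariance'")
    x = matrix.rates - matrix.rates.mean(axis=0)
    if matrix.rates.shape[0] < x.shape[1]:
        raise ValueError("need at least as many windows as cells")
    if mode == "correlation":
        sd = x.std(axis=0)
        if np.any(sd == 0):
            import warnings

            warnings.warn("zero-variance cell: falling back to covariance PCA")
            mode = "covariance"
        else:
            x = x / sd
    second_moment = (x.T @ x) / x.shape[0]
    evals, evecs = np.linalg.eigh(second_moment)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    comps = evecs[:, order].T
    for k in range(comps.shape[0]):  # deterministic sign convention
        if comps[k, np.argmax(np.abs(comps[k]))] < 0:
            comps[k] *= -1.0
    ratios = evals / evals.sum() if evals.sum() > 0 else np.full_like(evals, 1 / 6)
    scores = x @ comps[:2].T
    return PCAResult(comps, evals, ratios, scores, matrix.labels, mode)


def _centroids(result: PCAResult) -> dict[str, np.ndarray]:
    return {
        str(lab): result.projections[result.labels == lab].mean(axis=0)
        for lab in np.unique(result.labels)
    }


def _axis_angle(vec: np.ndarray) -> tuple[float, int]:
    """Angle (deg, in [0, 45]) to the nearest PC axis and that axis (0 or 1)."""
    ang = np.degrees(np.arctan2(abs(vec[1]), abs(vec[0])))  # [0, 90]
    return (ang, 0) if ang <= 45.0 else (90.0 - ang, 1)


def cluster_geometry(result: PCAResult) -> dict:
    """Quadrant separation of the four stimulus centroids and the angles
    of the C↔CC and FB↔BF centroid axes to the nearest PC axis."""
    cents = _centroids(result)
    if len(cents) < 2:
        raise ValueError("need at least two stimulus labels")
    out: dict = {}
    if all(s in cents for s in ("C", "CC", "FB", "BF")):
        quads = {
            (c[0] > 0, c[1] > 0)
            for s, c in cents.items() if s in ("C", "CC", "FB", "BF")
        }
        out["quadrant_separation"] = 1.0 if len(quads) == 4 else 0.0
    alignment = {}
    for pair, name in ((("C", "CC"), "in_phase"), (("FB", "BF"), "out_of_phase")):
        if pair[0] in cents and pair[1] in cents:
            axis = cents[pair[0]] - cents[pair[1]]
            if np.linalg.norm(axis) == 0:
                alignment[name] = float("nan")
            else:
                alignment[name] = _axis_angle(axis)[0]
    out["axis_alignment"] = alignment
    return out


def component_identity(result: PCAResult,
                       ambiguity_deg: float = 30.0) -> dict[str, str]:
    """Label PC1/PC2 by the stimulus-contrast axis each best aligns with.

    Candidate axes: in_phase (C−CC), out_of_phase (FB−BF),
    left/right_monocular (contrasts of the stimulus pairs sharing one
    eye's motion).  A PC further than ``ambiguity_deg`` from every axis
    is labelled 'mixed'.
    """
    cents = _centroids(result)
    axes: dict[str, np.ndarray] = {}
    for name, (plus, minus) in _AXIS_CONTRASTS.items():
        if plus | minus <= set(cents):
            a = np.mean([cents[s] for s in plus], axis=0)
            b = np.mean([cents[s] for s in minus], axis=0)
            v = a - b
            if np.linalg.norm(v) > 0:
                axes[name] = v / np.linalg.norm(v)
    assignment: dict[str, str] = {}
    for pc_idx, pc_name in ((0, "PC1"), (1, "PC2")):
        e = np.zeros(2)
        e[pc_idx] = 1.0
        best, best_ang = "mixed", ambiguity_deg
        for name, v in axes.items():
            ang = np.degrees(np.arccos(np.clip(abs(float(v @ e)), 0.0, 1.0)))
            if ang < best_ang:
                best, best_ang = name, ang
        assignment[pc_name] = best
    return assignment


def contribution_gap(result: PCAResult) -> float:
    """Contribution ratio of PC1 minus that of PC2."""
    return float(result.contribution_ratios[0] - result.contribution_ratios[1])
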