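"""The 16-cell bilateral horizontal-LPTC network.

Each hemisphere holds eight cells — spiking H1, H2, Hu and graded HSN,
HSE, HSS, dCH, vCH — mutually coupled by three synapse types:

* electrical (gap junctions): ohmic, conserving, 40 nS everywhere by
  default, including the two midline couplings H2 ↔ contralateral HSE;
* spike-triggered chemical synapses: single-exponential conductance
  (τ = 0.3 ms), reversal 0 mV (excitatory) / −70 mV (inhibitory);
* graded chemical synapses: sigmoidal current of the presynaptic
  graded potential (CH → ipsilateral H1/H2 inhibition, HS → ipsilateral
  Hu excitation).

Spiking cells project across the midline onto the contralateral HSE and
vCH: H1 excites cells preferring the same global rotation sense, Hu
(whose rotation preference is opposite) inhibits them, so that in-phase
(rotational) stimuli drive the network cooperatively while out-of-phase
(translational) stimuli frustrate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .cells import CellParams, DEFAULT_CELL_TABLE, resting_state

__all__ = [
    "CellId",
    "SynapseSpec",
    "NetworkSpec",
    "SimResult",
    "CELL_NAMES",
    "SPIKING_NAMES",
    "default_topology",
    "gap_current",
    "chem_spike_conductance",
    "chem_spike_current",
    "graded_current",
    "psp_amplitude",
    "calibrate_weight",
    "simulate",
    "ablate",
    "set_gap_conductance",
]

CELL_NAMES = ("H1", "H2", "Hu", "HSN", "HSE", "HSS", "dCH", "vCH")
SPIKING_NAMES = ("H1", "H2", "Hu")
SIDES = ("L", "R")

_NAME_TO_CLASS = {
    "H1": "H1", "H2": "H2", "Hu": "Hu",
    "HSN": "HS", "HSE": "HS", "HSS": "HS",
    "dCH": "CH", "vCH": "CH",
}


@dataclass(frozen=True)
class CellId:
    name: str
    side: str

    def __post_init__(self) -> None:
        if self.name not in CELL_NAMES:
            raise ValueError(f"unknown cell name {self.name!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def cell_class(self) -> str:
        return _NAME_TO_CLASS[self.name]

    @property
    def is_spiking(self) -> bool:
        return self.name in SPIKING_NAMES

    @property
    def label(self) -> str:
        return f"{self.name}{self.side}"

    def mirrored(self) -> "CellId":
        return CellId(self.name, "R" if self.side == "L" else "L")


def _cid(label: str) -> CellId:
    """Parse 'H1L'-style labels."""
    return CellId(label[:-1], label[-1])


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse.  Conductances in nS, currents in nA, potentials in mV."""

    kind: str  # electrical | chemical_spike | chemical_graded
    pre: CellId
    post: CellId
    sign: str | None = None  # excitatory | inhibitory (chemical only)
    g_gap: float | None = None  # nS (electrical); symmetric coupling
    weight: float | None = None  # nS (chemical_spike)
    tau_syn: float | None = None  # ms (chemical_spike)
    e_rev: float | None = None  # mV (chemical_spike)
    i_max: float | None = None  # nA (chemical_graded)
    theta: float | None = None  # mV (chemical_graded)
    slope: float | None = None  # mV (chemical_graded)

    def __post_init__(self) -> None:
        if self.kind not in ("electrical", "chemical_spike", "chemical_graded"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.kind == "electrical" and (self.g_gap is None or self.g_gap < 0):
            raise ValueError("electrical synapse needs g_gap ≥ 0")
        if self.kind != "electrical" and self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("chemical synapse needs a sign")
        if self.kind == "chemical_spike" and (self.tau_syn is None or self.tau_syn <= 0):
            raise ValueError("chemical_spike needs tau_syn > 0")
        if self.kind == "chemical_graded" and (self.slope is None or self.slope <= 0):
            raise ValueError("chemical_graded needs slope > 0")

    @property
    def is_midline(self) -> bool:
        return self.pre.side != self.post.side

    def mirrored(self) -> "SynapseSpec":
        return replace(self, pre=self.pre.mirrored(), post=self.post.mirrored())


@dataclass
class NetworkSpec:
    cells: list[tuple[CellId, CellParams]]
    synapses: list[SynapseSpec]
    connected: bool = True

    @property
    def cell_ids(self) -> list[CellId]:
        return [cid for cid, _ in self.cells]

    @property
    def labels(self) -> list[str]:
        return [cid.label for cid in self.cell_ids]

    def index(self, cell: CellId | str) -> int:
        if isinstance(cell, str):
            cell = _cid(cell)
        return self.cell_ids.index(cell)

    def scaled_length(self, factor: float) -> "NetworkSpec":
        cells = [(cid, p.scaled_length(factor)) for cid, p in self.cells]
        return NetworkSpec(cells, list(self.synapses), self.connected)


def _roster(cell_table: dict[str, CellParams]) -> list[tuple[CellId, CellParams]]:
    return [
        (CellId(name, side), cell_table[_NAME_TO_CLASS[name]])
        for side in SIDES
        for name in CELL_NAMES
    ]


def gap_current(v_i: float, v_j: float, g_gap: float) -> tuple[float, float]:
    """Currents (nA) into cells i and j from a g_gap (nS) gap junction."""
    if g_gap < 0:
        raise ValueError("g_gap must be non-negative")
    i_into_i = g_gap * 1e-3 * (v_j - v_i)
    return (i_into_i, -i_into_i)


def chem_spike_conductance(spike_times: Sequence[float], t: float,
                           weight: float, tau_syn: float) -> float:
    """Synaptic conductance (nS) at time t: each spike adds `weight`, then decays."""
    if tau_syn <= 0:
        raise ValueError("tau_syn must be positive")
    ts = np.asarray(spike_times, dtype=float)
    dt = t - ts[ts <= t]
    return float(weight * np.exp(-dt / tau_syn).sum())


def chem_spike_current(g: float, v_post: float, e_rev: float) -> float:
    """Postsynaptic current (nA) of a g (nS) conductance at v_post."""
    return g * 1e-3 * (e_rev - v_post)


def graded_current(v_pre: float, i_max: float, theta: float, slope: float,
                   sign: str = "excitatory") -> float:
    """Sigmoidal graded-synapse current (nA); inhibitory is the negative."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    x = (v_pre - theta) / slope
    if x > 35.0:
        s = 1.0
    elif x < -35.0:
        s = 0.0
    else:
        s = 1.0 / (1.0 + math.exp(-x))
    i = i_max * s
    return i if sign == "excitatory" else -i


def psp_amplitude(post: CellParams, weight: float, e_rev: float,
                  tau_syn: float = 0.3, dt: float = 0.005,
                  t_max: float = 20.0) -> float:
    """Peak |deflection| (mV) of an isolated cell at rest after one spike.

    Direct Euler integration of the postsynaptic membrane with an
    exponentially decaying conductance of initial value ``weight`` (nS).
    """
    rest = resting_state(post)
    v, w = rest.v, rest.w
    c = post.c_abs
    g0 = weight * 1e-3  # µS
    decay = math.exp(-dt / tau_syn)
    peak = 0.0
    g = g0
    ml = post.ml
    for _ in range(int(t_max / dt)):
        i = g * (e_rev - v) - post.g_leak_abs * (v - post.e_leak_eff)
        if ml is not None:
            i -= post.g_fast_abs * 0.5 * (1 + math.tanh((v - ml.v1) / ml.v2)) * (v - ml.e_fast)
            i -= post.g_slow_abs * w * (v - ml.e_slow)
            winf = 0.5 * (1 + math.tanh((v - ml.v3) / ml.v4))
            lam = ml.phi * math.cosh((v - ml.v3) / (2 * ml.v4))
            w += dt * lam * (winf - w)
        v += dt * i / c
        g *= decay
        peak = max(peak, abs(v - rest.v))
    return peak


def calibrate_weight(post: CellParams, e_rev: float, tau_syn: float = 0.3,
                     target_mv: float = 1.0) -> float:
    """Weight (nS) giving a single-spike PSP of ``target_mv`` at rest."""
    w = 1.0
    for _ in range(3):
        amp = psp_amplitude(post, w, e_rev, tau_syn)
        if abs(amp - target_mv) <= 0.005 * target_mv:
            break
        w *= target_mv / amp
    return w


# defaults shared by default_topology; all editable through the config layer
GAP_NS = 40.0
TAU_SYN_MS = 0.3
E_REV_EXC = 0.0
E_REV_INH = -70.0
GRADED_I_MAX = 0.5   # nA
GRADED_THETA = -40.0  # mV
GRADED_SLOPE = 5.0   # mV
PSP_TARGET_MV = 1.0
# literal conductances as printed; available via calibrate_psp=None
LITERAL_W_EXC_NS = 0.01
LITERAL_W_INH_NS = 0.005

# gap-junction pairs among the five graded cells of one hemisphere: a
# dorsoventral chain, so HSE's neighbours are the co-stimulated HSN/HSS
# and its driven potential is not diluted by the unstimulated CH cells
_INTRA_GAP_PAIRS = (("dCH", "HSN"), ("HSN", "HSE"),
                    ("HSE", "HSS"), ("HSS", "vCH"))


def default_topology(
    cell_table: dict[str, CellParams] | None = None,
    g_gap: float = GAP_NS,
    calibrate_psp: float | None = PSP_TARGET_MV,
    graded_i_max: float = GRADED_I_MAX,
    graded_theta: float = GRADED_THETA,
    graded_slope: float = GRADED_SLOPE,
) -> NetworkSpec:
    """Default 16-cell bilateral network (mirror-symmetric).

    ``calibrate_psp`` sets the single-spike PSP target (mV) used to scale
    the spike-chemical weights; pass None to use the literal printed
    conductances (0.01 / 0.005 nS) instead.
    """
    table = dict(cell_table or DEFAULT_CELL_TABLE)
    if calibrate_psp is not None:
        w_exc = calibrate_weight(table["HS"], E_REV_EXC, TAU_SYN_MS, calibrate_psp)
        w_inh = calibrate_weight(table["HS"], E_REV_INH, TAU_SYN_MS, calibrate_psp)
    else:
        w_exc, w_inh = LITERAL_W_EXC_NS, LITERAL_W_INH_NS

    synapses: list[SynapseSpec] = []
    for side, other in (("L", "R"), ("R", "L")):
        # gap junctions among the graded cells
        for a, b in _INTRA_GAP_PAIRS:
            synapses.append(SynapseSpec(
                "electrical", CellId(a, side), CellId(b, side), g_gap=g_gap))
        # CH → ipsilateral H1, H2 graded inhibition (vCH, the CH cell
        # receiving the contralateral projections, carries the link)
        for tgt in ("H1", "H2"):
            synapses.append(SynapseSpec(
                "chemical_graded", CellId("vCH", side), CellId(tgt, side),
                sign="inhibitory", i_max=graded_i_max,
                theta=graded_theta, slope=graded_slope))
        # HS → ipsilateral Hu graded excitation
        synapses.append(SynapseSpec(
            "chemical_graded", CellId("HSE", side), CellId("Hu", side),
            sign="excitatory", i_max=graded_i_max,
            theta=graded_theta, slope=graded_slope))
        # midline gap junction H2 ↔ contralateral HSE
        if side == "L":  # declared once; current flows both ways
            for s, o in (("L", "R"), ("R", "L")):
                synapses.append(SynapseSpec(
                    "electrical", CellId("H2", s), CellId("HSE", o), g_gap=g_gap))
        # spiking → contralateral HSE and vCH chemical projections
        for tgt in ("HSE", "vCH"):
            synapses.append(SynapseSpec(
                "chemical_spike", CellId("H1", side), CellId(tgt, other),
                sign="excitatory", weight=w_exc, tau_syn=TAU_SYN_MS,
                e_rev=E_REV_EXC))
            synapses.append(SynapseSpec(
                "chemical_spike", CellId("Hu", side), CellId(tgt, other),
                sign="inhibitory", weight=w_inh, tau_syn=TAU_SYN_MS,
                e_rev=E_REV_INH))
    return NetworkSpec(_roster(table), synapses, connected=True)


def ablate(network: NetworkSpec, which: str) -> NetworkSpec:
    """Remove lateral connections: 'all_lateral' (disconnected case) or
    'interhemispheric_electrical' (cut only the midline gap junctions)."""
    if which == "all_lateral":
        return NetworkSpec(list(network.cells), [], connected=False)
    if which == "interhemispheric_electrical":
        syn = [s for s in network.synapses
               if not (s.kind == "electrical" and s.is_midline)]
        return NetworkSpec(list(network.cells), syn, network.connected)
    raise ValueError(f"unknown ablation {which!r}")


def set_gap_conductance(network: NetworkSpec, g: float) -> NetworkSpec:
    """Set the midline (H2 ↔ contralateral HSE) gap conductance to g nS."""
    if g < 0:
        raise ValueError("conductance must be non-negative")
    syn = [replace(s, g_gap=g)
           if (s.kind == "electrical" and s.is_midline) else s
           for s in network.synapses]
    return NetworkSpec(list(network.cells), syn, network.connected)


@dataclass
class SimResult:
    """Output of one network simulation trial."""

    labels: list[str]
    dt: float
    duration: float
    spikes: dict[str, np.ndarray]  # label -> spike times (ms)
    v: np.ndarray | None  # (n_rec, 16) recorded voltages, or None
    rec_dt: float | None

    def spike_train(self, cell: str):
        from .spike_analysis import SpikeTrain
        return SpikeTrain(cell, self.spikes[cell], self.duration)


def _pack(network: NetworkSpec):
    """Flatten a NetworkSpec into the arrays the jit core consumes."""
    n = len(network.cells)
    c_abs = np.empty(n); g_leak = np.empty(n); e_leak = np.empty(n)
    spiking = np.zeros(n, dtype=np.bool_)
    g_fast = np.zeros(n); e_fast = np.zeros(n); g_slow = np.zeros(n)
    e_slow = np.zeros(n)
    v1 = np.ones(n); v2 = np.ones(n); v3 = np.ones(n); v4 = np.ones(n)
    phi = np.ones(n)
    v0 = np.empty(n); w0 = np.zeros(n)
    rest_cache: dict[int, tuple[float, float]] = {}
    for i, (cid, p) in enumerate(network.cells):
        c_abs[i] = p.c_abs
        g_leak[i] = p.g_leak_abs
        e_leak[i] = p.e_leak_eff
        key = id(p)
        if key not in rest_cache:
            r = resting_state(p)
            rest_cache[key] = (r.v, r.w)
        v0[i], w0[i] = rest_cache[key]
        if p.ml is not None:
            spiking[i] = True
            g_fast[i] = p.g_fast_abs
            e_fast[i] = p.ml.e_fast
            g_slow[i] = p.g_slow_abs
            e_slow[i] = p.ml.e_slow
            v1[i], v2[i] = p.ml.v1, p.ml.v2
            v3[i], v4[i] = p.ml.v3, p.ml.v4
            phi[i] = p.ml.phi

    elec = [s for s in network.synapses if s.kind == "electrical"]
    chem = [s for s in network.synapses if s.kind == "chemical_spike"]
    grad = [s for s in network.synapses if s.kind == "chemical_graded"]
    idx = network.index

    e_pre = np.array([idx(s.pre) for s in elec], dtype=np.int64)
    e_post = np.array([idx(s.post) for s in elec], dtype=np.int64)
    e_g = np.array([s.g_gap * 1e-3 for s in elec])  # µS

    c_pre = np.array([idx(s.pre) for s in chem], dtype=np.int64)
    c_post = np.array([idx(s.post) for s in chem], dtype=np.int64)
    c_w = np.array([s.weight * 1e-3 for s in chem])  # µS
    c_tau = np.array([s.tau_syn for s in chem])
    c_erev = np.array([s.e_rev for s in chem])

    gr_pre = np.array([idx(s.pre) for s in grad], dtype=np.int64)
    gr_post = np.array([idx(s.post) for s in grad], dtype=np.int64)
    gr_imax = np.array([s.i_max * (1.0 if s.sign == "excitatory" else -1.0)
                        for s in grad])
    gr_theta = np.array([s.theta for s in grad])
    gr_slope = np.array([s.slope for s in grad])

    # outgoing chem-synapse lists per cell (CSR layout) for spike triggering
    out_ptr = np.zeros(n + 1, dtype=np.int64)
    for s in range(len(chem)):
        out_ptr[c_pre[s] + 1] += 1
    out_ptr = np.cumsum(out_ptr).astype(np.int64)
    out_idx = np.zeros(len(chem), dtype=np.int64)
    fill = out_ptr[:-1].copy()
    for s in range(len(chem)):
        out_idx[fill[c_pre[s]]] = s
        fill[c_pre[s]] += 1

    return dict(
        c_abs=c_abs, g_leak=g_leak, e_leak=e_leak, spiking=spiking,
        g_fast=g_fast, e_fast=e_fast, g_slow=g_slow, e_slow=e_slow,
        v1=v1, v2=v2, v3=v3, v4=v4, phi=phi,
        e_pre=e_pre, e_post=e_post, e_g=e_g,
        c_pre=c_pre, c_post=c_post, c_w=c_w, c_tau=c_tau, c_erev=c_erev,
        out_ptr=out_ptr, out_idx=out_idx,
        gr_pre=gr_pre, gr_post=gr_post, gr_imax=gr_imax,
        gr_theta=gr_theta, gr_slope=gr_slope,
        v0=v0, w0=w0,
    )


def simulate(
    network: NetworkSpec,
    stimulus: np.ndarray,
    dt: float = 0.025,
    threshold: float = 0.0,
    refractory: float = 2.0,
    record_stride: int = 0,
    v0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> SimResult:
    """Advance the coupled network through the stimulus traces.

    ``stimulus`` is an (n_steps, n_cells) array of injected currents (nA)
    in roster order (zero for CH cells).  Deterministic given the traces
    and dt.  Set ``record_stride`` > 0 to keep voltages every that many
    steps.
    """
    from . import _core

    stim = np.ascontiguousarray(stimulus, dtype=np.float64)
    n = len(network.cells)
    if stim.ndim != 2 or stim.shape[1] != n:
        raise ValueError(f"stimulus must be (n_steps, {n})")
    p = _pack(network)
    duration = stim.shape[0] * dt
    # ML rates stay below ~30 Hz; generous headroom for noise-driven events
    max_spikes = int(duration / 1000.0 * 120) + 64
    v_rec, times, counts, status = _core.integrate_network(
        stim, dt,
        p["c_abs"], p["g_leak"], p["e_leak"], p["spiking"],
        p["g_fast"], p["e_fast"], p["g_slow"], p["e_slow"],
        p["v1"], p["v2"], p["v3"], p["v4"], p["phi"],
        p["e_pre"], p["e_post"], p["e_g"],
        p["c_pre"], p["c_post"], p["c_w"],
        np.exp(-dt / p["c_tau"]) if len(p["c_tau"]) else p["c_tau"],
        p["c_erev"], p["out_ptr"], p["out_idx"],
        p["gr_pre"], p["gr_post"], p["gr_imax"], p["gr_theta"], p["gr_slope"],
        np.asarray(v0, dtype=np.float64) if v0 is not None else p["v0"],
        np.asarray(w0, dtype=np.float64) if w0 is not None else p["w0"],
        threshold, refractory,
        record_stride, max_spikes,
    )
    if status[0] >= 0:
        bad = network.labels[int(status[0])]
        raise FloatingPointError(f"state blow-up in {bad} at t={status[1]:.3f} ms")
    spikes = {}
    for i, lab in enumerate(network.labels):
        k = min(int(counts[i]), times.shape[1])
        spikes[lab] = times[i, :k].copy()
    return SimResult(
        labels=network.labels, dt=dt, duration=duration, spikes=spikes,
        v=v_rec if record_stride > 0 else None,
        rec_dt=dt * record_stride if record_stride > 0 else None,
    )
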