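# Methods

`lptcnet` simulates the bilateral network of horizontal lobula-plate
tangential cells (LPTCs) of the blowfly visual system and analyses how
it integrates binocular motion: single-cell selectivity, pairwise
synchrony, and population coding of rotational (in-phase) versus
translational (out-of-phase) optic flow.

## Cell models

Each of the sixteen cells (eight per hemisphere) is a single cylindrical
compartment. Spiking cells (H1, H2, Hu) follow the type-I Morris-Lecar
(ML) equations

    C V' = −g_f·m∞(V)(V−E_f) − g_s·w(V−E_s) − g_L(V−E_L) + I_stim + I_syn
    w'   = φ cosh((V−V₃)/2V₄) · (w∞(V) − w)

with m∞(V) = ½[1+tanh((V−V₁)/V₂)] and w∞(V) = ½[1+tanh((V−V₃)/V₄)].
The channel set is the canonical type-I (SNIC) parameterization
(E_f = 120 mV, g_f = 4 mS/cm², E_s = −84 mV, g_s = 8 mS/cm²,
E_L = −60 mV, g_L = 2 mS/cm², C_m = 20 µF/cm², V₁ = −1.2, V₂ = 18,
V₃ = 12, V₄ = 17.4 mV, φ = 0.066 ms⁻¹); firing onset is continuous
(rheobase ≈ 6.3 nA for H1's geometry) and the steady-state rate stays
below ≈ 26 Hz over the whole stimulus range — the intrinsic ML ceiling.
Graded cells (HSN/HSE/HSS and dCH/vCH) are passive compartments
(C_m = 1 µF/cm², g_L = 1 mS/cm², E_L = −50 mV, τ_m = 1 ms).
Geometry: H1 1000×5 µm, H2/Hu 200×5 µm, HS/CH 250×15 µm; specific
parameters are converted to absolute ones through the lateral cylinder
area. The φ-form of the slow-channel relaxation (φ multiplying the cosh
rate) is the standard ML convention; the alternative convention only
rescales φ and is absorbed by the printed value.

Working units everywhere: mV, ms, nA, nF, µS.

## Network

Three synapse types connect the cells (`network.default_topology`, all
editable through the YAML config, which is the source of truth):

* **Electrical.** Ohmic gap junctions, 40 nS everywhere,
  I_i = g(V_j − V_i); current is conserved pairwise by construction.
  The five graded cells of each hemisphere form a dorsoventral chain
  dCH–HSN–HSE–HSS–vCH. A chain (rather than, e.g., coupling HSE
  directly to the CH cells) keeps HSE's neighbours the co-stimulated
  HSN/HSS, so its stimulus-driven depolarization is not diluted by the
  unstimulated CH cells; with a diluted pool the midline coupling acts
  on H2 as a net shunt and the in-phase sharpening of H2's ISIs
  inverts. Two midline gap junctions, H2 ↔ contralateral HSE, carry
  the only direct interhemispheric electrical path.
* **Spike-triggered chemical.** Single-exponential conductances,
  τ = 0.3 ms, reversal 0 mV (excitatory) / −70 mV (inhibitory). H1
  projects excitation and Hu inhibition onto the contralateral HSE and
  vCH; the signs follow the cooperation/frustration logic — H1 prefers
  the same global rotation sense as its contralateral targets, Hu the
  opposite — so in-phase motion drives the network cooperatively and
  out-of-phase motion frustrates it. Because physiologically calibrated
  weights are what the circuit needs (the printed nS values produce µV
  deflections), weights are calibrated numerically so one presynaptic
  spike produces a 1 mV PSP on the isolated postsynaptic cell at rest
  (±5 %, secant iteration on a direct Euler run); the literal values
  remain available via config.
* **Graded chemical.** Sigmoidal current of the presynaptic potential,
  I = i_max/(1+exp(−(V_pre−θ)/s)), negated for inhibition; defaults
  i_max = 0.5 nA, θ = −40 mV, s = 5 mV: silent near the graded cells'
  rest (−50 mV), near-saturating ~15 mV above it. vCH inhibits the
  ipsilateral H1 and H2; HSE excites the ipsilateral Hu (single links,
  following the circuit's singular wording).

Integration is fixed-step forward Euler at dt = 0.025 ms (numba-JIT;
halving dt changes the spike count of a 5 s noise-free run by ≤ 1).
The slow gating variable is clamped to its physical range [0, 1], which
matters only during extreme noise excursions. All cells start at their
numerically determined I = 0 resting state with w₀ = w∞(V₀). Spikes are
detected online as upward crossings of 0 mV separated by ≥ 2 ms (ML
spikes overshoot well above 0 mV); the same events drive the chemical
synapses. The disconnected ("isolated cells") variant has an empty
synapse list and is bit-identical to sixteen independent single-cell
integrations.

## Stimuli (synthetic-data generator)

Motion input from the earlier neuropils is mimicked per cell by a DC
current — depolarizing (A_PD) when the stimulus moves in the cell's
preferred direction, hyperpolarizing (A_ND) otherwise — plus white
noise, independent between cells. Four binocular stimuli (C, CC
rotations; FB, BF translations) are encoded in a polarity table with
the mirror symmetries C = −CC and FB = −BF. Amplitudes per class:
H1 (10, −1) nA, H2 (2, −0.2) nA, HS (3.6, −1.3) nA; CH cells receive
no direct input. H1's and H2's amplitudes correspond to the same
current density (63.7 µA/cm²); Hu, which has no printed row, defaults
to that density, which for its geometry equals the H2 pair. The
`spontaneous` condition zeroes all DCs but keeps the noise.

**Noise and SNR convention (read this before comparing SNR values
across implementations).** A realized trace sample is
DC + σ·√(t_ref/dt)·η with η ~ N(0,1) per integration step, so noise
power is independent of dt (Euler–Maruyama); SNR ≡ A_PD²/σ². σ is the
RMS noise current on the reference window t_ref = 0.1 ms (equivalently,
white-noise intensity D = σ²·t_ref/2). The reference window calibrates
where a quoted SNR puts the network: with t_ref = 1 ms the noise at
SNR = 0.166 drives every spiking cell to 45–50 Hz, far above the ML
ceiling; with t_ref at the integration step the out-of-phase response
is silenced entirely. t_ref = 0.1 ms is the operating point at which
the network behaves as the circuit should — rates within the type-I
ceiling, all four stimuli responsive, well-formed ISI distributions —
and is fixed once here, not per experiment. A quoted SNR puts every
stimulated cell at the same operating point: each cell's σ is derived
from its own A_PD (σ = A_PD/√SNR), which also equalizes noise current
densities across the spiking cells.

## Analysis

* **Rate difference**: mean rate under stimulation minus mean
  spontaneous rate, reported mean ± SEM over independently seeded
  trials (SEM is undefined, and reported missing, for one trial).
* **ISI dispersion**: histogram of successive intervals plus the
  coefficient of variation; undefined (missing) below two spikes.
* **Cross-correlograms**: firing rates binned at 10 ms; the default
  estimator is the non-centered normalized correlogram
  C(τ) = Σx(t)y(t+τ)/√(Σx²·Σy²) over the overlapping samples at each
  lag. Its zero-lag value deliberately reflects the rates and
  regularity of the two trains as well as coincident modulation — that
  is the quantity whose stimulus dependence the synchrony analyses
  track. The mean-subtracted (Pearson) form is available via
  `centered=True`; under it, the between-pair orderings at this
  operating point sit at the sampling noise floor (|C| ≲ 0.02) because
  cells on opposite sides share no low-frequency drive once the DC is
  removed. Both forms are bounded in [−1, 1] and exchange-symmetric.
* **Population PCA**: six-dimensional firing-rate vectors (one entry
  per spiking cell) in non-overlapping 150 ms windows, pooled over the
  four stimuli per trial; eigendecomposition of the correlation matrix
  by default (the covariance matrix behind a flag — the two correspond
  to the two common conventions of standard PCA routines; experiment
  outputs can report both). Component signs are fixed
  (largest-magnitude element positive). *Cluster geometry* (this
  package's quantification of the qualitative claims): quadrant
  separation = 1 when the four stimulus centroids occupy four distinct
  quadrants of the PC1–PC2 plane; axis alignment = angle between the
  C↔CC (and FB↔BF) centroid axes and the nearest PC axis. *Component
  identity* assigns each PC the stimulus-contrast axis (in-phase C−CC,
  out-of-phase FB−BF, left/right monocular — the contrasts of stimulus
  pairs sharing one eye's motion) it aligns best with; angles beyond
  30° from every axis give "mixed". The thresholds are documented
  constants, not fitted.

A structural note on the disconnected case: with all couplings removed
the network is exactly mirror-symmetric, so the left- and right-eye
cluster contrasts contribute identical variance and the PC1/PC2
orientation within that two-dimensional eigenspace is decided by
sampling fluctuations. Disconnected label assignments are therefore
intrinsically unstable across seeds — monocular and diagonal
orientations both occur — which is itself the diagnostic contrast with
the connected network, whose labels are stable (in-phase, out-of-phase)
trial after trial. Tests assert exactly this stability contrast.

## Reduced model

An eight-unit continuous-time rate model: per hemisphere H1, H2, Hu and
one HS/CH unit standing for the five electrically coupled graded cells;
τ ẋ = −x + W f(x) + g·(Px − x)|midline + ξ(t) + noise, with f the same
sigmoid as the graded synapses and the electrical coupling written as a
linear diffusive term (the standard form for gap junctions). W mirrors
the detailed circuit, including Hu's inhibitory contralateral sign. The
rotation input pattern is mirror-antisymmetric, the translation pattern
mirror-symmetric, and the two are orthogonal; a time-dependent sign
s(t) = ±1 selects the direction (the four fixed-s stimuli are run
separately in the experiments; periodic s-switching is available).
Parameters are dimensionless by design — τ = 10 ms, w_exc = w_inh = 1,
g = 1, unit input amplitudes, sigmoid (i_max = 1, θ = 0.5, s = 0.25),
noise σ = 0.3 — chosen once so the model operates in its sensitive
range; its role is purely the qualitative cross-check, and the
noise-free model settles to a fixed point (no limit cycle) under every
stimulus. Windowed means of the six spiking units feed the same PCA
pipeline as the detailed model.

## Problem sizes

Experiments default to the study conditions: 24 s trials at
SNR = 0.166, 8 trials for single-cell/pairwise statistics, 10 for the
PCA experiments, with a `--fast` mode (8 s trials) for exploratory
runs. The test suite runs the full experiments at these sizes except
the morphology check (3 trials). The acceptance script's f–I sweep uses
5 s per DC step, 1 s discarded, 0.25 nA steps from 0 to 20 nA.

## What the generator does and does not emulate

The DC-plus-noise surrogate captures direction-selective drive and its
reliability, not the visual front-end: no image-computable motion
detection, no receptive-field structure, no temporal dynamics of
pattern motion, no shared (stimulus-induced) noise between cells.
Passing tests therefore validate the circuit-level integration
mechanism — not the encoding of real optic flow. Other known
limitations: single compartments (no dendritic integration), one
parameter row per cell class, no synaptic delays or plasticity, an ISI
CV of ~0.5 rather than the sharper in vivo regularity, and absolute
firing rates capped by the ML ceiling (~26 Hz) well below real H2
rates (50–100 Hz) — orderings and population structure, not absolute
rates, are the reproducible content.
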