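# Default parameters of the bilateral horizontal-LPTC network model.
# Units are spelled out in the keys: lengths in um, capacitance in
# uF/cm^2, conductance densities in S/cm^2, potentials in mV,
# synaptic conductances in nS, currents in nA, time in ms.
#
# Spiking cells (H1, H2, Hu) use the type-I Morris-Lecar channel set
# below with its own leak reversal; graded cells (HS, CH) are passive.

cells:
  H1: {length_um: 1000.0, diameter_um: 5.0, c_m_uF_per_cm2: 20.0,
       e_leak_mV: -60.0, g_leak_S_per_cm2: 0.002, spiking: true}
  H2: {length_um: 200.0, diameter_um: 5.0, c_m_uF_per_cm2: 20.0,
       e_leak_mV: -60.0, g_leak_S_per_cm2: 0.002, spiking: true}
  Hu: {length_um: 200.0, diameter_um: 5.0, c_m_uF_per_cm2: 20.0,
       e_leak_mV: -60.0, g_leak_S_per_cm2: 0.002, spiking: true}
  HS: {length_um: 250.0, diameter_um: 15.0, c_m_uF_per_cm2: 1.0,
       e_leak_mV: -50.0, g_leak_S_per_cm2: 0.001, spiking: false}
  CH: {length_um: 250.0, diameter_um: 15.0, c_m_uF_per_cm2: 1.0,
       e_leak_mV: -50.0, g_leak_S_per_cm2: 0.001, spiking: false}

morris_lecar:
  e_fast_mV: 120.0
  g_fast_S_per_cm2: 0.004
  e_slow_mV: -84.0
  g_slow_S_per_cm2: 0.008
  e_leak_mV: -60.0
  v1_mV: -1.2
  v2_mV: 18.0
  v3_mV: 12.0
  v4_mV: 17.4
  phi_per_ms: 0.066

# topology: default  -> use the built-in mirror-symmetric wiring
# (gap junctions among the graded cells, CH -| ipsilateral H1/H2,
# HS -> ipsilateral Hu, midline H2 <-> contralateral HSE gap junctions,
# H1/Hu chemical projections onto contralateral HSE and vCH).
# Replace with an explicit `synapses:` list (see config.dump_network)
# to override the wiring.
topology: default

synapse_defaults:
  gap_ns: 40.0
  tau_syn_ms: 0.3
  e_rev_exc_mV: 0.0
  e_rev_inh_mV: -70.0
  # single-spike PSP amplitude the chemical weights are calibrated to;
  # set to null to use the literal printed weights (0.01 / 0.005 nS)
  psp_target_mV: 1.0
  graded:
    i_max_nA: 0.5
    theta_mV: -40.0
    slope_mV: 5.0

stimulus:
  # A_PD / A_ND per directly stimulated cell class; Hu has no printed
  # row and defaults to the H1/H2 current density, which for its
  # geometry equals the H2 amplitudes
  amplitudes_nA:
    H1: [10.0, -1.0]
    H2: [2.0, -0.2]
    Hu: [2.0, -0.2]
    HS: [3.6, -1.3]
  snr: 0.166            # per-cell noise sigma = A_PD / sqrt(snr)
  duration_ms: 24000.0
  dt_ms: 0.025
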