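"""Declarative YAML configuration for cells, topology and stimuli.

The shipped ``data/default.yaml`` mirrors the model's parameter tables
(cell geometry and membrane parameters, Morris-Lecar channel set,
synapse defaults, stimulus amplitudes) with units spelled out in the
keys.  A config may either rely on the built-in default wiring
(``topology: default``) or enumerate every synapse explicitly; an
explicit list written by :func:`dump_network` round-trips exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from . import network as net
from .cells import CellParams, MLParams
from .stimuli import StimulusSpec

__all__ = [
    "default_config_path",
    "load_config",
    "cell_table_from_config",
    "network_from_config",
    "stimulus_from_config",
    "dump_network",
]


def default_config_path() -> Path:
    return Path(str(resources.files("lptcnet") / "data" / "default.yaml"))


def load_config(path: str | Path | None = None) -> dict:
    p = Path(path) if path is not None else default_config_path()
    with open(p) as fh:
        return yaml.safe_load(fh)


def cell_table_from_config(cfg: dict) -> dict[str, CellParams]:
    ml_cfg = cfg.get("morris_lecar", {})
    ml = MLParams(
        e_fast=ml_cfg.get("e_fast_mV", 120.0),
        g_fast=ml_cfg.get("g_fast_S_per_cm2", 0.004),
        e_slow=ml_cfg.get("e_slow_mV", -84.0),
        g_slow=ml_cfg.get("g_slow_S_per_cm2", 0.008),
        e_leak_ml=ml_cfg.get("e_leak_mV", -60.0),
        v1=ml_cfg.get("v1_mV", -1.2), v2=ml_cfg.get("v2_mV", 18.0),
        v3=ml_cfg.get("v3_mV", 12.0), v4=ml_cfg.get("v4_mV", 17.4),
        phi=ml_cfg.get("phi_per_ms", 0.066),
    )
    table = {}
    for cls, row in cfg["cells"].items():
        spiking = bool(row.get("spiking", False))
        table[cls] = CellParams(
            cell_class=cls,
            length=row["length_um"],
            diameter=row["diameter_um"],
            c_m=row["c_m_uF_per_cm2"],
            e_leak=row["e_leak_mV"],
            g_leak=row["g_leak_S_per_cm2"],
            ml=ml if spiking else None,
        )
    return table


def _syn_from_record(rec: dict) -> net.SynapseSpec:
    return net.SynapseSpec(
        kind=rec["kind"],
        pre=net.CellId(rec["pre"][:-1], rec["pre"][-1]),
        post=net.CellId(rec["post"][:-1], rec["post"][-1]),
        sign=rec.get("sign"),
        g_gap=rec.get("g_gap_ns"),
        weight=rec.get("weight_ns"),
        tau_syn=rec.get("tau_syn_ms"),
        e_rev=rec.get("e_rev_mV"),
        i_max=rec.get("i_max_nA"),
        theta=rec.get("theta_mV"),
        slope=rec.get("slope_mV"),
    )


def network_from_config(cfg: dict | None = None) -> net.NetworkSpec:
    cfg = cfg if cfg is not None else load_config()
    table = cell_table_from_config(cfg)
    if isinstance(cfg.get("synapses"), list):
        roster = net._roster(table)
        spec = net.NetworkSpec(
            roster, [_syn_from_record(r) for r in cfg["synapses"]],
            connected=True)
        return spec
    d = cfg.get("synapse_defaults", {})
    psp = d.get("psp_target_mV", net.PSP_TARGET_MV)
    graded = d.get("graded", {})
    return net.default_topology(
        cell_table=table,
        g_gap=d.get("gap_ns", net.GAP_NS),
        calibrate_psp=psp,
        graded_i_max=graded.get("i_max_nA", net.GRADED_I_MAX),
        graded_theta=graded.get("theta_mV", net.GRADED_THETA),
        graded_slope=graded.get("slope_mV", net.GRADED_SLOPE),
    )


def stimulus_from_config(cfg: dict, stim_type: str, seed: int = 0,
                         duration: float | None = None) -> StimulusSpec:
    s = cfg.get("stimulus", {})
    amps = {k: tuple(v) for k, v in s.get("amplitudes_nA", {}).items()} or None
    kwargs = dict(
        stim_type=stim_type,
        duration=duration if duration is not None else s.get("duration_ms", 24000.0),
        dt=s.get("dt_ms", 0.025),
        seed=seed,
    )
    if amps:
        kwargs["amplitudes"] = amps
    if "snr" in s:
        kwargs["target_snr"] = s["snr"]
    elif "noise_sigma_nA_sqrt_ms" in s:
        kwargs["noise_sigma"] = s["noise_sigma_nA_sqrt_ms"]
    return StimulusSpec(**kwargs)


def _syn_to_record(s: net.SynapseSpec) -> dict:
    rec = {"kind": s.kind, "pre": s.pre.label, "post": s.post.label}
    if s.sign is not None:
        rec["sign"] = s.sign
    for key, val in (("g_gap_ns", s.g_gap), ("weight_ns", s.weight),
                     ("tau_syn_ms", s.tau_syn), ("e_rev_mV", s.e_rev),
                     ("i_max_nA", s.i_max), ("theta_mV", s.theta),
                     ("slope_mV", s.slope)):
        if val is not None:
            rec[key] = float(val)
    return rec


def dump_network(network: net.NetworkSpec, path: str | Path,
                 base_cfg: dict | None = None) -> None:
    """Write a config with the network's explicit synapse list."""
    cfg = dict(base_cfg if base_cfg is not None else load_config())
    cfg["synapses"] = [_syn_to_record(s) for s in network.synapses]
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
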