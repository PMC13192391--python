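"""Run configuration, trace CSV reading/writing, and artifact plumbing.

Configs are YAML with three optional blocks (``parameters``, ``protocol``,
``analysis``) plus ``outdir``, ``seed`` and ``log_level``; unset fields take
the documented defaults and unknown keys are errors.  Traces are diffable
CSV with '#'-prefixed metadata header lines; values round-trip at 17
significant digits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .params import ModelParameters, calibrated_parameters
from .plateau import DetectionConfig
from .protocols import StimulusProtocol, build_protocol
from .simulate import SimulationTrace

__all__ = ["RunConfig", "load_config", "write_trace", "read_trace"]

log = logging.getLogger("ca1plateau")

TRACE_COLUMNS = ["t", "V", "m_cal", "m_kca", "cai", "g_syn",
                 "I_pas", "I_VGCC", "I_KCa", "I_GABA", "I_inj", "I_sum"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Detection thresholds, bisection tolerances, and sweep grids."""

    detection: DetectionConfig = DetectionConfig()
    bisection_rel_tol: float = 0.005
    ipsg_onset: float = 50.0            # ms from plateau initiation
    tau_syn: float = 10.0               # ms, canonical IPSG decay
    timing_grid: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0)
    timing_fine_step: float = 5.0
    tau_grid: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0)
    dynamic_tau_grid: tuple[float, ...] = (2.0, 3.0, 5.0, 10.0)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        det = d.pop("detection", {})
        known_det = set(DetectionConfig.__dataclass_fields__)
        bad = set(det) - known_det
        if bad:
            raise KeyError(f"unknown detection key(s): {sorted(bad)}")
        known = set(cls.__dataclass_fields__) - {"detection"}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown analysis key(s): {sorted(bad)}")
        for k in ("timing_grid", "tau_grid", "dynamic_tau_grid"):
            if k in d:
                d[k] = tuple(float(x) for x in d[k])
        return cls(detection=DetectionConfig(**det), **d)


@dataclass(frozen=True)
class RunConfig:
    parameters: ModelParameters = field(default_factory=calibrated_parameters)
    protocol: StimulusProtocol | None = None
    analysis: AnalysisConfig = AnalysisConfig()
    outdir: Path = Path("ca1plateau_out")
    seed: int = 0
    log_level: str = "INFO"

    def resolved_dict(self) -> dict[str, Any]:
        return {
            "parameters": self.parameters.to_dict(),
            "protocol": None if self.protocol is None else self.protocol.to_dict(),
            "analysis": {
                **{k: getattr(self.analysis, k)
                   for k in AnalysisConfig.__dataclass_fields__ if k != "detection"},
                "detection": dataclasses.asdict(self.analysis.detection),
            },
            "outdir": str(self.outdir),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def echo_into(self, outdir: Path) -> None:
        """Write the fully resolved config (and seed) into an artifact dir."""
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "resolved_config.yaml", "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.resolved_dict())), f,
                           sort_keys=False)


_TOP_KEYS = {"parameters", "protocol", "analysis", "outdir", "seed", "log_level"}


def load_config(path: str | Path | None = None, *,
                overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML config; resolution order file < overrides."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded)}")
        raw.update(loaded)
    for k, v in (overrides or {}).items():
        if isinstance(v, Mapping) and isinstance(raw.get(k), Mapping):
            raw[k] = {**raw[k], **v}
        else:
            raw[k] = v
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    params_block = dict(raw.get("parameters", {}))
    base = calibrated_parameters().to_dict()
    known = set(base)
    bad = set(params_block) - known
    if bad:
        raise KeyError(f"unknown parameter key(s): {sorted(bad)}")
    base.update(params_block)
    params = ModelParameters.from_dict(base)
    proto = None
    if raw.get("protocol"):
        proto = build_protocol(raw["protocol"])
    analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
    return RunConfig(
        parameters=params, protocol=proto, analysis=analysis,
        outdir=Path(raw.get("outdir", "ca1plateau_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def write_trace(trace: SimulationTrace, path: str | Path) -> None:
    """CSV with '#' metadata header (parameters, protocol, optional noise
    seed) and the full per-sample state + current decomposition."""
    path = Path(path)
    meta = {
        "parameters": trace.params.to_dict(),
        "protocol": trace.protocol.to_dict(),
    }
    noise = getattr(trace, "noise_meta", None)
    if noise:
        meta["noise"] = noise
    cols = {
        "t": trace.t, "V": trace.V, "m_cal": trace.m_cal, "m_kca": trace.m_kca,
        "cai": trace.cai, "g_syn": trace.g_syn, "I_pas": trace.I_pas,
        "I_VGCC": trace.I_VGCC, "I_KCa": trace.I_KCa, "I_GABA": trace.I_GABA,
        "I_inj": trace.I_inj, "I_sum": trace.I_sum,
    }
    with open(path, "w") as f:
        f.write("# ca1plateau trace v1\n")
        f.write("# meta: " + json.dumps(meta) + "\n")
        f.write(",".join(TRACE_COLUMNS) + "\n")
        arr = np.column_stack([cols[c] for c in TRACE_COLUMNS])
        np.savetxt(f, arr, fmt="%.17g", delimiter=",")


def read_trace(path: str | Path) -> SimulationTrace:
    """Inverse of :func:`write_trace`; column order is header-keyed."""
    from . import mechanisms

    path = Path(path)
    meta: dict[str, Any] = {}
    header_lines = 0
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                header_lines += 1
                if line.startswith("# meta:"):
                    meta = json.loads(line[len("# meta:"):])
            else:
                break
    df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing trace column(s) {sorted(missing)} "
            f"(line {header_lines + 1})"
        )
    if "parameters" not in meta or "protocol" not in meta:
        raise ValueError(f"{path}: missing metadata header (line 2)")
    params = ModelParameters.from_dict(meta["parameters"])
    proto = build_protocol(meta["protocol"])
    trace = SimulationTrace(
        params=params, protocol=proto,
        t=df["t"].to_numpy(), V=df["V"].to_numpy(),
        m_cal=df["m_cal"].to_numpy(), m_kca=df["m_kca"].to_numpy(),
        cai=df["cai"].to_numpy(), g_syn=df["g_syn"].to_numpy(),
        I_pas=df["I_pas"].to_numpy(), I_VGCC=df["I_VGCC"].to_numpy(),
        I_KCa=df["I_KCa"].to_numpy(), I_GABA=df["I_GABA"].to_numpy(),
        I_inj=df["I_inj"].to_numpy(), I_sum=df["I_sum"].to_numpy(),
        m_inf_cal=mechanisms.cal_rates(df["V"].to_numpy(), params).m_inf,
        m_inf_kca=mechanisms.kca_gate(df["cai"].to_numpy(), params).m_inf,
    )
    if "noise" in meta:
        trace.noise_meta = meta["noise"]
    return trace
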