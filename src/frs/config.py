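"""JSON run configuration: simulator, processing and analysis sections.

A single JSON document configures a whole run. Unknown keys are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, fields
from typing import Any, Optional

from .core import FRSError
from .processing import FreqWindowSpec, TimeFilterSpec
from .synth import CampaignSpec, NoiseSpec, OscillatorModel, PulseSpec

__all__ = ["RunConfig", "ProcessingConfig", "AnalysisConfig"]


def _strict(cls, d: dict, context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise FRSError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class ProcessingConfig:
    roi: tuple[float, float] = (900.0, 1500.0)
    transition_width: float = 50.0
    filter: TimeFilterSpec = TimeFilterSpec("heaviside", 650.0, 4)
    floor_frac: float = 1e-3
    output_kind: str = "magnitude"

    def __post_init__(self) -> None:
        if self.output_kind not in ("magnitude", "complex"):
            raise FRSError("output_kind must be 'magnitude' or 'complex'")

    @property
    def window(self) -> FreqWindowSpec:
        return FreqWindowSpec(tuple(self.roi), self.transition_width)


@dataclass(frozen=True)
class AnalysisConfig:
    band: tuple[float, float] = (1000.0, 1400.0)
    cutoffs: tuple[float, float, float] = (0.0, 2000.0, 50.0)  # start, stop, step
    c_ref: float = 1000.0

    def cutoff_grid(self) -> list[float]:
        start, stop, step = self.cutoffs
        if step <= 0 or stop < start:
            raise FRSError("cutoffs must be (start, stop, step) with step > 0")
        out, c = [], start
        while c <= stop + 1e-9:
            out.append(round(c, 9))
            c += step
        return out


@dataclass(frozen=True)
class SimulatorConfig:
    pulse: PulseSpec = PulseSpec()
    oscillator: OscillatorModel = OscillatorModel()
    noise: NoiseSpec = NoiseSpec()
    campaign: CampaignSpec = CampaignSpec()


@dataclass(frozen=True)
class RunConfig:
    simulator: SimulatorConfig = SimulatorConfig()
    processing: ProcessingConfig = ProcessingConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        allowed = {"simulator", "processing", "analysis"}
        unknown = set(d) - allowed
        if unknown:
            raise FRSError(f"unknown top-level config sections: {sorted(unknown)}")
        sim_d = dict(d.get("simulator", {}))
        allowed_sim = {"pulse", "oscillator", "noise", "campaign"}
        unknown = set(sim_d) - allowed_sim
        if unknown:
            raise FRSError(f"unknown keys in simulator: {sorted(unknown)}")
        pulse = _strict(PulseSpec, dict(sim_d.get("pulse", {})), "simulator.pulse")
        osc_d = dict(sim_d.get("oscillator", {}))
        if "lines" in osc_d:
            osc_d["lines"] = tuple(tuple(l) for l in osc_d["lines"])
        if osc_d.get("echo") is not None and "echo" in osc_d:
            osc_d["echo"] = tuple(osc_d["echo"])
        oscillator = _strict(OscillatorModel, osc_d, "simulator.oscillator")
        noise = _strict(NoiseSpec, dict(sim_d.get("noise", {})), "simulator.noise")
        camp_d = dict(sim_d.get("campaign", {}))
        if "concentrations" in camp_d:
            camp_d["concentrations"] = tuple(camp_d["concentrations"])
        camp_d["base_pulse"] = pulse
        campaign = _strict(CampaignSpec, camp_d, "simulator.campaign")
        proc_d = dict(d.get("processing", {}))
        if "roi" in proc_d:
            proc_d["roi"] = tuple(proc_d["roi"])
        if "filter" in proc_d:
            proc_d["filter"] = _strict(TimeFilterSpec, dict(proc_d["filter"]), "processing.filter")
        processing = _strict(ProcessingConfig, proc_d, "processing")
        ana_d = dict(d.get("analysis", {}))
        for key in ("band", "cutoffs"):
            if key in ana_d:
                ana_d[key] = tuple(ana_d[key])
        analysis = _strict(AnalysisConfig, ana_d, "analysis")
        return cls(
            simulator=SimulatorConfig(pulse=pulse, oscillator=oscillator, noise=noise, campaign=campaign),
            processing=processing,
            analysis=analysis,
        )

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
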