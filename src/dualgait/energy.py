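"""Duty-cycle energy budget and telemetry throughput accounting.

The wearable runs an acquire-upload-sleep duty cycle: a microcontroller
samples locally at a low current, bursts data over Bluetooth at a higher
current, then sleeps.  On the generation side, a contact-separation
triboelectric harvester delivers an effective power during each foot-strike
contact, discounted by the rectification/regulation efficiency.  The budget
is exact arithmetic: energy per phase is V*I*t, harvest per step is
P*t_contact*eta, and the cycle is sustainable when harvest over the walking
bout exceeds the duty-cycle consumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "DutyCyclePhase",
    "HarvestParams",
    "FrameSpec",
    "EnergyScenario",
    "cycle_energy",
    "per_step_energy",
    "net_balance",
    "link_throughput",
    "budget_report",
]


@dataclass(frozen=True)
class DutyCyclePhase:
    """One phase of the operating duty cycle."""

    name: str
    voltage_V: float
    current_mA: float
    duration_s: float

    def __post_init__(self) -> None:
        if min(self.voltage_V, self.current_mA, self.duration_s) < 0:
            raise ValueError("phase quantities must be nonnegative")

    @property
    def energy_mJ(self) -> float:
        return self.voltage_V * self.current_mA * self.duration_s


@dataclass(frozen=True)
class HarvestParams:
    """Triboelectric harvest parameters."""

    effective_power_mW: float = 3.92
    contact_duration_s: float = 0.25
    conversion_efficiency: float = 0.72

    def __post_init__(self) -> None:
        if not (0 < self.conversion_efficiency <= 1):
            raise ValueError("efficiency must lie in (0, 1]")
        if self.effective_power_mW < 0 or self.contact_duration_s < 0:
            raise ValueError("power and duration must be >= 0")


@dataclass(frozen=True)
class FrameSpec:
    """Telemetry frame layout and rate."""

    payload_bytes: int = 64
    overhead_bytes: int = 3
    frame_rate_hz: float = 10.0
    wire_bits_per_byte: int = 10  # 8N1 UART: start + 8 data + stop

    def __post_init__(self) -> None:
        if self.payload_bytes <= 0 or self.overhead_bytes < 0:
            raise ValueError("byte counts must be positive")
        if self.frame_rate_hz < 0 or self.wire_bits_per_byte <= 0:
            raise ValueError("rates must be valid")

    @property
    def total_bytes(self) -> int:
        return self.payload_bytes + self.overhead_bytes


#: The measured duty cycle: 480 s acquisition + 20 s upload + 100 s sleep at
#: a rated 3.2 V system voltage.
DEFAULT_PHASES = (
    DutyCyclePhase("acquisition", 3.2, 0.2, 480.0),
    DutyCyclePhase("upload", 3.2, 1.8, 20.0),
    DutyCyclePhase("sleep", 3.2, 0.007, 100.0),
)


@dataclass
class EnergyScenario:
    """A complete duty-cycle / harvest / telemetry scenario."""

    phases: Sequence[DutyCyclePhase] = DEFAULT_PHASES
    harvest: HarvestParams = field(default_factory=HarvestParams)
    frame: FrameSpec = field(default_factory=FrameSpec)
    n_steps: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyScenario":
        raw = yaml.safe_load(Path(path).read_text())
        phases = tuple(
            DutyCyclePhase(
                p["name"], p["voltage_V"], p["current_mA"], p["duration_s"]
            )
            for p in raw.get("phases", [])
        ) or DEFAULT_PHASES
        return cls(
            phases=phases,
            harvest=HarvestParams(**raw.get("harvest", {})),
            frame=FrameSpec(**raw.get("frame", {})),
            n_steps=int(raw.get("n_steps", 1000)),
        )


def cycle_energy(phases: Sequence[DutyCyclePhase]) -> float:
    """Total duty-cycle consumption in mJ: sum of V*I*t over phases."""
    return float(sum(p.energy_mJ for p in phases))


def per_step_energy(h: HarvestParams) -> float:
    """Harvested energy per step in mJ: P * t_contact * efficiency."""
    return h.effective_power_mW * h.contact_duration_s * h.conversion_efficiency


def net_balance(
    phases: Sequence[DutyCyclePhase], h: HarvestParams, n_steps: int
) -> tuple[float, float, float]:
    """(harvest, consumption, surplus) in mJ over one duty cycle.

    Conservation holds exactly: harvest - consumption == surplus.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    harvest = n_steps * per_step_energy(h)
    consumption = cycle_energy(phases)
    return harvest, consumption, harvest - consumption


def link_throughput(f: FrameSpec) -> float:
    """Wireless link throughput in kbps."""
    return f.total_bytes * f.wire_bits_per_byte * f.frame_rate_hz / 1000.0


def budget_report(scenario: EnergyScenario, path: str | Path | None = None) -> dict:
    """Budget quantities (2-decimal mJ formatting) plus a sustainability verdict."""
    harvest, consumption, surplus = net_balance(
        scenario.phases, scenario.harvest, scenario.n_steps
    )
    report = {
        "cycle_consumption_mJ": round(consumption, 2),
        "per_step_harvest_mJ": round(per_step_energy(scenario.harvest), 4),
        "harvest_mJ": round(harvest, 2),
        "net_surplus_mJ": round(surplus, 2),
        "throughput_kbps": round(link_throughput(scenario.frame), 3),
        "sustainable": surplus >= 0,
        "n_steps": scenario.n_steps,
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
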