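"""Core domain types for time-gated FLIM analysis.

Gated FLIM records one image per detector gate position: the gate (a
nanosecond-wide global exposure window) is stepped relative to the laser
trigger, and the per-gate photon counts sample the fluorescence decay.
These dataclasses describe the acquisition clock (:class:`GateTimeline`),
the parametrized instrument response (:class:`IRFParams`), exponential
decay components, and the gated photon-count hyperstacks the rest of the
package operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GateTimeline",
    "IRFParams",
    "DecayComponent",
    "DecayModelSpec",
    "GatedStack",
    "LifetimePattern",
]


@dataclass(frozen=True)
class GateTimeline:
    """The acquisition clock of a gated measurement.

    Parameters
    ----------
    n_gates : int
        Number of gate positions ``k`` (>= 2).
    gate_width_ns : float
        Gate (exposure window) width ``w`` in ns.
    gate_step_ns : float
        Delay increment between consecutive gates in ns.
    first_delay_ns : float
        Opening delay of the first gate relative to the trigger (ns).
    laser_period_ns : float
        Laser repetition period in ns.  The model neglects wrap-around
        from previous pulses, valid when the period exceeds roughly five
        times the longest lifetime.
    """

    n_gates: int
    gate_width_ns: float = 5.0
    gate_step_ns: float = 2.0
    first_delay_ns: float = 0.0
    laser_period_ns: float = 50.0

    def __post_init__(self) -> None:
        if self.n_gates < 2:
            raise ValueError("need at least 2 gates")
        if self.gate_width_ns <= 0 or self.gate_step_ns <= 0:
            raise ValueError("gate width and step must be positive")
        if self.laser_period_ns <= 0:
            raise ValueError("laser period must be positive")
        if not np.isfinite(self.first_delay_ns) or self.first_delay_ns < 0:
            raise ValueError("first gate delay must be finite and >= 0")

    @property
    def delays(self) -> np.ndarray:
        """Gate opening delays ``t_m = t_start + m * step`` (ns), shape (k,)."""
        return self.first_delay_ns + self.gate_step_ns * np.arange(self.n_gates)

    @property
    def centers(self) -> np.ndarray:
        """Gate centers ``t_start + (m + 1/2) * step`` used by the phasor transform."""
        return self.first_delay_ns + self.gate_step_ns * (np.arange(self.n_gates) + 0.5)

    @property
    def total_detection_time_ns(self) -> float:
        """Total time spanned by the gate steps, ``k * step`` (ns)."""
        return self.n_gates * self.gate_step_ns

    def to_dict(self) -> dict:
        return {
            "n_gates": self.n_gates,
            "gate_width_ns": self.gate_width_ns,
            "gate_step_ns": self.gate_step_ns,
            "first_delay_ns": self.first_delay_ns,
            "laser_period_ns": self.laser_period_ns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateTimeline":
        return cls(**{k: d[k] for k in (
            "n_gates", "gate_width_ns", "gate_step_ns",
            "first_delay_ns", "laser_period_ns") if k in d})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateTimeline":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class IRFParams:
    """Parametrized instrument response.

    The combined response of a Gaussian laser pulse (width ``sigma``) and a
    sharp-edged detector gate of width ``w``; ``t0`` is the delay offset
    between gate clock and laser pulse.  ``amplitude`` scales the shape to
    measured counts (the shape itself carries no normalization).
    """

    sigma: float
    gate_width: float = 5.0
    t0: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.gate_width <= 0:
            raise ValueError("gate width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class DecayComponent:
    """One exponential decay component: pre-exponential amplitude and lifetime."""

    amplitude: float
    tau: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.tau <= 0:
            raise ValueError("lifetime must be > 0")


@dataclass(frozen=True)
class DecayModelSpec:
    """A multi-exponential gated decay model: components + IRF + baseline."""

    components: tuple[DecayComponent, ...]
    irf: IRFParams
    t0: float | None = None  # overrides irf.t0 when set
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.components) < 1 or len(self.components) > 4:
            raise ValueError("1 to 4 decay components supported")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    @property
    def time_offset(self) -> float:
        return self.irf.t0 if self.t0 is None else self.t0


@dataclass(frozen=True)
class LifetimePattern:
    """A fixed two-component decay signature for one fluorophore species.

    ``a1`` is the short-component amplitude fraction (pre-exponential),
    so the decay reads ``a1 * exp(-t/tau1) + (1 - a1) * exp(-t/tau2)``.
    """

    label: str
    tau1: float
    tau2: float
    a1: float

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau2):
            raise ValueError("need 0 < tau1 < tau2")
        if not (0.0 <= self.a1 <= 1.0):
            raise ValueError("a1 must be in [0, 1]")

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    @property
    def mean_lifetime(self) -> float:
        """Photon(intensity)-weighted mean lifetime in ns."""
        w1, w2 = self.a1 * self.tau1, self.a2 * self.tau2
        return (w1 * self.tau1 + w2 * self.tau2) / (w1 + w2)

    def to_dict(self) -> dict:
        return {"label": self.label, "tau1_ns": self.tau1,
                "tau2_ns": self.tau2, "a1": self.a1}

    @classmethod
    def from_dict(cls, d: dict) -> "LifetimePattern":
        return cls(label=d["label"], tau1=d["tau1_ns"],
                   tau2=d["tau2_ns"], a1=d["a1"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LifetimePattern":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GatedStack:
    """A gated photon-count hyperstack with its acquisition clock.

    ``data`` is indexed ``(gate, ..., y, x)``; leading axis is always the
    gate axis, optional intermediate axes are time and/or z.
    """

    data: np.ndarray
    timeline: GateTimeline

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 3:
            raise ValueError("stack must be at least (gate, y, x)")
        if self.data.shape[0] != self.timeline.n_gates:
            raise ValueError(
                f"gate axis has {self.data.shape[0]} pages, "
                f"timeline declares {self.timeline.n_gates} gates")

    @property
    def n_gates(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def total_counts(self) -> np.ndarray:
        """Gate-summed intensity image."""
        return self.data.sum(axis=0)

    def astype(self, dtype) -> "GatedStack":
        return GatedStack(self.data.astype(dtype), self.timeline)

    def copy(self) -> "GatedStack":
        return GatedStack(self.data.copy(), self.timeline)
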