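"""Core domain containers.

Everything is stored internally in SI units (m, Pa, s, N); file readers
convert from the μm / nN / min columns conventional in the source
instruments (see :mod:`cellmech.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "SLSParams",
    "CreepRecord",
    "SLSFit",
    "InstrumentConfig",
    "IndentationCurve",
    "HertzFit",
    "Trajectory",
    "ChemotaxisMetrics",
    "WoundSeries",
    "NoiseSpec",
    "WalkSpec",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SLSParams:
    """Standard linear solid parameter triplet.

    The model is a spring ``k1`` in parallel with a Maxwell arm
    (spring ``k2`` in series with a dashpot ``mu``): an instantaneous
    elastic jump followed by exponential creep toward a plateau set by
    ``k1`` alone.

    Parameters
    ----------
    k1, k2 : float
        Elastic moduli, Pa. Must be positive.
    mu : float
        Viscous coefficient, Pa·s. Must be positive.
    """

    k1: float
    k2: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "mu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def time_constant(self) -> float:
        """Creep e-folding time τ = μ(k1+k2)/(k1·k2), seconds."""
        return self.mu * (self.k1 + self.k2) / (self.k1 * self.k2)

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.mu])


@dataclass
class CreepRecord:
    """One micropipette-aspiration experiment.

    Attributes
    ----------
    delta_p : float
        Aspiration pressure ΔP, Pa (> 0).
    rp : float
        Pipette radius, m (> 0); a ~7 μm pipette diameter gives 3.5e-6.
    times : ndarray
        Sample times, s, strictly increasing, first element >= 0.
    lengths : ndarray
        Aspirated tongue length L(t), m, same count as ``times``.
    meta : dict
        Free-form sidecar (ground truth for synthetic records, seeds,
        source file, ...). Never consulted by fitting code.
    """

    delta_p: float
    rp: float
    times: np.ndarray
    lengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_p) or self.delta_p <= 0:
            raise InvalidParameterError(f"delta_p must be > 0, got {self.delta_p!r}")
        if not np.isfinite(self.rp) or self.rp <= 0:
            raise InvalidParameterError(f"rp must be > 0, got {self.rp!r}")
        self.times = _as_1d(self.times, "times")
        self.lengths = _as_1d(self.lengths, "lengths")
        if self.times.size != self.lengths.size:
            raise DomainError(
                f"times ({self.times.size}) and lengths ({self.lengths.size}) differ in length"
            )
        if self.times.size < 4:
            raise InsufficientDataError(
                f"need >= 4 samples to identify 3 parameters, got {self.times.size}"
            )
        if self.times[0] < 0:
            raise DomainError(f"first time must be >= 0, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            i = int(np.argmax(np.diff(self.times) <= 0))
            raise DomainError(f"times must be strictly increasing (violated at sample {i + 1})")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SLSFit:
    """Result of fitting the SLS creep model to one record."""

    params: Optional[SLSParams]
    residual_rms: float
    converged: bool
    method: str
    covariance_diag: Optional[np.ndarray] = None
    message: str = ""


@dataclass(frozen=True)
class InstrumentConfig:
    """Ferrule-top nanoindenter constants.

    Defaults follow the probe used throughout: cantilever spring constant
    0.048 N/m, 9 μm spherical tip, depth-controlled 5 μm indents with a
    2 s load/unload period. Whether the quoted "9 μm" tip is a radius or
    a diameter is ambiguous in practice, so the radius is an explicit
    setting; :meth:`with_tip_diameter` gives the 4.5 μm-radius reading.
    """

    spring_constant: float = 0.048  # N/m
    tip_radius: float = 9e-6  # m
    max_depth: float = 5e-6  # m
    load_period: float = 2.0  # s

    def __post_init__(self) -> None:
        for name in ("spring_constant", "tip_radius", "max_depth", "load_period"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def with_tip_diameter(cls, diameter: float = 9e-6, **kw) -> "InstrumentConfig":
        """Alternate preset reading the quoted tip size as a diameter."""
        return cls(tip_radius=diameter / 2.0, **kw)


@dataclass
class IndentationCurve:
    """One indentation recording.

    ``mode="raw"``: ``x`` is piezo displacement z (m), ``y`` is cantilever
    deflection d (m). ``mode="reduced"``: ``x`` is the tip advance
    coordinate (m; indentation depth is ``x - x[contact]``), ``y`` is load
    F (N). Reduction: F = k·d, δ = z − d.
    """

    mode: str
    x: np.ndarray
    y: np.ndarray
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "reduced"):
            raise ConfigError(f"mode must be 'raw' or 'reduced', got {self.mode!r}")
        self.x = _as_1d(self.x, "x")
        self.y = _as_1d(self.y, "y")
        if self.x.size != self.y.size:
            raise DomainError("x and y must have equal length")
        if self.x.size < 20:
            raise InsufficientDataError(
                f"indentation curves need >= 20 samples, got {self.x.size}"
            )

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass
class HertzFit:
    """Result of a Hertz spherical-contact fit to one loading curve."""

    e_reduced: float  # Pa
    contact_index: int
    baseline_force: float  # N
    residual_rms: float  # N
    converged: bool
    fit_depth_range: tuple = (0.0, 0.0)  # m
    message: str = ""


@dataclass
class Trajectory:
    """One cell's timestamped planar path in a chemotaxis channel.

    Positions are in μm, times in seconds; ``gradient_axis`` is a unit
    vector pointing toward the chemoattractant source (+x by the usual
    channel convention).
    """

    cell_id: str
    times: np.ndarray  # s
    xs: np.ndarray  # μm
    ys: np.ndarray  # μm
    gradient_axis: tuple = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        self.xs = _as_1d(self.xs, "xs")
        self.ys = _as_1d(self.ys, "ys")
        if not (self.times.size == self.xs.size == self.ys.size):
            raise DomainError("times, xs, ys must have equal length")
        if self.times.size < 2:
            raise InsufficientDataError("a trajectory needs >= 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError(
                f"trajectory {self.cell_id!r}: times must be strictly increasing "
                "(duplicate or reordered timestamps)"
            )
        ax = np.asarray(self.gradient_axis, dtype=float)
        norm = float(np.hypot(ax[0], ax[1]))
        if norm == 0:
            raise ConfigError("gradient_axis must be a nonzero vector")
        self.gradient_axis = (ax[0] / norm, ax[1] / norm)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ChemotaxisMetrics:
    """Per-cell motility summary. ``velocity`` is curvilinear speed."""

    velocity: float  # μm/min
    directionality: float  # dimensionless, in [-1, 1]
    path_length: float  # μm
    net_displacement: float  # μm


@dataclass
class WoundSeries:
    """Wound planimetry time course: observation days and areas (mm²)."""

    days: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.days = _as_1d(self.days, "days")
        self.areas = _as_1d(self.areas, "areas")
        if self.days.size != self.areas.size:
            raise DomainError("days and areas must have equal length")
        if self.days.size == 0:
            raise InsufficientDataError("empty wound series")
        if self.days[0] != 0:
            raise DomainError(f"first observation must be day 0, got day {self.days[0]}")
        if np.any(self.areas < 0):
            raise DomainError("areas must be >= 0")
        if self.areas[0] <= 0:
            raise DomainError("day-0 area must be > 0 (closure is relative to it)")


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded measurement-noise description for the generators.

    ``scale`` is a fraction of the signal ceiling for both kinds:
    additive noise has standard deviation scale×ceiling everywhere,
    multiplicative noise perturbs each sample by N(0, scale) relative
    to its own value.
    """

    kind: str = "additive_gaussian"
    scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ConfigError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.scale) or self.scale < 0:
            raise ConfigError(f"noise scale must be >= 0, got {self.scale!r}")

    def apply(self, values: np.ndarray, ceiling: float, rng: np.random.Generator) -> np.ndarray:
        """Return a noisy copy of ``values``; draws nothing when scale is 0."""
        values = np.asarray(values, dtype=float)
        if self.scale == 0:
            return values.copy()
        if self.kind == "additive_gaussian":
            return values + rng.normal(0.0, self.scale * abs(ceiling), size=values.shape)
        return values * (1.0 + rng.normal(0.0, self.scale, size=values.shape))


@dataclass(frozen=True)
class WalkSpec:
    """Biased persistent random-walk settings for synthetic trajectories.

    ``speed_scale`` is the target curvilinear speed (μm/min);
    ``drift_fraction`` splits each step between deterministic drift along
    the gradient axis and the persistent random component;
    ``persistence`` is the first-order autoregressive coefficient of the
    random velocity (0 = memoryless, → 1 = straight runs).
    """

    step_time: float = 180.0  # s (one frame every 3 min)
    duration: float = 21600.0  # s (6 h recording)
    speed_scale: float = 1.0  # μm/min
    drift_fraction: float = 0.3
    persistence: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_time <= 0 or self.duration <= 0:
            raise ConfigError("step_time and duration must be > 0")
        if self.speed_scale < 0:
            raise ConfigError("speed_scale must be >= 0")
        if not 0 <= self.drift_fraction <= 1:
            raise ConfigError("drift_fraction must lie in [0, 1]")
        if not 0 <= self.persistence < 1:
            raise ConfigError("persistence must lie in [0, 1)")
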