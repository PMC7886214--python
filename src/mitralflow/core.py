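"""Shared domain containers for the transmitral-flow analysis pipeline.

Conventions used throughout the package:

* Velocity fields are stored row-major, ``u[row, col]``; ``x`` indexes
  columns and ``y`` indexes rows.  ``y`` may ascend or descend with row
  index (image-derived fields have y decreasing with row, since image
  row 0 is the top of the frame and the physical y axis points up);
  finite differences use the signed node step, so either orientation is
  valid.
* ``mask`` marks nodes inside the analysis domain (True = included);
  ``valid`` marks vectors that passed outlier validation.
* Units are SI unless a field name says otherwise (pressures in mmHg,
  stroke volumes in mL — the clinical units of the quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from typing import Optional

import numpy as np

__all__ = [
    "FluidProps",
    "BeatSpec",
    "FlowSpec",
    "ImagingSpec",
    "VelocityField",
    "ParticleImagePair",
    "PressureTrace",
    "DopplerEnvelope",
    "VEDSeries",
    "VEDPeaks",
    "GorlinInputs",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a spec object violates its invariants."""


@dataclass(frozen=True)
class FluidProps:
    """Working-fluid properties.

    The blood analogue used by the pulse duplicator is a water/glycerol
    mixture with dynamic viscosity 4.2 cP and density 1100 kg/m^3; those
    are the defaults.
    """

    dynamic_viscosity: float = 4.2e-3  # Pa*s
    density: float = 1100.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (self.dynamic_viscosity > 0 and self.density > 0):
            raise ConfigurationError("viscosity and density must be positive")


@dataclass(frozen=True)
class BeatSpec:
    """One cardiac cycle of the duplicator's activation waveform.

    Diastolic inflow is a two-lobed waveform: a passive early-filling
    E wave followed by an active atrial-contraction A wave.  Lobes are
    raised cosines placed by onset/width fractions of the cycle; the A
    lobe may wrap past the end of the cycle, so its crest and decaying
    remnant appear at the start of the next cycle (as in the measured
    dissipation traces, whose first peak is the leftover A wave).

    Default timing puts the E crest at 0.59 of the cycle and the A crest
    just after cycle start; rest and exercise presets carry the pump
    settings (70 bpm / 60.08 mL and 110 bpm / 90.13 mL).
    """

    heart_rate: float = 70.0  # beats/min
    stroke_volume_ml: float = 60.08  # mL/beat
    e_onset: float = 0.47  # cycle fraction where the E lobe starts
    e_wave_fraction: float = 0.24  # E lobe width, cycle fraction
    a_onset: float = 0.92  # cycle fraction where the A lobe starts
    a_wave_fraction: float = 0.18  # A lobe width, cycle fraction
    e_a_ratio: float = 1.5  # peak-velocity ratio E/A
    condition: str = "rest"

    def __post_init__(self) -> None:
        if self.heart_rate <= 0 or self.stroke_volume_ml <= 0:
            raise ConfigurationError("heart_rate and stroke_volume must be positive")
        for f in (self.e_wave_fraction, self.a_wave_fraction):
            if not 0 < f < 1:
                raise ConfigurationError("wave fractions must lie in (0, 1)")
        if self.e_a_ratio <= 0:
            raise ConfigurationError("e_a_ratio must be positive")
        if self._lobes_overlap():
            raise ConfigurationError("E and A lobes overlap")

    def _lobes_overlap(self) -> bool:
        # Compare on the circle: sample both indicator functions.
        ph = np.linspace(0.0, 1.0, 2048, endpoint=False)
        in_e = ((ph - self.e_onset) % 1.0) < self.e_wave_fraction
        in_a = ((ph - self.a_onset) % 1.0) < self.a_wave_fraction
        return bool(np.any(in_e & in_a))

    @property
    def period_s(self) -> float:
        """Cycle period in seconds (60 / heart rate)."""
        return 60.0 / self.heart_rate

    @property
    def diastolic_fraction(self) -> float:
        """Fraction of the cycle from E-lobe onset to A-lobe end (flow period)."""
        return ((self.a_onset + self.a_wave_fraction) - self.e_onset) % 1.0

    def waveform(self, phase: np.ndarray) -> np.ndarray:
        """Dimensionless inflow waveform at cycle phase(s) in [0, 1).

        Raised-cosine lobes; E-lobe amplitude ``e_a_ratio``, A-lobe
        amplitude 1.  Scaling to physical velocity is left to callers.
        """
        phase = np.asarray(phase, dtype=float) % 1.0
        out = np.zeros_like(phase)
        for onset, frac, amp in (
            (self.e_onset, self.e_wave_fraction, self.e_a_ratio),
            (self.a_onset, self.a_wave_fraction, 1.0),
        ):
            s = ((phase - onset) % 1.0) / frac
            lobe = np.where(s < 1.0, 0.5 * (1.0 - np.cos(2.0 * np.pi * s)), 0.0)
            out = out + amp * lobe
        return out

    def waveform_mean(self) -> float:
        """Cycle-average of :meth:`waveform` (closed form)."""
        # A raised-cosine lobe of width f and amplitude a has mean a*f/2.
        return 0.5 * (
            self.e_a_ratio * self.e_wave_fraction + self.a_wave_fraction
        )

    @classmethod
    def rest(cls, **kw) -> "BeatSpec":
        return cls(heart_rate=70.0, stroke_volume_ml=60.08, condition="rest", **kw)

    @classmethod
    def exercise(cls, **kw) -> "BeatSpec":
        return cls(heart_rate=110.0, stroke_volume_ml=90.13, condition="exercise", **kw)


_FLOW_MODELS = ("uniform", "solid_rotation", "pure_shear", "lamb_oseen", "transmitral_jet")


@dataclass(frozen=True)
class FlowSpec:
    """Kinematic prescription of a planar velocity field on a uniform grid."""

    model: str
    params: dict = _field(default_factory=dict)
    grid_shape: tuple = (64, 64)  # (rows, cols)
    grid_spacing: float = 1.0e-3  # m per node
    mask: Optional[np.ndarray] = None  # True = inside the domain

    def __post_init__(self) -> None:
        if self.model not in _FLOW_MODELS:
            raise ConfigurationError(
                f"unknown flow model {self.model!r}; expected one of {_FLOW_MODELS}"
            )
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if len(self.grid_shape) != 2 or any(int(n) < 2 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be (rows, cols) with each >= 2")
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise ConfigurationError(f"parameter {k!r} is not finite")
        if self.mask is not None and tuple(self.mask.shape) != tuple(self.grid_shape):
            raise ConfigurationError("mask shape must equal grid_shape")


@dataclass(frozen=True)
class ImagingSpec:
    """Synthetic particle-imaging parameters.

    Defaults mirror the duplicator camera: 1632 x 1200 px at 1000 fps,
    ~50 um polyamide tracers rendered as Gaussian blobs about 3 px wide.
    """

    image_shape: tuple = (1200, 1632)  # (rows, cols) px
    magnification: float = 5.0e-5  # m per px
    frame_interval: float = 1.0e-3  # s between exposures (1000 fps)
    particle_density: float = 0.02  # particles per px^2
    particle_diameter: float = 3.0  # e^-2 intensity diameter, px
    peak_intensity: float = 200.0  # gray levels at blob centre
    noise_sd: float = 0.0  # additive Gaussian noise, gray levels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnification <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("magnification and frame_interval must be positive")
        if self.particle_diameter < 1.0:
            raise ConfigurationError("particle_diameter must be >= 1 px")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class VelocityField:
    """Planar velocity field on a uniform rectangular grid."""

    u: np.ndarray  # m/s, shape (rows, cols)
    v: np.ndarray  # m/s
    x: np.ndarray  # node x coordinates, m, shape (cols,)
    y: np.ndarray  # node y coordinates, m, shape (rows,)
    spacing: float  # m between adjacent nodes
    mask: Optional[np.ndarray] = None  # True = inside domain
    valid: Optional[np.ndarray] = None  # True = vector passed validation

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")
        if self.mask is None:
            self.mask = np.ones(self.u.shape, dtype=bool)
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        for name, arr in (("mask", self.mask), ("valid", self.valid)):
            if arr.shape != self.u.shape:
                raise ValueError(f"{name} shape must match u")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.u.shape

    @property
    def included(self) -> np.ndarray:
        """Nodes that enter integrals: inside the mask and validated."""
        return self.mask & self.valid

    def copy(self) -> "VelocityField":
        return VelocityField(
            self.u.copy(), self.v.copy(), self.x.copy(), self.y.copy(),
            self.spacing, self.mask.copy(), self.valid.copy(),
        )


@dataclass
class ParticleImagePair:
    """Two grayscale exposures of the same tracer particles."""

    frame_a: np.ndarray
    frame_b: np.ndarray
    frame_interval: float  # s
    magnification: float  # m per px

    def __post_init__(self) -> None:
        self.frame_a = np.asarray(self.frame_a, dtype=float)
        self.frame_b = np.asarray(self.frame_b, dtype=float)
        if self.frame_a.shape != self.frame_b.shape:
            raise ValueError("frames must share a shape")
        if self.frame_interval <= 0 or self.magnification <= 0:
            raise ValueError("frame_interval and magnification must be positive")


@dataclass
class PressureTrace:
    """Uniformly sampled pressure signal (mmHg). Default clock: 4 ms."""

    t: np.ndarray  # s
    p: np.ndarray  # mmHg
    site: str = "LA"  # "LA" or "LV"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape or self.t.ndim != 1:
            raise ValueError("t and p must be 1-D and equal length")
        dt = np.diff(self.t)
        if self.t.size >= 2 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("t must be strictly increasing with uniform step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class DopplerEnvelope:
    """Maximal-velocity envelope from continuous-wave Doppler (m/s)."""

    t: np.ndarray  # s
    v: np.ndarray  # m/s, >= 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D and equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.v < 0):
            raise ValueError("envelope velocities must be non-negative")


@dataclass
class VEDSeries:
    """Instantaneous viscous energy dissipation versus time (W/m)."""

    t: np.ndarray  # s
    ved: np.ndarray  # W per m of out-of-plane depth
    cycle_period: float  # s
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ved = np.asarray(self.ved, dtype=float)
        if self.t.shape != self.ved.shape or self.t.ndim != 1:
            raise ValueError("t and ved must be 1-D and equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.ved < -1e-12):
            raise ValueError("ved must be non-negative")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")


@dataclass(frozen=True)
class VEDPeaks:
    """The two diastolic dissipation peaks of one cycle."""

    first_peak_value: float  # W/m
    first_peak_time: float  # s
    second_peak_value: float  # W/m
    second_peak_time: float  # s


@dataclass(frozen=True)
class GorlinInputs:
    """Inputs to the Gorlin hydraulic valve-area formula.

    Cardiac output is heart_rate * stroke_volume in mL/min; with the
    mitral constant 0.85 and the Gorlin factor 44.3 the result is in
    cm^2.
    """

    heart_rate: float  # beats/min
    stroke_volume_ml: float  # mL/beat
    flow_period_s: float  # s of diastolic flow per beat
    mean_gradient_mmhg: float  # mmHg
    constant: float = 0.85
    factor: float = 44.3

    def __post_init__(self) -> None:
        vals = (
            self.heart_rate, self.stroke_volume_ml, self.flow_period_s,
            self.mean_gradient_mmhg, self.constant, self.factor,
        )
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all Gorlin inputs must be positive")
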