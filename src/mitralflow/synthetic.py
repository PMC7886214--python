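"""Synthetic stand-ins for the pulse-duplicator measurements.

The physical rig produces three kinds of raw data: particle images of a
seeded water/glycerol blood analogue, fiberoptic left-atrial and
left-ventricular pressure traces, and continuous-wave Doppler velocity
envelopes.  This module generates all three with the statistical and
physiological structure the downstream analysis assumes, so the whole
pipeline is testable on a desk.

Flow fields are kinematic prescriptions (no Navier-Stokes solve): a set
of analytic models with known velocity gradients, including a
transmitral jet whose amplitude follows the two-lobed E/A activation
waveform and whose time-integrated inflow matches the pump stroke
volume.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import (
    BeatSpec,
    ConfigurationError,
    DopplerEnvelope,
    FlowSpec,
    ImagingSpec,
    ParticleImagePair,
    PressureTrace,
    VelocityField,
)

__all__ = [
    "make_flow_field",
    "make_flow_series",
    "jet_velocity_scale",
    "integrated_inflow_volume_ml",
    "render_particle_pair",
    "make_pressure_traces",
    "make_doppler_envelope",
]

# Diastolic LV baseline and systolic LV crest of the canonical pressure
# shapes (mmHg).  Only the diastolic LA-LV difference is contractually
# meaningful; the rest is morphology.
_LV_BASELINE = 5.0
_LV_SYSTOLIC_PEAK = 120.0
# Floor of the E/A modulation of the diastolic gradient, as a fraction
# of its mean; keeps LA above LV throughout diastole.
_GRADIENT_FLOOR = 0.15


def _grid(spec: FlowSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    rows, cols = spec.grid_shape
    x = np.arange(cols) * spec.grid_spacing
    y = np.arange(rows) * spec.grid_spacing
    xx, yy = np.meshgrid(x, y)
    return x, y, xx, yy


def make_flow_field(spec: FlowSpec, amplitude: float = 1.0) -> VelocityField:
    """Sample an analytic velocity model at the grid nodes.

    Parameters
    ----------
    spec
        Model, parameters, and grid geometry.
    amplitude
        Scale factor applied to the whole field (used by
        :func:`make_flow_series` to modulate the jet over the cycle).

    Models and their parameters
    ---------------------------
    uniform          : ``u``, ``v`` (m/s)
    solid_rotation   : ``omega`` (rad/s), optional ``center`` (m, m)
    pure_shear       : ``gamma`` (1/s); u = gamma * y, v = 0
    lamb_oseen       : ``circulation`` (m^2/s), ``core_radius`` (m),
                       optional ``center``
    transmitral_jet  : ``width`` (m, e^-2 jet width), ``peak_velocity``
                       (m/s), optional ``x_center`` (m)
    """
    x, y, xx, yy = _grid(spec)
    p = spec.params
    if spec.model == "uniform":
        u = np.full(spec.grid_shape, float(p.get("u", 0.0)))
        v = np.full(spec.grid_shape, float(p.get("v", 0.0)))
    elif spec.model == "solid_rotation":
        omega = float(p["omega"])
        cx, cy = p.get("center", (x.mean(), y.mean()))
        u = -omega * (yy - cy)
        v = omega * (xx - cx)
    elif spec.model == "pure_shear":
        gamma = float(p["gamma"])
        u = gamma * yy
        v = np.zeros(spec.grid_shape)
    elif spec.model == "lamb_oseen":
        gamma_c = float(p["circulation"])
        rc = float(p["core_radius"])
        cx, cy = p.get("center", (x.mean(), y.mean()))
        dx, dy = xx - cx, yy - cy
        r2 = dx * dx + dy * dy
        # (1 - exp(-r^2/rc^2)) / r^2 -> 1/rc^2 as r -> 0
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(r2 > 0, -np.expm1(-r2 / rc**2) / np.where(r2 > 0, r2, 1.0), 1.0 / rc**2)
        u = -gamma_c / (2.0 * np.pi) * dy * f
        v = gamma_c / (2.0 * np.pi) * dx * f
    elif spec.model == "transmitral_jet":
        width = float(p["width"])
        v0 = float(p.get("peak_velocity", 1.0))
        # default centreline on a grid node so the sampled peak equals the
        # analytic peak (volume bookkeeping reads the spatial maximum)
        xc = float(p.get("x_center", x[(len(x) - 1) // 2]))
        sigma = width / 4.0  # e^-2 full width equals `width`
        profile = np.exp(-((xx - xc) ** 2) / (2.0 * sigma**2))
        u = np.zeros(spec.grid_shape)
        v = -v0 * profile  # jet enters from the top, flowing in -y
    else:  # pragma: no cover - guarded by FlowSpec validation
        raise ConfigurationError(f"unknown flow model {spec.model!r}")
    u = amplitude * u
    v = amplitude * v
    return VelocityField(u=u, v=v, x=x, y=y, spacing=spec.grid_spacing,
                         mask=None if spec.mask is None else spec.mask.copy())


def jet_velocity_scale(spec: FlowSpec, beat: BeatSpec) -> float:
    """Peak jet velocity (m/s) that makes the cycle inflow equal the stroke volume.

    The jet's Gaussian cross profile is read as an axisymmetric orifice
    velocity profile, giving an effective orifice area of 2*pi*sigma^2
    with sigma = width/4; volumetric inflow is that area times the
    instantaneous centreline velocity.  The activation waveform has a
    closed-form cycle mean, so the scale is exact.
    """
    if spec.model != "transmitral_jet":
        raise ConfigurationError("jet_velocity_scale requires the transmitral_jet model")
    sigma = float(spec.params["width"]) / 4.0
    area_eff = 2.0 * np.pi * sigma**2  # m^2
    sv_m3 = beat.stroke_volume_ml * 1e-6
    return sv_m3 / (area_eff * beat.period_s * beat.waveform_mean())


def make_flow_series(spec: FlowSpec, beat: BeatSpec, n_frames: int) -> List[VelocityField]:
    """One cardiac cycle of transmitral-jet fields, frame t at phase t/n.

    The jet amplitude follows the E/A activation waveform; the scale is
    set so the time-integrated inflow volume equals the beat's stroke
    volume (see :func:`jet_velocity_scale`).
    """
    if spec.model != "transmitral_jet":
        raise ConfigurationError("make_flow_series requires the transmitral_jet model")
    if n_frames < 2:
        raise ConfigurationError("need at least 2 frames")
    scale = jet_velocity_scale(spec, beat)
    phases = np.arange(n_frames) / n_frames
    amps = scale * beat.waveform(phases)
    base = FlowSpec(model="transmitral_jet",
                    params={**spec.params, "peak_velocity": 1.0},
                    grid_shape=spec.grid_shape, grid_spacing=spec.grid_spacing,
                    mask=spec.mask)
    return [make_flow_field(base, amplitude=a) for a in amps]


def integrated_inflow_volume_ml(fields: List[VelocityField], spec: FlowSpec,
                                beat: BeatSpec) -> float:
    """Cycle inflow volume (mL) measured from the sampled fields.

    Reads the spatial-peak jet speed of each frame, converts to
    volumetric rate through the effective orifice area, and integrates
    over the cycle treating the frames as uniform phase samples
    (periodic rectangle rule).
    """
    sigma = float(spec.params["width"]) / 4.0
    area_eff = 2.0 * np.pi * sigma**2
    peak_speed = np.array([np.abs(f.v).max() for f in fields])
    dt = beat.period_s / len(fields)
    return float(np.sum(peak_speed) * area_eff * dt * 1e6)


# ---------------------------------------------------------------------------
# particle images
# ---------------------------------------------------------------------------

def _sample_velocity_px(field: VelocityField, rows: np.ndarray, cols: np.ndarray,
                        imaging: ImagingSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Velocity (m/s) at particle pixel positions, bilinear in the field grid.

    Pixel (row, col) maps to physical (x, y) with x = col * magnification
    and y = (n_rows - 1 - row) * magnification: image row 0 is the top of
    the frame and physical y points up.  Positions outside the field grid
    take the nearest edge value.
    """
    h = imaging.image_shape[0]
    x_p = cols * imaging.magnification
    y_p = (h - 1 - rows) * imaging.magnification

    def interp(component: np.ndarray) -> np.ndarray:
        ys, xs = field.y, field.x
        comp = component
        if ys[0] > ys[-1]:
            ys = ys[::-1]
            comp = comp[::-1, :]
        yq = np.clip(y_p, ys[0], ys[-1])
        xq = np.clip(x_p, xs[0], xs[-1])
        itp = RegularGridInterpolator((ys, xs), comp, method="linear")
        return itp(np.column_stack([yq, xq]))

    return interp(field.u), interp(field.v)


def _render_particles(shape: Tuple[int, int], rows: np.ndarray, cols: np.ndarray,
                      diameter: float, peak: float) -> np.ndarray:
    """Accumulate Gaussian blobs (e^-2 diameter = `diameter`) into an image."""
    img = np.zeros(shape, dtype=float)
    sigma = diameter / 4.0
    rad = max(2, int(math.ceil(3.0 * sigma)))
    offs = np.arange(-rad, rad + 1)
    r0 = np.round(rows).astype(int)
    c0 = np.round(cols).astype(int)
    # stamp pixel coordinates for every particle: (n, k)
    rr = r0[:, None] + offs[None, :]
    cc = c0[:, None] + offs[None, :]
    gr = np.exp(-((rr - rows[:, None]) ** 2) / (2.0 * sigma**2))
    gc = np.exp(-((cc - cols[:, None]) ** 2) / (2.0 * sigma**2))
    stamp = peak * gr[:, :, None] * gc[:, None, :]  # (n, k, k)
    # zero out stamp pixels that fall outside the frame (no edge pile-up)
    inb = ((rr[:, :, None] >= 0) & (rr[:, :, None] < shape[0])
           & (cc[:, None, :] >= 0) & (cc[:, None, :] < shape[1]))
    stamp = stamp * inb
    rr = np.clip(rr, 0, shape[0] - 1)
    cc = np.clip(cc, 0, shape[1] - 1)
    flat = rr[:, :, None] * shape[1] + cc[:, None, :]
    np.add.at(img.ravel(), flat.ravel(), stamp.ravel())
    return img


def render_particle_pair(field: VelocityField, imaging: ImagingSpec,
                         max_displacement_px: float = 4.0) -> ParticleImagePair:
    """Render two exposures of tracer particles advected by ``field``.

    Frame A seeds particles uniformly at the configured density; frame B
    shows the same particles displaced by the local velocity times the
    frame interval.  Particles advected off the frame are dropped and no
    new particles are injected between exposures.

    Raises
    ------
    ConfigurationError
        If any particle displacement exceeds ``max_displacement_px``
        (one quarter of the 16 px final interrogation window by
        default), naming the offending maximum.
    """
    h, w = imaging.image_shape
    rng = np.random.default_rng(imaging.seed)
    n = rng.poisson(imaging.particle_density * h * w)
    rows = rng.uniform(0, h, size=n)
    cols = rng.uniform(0, w, size=n)

    u, v = _sample_velocity_px(field, rows, cols, imaging)
    dcols = u * imaging.frame_interval / imaging.magnification
    drows = -v * imaging.frame_interval / imaging.magnification
    disp = np.hypot(dcols, drows)
    if disp.size and disp.max() > max_displacement_px:
        raise ConfigurationError(
            f"maximum particle displacement {disp.max():.2f} px exceeds the "
            f"{max_displacement_px:.2f} px quarter-window rule"
        )

    frame_a = _render_particles((h, w), rows, cols,
                                imaging.particle_diameter, imaging.peak_intensity)
    rows_b = rows + drows
    cols_b = cols + dcols
    keep = (rows_b >= 0) & (rows_b < h) & (cols_b >= 0) & (cols_b < w)
    frame_b = _render_particles((h, w), rows_b[keep], cols_b[keep],
                                imaging.particle_diameter, imaging.peak_intensity)
    if imaging.noise_sd > 0:
        frame_a = frame_a + rng.normal(0.0, imaging.noise_sd, size=(h, w))
        frame_b = frame_b + rng.normal(0.0, imaging.noise_sd, size=(h, w))
    np.clip(frame_a, 0.0, None, out=frame_a)
    np.clip(frame_b, 0.0, None, out=frame_b)
    return ParticleImagePair(frame_a, frame_b, imaging.frame_interval,
                             imaging.magnification)


# ---------------------------------------------------------------------------
# pressure traces and Doppler envelopes
# ---------------------------------------------------------------------------

def _raised_cosine(s: np.ndarray) -> np.ndarray:
    return np.where((s >= 0) & (s < 1), 0.5 * (1.0 - np.cos(2.0 * np.pi * s)), 0.0)


def make_pressure_traces(beat: BeatSpec, diastolic_offset: float,
                         noise_sd: float = 0.0, seed: int = 0,
                         n_cycles: int = 3, dt: float = 0.004,
                         ) -> Tuple[PressureTrace, PressureTrace]:
    """Simultaneous LA and LV pressure traces (mmHg) on a 4 ms clock.

    During diastole (E-lobe onset to A-lobe end) LA exceeds LV by
    ``diastolic_offset`` on time average, modulated by the E/A waveform
    with a positive floor so the gradient never reverses mid-diastole.
    During systole LV rises to ~120 mmHg while LA shows a small v wave
    below the LV baseline, so the pressure crossover delimits diastole
    exactly.
    """
    if diastolic_offset < 0:
        raise ConfigurationError("diastolic_offset must be non-negative")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    t = np.arange(0.0, n_cycles * beat.period_s, dt)
    phase = (t / beat.period_s) % 1.0

    d_frac = beat.diastolic_fraction
    in_diastole = ((phase - beat.e_onset) % 1.0) < d_frac

    # E/A modulation with unit time-average over diastole
    w = beat.waveform(phase)
    # continuous-time mean of the waveform over the diastolic span
    w_mean_d = beat.waveform_mean() / d_frac
    m = _GRADIENT_FLOOR + (1.0 - _GRADIENT_FLOOR) * w / w_mean_d

    lv = np.full_like(t, _LV_BASELINE)
    # systole = complement of diastole; raised-cosine contraction bump
    sys_start = (beat.e_onset + d_frac) % 1.0
    s = ((phase - sys_start) % 1.0) / (1.0 - d_frac)
    systolic_bump = _raised_cosine(s) * (~in_diastole)
    lv = lv + (_LV_SYSTOLIC_PEAK - _LV_BASELINE) * systolic_bump

    la = np.where(in_diastole,
                  _LV_BASELINE + diastolic_offset * m,
                  _LV_BASELINE - 1.0 + 0.5 * systolic_bump)  # v wave, stays below LV

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        la = la + rng.normal(0.0, noise_sd, size=t.shape)
        lv = lv + rng.normal(0.0, noise_sd, size=t.shape)
    return PressureTrace(t, la, site="LA"), PressureTrace(t, lv, site="LV")


def make_doppler_envelope(beat: BeatSpec, e_peak: float, a_peak: float,
                          n_cycles: int = 1, sample_rate: float = 250.0,
                          ) -> DopplerEnvelope:
    """Half-sine E then half-sine A velocity lobes within diastole (m/s).

    Zero outside the lobes; sampled at ``sample_rate`` (default 250 Hz,
    the 4 ms clock of the pressure system).
    """
    if e_peak < 0 or a_peak < 0:
        raise ConfigurationError("peak velocities must be non-negative")
    t = np.arange(0.0, n_cycles * beat.period_s, 1.0 / sample_rate)
    phase = (t / beat.period_s) % 1.0
    v = np.zeros_like(t)
    for onset, frac, peak in ((beat.e_onset, beat.e_wave_fraction, e_peak),
                              (beat.a_onset, beat.a_wave_fraction, a_peak)):
        s = ((phase - onset) % 1.0) / frac
        lobe = np.where(s < 1.0, np.sin(np.pi * np.clip(s, 0.0, 1.0)), 0.0)
        v = v + peak * lobe
    return DopplerEnvelope(t, v)
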