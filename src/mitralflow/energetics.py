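"""Viscous energy dissipation (VED) of planar velocity fields.

The instantaneous dissipation rate per unit out-of-plane depth is

    VED = (mu/2) * integral over A of  sum_{i,j} (du_i/dx_j + du_j/dx_i)^2  dA

with the sum over all ordered index pairs (i, j) of the two in-plane
directions.  Expanded, the integrand is the standard two-dimensional
dissipation function

    Phi = 2 mu (u_x^2 + v_y^2) + mu (u_y + v_x)^2        [W/m^3 * m = W/m^2]

so VED carries units of W per metre of depth.  Velocity gradients are
second-order central differences, falling back to second-order
one-sided stencils at grid and mask edges; the area integral uses
trapezoidal weights with masked or invalid nodes excluded.

TVED is the time integral of VED over a fixed duration (1 s by
convention), with the series extended periodically by the cycle period
when the duration exceeds the recorded span — needed because one second
exceeds both the rest (60/70 s) and the exercise (60/110 s) cycle.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import FluidProps, VEDPeaks, VEDSeries, VelocityField

__all__ = [
    "dissipation_density",
    "ved_instant",
    "ved_series",
    "tved",
    "detect_peaks",
    "anova_recordings",
]

#: Default peak-search windows as fractions of the cycle: the first
#: catches the remnant of the previous A wave just after cycle start,
#: the second the E-wave crest in mid-to-late diastole.
DEFAULT_FIRST_WINDOW = (0.0, 0.15)
DEFAULT_SECOND_WINDOW = (0.45, 0.65)


def _shift(a: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Shift with NaN fill; result[i] = a[i + n] along ``axis``."""
    out = np.full_like(a, np.nan)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if n > 0:
        src[axis] = slice(n, None)
        dst[axis] = slice(None, -n)
    elif n < 0:
        src[axis] = slice(None, n)
        dst[axis] = slice(-n, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_gradient(f: np.ndarray, ok: np.ndarray, h: float, axis: int) -> np.ndarray:
    """d f / d coordinate along ``axis`` with signed node step ``h``.

    Central difference where both neighbors are usable; second-order
    one-sided where two consecutive neighbors on one side are; NaN where
    neither stencil applies (fewer than two usable neighbors).
    """
    f = np.where(ok, f, np.nan)
    fp = _shift(f, 1, axis)
    fm = _shift(f, -1, axis)
    fpp = _shift(f, 2, axis)
    fmm = _shift(f, -2, axis)
    central = (fp - fm) / (2.0 * h)
    fwd = (-3.0 * f + 4.0 * fp - fpp) / (2.0 * h)
    bwd = (3.0 * f - 4.0 * fm + fmm) / (2.0 * h)
    g = np.where(np.isfinite(central), central,
                 np.where(np.isfinite(fwd), fwd, bwd))
    return g


def _signed_steps(field: VelocityField) -> Tuple[float, float]:
    hx = float(field.x[1] - field.x[0]) if field.x.size > 1 else field.spacing
    hy = float(field.y[1] - field.y[0]) if field.y.size > 1 else field.spacing
    return hx, hy


def dissipation_density(field: VelocityField, fluid: FluidProps) -> np.ndarray:
    """Pointwise dissipation function Phi (W/m^2) on the field grid.

    NaN at nodes whose gradient stencils cannot be formed (masked or
    invalid neighborhoods).
    """
    ok = field.included
    hx, hy = _signed_steps(field)
    ux = _masked_gradient(field.u, ok, hx, axis=1)
    uy = _masked_gradient(field.u, ok, hy, axis=0)
    vx = _masked_gradient(field.v, ok, hx, axis=1)
    vy = _masked_gradient(field.v, ok, hy, axis=0)
    mu = fluid.dynamic_viscosity
    return 2.0 * mu * (ux**2 + vy**2) + mu * (uy + vx) ** 2


def ved_instant(field: VelocityField, fluid: FluidProps) -> float:
    """Instantaneous viscous energy dissipation of one field (W/m).

    Trapezoidal quadrature over the node grid; masked, invalid and
    stencil-deficient nodes carry zero weight.  Raises ``ValueError``
    for grids smaller than 3 nodes per axis; an all-masked field
    returns 0 with a warning.
    """
    if field.shape[0] < 3 or field.shape[1] < 3:
        raise ValueError("ved_instant needs at least 3 nodes per axis")
    if not np.any(field.included):
        warnings.warn("all nodes masked or invalid; VED = 0", stacklevel=2)
        return 0.0
    phi = dissipation_density(field, fluid)
    wr = np.ones(field.shape[0])
    wr[0] = wr[-1] = 0.5
    wc = np.ones(field.shape[1])
    wc[0] = wc[-1] = 0.5
    weights = np.outer(wr, wc) * field.spacing**2
    usable = field.included & np.isfinite(phi)
    return float(np.sum(np.where(usable, phi * weights, 0.0)))


def ved_series(fields: Sequence[VelocityField], fluid: FluidProps,
               times: np.ndarray, cycle_period: Optional[float] = None,
               condition: str = "rest") -> VEDSeries:
    """Element-wise :func:`ved_instant` over a field sequence."""
    if len(fields) < 2:
        raise ValueError("need at least 2 frames")
    times = np.asarray(times, dtype=float)
    if times.size != len(fields):
        raise ValueError("times must match the number of fields")
    shape = fields[0].shape
    spacing = fields[0].spacing
    for f in fields[1:]:
        if f.shape != shape or not np.isclose(f.spacing, spacing):
            raise ValueError("all fields must share the grid")
    ved = np.array([ved_instant(f, fluid) for f in fields])
    if cycle_period is None:
        cycle_period = float(times[-1] - times[0] + np.median(np.diff(times)))
    return VEDSeries(t=times, ved=ved, cycle_period=cycle_period,
                     condition=condition)


def tved(series: VEDSeries, duration: float = 1.0) -> float:
    """Total viscous energy dissipation: integral of VED over ``duration`` (J/m).

    The series must cover at least one cycle; when ``duration`` exceeds
    the recorded span the series is extended periodically by its cycle
    period (linear interpolation in phase, with the first sample closing
    the cycle).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = series.t - series.t[0]
    T = series.cycle_period
    dt_med = float(np.median(np.diff(t)))
    if t[-1] < T - 1.5 * dt_med:
        raise ValueError("series must cover at least one full cycle")
    # periodic lookup table over one cycle, closed at phase T
    tp = np.concatenate([t[t < T], [T]])
    vp = np.concatenate([series.ved[t < T], [series.ved[0]]])
    n = max(int(np.ceil(duration / min(dt_med, T / 64))) + 1, 9)
    tq = np.linspace(0.0, duration, n)
    vq = np.interp(tq % T, tp, vp)
    return float(np.trapezoid(vq, tq))


def detect_peaks(series: VEDSeries,
                 first_window: Tuple[float, float] = DEFAULT_FIRST_WINDOW,
                 second_window: Tuple[float, float] = DEFAULT_SECOND_WINDOW,
                 ) -> VEDPeaks:
    """Locate the two diastolic VED peaks inside configured windows.

    Windows are (start, end) fractions of the cycle period.  The first
    default window catches the remnant of the atrial (A) wave just
    after cycle start; the second the early-filling (E) crest.  If a
    window's maximum falls on its endpoint (monotone segment) the
    endpoint value is returned with a warning.
    """
    rel = (series.t - series.t[0]) / series.cycle_period
    out = []
    for lo, hi in (first_window, second_window):
        sel = (rel >= lo) & (rel <= hi)
        if not np.any(sel):
            raise ValueError(f"peak window ({lo}, {hi}) contains no samples")
        idx = np.flatnonzero(sel)
        k = idx[np.argmax(series.ved[idx])]
        if k == idx[0] or k == idx[-1]:
            warnings.warn(
                f"VED monotone inside window ({lo:.2f}, {hi:.2f}); "
                "endpoint maximum returned", stacklevel=2)
        out.append((float(series.ved[k]), float(series.t[k])))
    (v1, t1), (v2, t2) = out
    return VEDPeaks(first_peak_value=v1, first_peak_time=t1,
                    second_peak_value=v2, second_peak_time=t2)


def anova_recordings(recordings: List[VEDSeries]) -> Tuple[float, float]:
    """One-way ANOVA across replicate recordings (each a group of samples).

    Quantifies replicate dispersion of the dissipation traces: a small
    F (large p) means the recordings are statistically indistinguishable.
    """
    if len(recordings) < 2:
        raise ValueError("need at least 2 recordings")
    n = recordings[0].t.size
    for r in recordings[1:]:
        if r.t.size != n or not np.allclose(r.t, recordings[0].t):
            raise ValueError("recordings must be equal-length and time-aligned")
    res = stats.f_oneway(*[r.ved for r in recordings])
    return float(res.statistic), float(res.pvalue)
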