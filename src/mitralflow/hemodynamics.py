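"""Transvalvular gradients and Gorlin valve area.

Catheter gradients come from simultaneous left-atrial (LA) and
left-ventricular (LV) pressure traces: diastole is delimited by the
pressure crossover (LA above LV during transmitral filling), and the
mean gradient is the time average of LA - LV over those windows.

Doppler gradients come from the continuous-wave velocity envelope via
the simplified Bernoulli relation dP = 4 v^2 (v in m/s, dP in mmHg);
the mean gradient is the time average of the instantaneous 4 v^2 over
the flow period, the clinical "integrated in standard fashion".

Valve area uses the Gorlin hydraulic formula with the mitral constant:

    MVA = 0.85 * CO / (44.3 * HR * flow_period * sqrt(mean_gradient))

with cardiac output CO in mL/min (HR * stroke volume), heart rate in
beats/min, the diastolic flow period in s/beat and the gradient in
mmHg, giving cm^2.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np

from .core import DopplerEnvelope, GorlinInputs, PressureTrace

__all__ = [
    "diastolic_windows",
    "catheter_mean_gradient",
    "doppler_mean_gradient",
    "gorlin_mva",
]

#: Diastolic intervals shorter than this are treated as crossover
#: chatter and discarded (s).
MIN_WINDOW_S = 0.020


def _common_clock(la: PressureTrace, lv: PressureTrace) -> None:
    if la.t.size != lv.t.size or not np.allclose(la.t, lv.t):
        raise ValueError("LA and LV traces must be co-sampled on a common clock")


def diastolic_windows(la: PressureTrace, lv: PressureTrace,
                      min_duration: float = MIN_WINDOW_S,
                      smooth_s: float = 0.020) -> List[Tuple[int, int]]:
    """Maximal sample-index intervals where LA pressure is at or above LV.

    Returns ``(start, stop)`` index pairs (``stop`` exclusive) for each
    transmitral filling window; intervals shorter than ``min_duration``
    are discarded as crossover chatter.  Crossovers are located on a
    moving-average of the pressure difference (``smooth_s`` wide) so
    sensor noise near the crossing does not fragment the windows; the
    smoothing affects window detection only, never the integrand.
    """
    _common_clock(la, lv)
    diff = la.p - lv.p
    k = max(1, int(round(smooth_s / la.dt)) | 1) if la.t.size >= 3 else 1
    if k > 1:
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.concatenate([diff[:1].repeat(pad), diff, diff[-1:].repeat(pad)])
        diff = np.convolve(padded, kernel, mode="valid")
    above = diff >= 0
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    # refine each edge against the raw (unsmoothed) difference so the
    # smoothing cannot shave genuine boundary samples off the window
    raw = la.p - lv.p
    refined = []
    for a, b in zip(starts, stops):
        while a > 0 and raw[a - 1] >= 0:
            a -= 1
        while b < raw.size and raw[b] >= 0:
            b += 1
        refined.append((a, b))
    # merge overlaps introduced by refinement
    merged: List[Tuple[int, int]] = []
    for a, b in refined:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    dt = la.dt
    return [(a, b) for a, b in merged if (b - 1 - a) * dt >= min_duration]


def catheter_mean_gradient(la: PressureTrace, lv: PressureTrace) -> float:
    """Mean diastolic transmitral gradient from the pressure traces (mmHg).

    Trapezoidal time integral of LA - LV over the union of diastolic
    windows, divided by the total window duration.
    """
    windows = diastolic_windows(la, lv)
    if not windows:
        raise ValueError("no diastolic window found (LV never below LA)")
    diff = la.p - lv.p
    total_area = 0.0
    total_time = 0.0
    for a, b in windows:
        if b - a < 2:
            continue
        total_area += float(np.trapezoid(diff[a:b], la.t[a:b]))
        total_time += float(la.t[b - 1] - la.t[a])
    if total_time <= 0:
        raise ValueError("diastolic windows too short to integrate")
    return total_area / total_time


def doppler_mean_gradient(env: DopplerEnvelope, v_threshold: float = 0.0) -> float:
    """Mean transmitral gradient from a CW Doppler envelope (mmHg).

    Applies the simplified Bernoulli relation pointwise (dP = 4 v^2)
    and averages over the flow period: the maximal intervals where the
    envelope exceeds ``v_threshold``, each extended to the bounding
    below-threshold samples so the zero crossings are integrated.  With
    the default threshold of 0 a half-sine lobe of peak 1 m/s yields
    exactly 2 mmHg (mean of sin^2 = 1/2) and a constant 1 m/s envelope
    exactly 4 mmHg.
    """
    above = env.v > v_threshold
    if not np.any(above):
        raise ValueError("envelope has no samples above the flow threshold")
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    dp = 4.0 * env.v**2
    total_area = 0.0
    total_time = 0.0
    for a, b in zip(starts, stops):
        a_ext = max(a - 1, 0)  # include the bounding zero crossings
        b_ext = min(b + 1, env.v.size)
        if b_ext - a_ext < 2:
            continue
        total_area += float(np.trapezoid(dp[a_ext:b_ext], env.t[a_ext:b_ext]))
        total_time += float(env.t[b_ext - 1] - env.t[a_ext])
    if total_time <= 0:
        raise ValueError("flow period too short to integrate")
    return total_area / total_time


def gorlin_mva(inputs: GorlinInputs) -> float:
    """Mitral valve area by the Gorlin formula (cm^2)."""
    co = inputs.heart_rate * inputs.stroke_volume_ml  # mL/min
    return (inputs.constant * co
            / (inputs.factor * inputs.heart_rate * inputs.flow_period_s
               * math.sqrt(inputs.mean_gradient_mmhg)))
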