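"""End-to-end orchestration: simulate -> PIV -> VED -> hemodynamics.

A *run* reproduces one experimental cell of the duplicator study — a
valve model (``normal`` or ``mac``) under one pumping condition
(``rest``: 70 bpm / 60.08 mL, or ``exercise``: 110 bpm / 90.13 mL) —
with five replicate recordings per cell, and reports the quantities the
study tabulates: catheter and Doppler mean gradients, Gorlin valve
area (rest only; the exercise diastolic flow period is not defined),
the two diastolic VED peaks with their times, TVED over one second,
and replicate-consistency ANOVA.

The synthetic valve models differ in transmitral jet width.  The
calcified (``mac``) valve has a narrower inflow jet, and its effective
width narrows further under exercise (jet contraction through the
rigid, tunnel-like orifice at higher flow); the normal valve's width is
flow-independent.  Because the jet scale is set by volume conservation,
a narrower jet at fixed stroke volume means a faster jet and a sharper
shear layer, hence disproportionately larger dissipation — the
mechanism under study.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as _field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import __version__
from .core import (
    BeatSpec, ConfigurationError, FluidProps, FlowSpec, GorlinInputs, ImagingSpec,
)
from . import energetics, hemodynamics, io as mio, piv as piv_mod, synthetic

__all__ = ["RunConfig", "RunReport", "run_experiment", "compare_conditions"]

#: Jet e^-2 widths (m) per valve and condition.  The mac valve narrows
#: with exercise; the normal valve does not.
JET_WIDTH_M = {
    ("normal", "rest"): 0.024,
    ("normal", "exercise"): 0.024,
    ("mac", "rest"): 0.019,
    ("mac", "exercise"): 0.016,
}

#: Diastolic LA-LV offsets (mmHg) driving the synthetic pressure traces,
#: the catheter mean gradients measured on the physical duplicator.
CATHETER_GRADIENT_MMHG = {
    ("normal", "rest"): 1.3,
    ("mac", "rest"): 3.2,
    ("normal", "exercise"): 5.0,
    ("mac", "exercise"): 5.9,
}

#: Doppler mean gradients (mmHg) the synthetic envelopes are built to carry.
DOPPLER_GRADIENT_MMHG = {
    ("normal", "rest"): 2.1,
    ("mac", "rest"): 2.7,
    ("normal", "exercise"): 8.2,
    ("mac", "exercise"): 9.9,
}

#: Diastolic flow period (s/beat) entering the Gorlin formula at rest.
REST_FLOW_PERIOD_S = 0.465


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experimental cell."""

    condition: str = "rest"  # "rest" or "exercise"
    valve: str = "normal"  # "normal" or "mac"
    seed: int = 0
    output_dir: Optional[str] = None
    n_replicates: int = 5
    n_frames: int = 128  # frames per cycle of the flow series
    grid_shape: tuple = (64, 64)
    grid_spacing: float = 1.25e-3  # m (8 cm square domain)
    jet_width_m: Optional[float] = None  # override the valve/condition default
    trace_noise_sd: float = 0.15  # mmHg, pressure sensor noise
    sv_jitter_frac: float = 0.01  # beat-to-beat stroke-volume variability
    piv_image_px: int = 384  # side of the rendered PIV check frame
    piv_pulse_interval_s: float = 5.0e-5  # laser pulse separation
    run_piv_check: bool = True
    tved_duration_s: float = 1.0
    fluid: FluidProps = _field(default_factory=FluidProps)

    def __post_init__(self) -> None:
        if self.condition not in ("rest", "exercise"):
            raise ConfigurationError("condition must be 'rest' or 'exercise'")
        if self.valve not in ("normal", "mac"):
            raise ConfigurationError("valve must be 'normal' or 'mac'")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    @property
    def beat(self) -> BeatSpec:
        return BeatSpec.rest() if self.condition == "rest" else BeatSpec.exercise()

    @property
    def width(self) -> float:
        if self.jet_width_m is not None:
            return self.jet_width_m
        return JET_WIDTH_M[(self.valve, self.condition)]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fluid" in d and isinstance(d["fluid"], dict):
            d["fluid"] = FluidProps(**d["fluid"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-cell results in the layout of the study's summary table."""

    condition: str
    valve: str
    seed: int
    config_digest: str
    version: str
    catheter_gradient_mmhg: float
    doppler_gradient_mmhg: float
    mva_cm2: Optional[float]
    ved_first_peak_w_per_m: float
    ved_first_peak_time_s: float
    ved_second_peak_w_per_m: float
    ved_second_peak_time_s: float
    tved_j_per_m: float
    replicate_tved: List[float]
    anova_f: float
    anova_p: float
    piv_rms_px: Optional[float]

    ROW_LABELS = (
        "MVA (cm2)",
        "Mean Gradient, Catheter derived (mmHg)",
        "Mean Gradient, Doppler derived (mmHg)",
        "VED, first peak (W/m)",
        "First peak time (s)",
        "VED, second peak (W/m)",
        "Second peak time (s)",
        "TVED (J/m)",
    )

    def summary_frame(self) -> pd.DataFrame:
        col = f"{self.valve}-{self.condition}"
        vals = [
            self.mva_cm2,
            self.catheter_gradient_mmhg,
            self.doppler_gradient_mmhg,
            self.ved_first_peak_w_per_m,
            self.ved_first_peak_time_s,
            self.ved_second_peak_w_per_m,
            self.ved_second_peak_time_s,
            self.tved_j_per_m,
        ]
        fmt = ["---" if v is None else f"{v:.4g}" for v in vals]
        return pd.DataFrame({"parameter": list(self.ROW_LABELS), col: fmt})

    def to_dict(self) -> dict:
        return asdict(self)


def _doppler_peaks_for_gradient(beat: BeatSpec, gradient_mmhg: float
                                ) -> tuple:
    """Half-sine lobe peaks (E, A) that carry a target mean gradient.

    With half-sine lobes of durations T_E, T_A and peak ratio rho, the
    Bernoulli time-average over the flow period is
    2 (rho^2 T_E + T_A) v_A^2 / (T_E + T_A); invert for v_A.
    """
    te, ta = beat.e_wave_fraction, beat.a_wave_fraction
    rho = beat.e_a_ratio
    va = float(np.sqrt(gradient_mmhg * (te + ta) / (2.0 * (rho**2 * te + ta))))
    return rho * va, va


def _replicate(config: RunConfig, rep: int) -> dict:
    """One replicate recording of the configured cell."""
    seed = int(config.seed) * 1000 + rep
    rng = np.random.default_rng(seed)
    beat0 = config.beat
    sv = beat0.stroke_volume_ml * (1.0 + config.sv_jitter_frac * rng.standard_normal())
    beat = BeatSpec(heart_rate=beat0.heart_rate, stroke_volume_ml=sv,
                    condition=beat0.condition)

    spec = FlowSpec(model="transmitral_jet", params={"width": config.width},
                    grid_shape=config.grid_shape, grid_spacing=config.grid_spacing)
    fields = synthetic.make_flow_series(spec, beat, config.n_frames)
    times = np.arange(config.n_frames) * beat.period_s / config.n_frames
    series = energetics.ved_series(fields, config.fluid, times,
                                   cycle_period=beat.period_s,
                                   condition=config.condition)
    peaks = energetics.detect_peaks(series)
    total = energetics.tved(series, duration=config.tved_duration_s)

    la, lv = synthetic.make_pressure_traces(
        beat, CATHETER_GRADIENT_MMHG[(config.valve, config.condition)],
        noise_sd=config.trace_noise_sd, seed=seed)
    cath = hemodynamics.catheter_mean_gradient(la, lv)

    e_pk, a_pk = _doppler_peaks_for_gradient(
        beat, DOPPLER_GRADIENT_MMHG[(config.valve, config.condition)])
    env = synthetic.make_doppler_envelope(beat, e_pk, a_pk)
    dopp = hemodynamics.doppler_mean_gradient(env)

    piv_rms = None
    pair = None
    piv_field = None
    if config.run_piv_check:
        # render the peak-E frame at reduced scale and verify PIV recovery
        k = int(np.argmax([np.abs(f.v).max() for f in fields]))
        n_px = config.piv_image_px
        mag = config.grid_spacing * (config.grid_shape[1] - 1) / (n_px - 1)
        imaging = ImagingSpec(image_shape=(n_px, n_px), magnification=mag,
                              frame_interval=config.piv_pulse_interval_s,
                              seed=seed)
        pair = synthetic.render_particle_pair(fields[k], imaging)
        pcfg = piv_mod.PIVConfig(magnification=mag,
                                 frame_interval=config.piv_pulse_interval_s)
        piv_field = piv_mod.multipass_piv(pair, pcfg)
        # truth at the PIV nodes, in px, interior only
        tru_v = np.interp(piv_field.x, fields[k].x, fields[k].v[0])
        err_px = (piv_field.v - tru_v[None, :]) * (
            config.piv_pulse_interval_s / mag)
        inner = np.zeros(piv_field.shape, bool)
        inner[2:-2, 2:-2] = True
        piv_rms = float(np.sqrt(np.mean(err_px[inner & piv_field.valid] ** 2)))

    return {
        "series": series, "peaks": peaks, "tved": total,
        "catheter": cath, "doppler": dopp, "beat": beat,
        "la": la, "lv": lv, "env": env, "fields": fields,
        "pair": pair, "piv_field": piv_field, "piv_rms": piv_rms,
    }


def run_experiment(config: RunConfig) -> RunReport:
    """Execute every stage for one cell and assemble the report.

    Replicate recordings (default five) differ in pressure-sensor noise
    and beat-to-beat stroke-volume jitter; reported scalars are
    replicate means, and the replicate VED traces feed a one-way ANOVA.
    Deterministic for a fixed seed.  If ``config.output_dir`` is set,
    intermediate artifacts (traces, envelope, field and image samples,
    VED series, summary) are written there.
    """
    reps = []
    for r in range(config.n_replicates):
        try:
            reps.append(_replicate(config, r))
        except Exception as exc:
            raise RuntimeError(
                f"stage failure in replicate {r} of "
                f"{config.valve}-{config.condition}: {exc}"
            ) from exc

    cath = float(np.mean([r["catheter"] for r in reps]))
    dopp = float(np.mean([r["doppler"] for r in reps]))
    tveds = [float(r["tved"]) for r in reps]
    pk = reps[0]["peaks"]
    first_v = float(np.mean([r["peaks"].first_peak_value for r in reps]))
    second_v = float(np.mean([r["peaks"].second_peak_value for r in reps]))

    mva = None
    if config.condition == "rest":
        mva = hemodynamics.gorlin_mva(GorlinInputs(
            heart_rate=config.beat.heart_rate,
            stroke_volume_ml=config.beat.stroke_volume_ml,
            flow_period_s=REST_FLOW_PERIOD_S,
            mean_gradient_mmhg=cath))

    if config.n_replicates >= 2:
        f_val, p_val = energetics.anova_recordings([r["series"] for r in reps])
    else:
        f_val, p_val = float("nan"), float("nan")

    piv_vals = [r["piv_rms"] for r in reps if r["piv_rms"] is not None]
    report = RunReport(
        condition=config.condition, valve=config.valve, seed=config.seed,
        config_digest=config.digest(), version=__version__,
        catheter_gradient_mmhg=cath, doppler_gradient_mmhg=dopp,
        mva_cm2=mva,
        ved_first_peak_w_per_m=first_v,
        ved_first_peak_time_s=float(pk.first_peak_time),
        ved_second_peak_w_per_m=second_v,
        ved_second_peak_time_s=float(pk.second_peak_time),
        tved_j_per_m=float(np.mean(tveds)),
        replicate_tved=tveds,
        anova_f=f_val, anova_p=p_val,
        piv_rms_px=float(np.mean(piv_vals)) if piv_vals else None,
    )

    if config.output_dir is not None:
        _write_artifacts(config, reps, report)
    return report


def _write_artifacts(config: RunConfig, reps: List[dict], report: RunReport) -> None:
    out = Path(config.output_dir) / f"{config.valve}-{config.condition}"
    out.mkdir(parents=True, exist_ok=True)
    r0 = reps[0]
    mio.write_trace(out / "la.csv", r0["la"])
    mio.write_trace(out / "lv.csv", r0["lv"])
    mio.write_envelope(out / "doppler.csv", r0["env"])
    pd.DataFrame({"t_s": r0["series"].t, "ved_W_per_m": r0["series"].ved}
                 ).to_csv(out / "ved_series.csv", index=False)
    k = int(np.argmax([np.abs(f.v).max() for f in r0["fields"]]))
    mio.write_field(out / "field_peak_e.csv", r0["fields"][k])
    if r0["pair"] is not None:
        mio.write_pair(out, r0["pair"], stem="piv_check")
        mio.write_field(out / "piv_field.csv", r0["piv_field"])
    report.summary_frame().to_csv(out / "summary.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)


def compare_conditions(reports: List[RunReport]) -> pd.DataFrame:
    """Side-by-side table of cells with rest-to-exercise percent changes.

    Percent change is 100 * (exercise - rest) / rest for each valve that
    has both conditions; replicate TVED lists feed a Welch t-test per
    valve.  Identical reports yield zero percent change.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    cols = {f"{r.valve}-{r.condition}": r for r in reports}
    frames = [r.summary_frame().set_index("parameter") for r in cols.values()]
    table = pd.concat(frames, axis=1)

    by_valve: Dict[str, Dict[str, RunReport]] = {}
    for r in reports:
        by_valve.setdefault(r.valve, {})[r.condition] = r
    for valve, cell in by_valve.items():
        if "rest" in cell and "exercise" in cell:
            rest, ex = cell["rest"], cell["exercise"]
            rise = 100.0 * (ex.tved_j_per_m - rest.tved_j_per_m) / rest.tved_j_per_m
            if len(rest.replicate_tved) >= 2 and len(ex.replicate_tved) >= 2:
                t_res = _stats.ttest_ind(ex.replicate_tved, rest.replicate_tved,
                                         equal_var=False)
                pval = f"{t_res.pvalue:.3g}"
            else:
                pval = "---"
            table[f"{valve} rise (%)"] = ""
            table.loc["TVED (J/m)", f"{valve} rise (%)"] = f"{rise:.4g}"
            table.loc["Mean Gradient, Catheter derived (mmHg)", f"{valve} rise (%)"] = (
                f"{100.0 * (ex.catheter_gradient_mmhg - rest.catheter_gradient_mmhg) / rest.catheter_gradient_mmhg:.4g}"
            )
            table.attrs[f"{valve}_tved_rise_pct"] = rise
            table.attrs[f"{valve}_welch_p"] = pval
    return table.reset_index()
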