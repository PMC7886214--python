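"""Readers and writers for the pipeline's on-disk artifacts.

Images are 8- or 16-bit grayscale TIFF; fields, traces and envelopes
are comma-delimited text with a header row naming the columns
(``x_m,y_m,u_mps,v_mps,valid`` / ``t_s,p_mmHg`` / ``t_s,v_mps``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DopplerEnvelope, ParticleImagePair, PressureTrace, VelocityField

__all__ = [
    "write_image", "read_image", "write_pair", "read_pair",
    "write_field", "read_field",
    "write_trace", "read_trace",
    "write_envelope", "read_envelope",
    "load_config",
]

PathLike = Union[str, Path]


def write_image(path: PathLike, image: np.ndarray, bits: int = 16) -> None:
    if bits == 8:
        arr = np.clip(image, 0, 255).astype(np.uint8)
    elif bits == 16:
        arr = np.clip(image, 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    tifffile.imwrite(str(path), arr)


def read_image(path: PathLike) -> np.ndarray:
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        return tifffile.imread(p).astype(float)
    import imageio.v3 as iio  # PNG and other grayscale formats

    arr = iio.imread(p)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def write_pair(dir_path: PathLike, pair: ParticleImagePair, stem: str = "frame") -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_image(d / f"{stem}_a.tif", pair.frame_a)
    write_image(d / f"{stem}_b.tif", pair.frame_b)


def read_pair(path_a: PathLike, path_b: PathLike, frame_interval: float,
              magnification: float) -> ParticleImagePair:
    return ParticleImagePair(read_image(path_a), read_image(path_b),
                             frame_interval, magnification)


def write_field(path: PathLike, field: VelocityField) -> None:
    xx, yy = np.meshgrid(field.x, field.y)
    pd.DataFrame({
        "x_m": xx.ravel(),
        "y_m": yy.ravel(),
        "u_mps": field.u.ravel(),
        "v_mps": field.v.ravel(),
        "valid": field.included.ravel().astype(int),
    }).to_csv(path, index=False)


def read_field(path: PathLike) -> VelocityField:
    df = pd.read_csv(path)
    x = np.unique(df["x_m"].to_numpy())
    y_raw = df["y_m"].to_numpy()
    # preserve row order (y may descend for image-derived fields)
    _, idx = np.unique(y_raw, return_index=True)
    y = y_raw[np.sort(idx)]
    rows, cols = y.size, x.size
    if rows * cols != len(df):
        raise ValueError("field file is not a full rectangular grid")
    shape = (rows, cols)
    u = df["u_mps"].to_numpy().reshape(shape)
    v = df["v_mps"].to_numpy().reshape(shape)
    valid = df["valid"].to_numpy().astype(bool).reshape(shape)
    spacing = float(abs(x[1] - x[0])) if cols > 1 else float(abs(y[1] - y[0]))
    return VelocityField(u=u, v=v, x=x, y=y, spacing=spacing, valid=valid)


def write_trace(path: PathLike, trace: PressureTrace) -> None:
    pd.DataFrame({"t_s": trace.t, "p_mmHg": trace.p}).to_csv(path, index=False)


def read_trace(path: PathLike, site: str = "LA") -> PressureTrace:
    df = pd.read_csv(path)
    return PressureTrace(df["t_s"].to_numpy(), df["p_mmHg"].to_numpy(), site=site)


def write_envelope(path: PathLike, env: DopplerEnvelope) -> None:
    pd.DataFrame({"t_s": env.t, "v_mps": env.v}).to_csv(path, index=False)


def read_envelope(path: PathLike) -> DopplerEnvelope:
    df = pd.read_csv(path)
    return DopplerEnvelope(df["t_s"].to_numpy(), df["v_mps"].to_numpy())


def load_config(path: PathLike) -> dict:
    """Load a flat key: value run configuration (YAML syntax)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a key: value mapping")
    return cfg
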