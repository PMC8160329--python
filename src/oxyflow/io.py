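"""File I/O: multi-page TIFF images with JSON sidecars, CSV probe traces.

Images (kymographs, movies, volumes) are stored as multi-page TIFF with a
JSON sidecar of the same stem carrying units and channel roles; probe
sessions are CSV with one row per 25 ms sample.  Loading returns the typed
in-memory objects the analysis modules consume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .hemo import HemoTrace
from .linescan import Kymograph
from .vesselgeom import Movie, Volume

__all__ = [
    "save_kymograph", "save_movie", "save_volume", "save_hemo",
    "load_image", "load_hemo",
]

HEMO_COLUMNS = ["t", "flux", "speed", "HbO", "Hbr", "locomotion", "stimulus"]


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def save_kymograph(path, k: Kymograph) -> None:
    tifffile.imwrite(path, k.intensity.astype(np.float32))
    _write_sidecar(path, {
        "kind": "kymograph", "dt_line": k.dt_line, "px": k.px,
        "path_segments": {r: list(v) for r, v in k.path_segments.items()},
    })


def save_movie(path, m: Movie) -> None:
    roles = sorted(m.channels)
    stack = np.stack([m.channels[r] for r in roles], axis=1)  # (T, C, Y, X)
    tifffile.imwrite(path, stack.astype(np.float32))
    _write_sidecar(path, {
        "kind": "movie", "frame_rate": m.frame_rate, "px": m.px,
        "channels": roles,
    })


def save_volume(path, v: Volume) -> None:
    tifffile.imwrite(path, v.data.astype(np.float32))
    _write_sidecar(path, {"kind": "volume", "voxel_size": v.voxel_size})


def _require(meta: dict, field: str, path):
    if field not in meta:
        raise ValueError(f"sidecar for {path} is missing required field {field!r}")
    return meta[field]


def load_image(path):
    """Load a TIFF + sidecar as a Kymograph, Movie or Volume (per sidecar kind)."""
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"no JSON sidecar next to {path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = tifffile.imread(path)
    kind = _require(meta, "kind", path)
    if kind == "kymograph":
        return Kymograph(
            intensity=np.asarray(data, dtype=float),
            dt_line=_require(meta, "dt_line", path),
            px=_require(meta, "px", path),
            path_segments={r: tuple(v)
                           for r, v in _require(meta, "path_segments", path).items()},
        )
    if kind == "movie":
        roles = _require(meta, "channels", path)
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 4 or arr.shape[1] != len(roles):
            raise ValueError(f"movie stack shape {arr.shape} does not match channels {roles}")
        return Movie(channels={r: arr[:, i] for i, r in enumerate(roles)},
                     frame_rate=_require(meta, "frame_rate", path),
                     px=_require(meta, "px", path))
    if kind == "volume":
        return Volume(data=np.asarray(data, dtype=float),
                      voxel_size=_require(meta, "voxel_size", path))
    raise ValueError(f"unknown image kind {kind!r}")


def save_hemo(path, h: HemoTrace) -> None:
    import pandas as pd

    pd.DataFrame({
        "t": h.t, "flux": h.flux, "speed": h.speed, "HbO": h.hbo, "Hbr": h.hbr,
        "locomotion": h.locomotion, "stimulus": h.stimulus.astype(int),
    }).to_csv(path, index=False)


def load_hemo(path, resample: bool = False) -> HemoTrace:
    """Load a probe CSV; validates headers, monotone time and 40 Hz sampling.

    With ``resample=True`` an irregularly sampled file is linearly
    interpolated onto a regular 40 Hz grid instead of failing.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in HEMO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe CSV {path} is missing column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    regular = t.size < 2 or np.allclose(np.diff(t), 0.025, rtol=1e-3)
    if not regular:
        if not resample:
            raise ValueError("irregular sampling; pass resample=True to interpolate")
        tt = np.arange(t[0], t[-1] + 1e-9, 0.025)
        interp = {c: np.interp(tt, t, df[c].to_numpy(dtype=float))
                  for c in HEMO_COLUMNS if c != "t"}
        df = pd.DataFrame({"t": tt, **interp})
        t = tt
    return HemoTrace(
        t=t, flux=df["flux"].to_numpy(dtype=float),
        speed=df["speed"].to_numpy(dtype=float),
        hbo=df["HbO"].to_numpy(dtype=float), hbr=df["Hbr"].to_numpy(dtype=float),
        locomotion=df["locomotion"].to_numpy(dtype=float),
        stimulus=df["stimulus"].to_numpy(dtype=float) > 0.5,
    )
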