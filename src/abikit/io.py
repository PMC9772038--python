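"""File round-tripping for recordings, maps and configs.

Time series travel as two-column delimited text (``time_s,voltage``) with a
JSON sidecar holding the acquisition metadata (fs, prf, focus, seed); maps as
a delimited-text matrix with a JSON sidecar holding the mm coordinates.
Values are printed with 17 significant digits so a write/read round trip is
bit-exact for float64.  The sidecar of ``foo.csv`` is ``foo.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError, ParseError
from .imaging import ImageMap
from .phantom import PhantomConfig, RawRecording, ScanGrid, SourceSpec, TransducerSpec

__all__ = [
    "write_recording",
    "read_recording",
    "write_image",
    "read_image",
    "read_config",
    "phantom_config_from_dict",
    "scan_grid_from_dict",
]

_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: RawRecording, path) -> Path:
    """Write a recording as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    data = np.column_stack([rec.times(), rec.samples])
    np.savetxt(path, data, delimiter=",", header="time_s,voltage", comments="",
               fmt=_FMT)
    meta = {
        "fs": rec.fs,
        "prf": rec.prf,
        "focus_x_mm": rec.focus[0],
        "focus_y_mm": rec.focus[1],
        "seed": rec.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def _load_two_columns(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError:
        # locate the offending row for a useful message
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if lineno == 1:
                    continue
                parts = line.strip().split(",")
                for field_no, part in enumerate(parts, start=1):
                    try:
                        float(part)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: field {field_no} is not numeric: "
                            f"{part!r}"
                        ) from None
        raise ParseError(f"{path}: malformed delimited-text file")


def read_recording(path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "prf", "focus_x_mm", "focus_y_mm"):
        if key not in meta:
            raise InvalidConfigError(f"{sidecar}: missing required field {key!r}")
    data = _load_two_columns(path)
    if data.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {data.shape[1]}")
    return RawRecording(
        samples=data[:, 1],
        fs=meta["fs"],
        focus=(meta["focus_x_mm"], meta["focus_y_mm"]),
        prf=meta["prf"],
        seed=meta.get("seed"),
    )


def write_image(img: ImageMap, path) -> Path:
    """Write a map as a CSV matrix plus JSON coordinate sidecar."""
    path = Path(path)
    np.savetxt(path, img.values, delimiter=",", fmt=_FMT)
    meta = {
        "x_coords_mm": img.x_coords.tolist(),
        "y_coords_mm": img.y_coords.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_image(path) -> ImageMap:
    """Read a map written by :func:`write_image`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("x_coords_mm", "y_coords_mm"):
        if key not in meta:
            raise InvalidConfigError(f"{sidecar}: missing required field {key!r}")
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed matrix file: {exc}") from None
    return ImageMap(
        values=values,
        x_coords=np.asarray(meta["x_coords_mm"], dtype=float),
        y_coords=np.asarray(meta["y_coords_mm"], dtype=float),
    )


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    """Build a PhantomConfig from a JSON-style dict, naming missing fields."""
    if "sources" not in d:
        raise InvalidConfigError("config missing required field 'sources'")
    if "fs_record" not in d:
        raise InvalidConfigError("config missing required field 'fs_record'")
    sources = []
    for i, s in enumerate(d["sources"]):
        for key in ("position", "frequency", "amplitude"):
            if key not in s:
                raise InvalidConfigError(f"sources[{i}] missing required field {key!r}")
        sources.append(
            SourceSpec(
                position=tuple(s["position"]),
                frequency=s["frequency"],
                amplitude=s["amplitude"],
                phase=s.get("phase", 0.0),
            )
        )
    transducer = TransducerSpec(**d.get("transducer", {}))
    known = {
        "fs_record", "duration", "ae_constant", "pressure_peak",
        "modulation_index", "lf_leak_gain", "noise_sd", "seed",
    }
    extra = set(d) - known - {"sources", "transducer"}
    if extra:
        raise InvalidConfigError(f"unknown config fields: {sorted(extra)}")
    kwargs = {k: d[k] for k in known if k in d}
    return PhantomConfig(sources=tuple(sources), transducer=transducer, **kwargs)


def scan_grid_from_dict(d: dict) -> ScanGrid:
    """Build a ScanGrid from a JSON-style dict, naming missing fields."""
    for key in ("x_min", "x_max", "x_step", "y_min", "y_max", "y_step"):
        if key not in d:
            raise InvalidConfigError(f"grid missing required field {key!r}")
    return ScanGrid(**{k: d[k] for k in
                       ("x_min", "x_max", "x_step", "y_min", "y_max", "y_step")})


def read_config(path) -> PhantomConfig:
    """Read a phantom config JSON file."""
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    return phantom_config_from_dict(d)
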