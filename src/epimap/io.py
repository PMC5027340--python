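"""File formats.

* Geometry: CSV with header ``channel_id,row,col,x_mm,y_mm``.
* Recording: a single container file with a structured text header
  (``key: value`` lines, terminated by a ``---`` line) followed by the
  channels x samples matrix, either as raw little-endian 32-bit floats
  (``binary`` dialect, lossless round-trip) or as CSV rows (``csv``
  dialect, round-trips to the declared precision).
* Maps and reports: plain CSV/TSV/JSON via pandas.
"""

from __future__ import annotations

import ast
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .synthetic.geometry import ArrayGeometry, make_geometry
from .synthetic.signals import Recording

_HEADER_END = "---"
CSV_SIGNAL_DECIMALS = 6  # declared precision of the csv dialect, mV


def write_geometry(geometry: ArrayGeometry, path: str | Path) -> None:
    pd.DataFrame({
        "channel_id": geometry.channel_id, "row": geometry.row,
        "col": geometry.col, "x_mm": geometry.x_mm, "y_mm": geometry.y_mm,
    }).to_csv(path, index=False)


def read_geometry(path: str | Path,
                  stim_channels: tuple[int, ...] | None = None,
                  bad_channels: tuple[int, ...] = ()) -> ArrayGeometry:
    """Rebuild a regular-grid geometry from its CSV table.

    Grid topology (neighbors, triangles) is reconstructed from the row/col
    indices; the pitch is inferred from the coordinates.
    """
    df = pd.read_csv(path)
    required = {"channel_id", "row", "col", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"geometry file {path}: missing columns {sorted(missing)}")
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    if len(df) != rows * cols:
        raise FormatError(f"geometry file {path}: not a complete {rows}x{cols} grid")
    xs = np.sort(df["x_mm"].unique())
    ys = np.sort(df["y_mm"].unique())
    deltas = np.concatenate([np.diff(xs), np.diff(ys)])
    pitch = float(np.median(deltas)) if deltas.size else 1.0
    geom = make_geometry(rows, cols, pitch,
                         stim_channels=stim_channels, bad_channels=bad_channels)
    order = df.sort_values("channel_id")
    if not (np.allclose(order["x_mm"].to_numpy(), geom.x_mm)
            and np.allclose(order["y_mm"].to_numpy(), geom.y_mm)):
        raise FormatError(f"geometry file {path}: coordinates are not a regular "
                          f"grid with pitch {pitch}")
    return geom


def _parse_header_value(raw: str):
    raw = raw.strip()
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def write_recording(recording: Recording, path: str | Path, fmt: str = "binary") -> None:
    """Serialize a recording; ``fmt`` selects the matrix dialect."""
    if fmt not in ("binary", "csv"):
        raise FormatError(f"unknown recording format {fmt!r}")
    geom = recording.geometry
    header = {
        "format": fmt,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "units": "mV",
        "stimulus_times_ms": list(recording.stimulus_times_ms),
        "bad_channels": sorted(geom.bad_channels),
        "stim_channels": list(geom.stim_channels),
        "quantization_bits": recording.quantization_bits,
        "rng_seed": recording.rng_seed,
        "grid_rows": geom.n_rows,
        "grid_cols": geom.n_cols,
        "pitch_mm": geom.pitch_mm,
    }
    lines = "".join(f"{k}: {v!r}\n" for k, v in header.items()) + _HEADER_END + "\n"
    with open(path, "wb") as fh:
        fh.write(lines.encode("utf-8"))
        if fmt == "binary":
            fh.write(recording.signal_mv.astype("<f4").tobytes())
        else:
            for row in recording.signal_mv:
                fh.write((",".join(f"{v:.{CSV_SIGNAL_DECIMALS}f}" for v in row) + "\n")
                         .encode("ascii"))


def read_recording(path: str | Path) -> Recording:
    """Parse a recording container; validates header/matrix consistency."""
    with open(path, "rb") as fh:
        header: dict = {}
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: header terminator {_HEADER_END!r} not found")
            text = line.decode("utf-8").rstrip("\n")
            if text == _HEADER_END:
                break
            if ":" not in text:
                raise FormatError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            header[key.strip()] = _parse_header_value(value)
        payload = fh.read()

    for field in ("format", "sampling_rate_hz", "n_channels", "n_samples",
                  "grid_rows", "grid_cols", "pitch_mm"):
        if field not in header:
            raise FormatError(f"{path}: missing header field {field!r}")
    fmt = header["format"]
    n_ch = int(header["n_channels"])
    n_samp = int(header["n_samples"])

    if fmt == "binary":
        expected = n_ch * n_samp * 4
        if len(payload) != expected:
            raise FormatError(
                f"{path}: n_channels/n_samples mismatch: header promises "
                f"{expected} payload bytes, found {len(payload)}")
        signal = np.frombuffer(payload, dtype="<f4").reshape(n_ch, n_samp)
    elif fmt == "csv":
        rows = [r for r in payload.decode("ascii").splitlines() if r]
        if len(rows) != n_ch:
            raise FormatError(f"{path}: n_channels mismatch: header says {n_ch}, "
                              f"payload has {len(rows)} rows")
        signal = np.array([[float(v) for v in r.split(",")] for r in rows],
                          dtype=np.float32)
        if signal.shape[1] != n_samp:
            raise FormatError(f"{path}: n_samples mismatch: header says {n_samp}, "
                              f"payload rows have {signal.shape[1]} values")
    else:
        raise FormatError(f"{path}: unknown format dialect {fmt!r}")

    geom = make_geometry(int(header["grid_rows"]), int(header["grid_cols"]),
                         float(header["pitch_mm"]),
                         stim_channels=tuple(header.get("stim_channels") or ()) or None,
                         bad_channels=tuple(header.get("bad_channels") or ()))
    if geom.n_channels != n_ch:
        raise FormatError(f"{path}: grid {geom.n_rows}x{geom.n_cols} does not "
                          f"match n_channels {n_ch}")
    qbits = header.get("quantization_bits")
    return Recording(geometry=geom, sampling_rate_hz=float(header["sampling_rate_hz"]),
                     signal_mv=signal.copy(),
                     stimulus_times_ms=tuple(float(t) for t in
                                             (header.get("stimulus_times_ms") or ())),
                     quantization_bits=None if qbits is None else int(qbits),
                     rng_seed=header.get("rng_seed"))


def write_frame_csv(frame: pd.DataFrame, path: str | Path,
                    provenance: dict | None = None) -> None:
    """CSV with an optional single leading ``#`` provenance comment line."""
    with open(path, "w") as fh:
        if provenance is not None:
            fh.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False)


def read_frame_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
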