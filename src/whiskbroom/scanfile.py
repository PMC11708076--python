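"""Line-oriented text format for scan cubes.

Layout: a header block of ``key<TAB>value`` lines terminated by
``END_HEADER``, then one ``D`` record per dark frame and one ``P``
record per pixel::

    whiskbroom-scan 1
    unit_id  3
    ...
    END_HEADER
    D <after_row> <integration_time> <count> <count> ...
    P <row> <col> <flag> <integration_time> <count> <count> ...

Counts are stored as integers, derived floats at 9 significant digits;
writes are deterministic (stable key order, fixed formatting), so the
round trip is lossless.  Pixel flags: ``M`` measured, ``MS`` measured
and saturated-at-minimum, ``I`` interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acquisition import (
    DarkRecord,
    FLAG_INTERPOLATED,
    FLAG_MEASURED,
    PixelRecord,
    ScanCube,
    ScanPlan,
)
from .spectral import DarkFrame, RawFrame, WavelengthCalibration

FORMAT_NAME = "whiskbroom-scan"
FORMAT_VERSION = 1

_PLAN_KEYS = (
    "pan_start",
    "pan_stop",
    "pan_step_size",
    "tilt_start",
    "tilt_stop",
    "tilt_step_size",
    "max_integration",
    "min_integration",
    "dark_interval",
    "steps_per_revolution",
)


@dataclass
class ScanFileHeader:
    """Metadata stored alongside the raw records."""

    unit_id: int = 0
    label: str = ""
    timestamp: str = "1970-01-01T00:00:00Z"
    plan: Optional[ScanPlan] = None
    compression_window: int = 1
    wl_coeffs: tuple = ()
    lin_a: Optional[float] = None
    lin_b: Optional[float] = None
    version: int = FORMAT_VERSION


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def _flag_token(rec: PixelRecord) -> str:
    if rec.flag == FLAG_INTERPOLATED:
        return "I"
    return "MS" if rec.frame.saturated else "M"


def write_scan(cube: ScanCube, header: ScanFileHeader, path) -> None:
    """Serialise a cube; see module docstring for the layout."""
    plan = header.plan or cube.plan
    lines = [f"{FORMAT_NAME} {header.version}"]
    lines.append(f"unit_id\t{header.unit_id}")
    lines.append(f"label\t{header.label}")
    lines.append(f"timestamp\t{header.timestamp}")
    for key in _PLAN_KEYS:
        lines.append(f"{key}\t{getattr(plan, key)}")
    lines.append(f"compression_window\t{header.compression_window}")
    if header.wl_coeffs:
        lines.append("wl_coeffs\t" + ",".join(_fmt(c) for c in header.wl_coeffs))
    if header.lin_a is not None:
        lines.append(f"lin_a\t{_fmt(header.lin_a)}")
    if header.lin_b is not None:
        lines.append(f"lin_b\t{_fmt(header.lin_b)}")
    lines.append("END_HEADER")
    for d in cube.darks:
        counts = " ".join(str(int(c)) for c in d.frame.counts)
        lines.append(f"D {d.after_row} {d.frame.integration_time} {counts}")
    for (row, col) in sorted(cube.pixels):
        rec = cube.pixels[(row, col)]
        counts = " ".join(str(int(c)) for c in rec.frame.counts)
        lines.append(
            f"P {row} {col} {_flag_token(rec)} {rec.integration_time} {counts}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


_KNOWN_HEADER_KEYS = {
    "unit_id",
    "label",
    "timestamp",
    "compression_window",
    "wl_coeffs",
    "lin_a",
    "lin_b",
    *_PLAN_KEYS,
}


def read_scan(path) -> tuple:
    """Parse a scan file back into ``(ScanCube, ScanFileHeader)``.

    Unknown header keys are ignored with a warning (forward
    compatibility); an unrecognised version or a truncated pixel grid is
    an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty scan file")
    magic = lines[0].split()
    if len(magic) != 2 or magic[0] != FORMAT_NAME:
        raise ValueError(f"{path}: not a {FORMAT_NAME} file")
    version = int(magic[1])
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {version}")
    fields: dict = {}
    i = 1
    while i < len(lines) and lines[i] != "END_HEADER":
        line = lines[i]
        if "\t" not in line:
            raise ValueError(f"{path}: malformed header line {i + 1}: {line!r}")
        key, value = line.split("\t", 1)
        if key not in _KNOWN_HEADER_KEYS:
            warnings.warn(f"{path}: ignoring unknown header key {key!r}")
        else:
            fields[key] = value
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: missing END_HEADER")
    plan = ScanPlan(**{k: int(fields[k]) for k in _PLAN_KEYS})
    wl_coeffs = (
        tuple(float(v) for v in fields["wl_coeffs"].split(",")) if "wl_coeffs" in fields else ()
    )
    header = ScanFileHeader(
        unit_id=int(fields.get("unit_id", 0)),
        label=fields.get("label", ""),
        timestamp=fields.get("timestamp", ""),
        plan=plan,
        compression_window=int(fields.get("compression_window", 1)),
        wl_coeffs=wl_coeffs,
        lin_a=float(fields["lin_a"]) if "lin_a" in fields else None,
        lin_b=float(fields["lin_b"]) if "lin_b" in fields else None,
        version=version,
    )
    cube = ScanCube(
        plan=plan,
        pixels={},
        darks=[],
        metadata={
            "unit_id": header.unit_id,
            "label": header.label,
            "timestamp": header.timestamp,
        },
        wavelength_cal=(
            WavelengthCalibration(wl_coeffs, n_photosites=_infer_n(lines[i + 1 :]))
            if wl_coeffs
            else None
        ),
    )
    for j in range(i + 1, len(lines)):
        line = lines[j]
        if not line.strip():
            continue
        parts = line.split()
        if parts[0] == "D":
            after_row, t = int(parts[1]), int(parts[2])
            counts = np.array([int(v) for v in parts[3:]], dtype=np.int64)
            cube.darks.append(
                DarkRecord(after_row=after_row, frame=DarkFrame(counts=counts, integration_time=t))
            )
        elif parts[0] == "P":
            row, col, flag, t = int(parts[1]), int(parts[2]), parts[3], int(parts[4])
            counts = np.array([int(v) for v in parts[5:]], dtype=np.int64)
            frame = RawFrame(counts=counts, integration_time=t, saturated=flag == "MS")
            cube.pixels[(row, col)] = PixelRecord(
                frame=frame,
                flag=FLAG_INTERPOLATED if flag == "I" else FLAG_MEASURED,
            )
        else:
            raise ValueError(f"{path}: unknown record type {parts[0]!r} at line {j + 1}")
    missing = [
        (r, c)
        for r in range(plan.n_rows)
        for c in range(plan.n_cols)
        if (r, c) not in cube.pixels
    ]
    if missing:
        raise ValueError(f"{path}: truncated pixel grid; missing indices {missing[:10]}")
    return cube, header


def _infer_n(record_lines: list) -> int:
    for line in record_lines:
        parts = line.split()
        if parts and parts[0] == "D":
            return len(parts) - 3
        if parts and parts[0] == "P":
            return len(parts) - 5
    from .spectral import N_PHOTOSITES

    return N_PHOTOSITES
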