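"""Calibration procedures: linearisation-curve fitting from an
integration-time ladder, and spectral-sensitivity estimation from a
white-standard scan against a reference radiance spectrum.

The linearisation model is ``c = exp(ln(r - d) * a + b)``.  The fit
regresses the log of the expected linear response (proportional to the
known integration time) on ``ln(r - d)`` at the peak wavelength bin.

Scale convention: the proportionality constant between integration time
and expected linear counts is not identifiable from ladder data alone —
it only shifts ``b``, and any consistent choice cancels once the same
coefficients are used for both sensitivity calibration and radiance
conversion.  By default the constant is anchored so that the ladder
point nearest the median integration time satisfies
``c_expected = r - d`` (making ``a=1, b=0`` the exact no-op for a linear
sensor); callers that know the true counts-per-us rate (e.g. a
simulator) may pass it via ``expected_scale``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .acquisition import ScanCube, auto_expose, FLAG_MEASURED
from .instrument import GimbalState, InstrumentModel, SceneModel, dark_position_expose, expose
from .spectral import (
    DEFAULT_MAX_INTEGRATION_US,
    MIN_INTEGRATION_US,
    DarkFrame,
    RawFrame,
    Spectrum,
    WavelengthCalibration,
    gaussian_smooth,
    linearise_values,
)

#: Default relative exposure grid of the linearisation ladder: 16
#: log-spaced fractions of the auto-exposed base integration time.
DEFAULT_LADDER_FRACTIONS = tuple(np.geomspace(0.005, 1.5, 16))

#: Smoothing width (photosites) applied to ladder spectra before fitting.
LADDER_SMOOTH_SIGMA = 3.0


@dataclass(frozen=True)
class LadderPoint:
    integration_time: int
    light: RawFrame
    dark: DarkFrame


@dataclass
class Ladder:
    """Light/dark exposure pairs over a known integration-time series."""

    points: list
    base_integration_time: int
    warnings: list = field(default_factory=list)


@dataclass(frozen=True)
class LinearisationFit:
    a: float
    b: float
    r_squared: float
    #: (integration_time, smoothed peak-bin light-minus-dark, peak-bin dark)
    ladder: tuple = ()
    peak_bin: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        times = [p[0] for p in self.ladder]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("ladder integration times must be strictly increasing")


@dataclass
class SensitivityCurve:
    """Per-photosite sensitivity in linear counts per us per radiance unit."""

    wavelengths: np.ndarray
    values: np.ndarray  # NaN where the reference spectrum has no coverage
    reference_id: str = ""
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        defined = np.isfinite(self.values)
        if np.any(self.values[defined] < 0):
            raise ValueError("sensitivity values must be non-negative")


@dataclass
class CalibrationRecord:
    """Everything needed to convert one unit's raw scans to radiance."""

    unit_id: int
    wavelength_cal: WavelengthCalibration
    lin_a: float
    lin_b: float
    sensitivity: np.ndarray  # per photosite
    light_reducer: Optional[str] = None
    light_reducer_attenuation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.sensitivity.shape[0] != self.wavelength_cal.n_photosites:
            raise ValueError("sensitivity length must match the wavelength calibration")


def collect_linearisation_ladder(
    instrument: InstrumentModel,
    scene: SceneModel,
    pose: GimbalState,
    fractions: Optional[Sequence[float]] = None,
    max_integration: int = DEFAULT_MAX_INTEGRATION_US,
) -> Ladder:
    """Acquire light and dark frames over fractions of the auto-exposed time.

    Auto-exposes once to find the base time ``T``, then exposes at each
    ``fraction * T`` (rounded to whole us and clamped to >= 500), pairing
    every light frame with a dark frame at the identical time.
    """
    fractions = np.asarray(
        DEFAULT_LADDER_FRACTIONS if fractions is None else fractions, dtype=float
    )
    if np.any(fractions <= 0) or np.any(fractions > 1.5):
        raise ValueError("fractions must lie in (0, 1.5]")
    base_t, _ = auto_expose(instrument, scene, pose, max_integration)
    warns = []
    if base_t >= max(t for t in _octave_times(max_integration)):
        warns.append(
            f"auto-exposure reached the maximum integration time ({base_t} us); "
            "scene may be too dim for a reliable ladder "
            "(recommended upper ladder times: 200,000-800,000 us)"
        )
        warnings.warn(warns[-1])
    times = sorted({max(MIN_INTEGRATION_US, int(round(f * base_t))) for f in fractions})
    points = []
    for t in times:
        light = expose(instrument, scene, pose, t)
        dark = dark_position_expose(instrument, t)
        points.append(LadderPoint(integration_time=t, light=light, dark=dark))
    return Ladder(points=points, base_integration_time=base_t, warnings=warns)


def _octave_times(max_integration: int) -> list:
    times, t = [], MIN_INTEGRATION_US
    while t <= max_integration:
        times.append(t)
        t *= 2
    return times


def fit_linearisation(
    ladder: Ladder,
    *,
    sigma: float = LADDER_SMOOTH_SIGMA,
    expected_scale: Optional[float] = None,
) -> LinearisationFit:
    """Least-squares fit of the linearisation coefficients from a ladder.

    Saturated exposures are removed; light and dark spectra are
    Gaussian-smoothed (default sigma 3); darks are subtracted; the
    wavelength bin with the highest response is selected; the log of the
    expected linear response (proportional to integration time) is
    regressed on ``ln(r - d)``.  See the module docstring for the scale
    convention controlled by ``expected_scale`` (counts per us).
    """
    usable = [p for p in ladder.points if not p.light.saturated]
    if len(usable) < 4:
        raise ValueError(f"need >= 4 unsaturated ladder points, have {len(usable)}")
    smoothed = []
    for p in usable:
        light_s = gaussian_smooth(p.light.counts.astype(float), sigma)
        dark_s = gaussian_smooth(p.dark.counts.astype(float), sigma)
        smoothed.append((p.integration_time, light_s - dark_s, dark_s))
    # peak bin from the longest (highest-SNR) usable exposure
    peak_bin = int(np.argmax(smoothed[-1][1]))
    records = []
    for t, diff, dark_s in smoothed:
        v = diff[peak_bin]
        if v <= 0:
            warnings.warn(
                f"non-positive peak-bin response at {t} us; ladder point dropped"
            )
            continue
        records.append((t, float(v), float(dark_s[peak_bin])))
    if len(records) < 4:
        raise ValueError("fewer than 4 usable ladder points after dropping non-positive responses")
    times = np.array([r[0] for r in records], dtype=float)
    values = np.array([r[1] for r in records], dtype=float)
    if expected_scale is None:
        ref = int(np.argmin(np.abs(times - np.median(times))))
        expected_scale = values[ref] / times[ref]
    x = np.log(values)
    y = np.log(float(expected_scale) * times)
    a, b = np.polyfit(x, y, 1)
    fitted = a * x + b
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return LinearisationFit(
        a=float(a),
        b=float(b),
        r_squared=r2,
        ladder=tuple((int(t), v, d) for t, v, d in records),
        peak_bin=peak_bin,
    )


def fit_sensitivity(
    cube: ScanCube,
    reference: Spectrum,
    linearisation: tuple,
    *,
    pixels: Optional[Sequence[tuple]] = None,
    reference_id: str = "",
) -> SensitivityCurve:
    """Spectral sensitivity from a white-standard scan and a reference spectrum.

    Averages raw counts over the standard pixels (which must share one
    integration time), averages the dark frames taken before and after
    the standard at that time, linearises the difference and divides by
    integration time and by the reference radiance interpolated onto the
    unit's wavelength grid:  ``s = c / (t * Le_ref)``.
    """
    if cube.wavelength_cal is None:
        raise ValueError("cube carries no wavelength calibration")
    if pixels is None:
        pixels = [k for k, rec in cube.pixels.items() if rec.flag == FLAG_MEASURED]
    if not pixels:
        raise ValueError("no pixels selected for the white standard")
    recs = [cube.pixels[tuple(p)] for p in pixels]
    times = {r.integration_time for r in recs}
    if len(times) != 1:
        raise ValueError(
            f"standard pixels must share one integration time, found {sorted(times)}"
        )
    t = times.pop()
    light_avg = np.mean([r.frame.counts for r in recs], axis=0)
    rows = [p[0] for p in pixels]
    lo, hi = min(rows), max(rows)
    before = [d.frame for d in cube.darks if d.frame.integration_time == t and d.after_row < lo]
    after = [d.frame for d in cube.darks if d.frame.integration_time == t and d.after_row >= hi]
    chosen = []
    if before:
        chosen.append(before[-1].counts)
    if after:
        chosen.append(after[0].counts)
    if not chosen:
        chosen = [d.frame.counts for d in cube.darks if d.frame.integration_time == t]
    if not chosen:
        raise LookupError(f"no dark frames at integration time {t} us")
    dark_avg = np.mean([np.asarray(c, dtype=float) for c in chosen], axis=0)
    a, b = linearisation
    c = linearise_values(light_avg - dark_avg, a, b)
    wl = cube.wavelength_cal.wavelengths()
    covered = (wl >= reference.wavelengths[0]) & (wl <= reference.wavelengths[-1])
    le_ref = reference.interpolated_to(wl)
    s = np.full_like(wl, np.nan)
    ok = covered & (le_ref > 0)
    s[ok] = np.maximum(c[ok] / (t * le_ref[ok]), 0.0)
    return SensitivityCurve(
        wavelengths=wl,
        values=s,
        reference_id=reference_id,
        n_pixels=len(pixels),
    )


# ---------------------------------------------------------------------------
# calibration_data.txt + reference-spectrum I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_calibration_file(records: Sequence[CalibrationRecord], path) -> None:
    """Write ``calibration_data.txt``: one ``key=value`` block per unit."""
    lines = ["# whisk-broom unit calibration data", ""]
    for rec in records:
        lines.append(f"unit={rec.unit_id}")
        lines.append("wl_coeffs=" + ",".join(_fmt(c) for c in rec.wavelength_cal.coefficients))
        lines.append(f"lin_a={_fmt(rec.lin_a)}")
        lines.append(f"lin_b={_fmt(rec.lin_b)}")
        lines.append(
            "sensitivity="
            + ",".join("nan" if not np.isfinite(v) else _fmt(v) for v in rec.sensitivity)
        )
        if rec.light_reducer is not None:
            lines.append(f"light_reducer={rec.light_reducer}")
            if rec.light_reducer_attenuation is not None:
                lines.append(
                    "light_reducer_attenuation="
                    + ",".join(_fmt(v) for v in np.atleast_1d(rec.light_reducer_attenuation))
                )
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_calibration_file(path) -> dict:
    """Parse ``calibration_data.txt`` into ``{unit_id: CalibrationRecord}``.

    Blank lines and ``#`` comments are ignored; a ``unit=`` key starts a
    new block.  Multiple units per file are supported.
    """
    blocks: list = []
    current: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw_line in fh:
            line = raw_line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed calibration line: {line!r}")
            key, value = line.split("=", 1)
            key = key.strip()
            if key == "unit" and current:
                blocks.append(current)
                current = {}
            current[key] = value.strip()
    if current:
        blocks.append(current)
    out = {}
    for blk in blocks:
        missing = {"unit", "wl_coeffs", "lin_a", "lin_b", "sensitivity"} - set(blk)
        if missing:
            raise ValueError(f"calibration block missing keys: {sorted(missing)}")
        sens = np.array([float(v) for v in blk["sensitivity"].split(",")])
        coeffs = tuple(float(v) for v in blk["wl_coeffs"].split(","))
        rec = CalibrationRecord(
            unit_id=int(blk["unit"]),
            wavelength_cal=WavelengthCalibration(coeffs, n_photosites=len(sens)),
            lin_a=float(blk["lin_a"]),
            lin_b=float(blk["lin_b"]),
            sensitivity=sens,
            light_reducer=blk.get("light_reducer"),
            light_reducer_attenuation=(
                np.array([float(v) for v in blk["light_reducer_attenuation"].split(",")])
                if "light_reducer_attenuation" in blk
                else None
            ),
        )
        out[rec.unit_id] = rec
    return out


def read_reference_spectrum(path, kind: str = "radiance") -> Spectrum:
    """Read a 2-column CSV ``wavelength_nm,value`` (header optional)."""
    wl, vals = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header line
            wl.append(w)
            vals.append(v)
    if len(wl) < 2:
        raise ValueError(f"reference spectrum {path} has fewer than 2 numeric rows")
    return Spectrum(wavelengths=np.asarray(wl), values=np.asarray(vals), kind=kind)
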