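"""Radiometric back end: calibrated radiance, reflectance, preview
renders (sRGB, extended-band, saturation, NDVI) and quantal cone catches.

All renders are deterministic functions of their input cube.  Display
normalisation anchors the 99.5th-percentile luminance to white so that
single bright sources do not crush night-scene previews.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .acquisition import FLAG_INTERPOLATED, FLAG_MEASURED, ScanCube
from .calibration import CalibrationRecord
from .cmf import XYZ_TO_SRGB, srgb_transfer, xyz_cmf
from .spectral import Spectrum, linearise_values

#: Band edges (nm) for the extended-range preview and NDVI; configurable.
DEFAULT_BANDS = {
    "uv": (320.0, 400.0),
    "red": (620.0, 700.0),
    "nir": (750.0, 850.0),
}

#: Fraction of pixels allowed above "white" in preview normalisation.
DISPLAY_PERCENTILE = 99.5


@dataclass
class RadianceCube:
    """Grid of absolute spectral radiance with per-pixel provenance flags.

    ``data`` is ``(n_rows, n_cols, n_photosites)`` in W sr^-1 m^-2 nm^-1;
    photosites with undefined sensitivity are NaN.  Small negatives from
    noise subtraction are preserved in the data but clipped for renders.
    """

    wavelengths: np.ndarray
    data: np.ndarray
    saturated: np.ndarray  # bool (n_rows, n_cols)
    interpolated: np.ndarray  # bool (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def measured_mask(self) -> np.ndarray:
        return ~self.interpolated


@dataclass
class ReceptorSet:
    """Named receptor spectral-sensitivity functions on a common grid."""

    wavelengths: np.ndarray
    receptors: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name, vals in self.receptors.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.wavelengths.shape:
                raise ValueError(f"receptor {name!r} length mismatch")
            if np.any(vals < 0):
                raise ValueError(f"receptor {name!r} has negative sensitivity")
            self.receptors[name] = vals

    @classmethod
    def from_csv(cls, path) -> "ReceptorSet":
        """Read ``sensitivity_data.csv``: wavelength_nm then named columns."""
        import pandas as pd

        df = pd.read_csv(path)
        wl_col = df.columns[0]
        wl = df[wl_col].to_numpy(dtype=float)
        receptors = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
        if not receptors:
            raise ValueError(f"{path} contains no receptor columns")
        return cls(wavelengths=wl, receptors=receptors)


def _trapezoid_weights(wavelengths: np.ndarray) -> np.ndarray:
    """Per-sample integration weights for a non-uniform wavelength grid."""
    wl = np.asarray(wavelengths, dtype=float)
    w = np.empty_like(wl)
    w[1:-1] = (wl[2:] - wl[:-2]) / 2.0
    w[0] = (wl[1] - wl[0]) / 2.0
    w[-1] = (wl[-1] - wl[-2]) / 2.0
    return w


def cube_to_radiance(cube: ScanCube, cal: CalibrationRecord) -> RadianceCube:
    """Convert a raw scan cube to absolute spectral radiance.

    Per pixel: ``Le = linearise(raw - matched dark) / (t * s)`` with the
    temporally nearest dark frame at the pixel's integration time.
    """
    wl = cal.wavelength_cal.wavelengths()
    sens = cal.sensitivity.copy()
    if cal.light_reducer_attenuation is not None:
        sens = sens * np.broadcast_to(
            np.asarray(cal.light_reducer_attenuation, dtype=float), sens.shape
        )
    defined = np.isfinite(sens) & (sens > 0)
    n_rows, n_cols = cube.n_rows, cube.n_cols
    data = np.full((n_rows, n_cols, wl.shape[0]), np.nan)
    saturated = np.zeros((n_rows, n_cols), dtype=bool)
    interpolated = np.zeros((n_rows, n_cols), dtype=bool)
    for (row, col), rec in cube.pixels.items():
        t = rec.integration_time
        try:
            dark = cube.nearest_dark(t, row)
        except LookupError as exc:
            raise LookupError(
                f"missing dark frame at integration time {t} us for pixel ({row}, {col})"
            ) from exc
        diff = rec.frame.counts.astype(float) - dark.counts.astype(float)
        c = linearise_values(np.abs(diff), cal.lin_a, cal.lin_b) * np.sign(diff)
        le = np.full_like(c, np.nan)
        le[defined] = c[defined] / (t * sens[defined])
        data[row, col] = le
        saturated[row, col] = rec.frame.saturated
        interpolated[row, col] = rec.flag == FLAG_INTERPOLATED
    return RadianceCube(wavelengths=wl, data=data, saturated=saturated, interpolated=interpolated)


def to_reflectance(
    cube: RadianceCube,
    standard_pixel: tuple,
    standard_reflectance: float = 1.0,
) -> np.ndarray:
    """Per-pixel reflectance (%) relative to a standard pixel's radiance.

    ``R = 100 * Le / Le_standard * standard_reflectance``; wavelengths
    where the standard's radiance is ~0 are masked NaN.
    """
    row, col = standard_pixel
    if cube.saturated[row, col]:
        raise ValueError(f"standard pixel {standard_pixel} is saturated")
    if cube.interpolated[row, col]:
        raise ValueError(f"standard pixel {standard_pixel} is interpolated, not measured")
    std = cube.data[row, col]
    finite = np.isfinite(std)
    guard = np.zeros_like(std, dtype=bool)
    guard[finite] = std[finite] > 1e-12 * np.nanmax(np.abs(std))
    out = np.full_like(cube.data, np.nan)
    out[..., guard] = 100.0 * standard_reflectance * cube.data[..., guard] / std[guard]
    return out


def _display_clipped(cube: RadianceCube) -> np.ndarray:
    return np.nan_to_num(np.maximum(cube.data, 0.0), nan=0.0)


def xyz_image(cube: RadianceCube) -> np.ndarray:
    """Per-pixel CIE XYZ from trapezoid integration against the CMFs."""
    le = _display_clipped(cube)
    w = _trapezoid_weights(cube.wavelengths)
    cmf = xyz_cmf(cube.wavelengths)
    return np.einsum("rck,kj,k->rcj", le, cmf, w)


def _finalise_render(channels: np.ndarray, white: np.ndarray) -> np.ndarray:
    """White-balance to equal-energy, normalise, gamma-encode, to uint8."""
    balanced = channels / white
    lum = balanced.max(axis=-1)
    scale = np.percentile(lum, DISPLAY_PERCENTILE)
    if scale <= 0:
        scale = 1.0
    return (srgb_transfer(balanced / scale) * 255.0 + 0.5).astype(np.uint8)


def render_srgb(cube: RadianceCube) -> np.ndarray:
    """8-bit sRGB preview; equal-energy spectra render neutral grey."""
    xyz = xyz_image(cube)
    rgb = np.einsum("ij,rcj->rci", XYZ_TO_SRGB, xyz)
    w = _trapezoid_weights(cube.wavelengths)
    xyz_e = xyz_cmf(cube.wavelengths).T @ w  # equal-energy white
    white = XYZ_TO_SRGB @ xyz_e
    return _finalise_render(np.maximum(rgb, 0.0), white)


def band_integral(cube: RadianceCube, lo_nm: float, hi_nm: float) -> np.ndarray:
    """Per-pixel radiance integrated over [lo_nm, hi_nm]."""
    le = _display_clipped(cube)
    w = _trapezoid_weights(cube.wavelengths)
    sel = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    return np.einsum("rck,k->rc", le[..., sel], w[sel])


def extended_channels(cube: RadianceCube, bands: Optional[dict] = None) -> np.ndarray:
    """Linear extended-range channels: R=NIR band, G=CIE Y, B=UV band."""
    bands = dict(DEFAULT_BANDS, **(bands or {}))
    r = band_integral(cube, *bands["nir"])
    g = xyz_image(cube)[..., 1]
    b = band_integral(cube, *bands["uv"])
    return np.stack([r, g, b], axis=-1)


def render_extended(cube: RadianceCube, bands: Optional[dict] = None) -> np.ndarray:
    """8-bit extended-spectral-range preview (NIR / CIE Y / UV)."""
    bands = dict(DEFAULT_BANDS, **(bands or {}))
    channels = extended_channels(cube, bands)
    w = _trapezoid_weights(cube.wavelengths)
    sel_nir = (cube.wavelengths >= bands["nir"][0]) & (cube.wavelengths <= bands["nir"][1])
    sel_uv = (cube.wavelengths >= bands["uv"][0]) & (cube.wavelengths <= bands["uv"][1])
    white = np.array(
        [
            max(w[sel_nir].sum(), 1e-12),
            float(xyz_cmf(cube.wavelengths)[:, 1] @ w),
            max(w[sel_uv].sum(), 1e-12),
        ]
    )
    return _finalise_render(channels, white)


def render_saturation_mask(cube: ScanCube) -> np.ndarray:
    """Boolean image, true exactly where the stored frame saturated."""
    mask = np.zeros((cube.n_rows, cube.n_cols), dtype=bool)
    for (row, col), rec in cube.pixels.items():
        mask[row, col] = rec.frame.saturated
    return mask


def render_ndvi(cube: RadianceCube, bands: Optional[dict] = None) -> np.ndarray:
    """Per-pixel NDVI = (NIR - Red) / (NIR + Red) in [-1, 1]; 0/0 -> 0."""
    bands = dict(DEFAULT_BANDS, **(bands or {}))
    nir = band_integral(cube, *bands["nir"])
    red = band_integral(cube, *bands["red"])
    denom = nir + red
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = (nir[nz] - red[nz]) / denom[nz]
    return np.clip(out, -1.0, 1.0)


def cone_catch(cube: RadianceCube, receptors: ReceptorSet) -> Dict[str, np.ndarray]:
    """Relative quantal catch per receptor: ``Q = sum Le * lambda * S * dl``.

    The wavelength factor converts energy to quantal units (constants
    dropped; only relative catches are output).  Receptors are resampled
    onto the cube grid by linear interpolation, zero outside their range.
    """
    wl = cube.wavelengths
    if receptors.wavelengths[-1] < wl[0] or receptors.wavelengths[0] > wl[-1]:
        raise ValueError("receptor wavelength range does not overlap the cube's")
    le = _display_clipped(cube)
    w = _trapezoid_weights(wl)
    out = {}
    for name, vals in receptors.receptors.items():
        s = np.interp(wl, receptors.wavelengths, vals, left=0.0, right=0.0)
        out[name] = np.einsum("rck,k->rc", le, wl * s * w)
    return out


def scene_peak_ratio(cube: RadianceCube) -> float:
    """Highest per-pixel spectral peak over the lowest, measured pixels only.

    Interpolated pixels are excluded; saturated pixels are excluded from
    the denominator (their radiance is clipped, not low).  A non-positive
    minimum yields ``inf`` with a warning.
    """
    measured = cube.measured_mask()
    if measured.sum() < 2:
        raise ValueError("need at least 2 measured pixels")
    peaks = np.nanmax(np.maximum(cube.data, 0.0), axis=-1)
    numerator = float(np.max(peaks[measured]))
    valid_min = measured & ~cube.saturated
    denominator = float(np.min(peaks[valid_min]))
    if denominator <= 0:
        warnings.warn("lowest spectral peak is non-positive; ratio reported as inf")
        return float("inf")
    return numerator / denominator


def spectrum_at(cube: RadianceCube, pixel: tuple, kind: str = "radiance") -> Spectrum:
    """The radiance spectrum of one pixel as a :class:`Spectrum`."""
    row, col = pixel
    vals = np.maximum(np.nan_to_num(cube.data[row, col], nan=0.0), 0.0)
    return Spectrum(wavelengths=cube.wavelengths, values=vals, kind=kind)


def export_spectrum_csv(path, wavelengths: np.ndarray, values: np.ndarray, kind: str) -> None:
    """2-column CSV with a header naming the kind (radiance/reflectance)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"wavelength_nm,{kind}\n")
        for w, v in zip(wavelengths, values):
            fh.write(f"{w:.9g},{v:.9g}\n")
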