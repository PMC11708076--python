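"""Core spectral data types and photosite-domain math.

Everything downstream (simulation, acquisition, calibration, radiometry)
is built on the small vocabulary defined here: raw sensor readouts, dark
readouts, the photosite->wavelength polynomial, and generic spectra.

Count linearisation follows

    c = exp(ln(r - d) * a + b)

where ``r`` is the raw count, ``d`` the dark count at the same
integration time and ``(a, b)`` the linearisation coefficients.  With
``a = 1, b = 0`` this reduces exactly to plain dark subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: Number of photosites on the default sensor.
N_PHOTOSITES = 288

#: Shortest supported integration time, in microseconds.
MIN_INTEGRATION_US = 500

#: Default user-facing maximum integration time (2 s), in microseconds.
DEFAULT_MAX_INTEGRATION_US = 2_000_000

#: Hard firmware cap on integration time (30 s), in microseconds.
MAX_INTEGRATION_CAP_US = 30_000_000

#: Default ADC ceiling on a 16-bit count scale.  The saturation level is
#: configurable everywhere; only internal consistency matters.
DEFAULT_SATURATION_LEVEL = 65535

SPECTRUM_KINDS = ("raw-linear-counts", "radiance", "reflectance-percent", "sensitivity")


def _as_count_array(counts: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class RawFrame:
    """One spectrometer readout: per-photosite counts at one integration time."""

    counts: np.ndarray
    integration_time: int
    saturated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _as_count_array(self.counts, "counts"))
        if self.integration_time < MIN_INTEGRATION_US:
            raise ValueError(
                f"integration_time must be >= {MIN_INTEGRATION_US} us, "
                f"got {self.integration_time}"
            )

    @property
    def n_photosites(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        integration_time: int,
        saturation_level: int = DEFAULT_SATURATION_LEVEL,
    ) -> "RawFrame":
        """Build a frame, deriving the saturated flag from the ADC ceiling."""
        counts = np.asarray(counts)
        return cls(
            counts=counts,
            integration_time=int(integration_time),
            saturated=bool(counts.max(initial=0) >= saturation_level),
        )


@dataclass(frozen=True)
class DarkFrame:
    """A readout taken with the optic blocked; same layout as :class:`RawFrame`."""

    counts: np.ndarray
    integration_time: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _as_count_array(self.counts, "counts"))
        if self.integration_time < MIN_INTEGRATION_US:
            raise ValueError(
                f"integration_time must be >= {MIN_INTEGRATION_US} us, "
                f"got {self.integration_time}"
            )

    @property
    def n_photosites(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class WavelengthCalibration:
    """Polynomial mapping photosite index -> wavelength in nm.

    Coefficients are ordered lowest power first (``c0 + c1*i + c2*i**2 ...``),
    up to degree 5 (six coefficients), matching the manufacturer convention
    for this sensor family.  Shorter coefficient lists are zero-padded.
    """

    coefficients: tuple = ()
    n_photosites: int = N_PHOTOSITES

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        if not 1 <= len(coeffs) <= 6:
            raise ValueError("between 1 and 6 polynomial coefficients required")
        coeffs = coeffs + (0.0,) * (6 - len(coeffs))
        object.__setattr__(self, "coefficients", coeffs)
        wl = self.wavelengths()
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength polynomial is not strictly increasing over photosites")
        if wl[0] < 250.0 or wl[-1] > 1000.0:
            raise ValueError(
                f"wavelength range {wl[0]:.1f}-{wl[-1]:.1f} nm is implausible for this sensor"
            )

    def wavelengths(self) -> np.ndarray:
        """All ``n_photosites`` wavelengths, strictly increasing."""
        idx = np.arange(self.n_photosites, dtype=float)
        return np.polynomial.polynomial.polyval(idx, np.array(self.coefficients))


def wavelength_for_photosite(index: int, cal: WavelengthCalibration) -> float:
    """Wavelength (nm) of a single photosite under ``cal``."""
    if not 0 <= index < cal.n_photosites:
        raise IndexError(f"photosite index {index} out of range 0..{cal.n_photosites - 1}")
    return float(np.polynomial.polynomial.polyval(float(index), np.array(cal.coefficients)))


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed vector of one declared kind."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "radiance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind in ("radiance", "sensitivity") and np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def interpolated_to(self, wavelengths: np.ndarray) -> np.ndarray:
        """Values linearly interpolated onto another grid (end values held)."""
        return np.interp(np.asarray(wavelengths, dtype=float), self.wavelengths, self.values)


def linearise_values(diff: np.ndarray, a: float, b: float) -> np.ndarray:
    """Apply the linearisation curve to already dark-subtracted counts.

    Non-positive inputs (negative noise excursions at low light) map to 0.
    """
    diff = np.asarray(diff, dtype=float)
    out = np.zeros_like(diff)
    pos = diff > 0
    out[pos] = np.exp(np.log(diff[pos]) * a + b)
    return out


def linearise_counts(
    raw: RawFrame,
    dark: DarkFrame,
    a: float,
    b: float,
    *,
    allow_time_mismatch: bool = False,
) -> np.ndarray:
    """Linear counts ``c = exp(ln(r - d)*a + b)`` per photosite.

    ``raw`` and ``dark`` must share an integration time unless the caller
    explicitly overrides (darks are only valid at the matching time).
    """
    if raw.n_photosites != dark.n_photosites:
        raise ValueError(
            f"frame lengths differ: raw has {raw.n_photosites}, dark has {dark.n_photosites}"
        )
    if raw.integration_time != dark.integration_time and not allow_time_mismatch:
        raise ValueError(
            "raw and dark integration times differ "
            f"({raw.integration_time} vs {dark.integration_time} us); "
            "pass allow_time_mismatch=True to override"
        )
    return linearise_values(raw.counts.astype(float) - dark.counts.astype(float), a, b)


def compress_spectrum(values: np.ndarray, window: int) -> np.ndarray:
    """Boxcar-average consecutive non-overlapping windows of channels.

    ``window=1`` is the identity.  A trailing partial window is averaged
    over its actual members (no padding).
    """
    window = int(window)
    if window <= 0:
        raise ValueError(f"window must be a positive integer, got {window}")
    values = np.asarray(values, dtype=float)
    if window == 1:
        return values.copy()
    n = values.shape[0]
    n_full = n // window
    full = values[: n_full * window].reshape(n_full, window).mean(axis=1)
    if n_full * window == n:
        return full
    tail = values[n_full * window :].mean()
    return np.concatenate([full, [tail]])


def gaussian_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing over photosite index; reflect-at-boundary edges."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    values = np.asarray(values, dtype=float)
    if sigma == 0:
        return values.copy()
    return gaussian_filter1d(values, sigma=float(sigma), mode="reflect")
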