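"""Virtual instrument: forward model of sensor + gimbal + scene.

The simulated sensor embodies the *inverse* of the linearisation curve:
ideal linear counts ``c = sensitivity * Le * t`` are mapped to raw counts
through ``raw - dark = exp((ln c - b) / a)``, so that applying
:func:`whiskbroom.spectral.linearise_counts` with the same ``(a, b)``
recovers ``c`` exactly.  Dark counts are affine in integration time.
Noise is Gaussian with a shot-noise-like standard deviation
``sqrt(gain * expected + read_noise**2)``; both parameters are
configurable and may be zero for noise-free runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .spectral import (
    DEFAULT_SATURATION_LEVEL,
    MIN_INTEGRATION_US,
    DarkFrame,
    RawFrame,
    Spectrum,
    WavelengthCalibration,
)

#: Stepper resolution of the default gimbal motors.
DEFAULT_STEPS_PER_REV = 2048

#: Mechanical elevation limits of the gimbal, degrees.
ELEVATION_MIN_DEG = -20.0
ELEVATION_MAX_DEG = 90.0

_ELEVATION_TOL = 1e-6


@dataclass(frozen=True)
class GimbalState:
    """Pan/tilt pose in stepper steps.

    ``degrees = steps * 360 / (steps_per_revolution * gear_ratio)``; the
    gear ratio defaults to 1 (direct drive) and is exposed per axis for
    geared builds.
    """

    pan_step: int
    tilt_step: int
    steps_per_revolution: int = DEFAULT_STEPS_PER_REV
    pan_gear_ratio: float = 1.0
    tilt_gear_ratio: float = 1.0

    @property
    def azimuth_deg(self) -> float:
        return self.pan_step * 360.0 / (self.steps_per_revolution * self.pan_gear_ratio)

    @property
    def elevation_deg(self) -> float:
        return self.tilt_step * 360.0 / (self.steps_per_revolution * self.tilt_gear_ratio)

    def __post_init__(self) -> None:
        el = self.elevation_deg
        if not (ELEVATION_MIN_DEG - _ELEVATION_TOL <= el <= ELEVATION_MAX_DEG + _ELEVATION_TOL):
            raise ValueError(
                f"tilt step {self.tilt_step} (elevation {el:.2f} deg) outside "
                f"mechanical range {ELEVATION_MIN_DEG}..{ELEVATION_MAX_DEG} deg"
            )


@dataclass
class SceneModel:
    """Spectral radiance field over viewing direction.

    ``radiance_fn(azimuth_deg, elevation_deg)`` returns a radiance
    :class:`Spectrum` on the scene's own wavelength grid; the instrument
    interpolates it onto its photosite grid (pinhole approximation: the
    pose's central direction only).
    """

    radiance_fn: Callable[[float, float], Spectrum]
    description: str = ""


@dataclass
class InstrumentModel:
    """Ground-truth simulator state for one virtual unit."""

    wavelength_cal: WavelengthCalibration
    sensitivity: np.ndarray  # linear counts per us per (W sr^-1 m^-2 nm^-1)
    nonlinearity_a: float = 1.0
    nonlinearity_b: float = 0.0
    dark_offset: np.ndarray | float = 60.0  # counts at t -> 0
    dark_slope: np.ndarray | float = 2e-5  # counts per us
    noise_gain: float = 0.02
    read_noise: float = 0.5
    noise_sd_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    saturation_level: int = DEFAULT_SATURATION_LEVEL
    rng_seed: int = 0
    #: Round counts to integers (real ADC behaviour).  Disable for
    #: analytic tests of the continuous forward chain.
    quantise: bool = True

    def __post_init__(self) -> None:
        n = self.wavelength_cal.n_photosites
        self.sensitivity = np.broadcast_to(np.asarray(self.sensitivity, dtype=float), (n,)).copy()
        if np.any(self.sensitivity < 0):
            raise ValueError("sensitivity must be non-negative")
        self.dark_offset = np.broadcast_to(np.asarray(self.dark_offset, dtype=float), (n,)).copy()
        self.dark_slope = np.broadcast_to(np.asarray(self.dark_slope, dtype=float), (n,)).copy()
        self.reset_rng()

    @property
    def n_photosites(self) -> int:
        return self.wavelength_cal.n_photosites

    def reset_rng(self) -> None:
        """Restart the noise stream; same seed + call order => same frames."""
        self._rng = np.random.default_rng(self.rng_seed)

    def noiseless(self) -> "InstrumentModel":
        """A copy of this model with all noise switched off."""
        return replace(self, noise_gain=0.0, read_noise=0.0, noise_sd_fn=None)

    # -- internal helpers -------------------------------------------------

    def _dark_expected(self, integration_time: int) -> np.ndarray:
        return self.dark_offset + self.dark_slope * float(integration_time)

    def _noise_sd(self, expected: np.ndarray) -> np.ndarray:
        if self.noise_sd_fn is not None:
            return np.asarray(self.noise_sd_fn(expected), dtype=float)
        return np.sqrt(self.noise_gain * np.maximum(expected, 0.0) + self.read_noise**2)

    def _digitise(self, expected: np.ndarray) -> np.ndarray:
        sd = self._noise_sd(expected)
        raw = expected
        if np.any(sd > 0):
            raw = raw + sd * self._rng.standard_normal(expected.shape)
        if self.quantise:
            return np.clip(np.rint(raw), 0, self.saturation_level).astype(np.int64)
        return np.clip(raw, 0.0, float(self.saturation_level))


def _check_integration_time(integration_time: int) -> int:
    integration_time = int(integration_time)
    if integration_time < MIN_INTEGRATION_US:
        raise ValueError(f"integration time must be >= {MIN_INTEGRATION_US} us")
    return integration_time


def expose(
    model: InstrumentModel,
    scene: SceneModel,
    pose: GimbalState,
    integration_time: int,
) -> RawFrame:
    """Simulate one light exposure at a pose.

    Forward chain per photosite: ``c = s * Le * t`` ideal linear counts,
    ``raw = dark(t) + exp((ln c - b)/a) + noise``, rounded and clipped at
    the saturation level.  The saturated flag is set iff any photosite
    reached the ceiling.
    """
    t = _check_integration_time(integration_time)
    radiance = scene.radiance_fn(pose.azimuth_deg % 360.0, pose.elevation_deg)
    le = radiance.interpolated_to(model.wavelength_cal.wavelengths())
    c = model.sensitivity * np.maximum(le, 0.0) * float(t)
    signal = np.zeros_like(c)
    pos = c > 0
    signal[pos] = np.exp((np.log(c[pos]) - model.nonlinearity_b) / model.nonlinearity_a)
    expected = model._dark_expected(t) + signal
    counts = model._digitise(expected)
    return RawFrame(
        counts=counts,
        integration_time=t,
        saturated=bool(counts.max() >= model.saturation_level),
    )


def dark_position_expose(model: InstrumentModel, integration_time: int) -> DarkFrame:
    """Simulate a dark reading (spectrometer rotated into the housing)."""
    t = _check_integration_time(integration_time)
    return DarkFrame(counts=model._digitise(model._dark_expected(t)), integration_time=t)


# ---------------------------------------------------------------------------
# Reference scenes
# ---------------------------------------------------------------------------

_SCENE_GRID = np.arange(300.0, 951.0, 1.0)


def _gauss(wl: np.ndarray, centre: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / sd) ** 2)


def _planck_shape(wl_nm: np.ndarray, temperature_k: float) -> np.ndarray:
    """Blackbody spectral radiance shape, normalised to peak 1 on the grid."""
    h = 6.62607015e-34
    c = 2.99792458e8
    kb = 1.380649e-23
    lam = wl_nm * 1e-9
    vals = (1.0 / lam**5) / np.expm1(h * c / (lam * kb * temperature_k))
    return vals / vals.max()


@dataclass(frozen=True)
class PointSource:
    """Flat-top angular disk source with its own emission spectrum."""

    azimuth_deg: float
    elevation_deg: float
    radius_deg: float
    spectrum: np.ndarray  # on _SCENE_GRID

    def contains(self, az: float, el: float) -> bool:
        daz = (az - self.azimuth_deg + 180.0) % 360.0 - 180.0
        # small-angle chord distance; adequate at the low elevations used
        dist = np.hypot(daz * np.cos(np.deg2rad(el)), el - self.elevation_deg)
        return bool(dist <= self.radius_deg)


def _source_scene(
    sources: list[PointSource], background: np.ndarray, description: str
) -> SceneModel:
    def radiance_fn(az: float, el: float) -> Spectrum:
        vals = background.copy()
        for src in sources:
            if src.contains(az, el):
                vals = vals + src.spectrum
        return Spectrum(wavelengths=_SCENE_GRID, values=vals, kind="radiance")

    return SceneModel(radiance_fn=radiance_fn, description=description)


#: Default peak-radiance contrast of the hdr-night scene (construction
#: parameter; brightest source peak / background peak).
HDR_NIGHT_PEAK_RATIO = 60000.0

#: Default per-source directions of the hdr-night scene, degrees.
HDR_NIGHT_SOURCE_DIRECTIONS = ((42.0, 0.0), (84.0, 6.0), (21.0, 6.0), (63.0, 0.0))


def make_reference_scene(
    kind: str,
    *,
    level: float = 1.0,
    temperature_k: float = 2856.0,
    centres_nm: tuple = (450.0, 589.0, 546.0),
    peak_ratio: float = HDR_NIGHT_PEAK_RATIO,
    bright_peak: float = 100.0,
    source_radius_deg: float = 5.0,
) -> SceneModel:
    """Deterministic parametric scenes used as simulator fixtures.

    ``flat``
        Spatially and spectrally constant radiance ``level``.
    ``blackbody-like``
        Spatially uniform Planck-shaped spectrum (peak ``level``).
    ``narrowband-set``
        Dark background with one narrowband disk source per entry of
        ``centres_nm``, spread over azimuth at elevation 0.
    ``hdr-night``
        Dim broadband background plus point-like disk sources with
        distinct emission spectra; the brightest source's spectral peak
        is ``peak_ratio`` times the background's spectral peak.
    """
    wl = _SCENE_GRID
    if kind == "flat":
        vals = np.full_like(wl, float(level))

        def radiance_fn(az: float, el: float) -> Spectrum:
            return Spectrum(wavelengths=wl, values=vals, kind="radiance")

        return SceneModel(radiance_fn=radiance_fn, description="flat")

    if kind == "blackbody-like":
        vals = float(level) * _planck_shape(wl, temperature_k)

        def radiance_fn(az: float, el: float) -> Spectrum:
            return Spectrum(wavelengths=wl, values=vals, kind="radiance")

        return SceneModel(radiance_fn=radiance_fn, description=f"blackbody {temperature_k:.0f}K")

    if kind == "narrowband-set":
        sources = [
            PointSource(
                azimuth_deg=30.0 + 40.0 * i,
                elevation_deg=0.0,
                radius_deg=source_radius_deg,
                spectrum=float(level) * _gauss(wl, c, 4.0),
            )
            for i, c in enumerate(centres_nm)
        ]
        return _source_scene(sources, np.zeros_like(wl), "narrowband-set")

    if kind == "hdr-night":
        background_peak = bright_peak / float(peak_ratio)
        # broad sky-glow-like background, peak exactly background_peak
        bg_shape = 0.85 * _gauss(wl, 600.0, 150.0) + 0.15 * _gauss(wl, 450.0, 60.0)
        background = background_peak * bg_shape / bg_shape.max()
        shapes = [
            # low-pressure-sodium-like doublet
            _gauss(wl, 589.0, 3.0) + 0.7 * _gauss(wl, 595.0, 3.0),
            # white-LED-like: blue pump + phosphor hump
            _gauss(wl, 450.0, 10.0) + 0.55 * _gauss(wl, 560.0, 50.0),
            # metal-halide-like line set
            _gauss(wl, 436.0, 4.0) + 0.9 * _gauss(wl, 546.0, 4.0) + 0.6 * _gauss(wl, 578.0, 4.0),
            # halogen-like broadband
            _planck_shape(wl, 3000.0),
        ]
        brightness = (1.0, 0.04, 0.002, 0.0002)  # spreads exposures over octaves
        sources = []
        for (az, el), shape, rel in zip(HDR_NIGHT_SOURCE_DIRECTIONS, shapes, brightness):
            peak = bright_peak * rel
            sources.append(
                PointSource(
                    azimuth_deg=az,
                    elevation_deg=el,
                    radius_deg=source_radius_deg,
                    spectrum=peak * shape / shape.max(),
                )
            )
        return _source_scene(sources, background, "hdr-night")

    raise ValueError(f"unknown reference scene kind {kind!r}")


# ---------------------------------------------------------------------------
# Default unit
# ---------------------------------------------------------------------------

DEFAULT_WAVELENGTH_COEFFS = (320.0, 2.4, -0.0016)


def default_instrument(seed: int = 0, **overrides) -> InstrumentModel:
    """A plausible default virtual unit (320-877 nm over 288 photosites)."""
    cal = overrides.pop("wavelength_cal", WavelengthCalibration(DEFAULT_WAVELENGTH_COEFFS))
    wl = cal.wavelengths()
    sens = overrides.pop("sensitivity", np.exp(-(((wl - 580.0) / 180.0) ** 2)))
    idx = np.arange(cal.n_photosites)
    params = dict(
        wavelength_cal=cal,
        sensitivity=sens,
        nonlinearity_a=1.04,
        nonlinearity_b=0.2,
        dark_offset=60.0 + 5.0 * np.sin(idx / 7.0),
        dark_slope=2e-5,
        rng_seed=int(seed),
    )
    params.update(overrides)
    return InstrumentModel(**params)
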