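"""Firmware decision logic, run against any instrument exposing the
``expose``/``dark_position_expose`` contract.

Per-pixel HDR exposure: integration times start at the 500 us minimum and
double (octaves) until an exposure saturates or the configured maximum is
reached; the last non-saturated frame is kept.  Exposures are computed
independently at every gimbal position.

Scan grids are laid out on a Mercator-style pan/tilt raster.  Rows near
the poles are over-sampled by that projection, so the planner measures
only ``max(1, round(n_cols * cos(elevation)))`` columns per row and the
remaining pixels are filled by per-photosite linear interpolation of
exposure-normalised (counts-per-us, dark-subtracted) values.

Dark frames are taken after every ``dark_interval`` rows (and always at
scan end) at every integration time used since the previous dark set.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .instrument import (
    DEFAULT_STEPS_PER_REV,
    ELEVATION_MAX_DEG,
    ELEVATION_MIN_DEG,
    GimbalState,
    InstrumentModel,
    SceneModel,
    dark_position_expose,
    expose,
)
from .spectral import (
    DEFAULT_MAX_INTEGRATION_US,
    MAX_INTEGRATION_CAP_US,
    MIN_INTEGRATION_US,
    DarkFrame,
    RawFrame,
    WavelengthCalibration,
)

#: Steps the pan axis overshoots (then returns) at the start of each
#: panning pass to take up gear backlash.
BACKLASH_OVERSHOOT_STEPS = 8

FLAG_MEASURED = "measured"
FLAG_INTERPOLATED = "interpolated"


@dataclass(frozen=True)
class ScanPlan:
    """Scan-grid and exposure limits, all positions in stepper steps."""

    pan_start: int
    pan_stop: int
    pan_step_size: int
    tilt_start: int
    tilt_stop: int
    tilt_step_size: int
    max_integration: int = DEFAULT_MAX_INTEGRATION_US
    min_integration: int = MIN_INTEGRATION_US
    dark_interval: int = 1
    steps_per_revolution: int = DEFAULT_STEPS_PER_REV

    def __post_init__(self) -> None:
        if self.pan_step_size < 1 or self.tilt_step_size < 1:
            raise ValueError("step sizes must be >= 1")
        if self.pan_stop < self.pan_start or self.tilt_stop < self.tilt_start:
            raise ValueError("stop positions must be >= start positions")
        deg = 360.0 / self.steps_per_revolution
        if (self.pan_stop - self.pan_start) * deg > 360.0:
            raise ValueError("pan span exceeds 360 degrees")
        el_lo = self.tilt_start * deg
        el_hi = self.tilt_stop * deg
        if el_lo < ELEVATION_MIN_DEG - 1e-6 or el_hi > ELEVATION_MAX_DEG + 1e-6:
            raise ValueError(
                f"tilt span {el_lo:.2f}..{el_hi:.2f} deg outside "
                f"{ELEVATION_MIN_DEG}..{ELEVATION_MAX_DEG} deg"
            )
        if not (
            MIN_INTEGRATION_US
            <= self.min_integration
            <= self.max_integration
            <= MAX_INTEGRATION_CAP_US
        ):
            raise ValueError(
                "require 500 <= min_integration <= max_integration <= 30,000,000 us"
            )
        if self.dark_interval < 1:
            raise ValueError("dark_interval must be >= 1")

    @property
    def pan_positions(self) -> np.ndarray:
        return np.arange(self.pan_start, self.pan_stop + 1, self.pan_step_size)

    @property
    def tilt_positions(self) -> np.ndarray:
        return np.arange(self.tilt_start, self.tilt_stop + 1, self.tilt_step_size)

    @property
    def n_cols(self) -> int:
        return len(self.pan_positions)

    @property
    def n_rows(self) -> int:
        return len(self.tilt_positions)

    def elevation_deg(self, row: int) -> float:
        return self.tilt_positions[row] * 360.0 / self.steps_per_revolution


@dataclass
class PixelRecord:
    """One grid cell: its frame, exposure, and measured/interpolated flag."""

    frame: RawFrame
    flag: str = FLAG_MEASURED

    @property
    def integration_time(self) -> int:
        return self.frame.integration_time


@dataclass
class DarkRecord:
    """A dark frame plus the row index after which it was acquired."""

    after_row: int
    frame: DarkFrame


@dataclass
class ScanCube:
    """Grid of independently exposed pixels plus dark frames and metadata."""

    plan: ScanPlan
    pixels: dict  # (row, col) -> PixelRecord
    darks: list  # of DarkRecord, in acquisition order
    metadata: dict = field(default_factory=dict)
    wavelength_cal: Optional[WavelengthCalibration] = None
    backlash_events: list = field(default_factory=list)  # (row, overshoot_steps)

    @property
    def n_rows(self) -> int:
        return self.plan.n_rows

    @property
    def n_cols(self) -> int:
        return self.plan.n_cols

    def used_integration_times(self) -> list:
        return sorted({rec.frame.integration_time for rec in self.pixels.values()})

    def nearest_dark(self, integration_time: int, row: int) -> DarkFrame:
        """Temporally nearest dark frame at the matching integration time."""
        candidates = [d for d in self.darks if d.frame.integration_time == integration_time]
        if not candidates:
            raise LookupError(
                f"no dark frame at integration time {integration_time} us in cube"
            )
        best = min(candidates, key=lambda d: (abs(d.after_row - row), d.after_row))
        return best.frame


def octave_ladder(min_integration: int, max_integration: int) -> list:
    """Integration times ``min, 2*min, 4*min, ...`` not exceeding the max."""
    if not MIN_INTEGRATION_US <= min_integration <= max_integration <= MAX_INTEGRATION_CAP_US:
        raise ValueError("invalid integration-time range")
    times = []
    t = int(min_integration)
    while t <= max_integration:
        times.append(t)
        t *= 2
    return times


def auto_expose(
    instrument: InstrumentModel,
    scene: SceneModel,
    pose: GimbalState,
    max_integration: int = DEFAULT_MAX_INTEGRATION_US,
    min_integration: int = MIN_INTEGRATION_US,
) -> tuple:
    """Find the longest non-saturating octave exposure at a pose.

    Returns ``(integration_time, RawFrame)``.  If the minimum exposure
    already saturates, that frame is returned with its saturated flag
    set.  If the ladder tops out without saturating, the frame at the
    largest octave not exceeding ``max_integration`` is returned.
    """
    previous = None
    for t in octave_ladder(min_integration, max_integration):
        frame = expose(instrument, scene, pose, t)
        if frame.saturated:
            if previous is None:
                return t, frame
            return previous.integration_time, previous
        previous = frame
    return previous.integration_time, previous


def plan_rows(plan: ScanPlan) -> list:
    """Measured column indices per row, skipping redundant pole pixels.

    A row at elevation ``e`` measures ``max(1, round(n_cols * cos(e)))``
    columns (round half up), spread uniformly over the column range; at
    ``e = 0`` every column is measured.
    """
    n_cols = plan.n_cols
    rows = []
    for row in range(plan.n_rows):
        e = plan.elevation_deg(row)
        m = int(np.floor(n_cols * np.cos(np.deg2rad(e)) + 0.5))
        m = max(1, min(n_cols, m))
        cols = np.floor((np.arange(m) + 0.5) * n_cols / m).astype(int)
        rows.append(cols)
    return rows


def interpolate_row(values: np.ndarray, measured_cols: np.ndarray, n_cols: int) -> np.ndarray:
    """Densify a sparse row of spectra by per-photosite linear interpolation.

    ``values`` has shape ``(n_measured, n_photosites)`` aligned with
    ``measured_cols`` (strictly increasing column indices).  Columns
    outside the measured span copy the nearest measured spectrum.
    """
    measured_cols = np.asarray(measured_cols, dtype=int)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if measured_cols.size == 0:
        raise ValueError("cannot interpolate an empty row")
    if values.shape[0] != measured_cols.size:
        raise ValueError("values and measured_cols lengths differ")
    if np.any(np.diff(measured_cols) <= 0):
        raise ValueError("measured_cols must be strictly increasing")
    out = np.empty((n_cols, values.shape[1]), dtype=float)
    for col in range(n_cols):
        j = int(np.searchsorted(measured_cols, col))
        if j < measured_cols.size and measured_cols[j] == col:
            out[col] = values[j]
        elif j == 0:
            out[col] = values[0]
        elif j == measured_cols.size:
            out[col] = values[-1]
        else:
            lo, hi = measured_cols[j - 1], measured_cols[j]
            w = (col - lo) / (hi - lo)
            out[col] = (1.0 - w) * values[j - 1] + w * values[j]
    return out


def run_scan(
    instrument: InstrumentModel,
    scene: SceneModel,
    plan: ScanPlan,
    *,
    metadata: Optional[dict] = None,
) -> ScanCube:
    """Execute a full whisk-broom scan of ``scene`` under ``plan``.

    Rows are visited in tilt order and measured columns in pan order,
    each pixel independently auto-exposed.  Skipped pole pixels are
    filled afterwards by linear interpolation of dark-subtracted count
    rates and flagged as interpolated.
    """
    meta = dict(metadata or {})
    meta.setdefault("unit_id", 0)
    meta.setdefault("label", "")
    meta.setdefault(
        "timestamp",
        _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
    )
    cube = ScanCube(
        plan=plan,
        pixels={},
        darks=[],
        metadata=meta,
        wavelength_cal=instrument.wavelength_cal,
    )
    pan_pos = plan.pan_positions
    tilt_pos = plan.tilt_positions
    row_plan = plan_rows(plan)
    pending_times: set = set()

    def take_darks(after_row: int) -> None:
        for t in sorted(pending_times):
            cube.darks.append(DarkRecord(after_row=after_row, frame=dark_position_expose(instrument, t)))
        pending_times.clear()

    try:
        for row, tilt in enumerate(tilt_pos):
            cube.backlash_events.append((row, BACKLASH_OVERSHOOT_STEPS))
            for col in row_plan[row]:
                pose = GimbalState(
                    pan_step=int(pan_pos[col]),
                    tilt_step=int(tilt),
                    steps_per_revolution=plan.steps_per_revolution,
                )
                t, frame = auto_expose(
                    instrument, scene, pose, plan.max_integration, plan.min_integration
                )
                cube.pixels[(row, int(col))] = PixelRecord(frame=frame, flag=FLAG_MEASURED)
                pending_times.add(t)
            if (row + 1) % plan.dark_interval == 0:
                take_darks(row)
        if pending_times:
            take_darks(plan.n_rows - 1)
    except Exception:
        # partial cube preserved for inspection
        if pending_times:
            take_darks(plan.n_rows - 1)
        raise

    _fill_skipped_pixels(cube, row_plan)
    return cube


def _fill_skipped_pixels(cube: ScanCube, row_plan: list) -> None:
    """Interpolate pole-skipped pixels from their row's measured columns.

    Interpolation runs on dark-subtracted counts-per-us so that pixels
    with different integration times combine correctly; the synthesised
    frame is stored at the nearest measured neighbour's integration time
    with that time's dark re-added.
    """
    plan = cube.plan
    for row, measured_cols in enumerate(row_plan):
        if len(measured_cols) == plan.n_cols:
            continue
        rates = []
        for col in measured_cols:
            rec = cube.pixels[(row, int(col))]
            dark = cube.nearest_dark(rec.integration_time, row)
            diff = rec.frame.counts.astype(float) - dark.counts.astype(float)
            rates.append(diff / rec.integration_time)
        dense = interpolate_row(np.asarray(rates), measured_cols, plan.n_cols)
        measured_set = set(int(c) for c in measured_cols)
        for col in range(plan.n_cols):
            if col in measured_set:
                continue
            j = int(np.argmin(np.abs(np.asarray(measured_cols) - col)))
            ref_rec = cube.pixels[(row, int(measured_cols[j]))]
            t_ref = ref_rec.integration_time
            dark = cube.nearest_dark(t_ref, row)
            counts = np.clip(dense[col] * t_ref + dark.counts.astype(float), 0, None)
            if np.issubdtype(ref_rec.frame.counts.dtype, np.integer):
                counts = np.rint(counts).astype(np.int64)
            frame = RawFrame(counts=counts, integration_time=t_ref, saturated=False)
            cube.pixels[(row, col)] = PixelRecord(frame=frame, flag=FLAG_INTERPOLATED)
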