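"""Stimulus protocols and their rendering into luminance movies.

The experimental battery consists of six spot-based protocols (receptive-field
grid mapping, repeated flash trains, recovery-from-adaptation series, adaptor
displacement series, adaptor-duration series and a stimulus-size series) plus
drifting sinusoidal gratings.  All geometry is in degrees of visual angle with
the origin at the mapping-grid centre, x rightward and y upward; time is in
seconds.  A schedule is an ordered list of :class:`SpotEvent` with per-event
condition labels, and can be rendered into a :class:`LuminanceField` (a
discretized spatiotemporal movie, luminance in [0, 1]) for the mechanistic
model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotEvent",
    "GratingSpec",
    "ProtocolSchedule",
    "LuminanceField",
    "ProtocolError",
    "build_protocol",
    "render_luminance",
    "cm_to_degrees",
    "extent_to_degrees",
    "schedule_to_table",
    "schedule_from_table",
    "RECOVERY_GAPS",
    "DURATION_SERIES",
]

#: Recovery-protocol gap set (s): adaptor-offset to test-onset intervals.
RECOVERY_GAPS = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8)

#: Adaptor-duration series (s); the shortest equals three 60 Hz monitor frames.
DURATION_SERIES = (0.05, 0.1, 0.25, 0.6, 1.5)

_ROLES = ("adaptor", "test", "control", "map")
_KINDS = (
    "flash_train",
    "recovery",
    "duration_series",
    "displacement",
    "rf_grid",
    "size_series",
)


class ProtocolError(ValueError):
    """Raised for malformed protocol parameters or schedules."""


@dataclass(frozen=True)
class SpotEvent:
    """One presentation of a bright round spot on the dark background."""

    t_on: float
    t_off: float
    x: float
    y: float
    diameter: float
    role: str = "test"
    luminance: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_off > self.t_on:
            raise ProtocolError(f"t_off ({self.t_off}) must exceed t_on ({self.t_on})")
        if not self.diameter > 0:
            raise ProtocolError(f"diameter must be positive, got {self.diameter}")
        if not 0.0 <= self.luminance <= 1.0:
            raise ProtocolError(f"luminance must lie in [0, 1], got {self.luminance}")
        if self.role not in _ROLES:
            raise ProtocolError(f"unknown role {self.role!r}; expected one of {_ROLES}")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass(frozen=True)
class GratingSpec:
    """A full-field drifting sinusoidal grating."""

    spatial_freq: float  # cycles/degree
    temporal_freq: float  # Hz
    duration: float  # s
    contrast: float = 1.0  # relative, [0, 1]
    drift_axis: float = 0.0  # degrees; 0 = drift along +x

    def __post_init__(self) -> None:
        if self.spatial_freq < 0 or self.temporal_freq < 0:
            raise ProtocolError("grating frequencies must be non-negative")
        if not self.duration > 0:
            raise ProtocolError("grating duration must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise ProtocolError("contrast must lie in [0, 1]")


@dataclass
class ProtocolSchedule:
    """An ordered sequence of spot events with condition labels.

    ``condition_labels`` maps event index -> (condition name, numeric value);
    ``trial_ids`` groups events into trials/blocks.
    """

    events: list[SpotEvent]
    kind: str
    condition_labels: dict[int, tuple[str, float]] = field(default_factory=dict)
    trial_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        onsets = [e.t_on for e in self.events]
        if onsets != sorted(onsets):
            raise ProtocolError("events must be sorted by onset time")
        if not self.trial_ids:
            self.trial_ids = [0] * len(self.events)
        if len(self.trial_ids) != len(self.events):
            raise ProtocolError("trial_ids must parallel events")
        # No two events of one trial may overlap in time.
        by_trial: dict[int, list[SpotEvent]] = {}
        for tid, ev in zip(self.trial_ids, self.events):
            by_trial.setdefault(tid, []).append(ev)
        for tid, evs in by_trial.items():
            for a, b in zip(evs, evs[1:]):
                if b.t_on < a.t_off:
                    raise ProtocolError(
                        f"overlapping events in trial {tid}: "
                        f"[{a.t_on}, {a.t_off}] and [{b.t_on}, {b.t_off}]"
                    )

    @property
    def t_end(self) -> float:
        return max((e.t_off for e in self.events), default=0.0)

    def condition_of(self, index: int) -> tuple[str, float]:
        return self.condition_labels.get(index, ("", math.nan))


@dataclass
class LuminanceField:
    """Discretized luminance movie on a uniform degree grid."""

    grid_x: np.ndarray  # (nx,) degrees
    grid_y: np.ndarray  # (ny,) degrees
    dt: float  # s
    frames: np.ndarray  # (nt, ny, nx), values in [0, 1]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")
        for g in (self.grid_x, self.grid_y):
            d = np.diff(g)
            if d.size and not np.allclose(d, d[0]):
                raise ProtocolError("grid spacing must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0]) if self.grid_x.size > 1 else 1.0

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.dt


def cm_to_degrees(cm: float, viewing_distance: float) -> float:
    """Visual angle (degrees) subtended by an on-axis extent of ``cm``.

    At the 16 cm viewing distance used for stimulus display, 1 cm at the
    screen centre corresponds to ~3.6 degrees of visual angle.
    """
    if viewing_distance <= 0:
        raise ValueError("viewing_distance must be positive")
    if cm < 0:
        raise ValueError("cm must be non-negative")
    return math.degrees(math.atan(cm / viewing_distance))


def extent_to_degrees(width_cm: float, viewing_distance: float) -> float:
    """Visual angle of a symmetric extent of ``width_cm`` centred on-axis."""
    if width_cm < 0:
        raise ValueError("width_cm must be non-negative")
    return 2.0 * cm_to_degrees(width_cm / 2.0, viewing_distance)


# ---------------------------------------------------------------------------
# Protocol builders
# ---------------------------------------------------------------------------

def _flash_train(
    n_flashes: int = 6,
    duration: float = 0.6,
    isi: float = 1.5,
    x: float = 0.0,
    y: float = 0.0,
    diameter: float = 2.5,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """Repeated identical flashes: 0.6 s spots at 1.5 s ISI (0.9 s gap)."""
    if duration >= isi:
        raise ProtocolError("flash duration must be shorter than the ISI")
    events, labels = [], {}
    for k in range(n_flashes):
        t0 = t_start + k * isi
        events.append(SpotEvent(t0, t0 + duration, x, y, diameter, role="test"))
        labels[k] = ("presentation", float(k + 1))
    return ProtocolSchedule(events, "flash_train", labels, [0] * n_flashes)


def _recovery(
    gaps: Sequence[float] = RECOVERY_GAPS,
    adaptor_duration: float = 0.6,
    test_duration: float = 0.6,
    cycle_period: float = 30.0,
    control_spacing: float = 31.0,
    x: float = 0.0,
    y: float = 0.0,
    adaptor_dx: float = 0.0,
    adaptor_dy: float = 0.0,
    diameter: float = 2.5,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """Recovery-from-adaptation cycle.

    Two control presentations open the cycle (conditioning stimulus alone,
    then a test stimulus 31 s later), after which a conditioning adaptor is
    presented every 30 s followed by a test after each listed gap, gaps in
    increasing order.
    """
    gaps = sorted(gaps)
    if any(g <= 0 for g in gaps):
        raise ProtocolError("gaps must be positive")
    if cycle_period < max(gaps) + adaptor_duration + test_duration:
        raise ProtocolError("cycle_period too short for the longest gap")
    events, labels, trials = [], {}, []
    t = t_start
    events.append(SpotEvent(t, t + adaptor_duration, x + adaptor_dx, y + adaptor_dy,
                            diameter, role="control"))
    labels[0] = ("control_adaptor", 0.0)
    trials.append(0)
    t += control_spacing
    events.append(SpotEvent(t, t + test_duration, x, y, diameter, role="control"))
    labels[1] = ("control_test", 0.0)
    trials.append(1)
    t += control_spacing
    for k, gap in enumerate(gaps):
        i = len(events)
        events.append(SpotEvent(t, t + adaptor_duration, x + adaptor_dx,
                                y + adaptor_dy, diameter, role="adaptor"))
        labels[i] = ("gap", float(gap))
        t_test = t + adaptor_duration + gap
        events.append(SpotEvent(t_test, t_test + test_duration, x, y, diameter,
                                role="test"))
        labels[i + 1] = ("gap", float(gap))
        trials += [2 + k, 2 + k]
        t += cycle_period
    return ProtocolSchedule(events, "recovery", labels, trials)


def _duration_series(
    durations: Sequence[float] = DURATION_SERIES,
    gap: float = 0.8,
    test_duration: float = 0.6,
    period: float = 30.0,
    x: float = 0.0,
    y: float = 0.0,
    diameter: float = 2.5,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """Adaptor-duration series: adaptors of varying length, fixed gap to test."""
    if gap < 0:
        raise ProtocolError("gap must be non-negative")
    if any(d <= 0 for d in durations):
        raise ProtocolError("durations must be positive")
    events, labels, trials = [], {}, []
    t = t_start
    # Control: test alone, measured from rest.
    events.append(SpotEvent(t, t + test_duration, x, y, diameter, role="control"))
    labels[0] = ("control_test", 0.0)
    trials.append(0)
    t += period
    for k, dur in enumerate(durations):
        i = len(events)
        events.append(SpotEvent(t, t + dur, x, y, diameter, role="adaptor"))
        labels[i] = ("duration", float(dur))
        t_test = t + dur + gap
        events.append(SpotEvent(t_test, t_test + test_duration, x, y, diameter,
                                role="test"))
        labels[i + 1] = ("duration", float(dur))
        trials += [1 + k, 1 + k]
        t += period
    return ProtocolSchedule(events, "duration_series", labels, trials)


def _displacement(
    distances: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0),
    n_adaptors: int = 4,
    n_tests: int = 2,
    duration: float = 0.6,
    isi: float = 1.5,
    block_period: float = 30.0,
    x: float = 0.0,
    y: float = 0.0,
    diameter: float = 2.5,
    axis: float = 0.0,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """Spatial-specificity series: 4 adaptors then 2 tests at 1.5 s ISI.

    The test stimulus sits at (x, y); the adaptor of each block is displaced
    by the block's distance along ``axis``.  The zero-distance block doubles
    as the co-localized control series used to define the adaptation-
    sensitive response fraction.
    """
    if any(d < 0 for d in distances):
        raise ProtocolError("distances must be non-negative")
    n_stim = n_adaptors + n_tests
    if block_period < n_stim * isi:
        raise ProtocolError("block_period too short for the stimulus train")
    ux, uy = math.cos(math.radians(axis)), math.sin(math.radians(axis))
    events, labels, trials = [], {}, []
    t0 = t_start
    for b, dist in enumerate(distances):
        ax, ay = x + dist * ux, y + dist * uy
        for k in range(n_stim):
            i = len(events)
            t = t0 + k * isi
            if k < n_adaptors:
                events.append(SpotEvent(t, t + duration, ax, ay, diameter,
                                        role="adaptor"))
            else:
                events.append(SpotEvent(t, t + duration, x, y, diameter,
                                        role="test"))
            labels[i] = ("distance", float(dist))
            trials.append(b)
        t0 += block_period
    return ProtocolSchedule(events, "displacement", labels, trials)


def _rf_grid(
    nx: int = 18,
    ny: int = 11,
    spacing: float = 7.5,
    duration: float = 0.6,
    isi: float = 1.5,
    diameter: float = 2.5,
    seed: int | None = 0,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """RF mapping: spots flashed once per node of an nx x ny grid.

    The presentation order is a quasi-random (seeded uniform) permutation of
    the grid nodes; the grid is centred on the origin.
    """
    if nx < 1 or ny < 1 or spacing <= 0:
        raise ProtocolError("grid dimensions and spacing must be positive")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    cells = [(i, j) for j in range(ny) for i in range(nx)]
    order = np.random.default_rng(seed).permutation(len(cells))
    events, labels, trials = [], {}, []
    for k, idx in enumerate(order):
        i, j = cells[idx]
        t = t_start + k * isi
        events.append(SpotEvent(t, t + duration, float(xs[i]), float(ys[j]),
                                diameter, role="map"))
        labels[k] = ("grid_cell", float(idx))
        trials.append(k)
    return ProtocolSchedule(events, "rf_grid", labels, trials)


def _size_series(
    sizes: Sequence[float] = (0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 20.0),
    duration: float = 0.6,
    period: float = 20.0,
    x: float = 0.0,
    y: float = 0.0,
    t_start: float = 1.0,
) -> ProtocolSchedule:
    """Optimal-size series: spots of growing diameter presented every 20 s."""
    if any(s <= 0 for s in sizes):
        raise ProtocolError("sizes must be positive")
    events, labels, trials = [], {}, []
    for k, s in enumerate(sizes):
        t = t_start + k * period
        events.append(SpotEvent(t, t + duration, x, y, float(s), role="test"))
        labels[k] = ("size", float(s))
        trials.append(k)
    return ProtocolSchedule(events, "size_series", labels, trials)


_BUILDERS = {
    "flash_train": _flash_train,
    "recovery": _recovery,
    "duration_series": _duration_series,
    "displacement": _displacement,
    "rf_grid": _rf_grid,
    "size_series": _size_series,
}


def build_protocol(kind: str, **params) -> ProtocolSchedule:
    """Construct one of the six stimulation protocols as an event schedule.

    Parameters are protocol specific; every builder has defaults matching the
    experimental battery (e.g. ``build_protocol("flash_train")`` yields six
    0.6 s flashes at 1.5 s ISI, i.e. 0.9 s gaps).
    """
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol kind {kind!r}; expected one of {sorted(_BUILDERS)}"
        ) from None
    return builder(**params)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _make_grid(extent: float, grid_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    half = extent / 2.0
    n = int(round(extent / grid_spacing)) + 1
    return (np.linspace(-half, half, n), np.linspace(-half, half, n))


def render_luminance(
    schedule: ProtocolSchedule | GratingSpec,
    grid_spacing: float = 1.0,
    dt: float = 0.005,
    extent: float = 80.0,
    t_pad: float = 0.5,
) -> LuminanceField:
    """Render a schedule (or grating) into a spatiotemporal luminance movie.

    Spots become discs of luminance 1 on a background of 0 (a grid node is
    inside if its centre lies within diameter/2; no anti-aliasing).  Gratings
    render as ``0.5*(1 + contrast*sin(2*pi*(f_s*x' - f_t*t)))`` with ``x'``
    the coordinate along the drift axis.
    """
    gx, gy = _make_grid(extent, grid_spacing)
    if isinstance(schedule, GratingSpec):
        g = schedule
        nt = int(round(g.duration / dt))  # gratings start at t=0; no lead-in
        t = np.arange(nt) * dt
        th = math.radians(g.drift_axis)
        xr = np.cos(th) * gx[None, :] + np.sin(th) * gy[:, None]  # (ny, nx)
        phase = 2.0 * np.pi * (g.spatial_freq * xr[None, :, :]
                               - g.temporal_freq * t[:, None, None])
        frames = 0.5 * (1.0 + g.contrast * np.sin(phase))
        return LuminanceField(gx, gy, dt, frames.astype(np.float32))

    if schedule.events:
        shortest = min(e.duration for e in schedule.events)
        if dt > shortest / 3.0:
            raise ProtocolError(
                f"dt={dt} too coarse for the shortest event ({shortest} s); "
                f"need dt <= {shortest / 3.0:.4g}"
            )
        if min(e.diameter for e in schedule.events) < grid_spacing:
            raise ProtocolError("spot diameters must be >= grid_spacing")
    nt = int(round((schedule.t_end + t_pad) / dt))
    frames = np.zeros((nt, gy.size, gx.size), dtype=np.float32)
    half = extent / 2.0
    X, Y = np.meshgrid(gx, gy)
    for ev in schedule.events:
        r = ev.diameter / 2.0
        if abs(ev.x) + r > half or abs(ev.y) + r > half:
            raise ProtocolError(
                f"spot at ({ev.x}, {ev.y}) dia {ev.diameter} falls outside the "
                f"rendered extent (+-{half} deg)"
            )
        mask = (X - ev.x) ** 2 + (Y - ev.y) ** 2 <= r * r
        i0 = int(round(ev.t_on / dt))
        i1 = i0 + int(round(ev.duration / dt))
        frames[i0:i1, mask] = np.maximum(frames[i0:i1, mask], ev.luminance)
    return LuminanceField(gx, gy, dt, frames)


# ---------------------------------------------------------------------------
# Event-table round trip
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "trial_id", "role", "t_on_s", "t_off_s", "x_deg", "y_deg",
    "diameter_deg", "condition_name", "condition_value",
]


def schedule_to_table(schedule: ProtocolSchedule) -> pd.DataFrame:
    """Flatten a schedule to the standard event table (one row per event)."""
    rows = []
    for i, (tid, ev) in enumerate(zip(schedule.trial_ids, schedule.events)):
        name, value = schedule.condition_of(i)
        rows.append((tid, ev.role, ev.t_on, ev.t_off, ev.x, ev.y,
                     ev.diameter, name, value))
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def schedule_from_table(table: pd.DataFrame, kind: str) -> ProtocolSchedule:
    """Rebuild a schedule from an event table (inverse of schedule_to_table)."""
    missing = [c for c in _EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ProtocolError(f"event table missing columns: {missing}")
    events, labels, trials = [], {}, []
    for i, row in enumerate(table.itertuples(index=False)):
        events.append(SpotEvent(row.t_on_s, row.t_off_s, row.x_deg, row.y_deg,
                                row.diameter_deg, role=row.role))
        if isinstance(row.condition_name, str) and row.condition_name:
            labels[i] = (row.condition_name, float(row.condition_value))
        trials.append(int(row.trial_id))
    return ProtocolSchedule(events, kind, labels, trials)
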