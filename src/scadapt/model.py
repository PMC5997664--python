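"""Mechanistic ON-response model: Gaussian RF, transient stage, and divisive
normalization fed by low-pass-filtered local and non-local light signals.

The model is the experimentally derived account of ON-response adaptation in
collicular units.  Luminance ``S(x, y, t)`` drives three slow states:

* a **local adaptation field** ``a(x, y, t)`` charging toward the local
  luminance with a fast time constant and decaying with a slow one
  (fast onset, slow recovery).  Spatially blurred with a Gaussian of width
  ``sigma_spread``, it sets a divisive gain ``g = 1/(1 + kappa_L * a_bar)``
  applied to the stimulus *before* receptive-field pooling — adaptation is
  therefore confined to the neighbourhood of the adaptor (local adaptation).
* a **non-local signal** ``A_non(t)``: the RF-pooled light flux passed
  through a fast-charging, sub-second-decaying asymmetric low-pass filter.
  It enters the normalization denominator, suppressing responses to any
  stimulus in the RF regardless of position (non-local adaptation) and
  recovering in a few hundred milliseconds.
* a **per-node transient stage**: luminance is first integrated with the
  front-end time constant ``tau_f`` (photoreceptor/bipolar integration,
  setting the high-temporal-frequency roll-off), and a slower copy
  (``tau_m``) is subtracted; the rectified difference
  ``q = max(u - m, 0)`` passes only luminance *increments*, making the
  output ON-only and band-pass in temporal frequency.  Transient
  extraction precedes gain and pooling, so each luminance step launches a
  stereotyped burst whose size the adaptation gain then scales — matching
  the recorded behaviour, where adaptation reduces the response amplitude
  rather than reshaping its time course.

The divisive gain follows the adaptation field through a brief additional
integration stage (``tau_g``, the latency of retinal gain control), so the
first burst of a response largely escapes the adaptation it itself induces.

The pooled drive is ``p(t) = sum_xy w * q * g`` (``w`` a unit-sum Gaussian
of width ``sigma_RF``) and the firing rate is the canonical normalization
equation

    r(t) = r0 + R_max * p / (sigma_50 + p + kappa_N * A_non).

Only ON responses are produced; the OFF pathway and the inhibitory surround
are outside the model's scope.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .protocols import (
    GratingSpec,
    LuminanceField,
    ProtocolSchedule,
    RECOVERY_GAPS,
    build_protocol,
    render_luminance,
)

__all__ = [
    "ModelParameters",
    "ModelState",
    "RateTrace",
    "ON_WINDOW",
    "simulate",
    "response_amplitude",
    "run_flash_train",
    "run_recovery_experiment",
    "run_displacement_experiment",
    "grating_tuning",
]

#: Default ON-response measurement window relative to stimulus onset (s).
ON_WINDOW = (0.02, 0.32)


@dataclass(frozen=True)
class ModelParameters:
    """Calibrated model parameters.

    ``rf_diameter`` follows the RF-mapping convention (sqrt(a^2 + b^2) of the
    2-D Gaussian fit); for an isotropic Gaussian the width is
    ``sigma_RF = rf_diameter / sqrt(2)``.  Defaults are the calibrated
    small-RF instantiation: the local-adaptation charging constant is the
    measured ON onset tau (0.078 s); the remaining constants were tuned so
    that a 0.6 s flash train at 1.5 s ISI halves-and-more the second response
    (~60%), recovery at 11 s exceeds 90%, the displacement-series d50 is a
    few degrees, the non-local half-recovery is ~0.3 s and the grating
    temporal tuning peaks at 2 Hz.
    """

    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_diameter: float = 15.0  # degrees; mapping convention sqrt(a^2+b^2)
    tau_f: float = 0.05  # s, front-end integration (low-pass)
    tau_m: float = 0.10  # s, transient (high-pass) subtractor
    tau_Lr: float = 0.078  # s, local adaptation charging = ON onset tau
    tau_Ld: float = 2.5  # s, local adaptation decay (small-RF units)
    tau_g: float = 0.05  # s, latency of the divisive gain behind the state
    sigma_spread: float = 1.6  # degrees, spatial blur of local adaptation
    kappa_L: float = 100.0  # local gain weight
    tau_Nr: float = 0.06  # s, non-local signal charging
    tau_Nd: float = 0.30  # s, non-local signal decay
    kappa_N: float = 40.0  # non-local weight in the denominator
    sigma_50: float = 0.1  # semi-saturation constant, drive units
    R_max: float = 40.0  # Hz
    r_0: float = 2.0  # Hz, baseline

    def __post_init__(self) -> None:
        for name in ("tau_f", "tau_m", "tau_Lr", "tau_Ld", "tau_g", "tau_Nr",
                     "tau_Nd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kappa_L < 0 or self.kappa_N < 0:
            raise ValueError("kappa weights must be non-negative")
        if self.sigma_50 <= 0 or self.R_max <= 0 or self.rf_diameter <= 0:
            raise ValueError("sigma_50, R_max and rf_diameter must be positive")

    @property
    def sigma_rf(self) -> float:
        return self.rf_diameter / math.sqrt(2.0)

    @classmethod
    def large_rf(cls, rf_diameter: float = 30.0, **overrides) -> "ModelParameters":
        """Large-RF variant: faster recovery from local adaptation."""
        overrides.setdefault("tau_Ld", 1.0)
        return cls(rf_diameter=rf_diameter, **overrides)


@dataclass
class ModelState:
    """Slow states carried between simulation steps."""

    a_loc: np.ndarray  # (ny, nx), local adaptation level in [0, 1]
    b_gain: np.ndarray | float = 0.0  # (ny, nx) delayed copy of a_loc driving g
    A_non: float = 0.0  # non-local adaptation level, >= 0
    u: np.ndarray | float = 0.0  # (ny, nx) integrated (low-passed) luminance
    m: np.ndarray | float = 0.0  # (ny, nx) slower subtractive copy of u


@dataclass
class RateTrace:
    """Firing rate versus time on a uniform grid (continuous PSTH analogue)."""

    dt: float
    r: np.ndarray  # Hz
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.r = np.asarray(self.r, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.r.size) * self.dt

    @property
    def duration(self) -> float:
        return self.r.size * self.dt


def _rf_weights(field: LuminanceField, params: ModelParameters) -> np.ndarray:
    x0, y0 = params.rf_center
    X, Y = np.meshgrid(field.grid_x, field.grid_y)
    w = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * params.sigma_rf**2))
    return w / w.sum()


def simulate(
    field: LuminanceField,
    params: ModelParameters,
    initial: ModelState | None = None,
) -> RateTrace:
    """Integrate the model over a luminance movie and return the rate trace.

    The three linear low-pass states are advanced with the exact exponential
    update for piecewise-constant input (one luminance frame per step), which
    matches the closed-form solution for constant stimuli to machine
    precision and keeps amplitudes stable under dt refinement.  At rest
    (all-zero luminance from a zero state) the output is identically ``r_0``.
    """
    dt = field.dt
    frames = field.frames
    ny, nx = frames.shape[1:]
    w = _rf_weights(field, params)
    state = initial if initial is not None else ModelState(np.zeros((ny, nx)))
    if state.a_loc.shape != (ny, nx):
        raise ValueError("initial state grid does not match the luminance field")

    k_Lr = 1.0 - math.exp(-dt / params.tau_Lr)
    k_Ld = 1.0 - math.exp(-dt / params.tau_Ld)
    k_g = 1.0 - math.exp(-dt / params.tau_g)
    k_f = 1.0 - math.exp(-dt / params.tau_f)
    k_m = 1.0 - math.exp(-dt / params.tau_m)
    k_Nr = 1.0 - math.exp(-dt / params.tau_Nr)
    k_Nd = 1.0 - math.exp(-dt / params.tau_Nd)
    sig_px = params.sigma_spread / field.spacing

    a = state.a_loc.astype(float)
    b = np.broadcast_to(np.asarray(state.b_gain, dtype=float), (ny, nx)).copy()
    A_non = float(state.A_non)
    u = np.broadcast_to(np.asarray(state.u, dtype=float), (ny, nx)).copy()
    m = np.broadcast_to(np.asarray(state.m, dtype=float), (ny, nx)).copy()
    r = np.empty(frames.shape[0])
    for i in range(frames.shape[0]):
        S = frames[i]
        active = S.max() > 1e-12 or u.max() > 1e-12 or m.max() > 1e-12
        if b.max() > 1e-12:
            a_bar = gaussian_filter(b, sig_px, mode="constant")
        else:
            a_bar = b
        if active:
            g = 1.0 / (1.0 + params.kappa_L * a_bar)
            q = np.clip(u - m, 0.0, None)  # per-node ON transient
            p = float(np.sum(w * q * g))
            flux = float(np.sum(w * S))
        else:
            p = 0.0
            flux = 0.0
        r[i] = params.r_0 + params.R_max * p / (
            params.sigma_50 + p + params.kappa_N * A_non
        )
        # state updates (exponential stepping, input held over the frame)
        if active:
            u += (S - u) * k_f
            m += (u - m) * k_m
        A_non += (flux - A_non) * (k_Nr if flux >= A_non else k_Nd)
        if active or a.max() > 1e-12 or b.max() > 1e-12:
            charging = S >= a
            a = np.where(charging, a + (S - a) * k_Lr, a + (S - a) * k_Ld)
            b += (a - b) * k_g
    state.a_loc, state.b_gain, state.A_non = a, b, A_non
    state.u, state.m = u, m
    return RateTrace(dt=dt, r=r)


def response_amplitude(
    trace: RateTrace,
    event_onset: float,
    window: tuple[float, float] = ON_WINDOW,
    baseline: float | None = None,
) -> float:
    """Mean rate above baseline in a window after ``event_onset``, floored at 0."""
    lo, hi = event_onset + window[0], event_onset + window[1]
    if lo < trace.t0 or hi > trace.t0 + trace.duration:
        raise ValueError(
            f"response window [{lo:.3f}, {hi:.3f}] falls outside the trace"
        )
    i0 = int(round((lo - trace.t0) / trace.dt))
    i1 = int(round((hi - trace.t0) / trace.dt))
    return max(float(np.mean(trace.r[i0:i1]) - (baseline if baseline is not None else 0.0)), 0.0)


def _render_for(params: ModelParameters, schedule: ProtocolSchedule, dt: float,
                grid_spacing: float, extent: float, t_pad: float = 0.5) -> LuminanceField:
    return render_luminance(schedule, grid_spacing=grid_spacing, dt=dt,
                            extent=extent, t_pad=t_pad)


def run_flash_train(
    params: ModelParameters = ModelParameters(),
    n_flashes: int = 6,
    duration: float = 0.6,
    isi: float = 1.5,
    diameter: float = 2.5,
    dt: float = 0.005,
    grid_spacing: float = 1.0,
    extent: float = 80.0,
    window: tuple[float, float] = ON_WINDOW,
) -> np.ndarray:
    """ON amplitudes (Hz) for each presentation of a co-localized flash train."""
    x0, y0 = params.rf_center
    sched = build_protocol("flash_train", n_flashes=n_flashes, duration=duration,
                           isi=isi, x=x0, y=y0, diameter=diameter)
    trace = simulate(_render_for(params, sched, dt, grid_spacing, extent), params)
    return np.array([
        response_amplitude(trace, ev.t_on, window, baseline=params.r_0)
        for ev in sched.events
    ])


def run_recovery_experiment(
    params: ModelParameters = ModelParameters(),
    gaps: tuple[float, ...] = RECOVERY_GAPS,
    displacement: float = 0.0,
    adaptor_duration: float = 0.6,
    test_duration: float = 0.6,
    diameter: float = 2.5,
    dt: float = 0.005,
    grid_spacing: float = 1.0,
    extent: float = 80.0,
    window: tuple[float, float] = ON_WINDOW,
) -> pd.DataFrame:
    """Test-response amplitude versus gap, normalized to a test-alone control.

    Each gap is simulated from rest (cycle independence; the 30 s cycle of
    the recording protocol makes carry-over negligible).  The adaptor-alone
    response is subtracted from the combined trace before measuring the test
    response, mirroring the subtraction procedure used for short gaps.
    Columns: ``gap``, ``amplitude`` (Hz), ``norm_amplitude``.
    """
    if any(g <= 0 for g in gaps):
        raise ValueError("gaps must be positive")
    x0, y0 = params.rf_center
    ax, ay = x0 + displacement, y0
    half = extent / 2.0
    if abs(ax) + diameter / 2.0 > half or abs(ay) + diameter / 2.0 > half:
        raise ValueError("displacement places the adaptor outside the extent")
    t_start = 0.5
    # Control: test stimulus alone, from rest.
    ctrl = ProtocolSchedule(
        [_spot(t_start, test_duration, x0, y0, diameter, "control")],
        "recovery", {0: ("control_test", 0.0)})
    ctrl_trace = simulate(_render_for(params, ctrl, dt, grid_spacing, extent), params)
    a_ctrl = response_amplitude(ctrl_trace, t_start, window, baseline=params.r_0)
    # Adaptor alone, from rest (shared across gaps; simulated long enough once).
    max_gap = max(gaps)
    adapt_alone = ProtocolSchedule(
        [_spot(t_start, adaptor_duration, ax, ay, diameter, "adaptor")],
        "recovery", {0: ("control_adaptor", 0.0)})
    alone_field = render_luminance(
        adapt_alone, grid_spacing=grid_spacing, dt=dt, extent=extent,
        t_pad=max_gap + test_duration + 1.0)
    alone_trace = simulate(alone_field, params)

    rows = []
    for gap in sorted(gaps):
        t_test = t_start + adaptor_duration + gap
        sched = ProtocolSchedule(
            [_spot(t_start, adaptor_duration, ax, ay, diameter, "adaptor"),
             _spot(t_test, test_duration, x0, y0, diameter, "test")],
            "recovery", {0: ("gap", gap), 1: ("gap", gap)}, [0, 1])
        trace = simulate(_render_for(params, sched, dt, grid_spacing, extent), params)
        n = trace.r.size
        diff = RateTrace(dt=dt, r=trace.r - alone_trace.r[:n] + params.r_0)
        amp = response_amplitude(diff, t_test, window, baseline=params.r_0)
        rows.append((gap, amp, amp / a_ctrl if a_ctrl > 0 else math.nan))
    return pd.DataFrame(rows, columns=["gap", "amplitude", "norm_amplitude"])


def _spot(t_on, duration, x, y, diameter, role):
    from .protocols import SpotEvent

    return SpotEvent(t_on, t_on + duration, x, y, diameter, role=role)


def run_displacement_experiment(
    params: ModelParameters = ModelParameters(),
    distances: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0),
    n_adaptors: int = 4,
    duration: float = 0.6,
    isi: float = 1.5,
    diameter: float = 2.5,
    dt: float = 0.005,
    grid_spacing: float = 1.0,
    extent: float = 80.0,
    window: tuple[float, float] = ON_WINDOW,
) -> pd.DataFrame:
    """First-test amplitude versus adaptor displacement (each block from rest).

    Four adaptor presentations at the displaced location are followed by a
    test at the RF centre (1.5 s ISI throughout); the response to the fifth
    stimulus probes the adapted state.  Columns: ``distance``, ``amplitude``,
    ``control`` (first-presentation amplitude of the co-localized series).
    """
    x0, y0 = params.rf_center
    rows = []
    for dist in distances:
        sched = build_protocol(
            "displacement", distances=(dist,), n_adaptors=n_adaptors, n_tests=2,
            duration=duration, isi=isi, x=x0, y=y0, diameter=diameter, t_start=0.5)
        trace = simulate(_render_for(params, sched, dt, grid_spacing, extent), params)
        amps = [response_amplitude(trace, ev.t_on, window, baseline=params.r_0)
                for ev in sched.events]
        rows.append((dist, amps[n_adaptors], amps[0]))
    df = pd.DataFrame(rows, columns=["distance", "amplitude", "first_amplitude"])
    # Unadapted reference: the first presentation of any block is from rest.
    df["control"] = df["first_amplitude"].iloc[0]
    return df


def grating_tuning(
    params: ModelParameters = ModelParameters(),
    spatial_freqs: tuple[float, ...] = (0.01,),
    temporal_freqs: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    duration: float = 6.0,
    contrast: float = 1.0,
    dt: float = 0.005,
    grid_spacing: float = 1.0,
    extent: float = 80.0,
) -> pd.DataFrame:
    """Steady-state response amplitude per (spatial, temporal) frequency pair.

    Amplitude is the mean rate above baseline over the final half of the
    presentation.  For the temporal sweep the spatial frequency is fixed at
    0.01 cycles/deg; for a spatial sweep fix the temporal frequency at 2 Hz.
    """
    if not spatial_freqs or not temporal_freqs:
        raise ValueError("frequency lists must be non-empty")
    if duration < 4.0:
        raise ValueError("duration must be >= 4 s to reach steady state")
    rows = []
    for fs in spatial_freqs:
        for ft in temporal_freqs:
            spec = GratingSpec(spatial_freq=fs, temporal_freq=ft,
                               duration=duration, contrast=contrast)
            fld = render_luminance(spec, grid_spacing=grid_spacing, dt=dt,
                                   extent=extent)
            trace = simulate(fld, params)
            half = trace.r.size // 2
            amp = float(np.mean(trace.r[half:]) - params.r_0)
            rows.append((fs, ft, amp))
    return pd.DataFrame(rows, columns=["spatial_freq", "temporal_freq", "amplitude"])
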