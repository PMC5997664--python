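"""Synthetic populations of collicular units with calibrated ground truth.

The generator is deliberately *phenomenological and separable* — onset
dynamics, recovery dynamics and spatial spread factor into independent laws —
so that every quantity the analysis pipeline estimates has an exact known
value.  (The mechanistic normalization model is validated separately.)

Each unit carries an ON and an OFF channel.  A per-location adaptation state
``A`` charges toward 1 during a stimulus with the onset time constant
(``tau_on``) and decays exponentially between stimuli with the recovery time
constant (``tau_rec``); both constants are channel specific.  The expected
response to an event is::

    amplitude = peak * (1 - rho * sum_L A_L * Sigma(d_L)) * F

where ``Sigma(d) = 1 / (1 + exp((d - d50)/slope))`` is the sigmoidal spatial
release of adaptation with distance ``d`` between the location that charged
``A_L`` and the probed location, ``rho`` is the channel's maximal adaptation
fraction, and ``F`` is an optional brief ON facilitation (active only when
the adaptor sits just outside a small RF).  ON responses are evaluated at
stimulus onset, OFF responses at offset (so a control OFF response is itself
partially adapted by its own 0.6 s stimulus — as in the recordings, where
every OFF response is preceded by the stimulus that elicits it).

Rate traces superpose alpha-function kernels (brief ON burst, slower OFF
response) on a constant baseline; spikes are drawn from an inhomogeneous
Poisson process by thinning.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .model import ON_WINDOW, RateTrace
from .protocols import ProtocolSchedule, SpotEvent

__all__ = [
    "UnitSpec",
    "PopulationSpec",
    "SpikeTrain",
    "sample_population",
    "expected_amplitudes",
    "generate_rate_trace",
    "generate_spikes",
    "generate_trials",
    "default_unit",
]

#: Flash-train geometry used for calibration: 0.6 s stimuli, 0.9 s gaps.
_CAL_DURATION = 0.6
_CAL_GAP = 0.9


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth parameters of one synthetic unit (ON and OFF channels)."""

    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_diameter: float = 15.0  # degrees
    baseline_rate: float = 2.0  # Hz
    on_peak: float = 30.0  # Hz
    off_peak: float = 20.0  # Hz
    rho_on: float = 0.86  # maximal ON adaptation fraction
    rho_off: float = 1.0
    tau_on_on: float = 0.078  # s, ON onset time constant
    tau_on_off: float = 0.28  # s, OFF onset time constant
    tau_rec_on: float = 2.5  # s, ON recovery time constant
    tau_rec_off: float = 0.9  # s, OFF recovery time constant
    d50_on: float = 3.9  # degrees
    d50_off: float = 5.4
    slope_on: float = 1.2  # degrees, sigmoid slope ("rate")
    slope_off: float = 0.8
    facilitating: bool = False
    phi: float = 0.3  # facilitation fraction
    tau_phi: float = 0.3  # s, facilitation decay

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "on_peak", "off_peak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rho_on", "rho_off"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("tau_on_on", "tau_on_off", "tau_rec_on", "tau_rec_off",
                     "tau_phi", "d50_on", "d50_off", "slope_on", "slope_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def second_on_reduction(self) -> float:
        """Exact fractional 2nd-ON reduction under the 0.6 s / 0.9 s train."""
        charge = 1.0 - math.exp(-_CAL_DURATION / self.tau_on_on)
        return self.rho_on * charge * math.exp(-_CAL_GAP / self.tau_rec_on)

    def second_off_reduction(self) -> float:
        """Exact fractional 2nd-OFF reduction under the 0.6 s / 0.9 s train."""
        q = math.exp(-_CAL_DURATION / self.tau_on_off)
        C = 1.0 - q
        dcy = math.exp(-_CAL_GAP / self.tau_rec_off)
        A1 = C
        A2 = C * (1.0 + q * dcy)
        return 1.0 - (1.0 - self.rho_off * A2) / (1.0 - self.rho_off * A1)


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distributions for a heterogeneous population.

    Means follow the recorded-population values; spreads use SEM*sqrt(n)
    where a printed mean +- SEM exists, otherwise a 20% coefficient of
    variation.  ``fraction_small_rf`` is the target fraction of units with
    RF diameter below 20 degrees.
    """

    n_units: int = 31
    seed: int = 0
    # RF diameter: log-normal, median 15 deg, ~2/3 of units below 20 deg.
    rf_diameter_median: float = 15.0
    fraction_small_rf: float = 2.0 / 3.0
    small_rf_threshold: float = 20.0
    # Flash-train reductions (truncated normal on the realized reduction).
    mean_reduction_on: float = 0.60
    sd_reduction_on: float = 0.33  # SEM 6% at n=31
    mean_reduction_off: float = 0.32
    sd_reduction_off: float = 0.33  # SEM 6% at n=30
    # Onset time constants.
    mean_tau_on_on: float = 0.078
    sd_tau_on_on: float = 0.022  # SEM 0.004 at n=31
    mean_tau_on_off: float = 0.28
    sd_tau_on_off: float = 0.056  # 20% CV (the printed SEM*sqrt(n) is degenerate)
    # Spatial spread of adaptation; the OFF d50 distribution is narrower.
    mean_d50_on: float = 3.9
    sd_d50_on: float = 1.6  # SEM 0.5 at n=10
    mean_d50_off: float = 5.4
    sd_d50_off: float = 0.8  # Gaussian-fit half-width ordering: OFF < ON
    # Peaks and baseline (20% CV defaults).
    mean_on_peak: float = 30.0
    mean_off_peak: float = 20.0
    mean_baseline: float = 2.0
    peak_cv: float = 0.2
    # Facilitation among small-RF units.
    fraction_facilitating_small_rf: float = 7.0 / 11.0
    phi: float = 0.3
    tau_phi: float = 0.3

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("fraction_small_rf", "fraction_facilitating_small_rf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: int
    times: np.ndarray  # s, strictly increasing, non-negative

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def _truncnorm_mean_matched(target_mean: float, sd: float, lo: float, hi: float,
                            rng: np.random.Generator, size: int) -> np.ndarray:
    """Truncated-normal draws whose *post-truncation* mean equals the target.

    The pre-truncation location is solved so that truncation to [lo, hi] does
    not shift the mean away from the stated population value.
    """
    if not lo < target_mean < hi:
        raise ValueError("target mean must lie strictly inside the truncation bounds")

    def post_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd)

    mu = brentq(lambda m: post_mean(m) - target_mean,
                lo - 10 * sd, hi + 10 * sd, xtol=1e-10)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _on_params_for_reduction(R: float) -> tuple[float, float]:
    """(rho_on, tau_rec_on) realizing flash-train ON reduction R exactly."""
    charge = 1.0 - math.exp(-_CAL_DURATION / 0.078)
    base_decay = math.exp(-_CAL_GAP / 2.5)
    r_max_default = charge * base_decay  # reduction at rho_on = 1, tau_rec = 2.5
    if R <= r_max_default:
        return R / r_max_default, 2.5
    # rho pinned at 1; slow the recovery instead.
    decay = min(R / charge, 0.999999)
    return 1.0, -_CAL_GAP / math.log(decay)


def _off_params_for_reduction(R: float, tau_on_off: float) -> tuple[float, float]:
    """(rho_off, tau_rec_off) realizing flash-train OFF reduction R exactly."""
    q = math.exp(-_CAL_DURATION / tau_on_off)
    C = 1.0 - q
    dcy = math.exp(-_CAL_GAP / 0.9)
    A1, A2 = C, C * (1.0 + q * dcy)
    r_max_default = 1.0 - (1.0 - A2) / (1.0 - A1)  # rho = 1, tau_rec = 0.9
    if R <= r_max_default:
        rho = R / (A2 - (1.0 - R) * A1)
        return min(rho, 1.0), 0.9
    # rho = 1: reduction = C * exp(-gap/tau); cap just below the structural max C.
    decay = min(R / C, 0.999999)
    return 1.0, -_CAL_GAP / math.log(decay)


def sample_population(spec: PopulationSpec) -> list[UnitSpec]:
    """Draw a deterministic, seed-reproducible population of units.

    RF diameters are log-normal with the requested median and a shape chosen
    so the expected small-RF fraction matches ``fraction_small_rf``.  Each
    unit's flash-train reductions are drawn around the population means and
    mapped exactly onto (rho, tau_rec) pairs, so population averages of the
    *realized* reductions match the targets by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units
    from scipy.stats import norm

    z = norm.ppf(spec.fraction_small_rf)
    log_sd = math.log(spec.small_rf_threshold / spec.rf_diameter_median) / z
    rf = spec.rf_diameter_median * np.exp(log_sd * rng.standard_normal(n))

    red_on = _truncnorm_mean_matched(spec.mean_reduction_on, spec.sd_reduction_on,
                                     0.0, 1.0, rng, n)
    tau_on_off = np.clip(
        rng.normal(spec.mean_tau_on_off, spec.sd_tau_on_off, n), 0.05, None)
    # OFF reduction is structurally capped at 1 - exp(-0.6/tau_on_off).
    off_cap = float(1.0 - math.exp(-_CAL_DURATION / spec.mean_tau_on_off)) - 1e-3
    red_off = _truncnorm_mean_matched(spec.mean_reduction_off, spec.sd_reduction_off,
                                      0.0, off_cap, rng, n)
    tau_on_on = np.clip(
        rng.normal(spec.mean_tau_on_on, spec.sd_tau_on_on, n), 0.02, None)
    d50_on = np.clip(rng.normal(spec.mean_d50_on, spec.sd_d50_on, n), 0.5, None)
    d50_off = np.clip(rng.normal(spec.mean_d50_off, spec.sd_d50_off, n), 0.5, None)
    on_peak = np.clip(rng.normal(spec.mean_on_peak, spec.peak_cv * spec.mean_on_peak, n), 1.0, None)
    off_peak = np.clip(rng.normal(spec.mean_off_peak, spec.peak_cv * spec.mean_off_peak, n), 1.0, None)
    baseline = np.clip(rng.normal(spec.mean_baseline, spec.peak_cv * spec.mean_baseline, n), 0.0, None)
    facil_draw = rng.random(n)

    units = []
    for i in range(n):
        rho_on, tau_rec_on = _on_params_for_reduction(float(red_on[i]))
        rho_off, tau_rec_off = _off_params_for_reduction(float(red_off[i]),
                                                         float(tau_on_off[i]))
        small = rf[i] < spec.small_rf_threshold
        units.append(UnitSpec(
            rf_center=(0.0, 0.0),
            rf_diameter=float(rf[i]),
            baseline_rate=float(baseline[i]),
            on_peak=float(on_peak[i]),
            off_peak=float(off_peak[i]),
            rho_on=float(np.clip(rho_on, 0.0, 1.0)),
            rho_off=float(np.clip(rho_off, 0.0, 1.0)),
            tau_on_on=float(tau_on_on[i]),
            tau_on_off=float(tau_on_off[i]),
            tau_rec_on=float(tau_rec_on),
            tau_rec_off=float(tau_rec_off),
            d50_on=float(d50_on[i]),
            d50_off=float(d50_off[i]),
            facilitating=bool(small and facil_draw[i] < spec.fraction_facilitating_small_rf),
            phi=spec.phi,
            tau_phi=spec.tau_phi,
        ))
    return units


def default_unit(**overrides) -> UnitSpec:
    """The central (population-mean) unit used for calibration checks."""
    return UnitSpec(**overrides)


# ---------------------------------------------------------------------------
# Expected (noiseless) response amplitudes
# ---------------------------------------------------------------------------

def _sigma(d: float, d50: float, slope: float) -> float:
    """Spatial release of adaptation.

    Co-localized stimuli (d = 0) share the adaptation state fully (factor 1);
    a *displaced* adaptor's effect falls off sigmoidally with distance,
    reaching exactly 1/2 at d50.
    """
    if d < 1e-9:
        return 1.0
    return 1.0 / (1.0 + math.exp((d - d50) / slope))


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def expected_amplitudes(unit: UnitSpec, schedule: ProtocolSchedule) -> pd.DataFrame:
    """Ground-truth ON and OFF response amplitudes for every event.

    Walks the schedule in time, carrying one adaptation state per channel and
    per stimulus location.  ON amplitudes are evaluated at event onset (state
    before the event charges it), OFF amplitudes at offset (after charging).
    Facilitation multiplies the ON amplitude when the most recent preceding
    event at another location sits outside the RF but within 10 degrees of
    its edge.  Columns: ``event_index``, ``channel``, ``condition_name``,
    ``condition_value``, ``t_ref``, ``amplitude``.
    """
    states: dict[str, dict[tuple[float, float], float]] = {"ON": {}, "OFF": {}}
    taus = {"ON": (unit.tau_on_on, unit.tau_rec_on),
            "OFF": (unit.tau_on_off, unit.tau_rec_off)}
    rhos = {"ON": unit.rho_on, "OFF": unit.rho_off}
    d50s = {"ON": unit.d50_on, "OFF": unit.d50_off}
    slopes = {"ON": unit.slope_on, "OFF": unit.slope_off}
    peaks = {"ON": unit.on_peak, "OFF": unit.off_peak}

    t_prev = None
    last_event: tuple[tuple[float, float], float] | None = None  # (loc, t_off)
    rows = []
    for i, ev in enumerate(schedule.events):
        loc = (ev.x, ev.y)
        name, value = schedule.condition_of(i)
        # Decay all location states over the preceding silent interval.
        if t_prev is not None:
            silent = max(ev.t_on - t_prev, 0.0)
            for ch in ("ON", "OFF"):
                tau_rec = taus[ch][1]
                decay = math.exp(-silent / tau_rec)
                for k in states[ch]:
                    states[ch][k] *= decay
        for ch, t_ref in (("ON", ev.t_on), ("OFF", ev.t_off)):
            tau_on, tau_rec = taus[ch]
            if ch == "OFF":
                # state after this event has charged its own location
                charged = dict(states[ch])
                a_self = charged.get(loc, 0.0)
                charged[loc] = 1.0 + (a_self - 1.0) * math.exp(-ev.duration / tau_on)
                # other locations keep decaying during the stimulus
                for k in charged:
                    if k != loc:
                        charged[k] *= math.exp(-ev.duration / tau_rec)
                pool = charged
            else:
                pool = states[ch]
            suppression = sum(
                a * _sigma(_dist(loc, k), d50s[ch], slopes[ch])
                for k, a in pool.items())
            amp = peaks[ch] * (1.0 - rhos[ch] * min(suppression, 1.0))
            if (ch == "ON" and unit.facilitating and last_event is not None
                    and _dist(last_event[0], loc) > 1e-9):
                a_loc, a_toff = last_event
                r_ad = _dist(a_loc, unit.rf_center)
                r_rf = unit.rf_diameter / 2.0
                if r_rf < r_ad <= r_rf + 10.0:
                    gap = max(ev.t_on - a_toff, 0.0)
                    amp *= 1.0 + unit.phi * math.exp(-gap / unit.tau_phi)
            rows.append((i, ch, name, value, t_ref, max(amp, 0.0)))
        # Charge this event's location; decay others through the stimulus.
        for ch in ("ON", "OFF"):
            tau_on, tau_rec = taus[ch]
            a = states[ch].get(loc, 0.0)
            states[ch][loc] = 1.0 + (a - 1.0) * math.exp(-ev.duration / tau_on)
            for k in states[ch]:
                if k != loc:
                    states[ch][k] *= math.exp(-ev.duration / tau_rec)
        last_event = (loc, ev.t_off)
        t_prev = ev.t_off
    return pd.DataFrame(rows, columns=[
        "event_index", "channel", "condition_name", "condition_value",
        "t_ref", "amplitude"])


# ---------------------------------------------------------------------------
# Rate traces and spikes
# ---------------------------------------------------------------------------

def _alpha_kernel(t: np.ndarray, t_peak: float) -> np.ndarray:
    """Alpha function peaking at ``t_peak`` with unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    k = np.zeros_like(t)
    pos = t >= 0
    k[pos] = (t[pos] / t_peak) * np.exp(1.0 - t[pos] / t_peak)
    return k


def generate_rate_trace(
    unit: UnitSpec,
    schedule: ProtocolSchedule,
    amplitudes: pd.DataFrame | None = None,
    dt: float = 0.001,
    t_pad: float = 1.0,
    window: tuple[float, float] = ON_WINDOW,
    on_t_peak: float = 0.05,
    off_t_peak: float = 0.10,
) -> RateTrace:
    """Superpose response kernels on the baseline to form a firing-rate trace.

    Each event contributes an ON kernel at its onset and an OFF kernel at its
    offset, scaled so that the *mean of the kernel over the measurement
    window* equals the event's expected amplitude; overlapping responses add.
    """
    if amplitudes is None:
        amplitudes = expected_amplitudes(unit, schedule)
    nt = int(round((schedule.t_end + t_pad) / dt))
    t = np.arange(nt) * dt
    r = np.full(nt, unit.baseline_rate)
    i0 = int(round(window[0] / dt))
    i1 = int(round(window[1] / dt))
    for row in amplitudes.itertuples(index=False):
        t_peak = on_t_peak if row.channel == "ON" else off_t_peak
        kern = _alpha_kernel(t - row.t_ref, t_peak)
        wmean = float(np.mean(_alpha_kernel((np.arange(i0, i1) * dt), t_peak)))
        r += row.amplitude / wmean * kern
    return RateTrace(dt=dt, r=np.maximum(r, 0.0))


def generate_spikes(trace: RateTrace, seed: int | np.random.Generator) -> SpikeTrain:
    """Inhomogeneous Poisson spike train drawn from a rate trace by thinning.

    The rate is treated as piecewise constant over trace samples, so counts
    in any window are Poisson with mean equal to the integral of the rate.
    Deterministic for a fixed seed.
    """
    if np.any(trace.r < 0):
        raise ValueError("rate trace must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_max = float(trace.r.max(initial=0.0))
    T = trace.duration
    if r_max <= 0 or T <= 0:
        return SpikeTrain(0, np.empty(0))
    n_cand = rng.poisson(r_max * T)
    cand = np.sort(rng.uniform(0.0, T, n_cand))
    idx = np.minimum((cand / trace.dt).astype(int), trace.r.size - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) < trace.r[idx] / r_max
    times = trace.t0 + cand[keep]
    times = np.unique(times)  # enforce strict monotonicity
    return SpikeTrain(0, times)


def generate_trials(
    unit: UnitSpec,
    schedule: ProtocolSchedule,
    n_trials: int,
    seed: int,
    dt: float = 0.001,
) -> list[SpikeTrain]:
    """Independent Poisson realizations of the same expected rate trace."""
    trace = generate_rate_trace(unit, schedule, dt=dt)
    rng = np.random.default_rng(seed)
    return [generate_spikes(trace, rng) for _ in range(n_trials)]
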