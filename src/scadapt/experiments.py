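"""End-to-end experiment runners shared by the CLI, tests and the
reproduction script.

Generator-side runners drive a synthetic unit through a stimulation protocol
in noiseless rate mode, measure responses with the analysis pipeline's
window conventions and return the fitted quantities; model-side runners do
the same for the mechanistic normalization model.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import analysis
from .analysis import ON_WINDOW, estimate_t50, fit_monoexp_onset, fit_sigmoid_d50
from .model import (
    ModelParameters,
    RateTrace,
    grating_tuning,
    response_amplitude,
    run_flash_train,
    run_recovery_experiment,
)
from .population import (
    UnitSpec,
    default_unit,
    expected_amplitudes,
    generate_rate_trace,
)
from .protocols import DURATION_SERIES, RECOVERY_GAPS, ProtocolSchedule, SpotEvent, build_protocol

__all__ = [
    "unit_flash_train_amplitudes",
    "unit_flash_train_reduction",
    "unit_onset_tau",
    "unit_recovery_fraction",
    "unit_displacement_d50",
    "model_flash_train_reduction",
    "model_recovery_fraction",
    "model_recovery_t50",
    "model_grating_peak",
]


def _measure(trace: RateTrace, t_ref: float, baseline: float) -> float:
    return response_amplitude(trace, t_ref, ON_WINDOW, baseline=baseline)


def _spot(t_on, duration, x, y, diameter=2.5, role="test"):
    return SpotEvent(t_on, t_on + duration, x, y, diameter, role=role)


# ---------------------------------------------------------------------------
# Generator-side (noiseless rate mode)
# ---------------------------------------------------------------------------

def unit_flash_train_amplitudes(
    unit: UnitSpec | None = None,
    channel: str = "ON",
    n_flashes: int = 6,
    duration: float = 0.6,
    isi: float = 1.5,
) -> np.ndarray:
    """Per-presentation response amplitudes under the repeated flash train."""
    unit = unit or default_unit()
    x0, y0 = unit.rf_center
    sched = build_protocol("flash_train", n_flashes=n_flashes, duration=duration,
                           isi=isi, x=x0, y=y0)
    amps = expected_amplitudes(unit, sched)
    trace = generate_rate_trace(unit, sched, amps)
    sel = amps[amps.channel == channel]
    return np.array([
        _measure(trace, row.t_ref, unit.baseline_rate)
        for row in sel.itertuples(index=False)
    ])


def unit_flash_train_reduction(unit: UnitSpec | None = None,
                               channel: str = "ON") -> float:
    """Percent reduction of the 2nd response relative to the 1st."""
    a = unit_flash_train_amplitudes(unit, channel)
    return 100.0 * (1.0 - a[1] / a[0])


def unit_onset_tau(
    unit: UnitSpec | None = None,
    channel: str = "ON",
    durations: tuple[float, ...] = DURATION_SERIES,
    gap: float = 0.8,
) -> analysis.OnsetFit:
    """Adaptation-onset time constant from the adaptor-duration series.

    Each adaptor duration runs from rest; test-response reductions relative
    to a test-alone control are normalized to the longest (1.5 s) adaptor and
    fitted with the mono-exponential onset law.
    """
    unit = unit or default_unit()
    x0, y0 = unit.rf_center
    sched = build_protocol("duration_series", durations=durations, gap=gap,
                           x=x0, y=y0)
    amps = expected_amplitudes(unit, sched)
    trace = generate_rate_trace(unit, sched, amps)
    sel = amps[(amps.channel == channel)]
    control = None
    by_dur = {}
    for row in sel.itertuples(index=False):
        a = _measure(trace, row.t_ref, unit.baseline_rate)
        if row.condition_name == "control_test":
            control = a
        elif row.condition_name == "duration":
            # the test event is the second event of its trial
            by_dur.setdefault(row.condition_value, []).append((row.event_index, a))
    assert control is not None and control > 0
    durations_out, reductions = [], []
    for dur, pairs in sorted(by_dur.items()):
        test_amp = max(pairs, key=lambda p: p[0])[1]  # later event = the test
        durations_out.append(dur)
        reductions.append(1.0 - test_amp / control)
    reductions = np.asarray(reductions)
    ref = reductions[np.argmax(durations_out)]
    return fit_monoexp_onset(durations_out, reductions / ref)


def _unit_recovery_curve(
    unit: UnitSpec,
    gaps: tuple[float, ...],
    channel: str,
    displacement: float,
    adaptor_duration: float = 0.6,
    test_duration: float = 0.6,
) -> pd.DataFrame:
    """Normalized test amplitude vs gap, each gap simulated from rest.

    The adaptor-alone trace is subtracted from the combined trace before the
    test response is measured (needed for sub-0.2 s gaps where the adaptor's
    OFF response overlaps the test window).
    """
    x0, y0 = unit.rf_center
    ax = x0 + displacement
    t0 = 0.5
    ctrl_sched = ProtocolSchedule([_spot(t0, test_duration, x0, y0, role="control")],
                                  "recovery", {0: ("control_test", 0.0)})
    ctrl_amps = expected_amplitudes(unit, ctrl_sched)
    ctrl_trace = generate_rate_trace(unit, ctrl_sched, ctrl_amps)
    row = ctrl_amps[ctrl_amps.channel == channel].iloc[0]
    a_ctrl = _measure(ctrl_trace, row.t_ref, unit.baseline_rate)

    rows = []
    for gap in sorted(gaps):
        t_test = t0 + adaptor_duration + gap
        sched = ProtocolSchedule(
            [_spot(t0, adaptor_duration, ax, y0, role="adaptor"),
             _spot(t_test, test_duration, x0, y0, role="test")],
            "recovery", {0: ("gap", gap), 1: ("gap", gap)}, [0, 1])
        amps = expected_amplitudes(unit, sched)
        trace = generate_rate_trace(unit, sched, amps)
        alone_sched = ProtocolSchedule(
            [_spot(t0, adaptor_duration, ax, y0, role="adaptor")],
            "recovery", {0: ("control_adaptor", 0.0)})
        alone_amps = expected_amplitudes(unit, alone_sched)
        alone_trace = generate_rate_trace(unit, alone_sched, alone_amps,
                                          t_pad=t_test + test_duration + 1.0 - alone_sched.t_end)
        diff = RateTrace(dt=trace.dt,
                         r=trace.r - alone_trace.r[:trace.r.size] + unit.baseline_rate)
        row = amps[(amps.channel == channel) & (amps.event_index == 1)].iloc[0]
        amp = _measure(diff, row.t_ref, unit.baseline_rate)
        rows.append((gap, amp, amp / a_ctrl))
    return pd.DataFrame(rows, columns=["gap", "amplitude", "norm_amplitude"])


def unit_recovery_fraction(
    unit: UnitSpec | None = None,
    channel: str = "OFF",
    gap: float = 11.0,
    displacement: float = 0.0,
) -> float:
    """Test amplitude after a gap as percent of the test-alone control."""
    unit = unit or default_unit()
    df = _unit_recovery_curve(unit, (gap,), channel, displacement)
    return 100.0 * float(df["norm_amplitude"].iloc[0])


def unit_recovery_curve(
    unit: UnitSpec | None = None,
    channel: str = "ON",
    gaps: tuple[float, ...] = RECOVERY_GAPS,
    displacement: float = 0.0,
) -> pd.DataFrame:
    unit = unit or default_unit()
    return _unit_recovery_curve(unit, gaps, channel, displacement)


def unit_displacement_d50(
    unit: UnitSpec | None = None,
    channel: str = "ON",
    distances: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0),
) -> analysis.SigmoidFit:
    """d50 from the displacement series (4 adaptors + 2 tests, 1.5 s ISI).

    The co-localized (zero-distance) block defines the adaptation-sensitive
    response; the sigmoid is fitted to the released response versus distance.
    """
    unit = unit or default_unit()
    x0, y0 = unit.rf_center
    sched = build_protocol("displacement", distances=distances, x=x0, y=y0)
    amps = expected_amplitudes(unit, sched)
    trace = generate_rate_trace(unit, sched, amps)
    sel = amps[amps.channel == channel]
    test_amp = {}
    for row in sel.itertuples(index=False):
        # first test of each block: 5th stimulus = event index 4 within block
        if row.event_index % 6 == 4:
            test_amp[row.condition_value] = _measure(trace, row.t_ref,
                                                     unit.baseline_rate)
    d = np.array(sorted(test_amp))
    amp = np.array([test_amp[k] for k in d])
    sensitive = amp - amp[d == 0.0][0]
    return fit_sigmoid_d50(d, sensitive)


def unit_onset_tau_from_spikes(
    unit: UnitSpec | None = None,
    channel: str = "ON",
    n_trials: int = 40,
    seed: int = 0,
    durations: tuple[float, ...] = DURATION_SERIES,
    gap: float = 0.8,
    period: float = 15.0,
) -> analysis.OnsetFit:
    """Onset time constant recovered from Poisson spike trains.

    Trials are independent Poisson realizations of the duration-series rate
    trace; responses are measured from trial-summed PSTHs with the standard
    windows and baseline correction, then fitted as in the noiseless path.
    """
    from .analysis import BASELINE_WINDOW, build_psth, measure_response
    from .population import generate_rate_trace, generate_spikes

    unit = unit or default_unit()
    x0, y0 = unit.rf_center
    sched = build_protocol("duration_series", durations=durations, gap=gap,
                           period=period, x=x0, y=y0)
    trace = generate_rate_trace(unit, sched)
    rng = np.random.default_rng(seed)
    span = trace.duration
    # Concatenate trials on a shifted timeline so one PSTH covers them all.
    all_spikes = np.concatenate([
        generate_spikes(trace, rng).times + k * span for k in range(n_trials)])
    amps = expected_amplitudes(unit, sched)
    sel = amps[amps.channel == channel]

    # Baseline from the 0.5 s before each cycle's first stimulus (the
    # pre-test window is contaminated by the adaptor's OFF response).
    cycle_starts = [sched.events[i].t_on for i in range(len(sched.events))
                    if i == 0 or sched.trial_ids[i] != sched.trial_ids[i - 1]]
    base_aligns = [t + k * span for t in cycle_starts for k in range(n_trials)]
    base_psth = build_psth(all_spikes, base_aligns, window=(-0.5, 0.0),
                           bin_width=0.025)
    baseline = float(np.mean(base_psth.rate))

    def amp_at(t_ref: float) -> float:
        aligns = [t_ref + k * span for k in range(n_trials)]
        psth = build_psth(all_spikes, aligns, window=(-0.5, 0.5), bin_width=0.025)
        return measure_response(psth, response_window=ON_WINDOW,
                                baseline=baseline)

    control, by_dur = None, {}
    for row in sel.itertuples(index=False):
        if row.condition_name == "control_test":
            control = amp_at(row.t_ref)
        elif row.condition_name == "duration":
            by_dur.setdefault(row.condition_value, []).append(
                (row.event_index, row.t_ref))
    assert control is not None and control > 0
    durations_out, reductions = [], []
    for dur, pairs in sorted(by_dur.items()):
        t_ref = max(pairs, key=lambda p: p[0])[1]
        durations_out.append(dur)
        reductions.append(1.0 - amp_at(t_ref) / control)
    reductions = np.asarray(reductions)
    ref = reductions[np.argmax(durations_out)]
    return fit_monoexp_onset(durations_out, reductions / ref)


# ---------------------------------------------------------------------------
# Model-side
# ---------------------------------------------------------------------------

def model_flash_train_reduction(params: ModelParameters | None = None,
                                **kwargs) -> float:
    """Percent reduction of the model's 2nd ON response in the flash train."""
    params = params or ModelParameters()
    amps = run_flash_train(params, **kwargs)
    return 100.0 * (1.0 - amps[1] / amps[0])


def model_recovery_fraction(params: ModelParameters | None = None,
                            gap: float = 11.0, displacement: float = 0.0,
                            **kwargs) -> float:
    """Model test amplitude after a gap, percent of the unadapted control."""
    params = params or ModelParameters()
    df = run_recovery_experiment(params, gaps=(gap,), displacement=displacement,
                                 **kwargs)
    return 100.0 * float(df["norm_amplitude"].iloc[0])


def model_recovery_t50(params: ModelParameters | None = None,
                       displacement: float = 0.0,
                       gaps: tuple[float, ...] = RECOVERY_GAPS,
                       **kwargs) -> analysis.T50Estimate:
    """Half-recovery gap of the model over the standard gap set."""
    params = params or ModelParameters()
    df = run_recovery_experiment(params, gaps=gaps, displacement=displacement,
                                 **kwargs)
    return estimate_t50(df["gap"].to_numpy(), df["norm_amplitude"].to_numpy())


def model_grating_peak(params: ModelParameters | None = None,
                       temporal_freqs: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
                       spatial_freq: float = 0.01,
                       **kwargs) -> tuple[float, pd.DataFrame]:
    """Peak temporal frequency of the model's grating tuning (and the table)."""
    params = params or ModelParameters()
    df = grating_tuning(params, spatial_freqs=(spatial_freq,),
                        temporal_freqs=temporal_freqs, **kwargs)
    peak = float(df.loc[df["amplitude"].idxmax(), "temporal_freq"])
    return peak, df
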