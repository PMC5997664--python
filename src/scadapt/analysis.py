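"""Spike-train quantification: PSTHs, ON/OFF response measures, adaptor
subtraction, curve fits (2-D Gaussian RF, sigmoidal spatial release,
mono-exponential onset), t50 interpolation, rank statistics and per-unit
classification.

Responses are measured as the mean firing rate above baseline in a fixed
window after stimulus onset (ON) or offset (OFF); the default window of
0.02-0.32 s covers the transient while excluding the 0.6 s stimulus tail.
For short adaptor-test gaps the response to the adaptor alone is subtracted
from the combined histogram before the test response is measured.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PSTH",
    "RFGaussianFit",
    "SigmoidFit",
    "OnsetFit",
    "RankTestResult",
    "T50Estimate",
    "ON_WINDOW",
    "BASELINE_WINDOW",
    "build_psth",
    "measure_response",
    "subtract_adaptor",
    "fit_rf_gaussian",
    "fit_sigmoid_d50",
    "fit_monoexp_onset",
    "estimate_t50",
    "rank_test",
    "classify_unit",
    "population_summary",
    "gaussian_hist_fit",
]

ON_WINDOW = (0.02, 0.32)
BASELINE_WINDOW = (-0.5, 0.0)


@dataclass
class PSTH:
    """Peristimulus time histogram with half-open bins [left, right).

    ``counts`` may be fractional after subtraction; the rate identity
    ``rate = counts / (n_trials * bin_width)`` always holds.
    """

    edges: np.ndarray  # (n_bins + 1,) s, relative to the alignment event
    counts: np.ndarray  # (n_bins,)
    n_trials: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.edges.size - 1:
            raise ValueError("counts must have len(edges) - 1 entries")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def rate(self) -> np.ndarray:
        """Trial-averaged firing rate per bin (Hz)."""
        return self.counts / (self.n_trials * self.bin_width)


def build_psth(
    spike_times: np.ndarray | Sequence[float],
    align_times: Sequence[float],
    window: tuple[float, float] = (-0.5, 1.5),
    bin_width: float = 0.025,
) -> PSTH:
    """Histogram spike times relative to each alignment event, summed.

    Bins are half-open [left, right): a spike exactly on an interior bin's
    left edge is counted in that bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pre, post = window
    if not post > pre:
        raise ValueError("window must be non-empty")
    align = np.asarray(align_times, dtype=float)
    if align.size == 0:
        raise ValueError("at least one alignment time is required")
    n_bins = int(round((post - pre) / bin_width))
    edges = pre + np.arange(n_bins + 1) * bin_width
    spikes = np.asarray(spike_times, dtype=float)
    counts = np.zeros(n_bins)
    for t0 in align:
        rel = spikes - t0
        rel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        idx = np.floor((rel - pre) / bin_width).astype(int)
        np.add.at(counts, idx, 1.0)
    return PSTH(edges, counts, n_trials=align.size)


def _window_mean_rate(psth: PSTH, window: tuple[float, float]) -> float:
    """Time-weighted mean rate over a window (partial bins weighted)."""
    lo, hi = window
    left = np.maximum(psth.edges[:-1], lo)
    right = np.minimum(psth.edges[1:], hi)
    overlap = np.clip(right - left, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(f"window {window} does not overlap the histogram")
    return float(np.sum(psth.rate * overlap) / total)


def measure_response(
    psth: PSTH,
    response_window: tuple[float, float] = ON_WINDOW,
    baseline_window: tuple[float, float] | None = BASELINE_WINDOW,
    baseline: float | None = None,
) -> float:
    """Response amplitude: mean rate in the window minus baseline, floored at 0.

    Align the histogram to stimulus onset for ON responses and to offset for
    OFF responses.  Either a baseline window (measured on the same PSTH) or
    a precomputed baseline rate may be given.
    """
    if baseline is None:
        baseline = (_window_mean_rate(psth, baseline_window)
                    if baseline_window is not None else 0.0)
    return max(_window_mean_rate(psth, response_window) - baseline, 0.0)


def subtract_adaptor(combined: PSTH, adaptor_alone: PSTH) -> PSTH:
    """Remove the adaptor's own response from a combined adaptor+test PSTH.

    Both histograms must share binning and be aligned to the adaptor onset.
    The difference is not clipped: negative bins are preserved so window
    means stay unbiased (flooring happens at the amplitude stage).
    """
    if (combined.edges.size != adaptor_alone.edges.size
            or not np.allclose(combined.edges, adaptor_alone.edges)):
        raise ValueError("PSTH binning mismatch")
    rate = combined.rate - adaptor_alone.rate
    counts = rate * combined.n_trials * combined.bin_width
    return PSTH(combined.edges.copy(), counts, combined.n_trials)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass
class RFGaussianFit:
    """2-D Gaussian receptive-field fit; diameter = sqrt(a^2 + b^2)."""

    A: float
    a: float
    b: float
    theta: float  # radians
    x0: float
    y0: float
    residual: float
    converged: bool
    param_se: np.ndarray | None = None

    @property
    def rf_diameter(self) -> float:
        return math.hypot(self.a, self.b)


def _gauss2d(coords, A, a, b, theta, x0, y0):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xp = ct * (x - x0) + st * (y - y0)
    yp = -st * (x - x0) + ct * (y - y0)
    return (A / (2.0 * np.pi * a * b)) * np.exp(
        -(xp**2 / (2.0 * a**2) + yp**2 / (2.0 * b**2)))


def fit_rf_gaussian(grid_rates: pd.DataFrame) -> RFGaussianFit:
    """Least-squares 2-D Gaussian fit of spot-mapping responses.

    ``grid_rates`` needs columns x, y, amplitude (>= 8 points).  The Gaussian
    is oriented: coordinates are rotated by theta before the axis widths a, b
    apply.  Initialization is moment based (centroid and second moments);
    the a >= b, theta in [0, pi) convention breaks the relabelling
    degeneracy.  Isotropic data leave theta undetermined (any value yields
    the same residual).
    """
    df = grid_rates
    for c in ("x", "y", "amplitude"):
        if c not in df.columns:
            raise ValueError(f"grid_rates missing column {c!r}")
    if len(df) < 8:
        raise ValueError("need at least 8 grid points")
    if np.any(df["amplitude"] < 0):
        raise ValueError("amplitudes must be non-negative")
    amp = df["amplitude"].to_numpy(dtype=float)
    if amp.sum() <= 0:
        raise ValueError("all-zero amplitudes: nothing to fit")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)

    # Moment initialization.
    wsum = amp.sum()
    x0 = float(np.sum(amp * x) / wsum)
    y0 = float(np.sum(amp * y) / wsum)
    cxx = float(np.sum(amp * (x - x0) ** 2) / wsum)
    cyy = float(np.sum(amp * (y - y0) ** 2) / wsum)
    cxy = float(np.sum(amp * (x - x0) * (y - y0)) / wsum)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    a0 = math.sqrt(max(evals[1], 1e-3))
    b0 = math.sqrt(max(evals[0], 1e-3))
    th0 = math.atan2(evecs[1, 1], evecs[0, 1])
    # Amplitude init: unique x (or y) spacings estimate the cell area.
    ux = np.unique(x)
    dx = float(np.min(np.diff(ux))) if ux.size > 1 else 1.0
    uy = np.unique(y)
    dy = float(np.min(np.diff(uy))) if uy.size > 1 else 1.0
    A0 = float(wsum * dx * dy)

    p0 = [A0, a0, b0, th0, x0, y0]
    converged = True
    perr = None
    try:
        popt, pcov = optimize.curve_fit(
            _gauss2d, (x, y), amp, p0=p0,
            bounds=([0, 1e-3, 1e-3, -np.pi, -np.inf, -np.inf],
                    [np.inf, np.inf, np.inf, np.pi, np.inf, np.inf]),
            maxfev=20000)
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt, converged = np.array(p0), False
    A, a, b, theta, x0, y0 = popt
    if b > a:  # tie-break the a<->b, theta+90 deg relabelling
        a, b = b, a
        theta += math.pi / 2.0
    theta = (theta + math.pi / 2.0) % math.pi - math.pi / 2.0
    resid = float(np.linalg.norm(_gauss2d((x, y), A, a, b, theta, x0, y0) - amp))
    return RFGaussianFit(float(A), float(a), float(b), float(theta),
                         float(x0), float(y0), resid, converged, perr)


@dataclass
class SigmoidFit:
    """Sigmoidal spatial-release fit: S(d) = A / (1 + exp((d50 - d)/rate))."""

    A: float  # maximal spike rate, Hz
    d50: float  # degrees
    slope: float  # degrees (the fit's "rate" parameter)
    residual: float
    converged: bool
    flagged: bool = False  # set when the data show no release with distance
    param_se: np.ndarray | None = None


def _sigmoid(d, A, d50, rate):
    return A / (1.0 + np.exp((d50 - d) / rate))


def fit_sigmoid_d50(distances: Sequence[float], rates: Sequence[float]) -> SigmoidFit:
    """Fit the sigmoidal release of adaptation with adaptor-test distance.

    ``rates`` should be the adaptation-sensitive response (response above the
    co-localized floor) or any quantity rising from ~0 to its maximum with
    distance; S(d50) = A/2 exactly by construction of the fitted form.
    """
    d = np.asarray(distances, dtype=float)
    r = np.asarray(rates, dtype=float)
    if d.size != r.size:
        raise ValueError("distances and rates must have equal length")
    if np.unique(d).size < 4:
        raise ValueError("need >= 4 distinct distances")
    flagged = bool(np.polyfit(d, r, 1)[0] < 0)  # no release with distance
    rmax = float(r.max())
    half = rmax / 2.0
    above = d[r >= half]
    d50_0 = float(above.min()) if above.size else float(np.median(d))
    p0 = [rmax if rmax > 0 else 1.0, d50_0, 1.0]
    converged = True
    perr = None
    try:
        popt, pcov = optimize.curve_fit(
            _sigmoid, d, r, p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000)
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt, converged = np.array(p0), False
    A, d50, rate = (float(v) for v in popt)
    resid = float(np.linalg.norm(_sigmoid(d, A, d50, rate) - r))
    return SigmoidFit(A, d50, rate, resid, converged, flagged, perr)


@dataclass
class OnsetFit:
    """Mono-exponential adaptation-onset fit: rho(T) = asym*(1 - exp(-T/tau))."""

    tau: float  # s
    asymptote: float
    residual: float
    converged: bool
    flagged: bool = False
    param_se: np.ndarray | None = None


def fit_monoexp_onset(durations: Sequence[float],
                      normalized_reductions: Sequence[float]) -> OnsetFit:
    """Fit the adaptation-onset time constant from the duration series.

    Reductions should be normalized to the longest (1.5 s) adaptor's value.
    With fewer than 3 durations the fit is rejected; constant reductions
    leave tau unidentifiable and the result is flagged.
    """
    T = np.asarray(durations, dtype=float)
    rho = np.asarray(normalized_reductions, dtype=float)
    if T.size != rho.size:
        raise ValueError("durations and reductions must have equal length")
    if np.unique(T).size < 3:
        raise ValueError("need >= 3 distinct adaptor durations")
    if np.any(T <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(rho) < 1e-12:
        return OnsetFit(math.nan, float(rho.mean()), 0.0, False, flagged=True)

    def f(t, asym, tau):
        return asym * (1.0 - np.exp(-t / tau))

    p0 = [max(float(rho.max()), 1e-6), float(T.min())]
    converged = True
    perr = None
    try:
        popt, pcov = optimize.curve_fit(
            f, T, rho, p0=p0, bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=20000)
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt, converged = np.array(p0), False
    asym, tau = (float(v) for v in popt)
    resid = float(np.linalg.norm(f(T, asym, tau) - rho))
    return OnsetFit(tau, asym, resid, converged, False, perr)


# ---------------------------------------------------------------------------
# t50
# ---------------------------------------------------------------------------

@dataclass
class T50Estimate:
    """Gap at which the response recovers halfway between its adapted floor
    and the control level.  ``status`` is 'ok' for an interpolated value,
    'lower_bound' when recovery never reaches the midpoint inside the tested
    gap range (t50 exceeds ``value``), 'upper_bound' when even the shortest
    gap is above the midpoint (t50 is below ``value``)."""

    value: float  # s
    status: str = "ok"


def estimate_t50(gaps: Sequence[float],
                 normalized_amplitudes: Sequence[float]) -> T50Estimate:
    """Half-recovery gap by linear interpolation in log(gap).

    The midpoint is halfway between the shortest-gap amplitude (the adapted
    floor) and 1 (full recovery).
    """
    g = np.asarray(gaps, dtype=float)
    a = np.asarray(normalized_amplitudes, dtype=float)
    if g.size != a.size or g.size < 2:
        raise ValueError("need matching gaps and amplitudes (>= 2 points)")
    if np.any(g <= 0):
        raise ValueError("gaps must be positive")
    order = np.argsort(g)
    g, a = g[order], a[order]
    midpoint = 0.5 * (a[0] + 1.0)
    if a[0] >= midpoint:  # already fully recovered at the shortest gap
        return T50Estimate(float(g[0]), "upper_bound")
    below = np.nonzero(a < midpoint)[0]
    i = below[-1]  # last point below the midpoint
    if i == g.size - 1:
        return T50Estimate(float(g[-1]), "lower_bound")
    lg0, lg1 = math.log(g[i]), math.log(g[i + 1])
    frac = (midpoint - a[i]) / (a[i + 1] - a[i])
    return T50Estimate(math.exp(lg0 + frac * (lg1 - lg0)), "ok")


# ---------------------------------------------------------------------------
# Rank statistics and classification
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    kind: str


def rank_test(kind: str, *samples, zero_method: str = "wilcox") -> RankTestResult:
    """Non-parametric rank tests used throughout the analysis.

    ``kruskal_wallis``: >= 2 independent groups; H with tie correction, p
    from the chi-squared approximation with k-1 df.  ``wilcoxon_signed``:
    paired samples (or one sample of differences); exact two-tailed p for
    n <= 25 without ties, normal approximation otherwise.  ``mann_whitney``:
    two independent samples, two-tailed.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty sample")
    if kind == "kruskal_wallis":
        if len(samples) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        if np.ptp(np.concatenate(samples)) == 0:
            # identical groups: H = 0 by definition, p -> 1
            return RankTestResult(0.0, 1.0, kind)
        stat, p = stats.kruskal(*samples)
        return RankTestResult(float(stat), float(p), kind)
    if kind == "wilcoxon_signed":
        if len(samples) == 2:
            if samples[0].size != samples[1].size:
                raise ValueError("paired samples must have equal length")
            d = samples[0] - samples[1]
        elif len(samples) == 1:
            d = samples[0]
        else:
            raise ValueError("wilcoxon_signed takes one or two samples")
        n = d.size
        has_ties = np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)
        method = "exact" if (n <= 25 and not has_ties and np.all(d != 0)) else "approx"
        stat, p = stats.wilcoxon(d, zero_method=zero_method, method=method,
                                 alternative="two-sided")
        return RankTestResult(float(stat), float(p), kind)
    if kind == "mann_whitney":
        if len(samples) != 2:
            raise ValueError("mann_whitney takes exactly two samples")
        stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
        return RankTestResult(float(stat), float(p), kind)
    raise ValueError(f"unknown test kind {kind!r}")


def classify_unit(
    condition_counts: Mapping[float, Sequence[float]],
    control: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> str:
    """Classify a unit/channel as adapting, facilitating, or unaffected.

    ``condition_counts`` maps an ordered condition value (presentation index
    or gap duration) to per-trial spike counts.  Adapting: Kruskal-Wallis
    across conditions significant at ``alpha`` *and* the pooled median of
    later conditions below the first condition's median.  Facilitating (only
    testable when a ``control`` sample is given): some condition
    significantly above control (two-tailed Mann-Whitney at ``alpha`` with a
    larger median).  No multiple-testing correction is applied.
    """
    if len(condition_counts) < 2:
        raise ValueError("need >= 2 conditions")
    keys = sorted(condition_counts)
    groups = [np.asarray(condition_counts[k], dtype=float) for k in keys]
    if control is not None:
        control = np.asarray(control, dtype=float)
        for g in groups:
            res = rank_test("mann_whitney", g, control)
            if res.p_value < alpha and np.median(g) > np.median(control):
                return "facilitating"
    pooled = np.concatenate(groups)
    if np.ptp(pooled) > 0:
        res = rank_test("kruskal_wallis", *groups)
        later = np.concatenate(groups[1:])
        if res.p_value < alpha and np.median(later) < np.median(groups[0]):
            return "adapting"
    return "unaffected"


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------

@dataclass
class GaussianHistFit:
    mu: float
    sigma: float
    amplitude: float
    half_width: float  # half width at half maximum
    converged: bool


def gaussian_hist_fit(values: Sequence[float], bins: int = 10) -> GaussianHistFit:
    """Gaussian fit of a histogram of per-unit values (e.g. d50 spreads)."""
    v = np.asarray(values, dtype=float)
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def f(x, amp, mu, sig):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))

    p0 = [float(counts.max()), float(v.mean()), float(max(v.std(), 1e-3))]
    try:
        popt, _ = optimize.curve_fit(f, centers, counts, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    amp, mu, sig = (float(x) for x in popt)
    sig = abs(sig)
    return GaussianHistFit(mu, sig, amp, sig * math.sqrt(2.0 * math.log(2.0)),
                           converged)


def population_summary(values: Sequence[float]) -> dict:
    """Mean +- SEM summary (results are reported as average +- SEM)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("no values")
    out = {"n": int(v.size), "mean": float(v.mean())}
    if v.size >= 2:
        out["sem"] = float(v.std(ddof=1) / math.sqrt(v.size))
    else:
        out["sem"] = math.nan  # undefined for a single value
    return out
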