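"""Bolus-kinetics analysis of CEUS time-intensity curves.

After a bolus injection of microbubble contrast, the mean ROI intensity
rises from a pre-bolus baseline to a peak and decays.  The enhancement is
modelled as a lognormal bolus transit,

    I(t) = baseline + A * f(t - t_a; mu, sigma),   t > t_a,

where f is the lognormal probability density.  The mode of f sits at
exp(mu - sigma^2) after arrival, so the time-to-peak (TTP, the interval
from first contrast appearance in the ROI to maximal enhancement) has the
closed form TTP = exp(mu - sigma^2).  The wash-in rate (WiR) is the slope
of an ordinary least-squares line fitted to the enhancement between
arrival and peak.

Frames corrupted by motion are carried as an excluded-frame mask and never
enter any estimate; curves that lose too many frames fail the quality gate
and are reported unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    NoEnhancementError,
)

__all__ = [
    "TimeIntensityCurve",
    "BolusFit",
    "PerfusionParams",
    "lognormal_bolus",
    "quality_gate",
    "estimate_baseline_and_arrival",
    "fit_bolus",
    "compute_ttp",
    "compute_wir",
    "analyze_tic",
]

#: excluded-frame fraction above which a curve is unusable.
DEFAULT_MAX_EXCLUDED_FRACTION = 0.4

#: arrival detection threshold, in pre-bolus noise standard deviations.
DEFAULT_K_SD = 3.0

#: fraction of non-excluded frames treated as the pre-bolus baseline window.
BASELINE_FRACTION = 0.1

MIN_SAMPLES = 50
MIN_USABLE_SAMPLES = 10


@dataclass
class TimeIntensityCurve:
    """Sampled CEUS enhancement of one ROI with an excluded-frame mask."""

    time_s: np.ndarray
    intensity: np.ndarray
    excluded: np.ndarray
    node_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.time_s.size
        if not (self.intensity.size == n == self.excluded.size):
            raise InvalidInputError("time, intensity and mask lengths differ")
        if n < MIN_SAMPLES:
            raise InvalidInputError(f"need >= {MIN_SAMPLES} samples, got {n}")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidInputError("time_s must be strictly increasing")

    @property
    def excluded_fraction(self) -> float:
        return float(self.excluded.mean())

    @property
    def frame_period_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def usable_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded
        return self.time_s[keep], self.intensity[keep]


@dataclass
class BolusFit:
    """Converged lognormal-bolus fit of one curve."""

    t_arrival_s: float
    mu: float
    sigma: float
    amplitude: float
    baseline: float
    rmse: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return lognormal_bolus(
            t, self.t_arrival_s, self.mu, self.sigma, self.amplitude, self.baseline
        )


@dataclass
class PerfusionParams:
    """Summary perfusion parameters of one node."""

    node_id: str
    usable: bool
    excluded_fraction: float
    t_arrival_s: float = np.nan
    t_peak_s: float = np.nan
    ttp_s: float = np.nan
    wir_au_per_s: float = np.nan
    peak_enhancement_au: float = np.nan
    baseline_au: float = np.nan
    fit_rmse: float = np.nan


def lognormal_bolus(
    t: np.ndarray,
    t_arrival: float,
    mu: float,
    sigma: float,
    amplitude: float,
    baseline: float,
) -> np.ndarray:
    """Baseline plus a scaled lognormal density starting at ``t_arrival``."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(baseline))
    dt = t - t_arrival
    pos = dt > 0
    x = dt[pos]
    out[pos] += (
        amplitude
        / (x * sigma * np.sqrt(2.0 * np.pi))
        * np.exp(-((np.log(x) - mu) ** 2) / (2.0 * sigma**2))
    )
    return out


def _lognormal_peak_density(mu: float, sigma: float) -> float:
    """Value of the unit-area lognormal density at its mode."""
    mode = np.exp(mu - sigma**2)
    return float(
        1.0 / (mode * sigma * np.sqrt(2.0 * np.pi)) * np.exp(-(sigma**2) / 2.0)
    )


def quality_gate(
    tic: TimeIntensityCurve,
    max_excluded_fraction: float = DEFAULT_MAX_EXCLUDED_FRACTION,
) -> bool:
    """True iff the excluded-frame fraction is within the gate (inclusive)."""
    return tic.excluded_fraction <= max_excluded_fraction


def estimate_baseline_and_arrival(
    tic: TimeIntensityCurve, k_sd: float = DEFAULT_K_SD
) -> tuple[float, float]:
    """Pre-bolus baseline and contrast arrival time.

    Baseline is the median of the first 10% of non-excluded frames; its
    standard deviation sets a detection threshold baseline + k_sd * sd.
    Enhancement is detected at the earliest time the intensity stays above
    the threshold for at least three consecutive non-excluded frames; the
    threshold crossing is systematically late in noise, so arrival is then
    refined by walking back from the crossing to the start of the
    contiguous run of frames above baseline + 1 sd.
    """
    t, y = tic.usable_arrays()
    if t.size < MIN_USABLE_SAMPLES:
        raise InsufficientDataError(
            f"only {t.size} usable samples in node {tic.node_id!r}"
        )
    n_base = max(3, int(round(BASELINE_FRACTION * t.size)))
    baseline = float(np.median(y[:n_base]))
    sd = float(np.std(y[:n_base]))
    threshold = baseline + k_sd * sd
    above = y > threshold
    run = above & np.roll(above, -1) & np.roll(above, -2)
    run[-2:] = False
    idx = np.flatnonzero(run)
    if idx.size == 0:
        raise NoEnhancementError(
            f"no sustained enhancement above baseline in node {tic.node_id!r}"
        )
    i = int(idx[0])
    low = y > baseline + sd
    while i > 0 and low[i - 1]:
        i -= 1
    return baseline, float(t[i])


def _moment_starts(
    t: np.ndarray, y: np.ndarray, baseline: float, t_arrival: float
) -> list[np.ndarray]:
    """Deterministic multi-start initial parameter vectors for the fit."""
    after = t > t_arrival
    if not after.any():
        raise FitFailureError("no samples after arrival")
    i_peak = np.argmax(np.where(after, y, -np.inf))
    ttp_raw = max(t[i_peak] - t_arrival, 2.0 * np.median(np.diff(t)))
    peak_raw = max(y[i_peak] - baseline, 1e-9)
    starts = []
    for sigma0 in (0.25, 0.5, 0.9):
        mu0 = np.log(ttp_raw) + sigma0**2
        amp0 = peak_raw / _lognormal_peak_density(mu0, sigma0)
        starts.append(np.array([t_arrival, mu0, sigma0, amp0]))
    # arrival perturbations at the middle sigma (detection runs late)
    for dt0 in (-1.0, -0.5, 0.25):
        mu0 = np.log(max(ttp_raw - dt0, 1e-3)) + 0.25
        amp0 = peak_raw / _lognormal_peak_density(mu0, 0.5)
        starts.append(np.array([t_arrival + dt0, mu0, 0.5, amp0]))
    return starts


def fit_bolus(
    tic: TimeIntensityCurve,
    baseline: float,
    t_arrival: float,
    arrival_window_s: tuple[float, float] = (2.5, 0.5),
) -> BolusFit:
    """Least-squares lognormal-bolus fit to the non-excluded samples.

    The baseline is held fixed; amplitude, mu and sigma are free, and the
    arrival time is refined within ``arrival_window_s`` (allowance before,
    after) of the detected value — detection triggers systematically late
    in noise, and TTP is measured from arrival, so the window reaches
    further back than forward.  Six deterministic starts from
    method-of-moments estimates guard against local minima.
    """
    t, y = tic.usable_arrays()
    starts = _moment_starts(t, y, baseline, t_arrival)
    lo = [t_arrival - arrival_window_s[0], -5.0, 0.02, 1e-12]
    hi = [t_arrival + arrival_window_s[1], 6.0, 3.0, np.inf]

    def resid(p: np.ndarray) -> np.ndarray:
        return lognormal_bolus(t, p[0], p[1], p[2], p[3], baseline) - y

    best = None
    for p0 in starts:
        p0 = np.clip(p0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(f"bolus fit did not converge for node {tic.node_id!r}")
    p = best.x
    rmse = float(np.sqrt(np.mean(resid(p) ** 2)))
    return BolusFit(
        t_arrival_s=float(p[0]),
        mu=float(p[1]),
        sigma=float(p[2]),
        amplitude=float(p[3]),
        baseline=float(baseline),
        rmse=rmse,
        converged=True,
    )


def compute_ttp(fit: BolusFit) -> float:
    """Time-to-peak from the fitted curve: exp(mu - sigma^2)."""
    return float(np.exp(fit.mu - fit.sigma**2))


def compute_wir(
    tic: TimeIntensityCurve,
    fit: BolusFit,
    t_arrival: float,
    t_peak: float,
    source: str = "fitted",
) -> float:
    """OLS slope of enhancement vs time over the wash-in window.

    ``source='fitted'`` evaluates the fitted curve on the frame grid inside
    [t_arrival, t_peak]; ``source='raw'`` uses the raw non-excluded samples
    in the same window.
    """
    if t_peak <= t_arrival:
        raise InvalidInputError("t_peak must exceed t_arrival")
    if source == "fitted":
        keep = (tic.time_s >= t_arrival) & (tic.time_s <= t_peak) & ~tic.excluded
        tt = tic.time_s[keep]
        yy = fit.predict(tt)
    elif source == "raw":
        t, y = tic.usable_arrays()
        keep = (t >= t_arrival) & (t <= t_peak)
        tt, yy = t[keep], y[keep]
    else:
        raise InvalidInputError(f"unknown WiR source {source!r}")
    if tt.size < 3:
        raise InsufficientDataError(
            f"only {tt.size} samples in the wash-in window of node {tic.node_id!r}"
        )
    slope, _ = np.polyfit(tt, yy, 1)
    return float(slope)


def analyze_tic(
    tic: TimeIntensityCurve,
    max_excluded_fraction: float = DEFAULT_MAX_EXCLUDED_FRACTION,
    k_sd: float = DEFAULT_K_SD,
    wir_source: str = "fitted",
) -> PerfusionParams:
    """Quality gate, arrival detection, bolus fit and parameter extraction.

    Curves failing the gate, lacking enhancement, or defeating the fit are
    returned with ``usable=False`` rather than raising, so a cohort run
    degrades per-node (the study's unusable control node becomes N/A in
    the scorecard instead of aborting the pipeline).
    """
    frac = tic.excluded_fraction
    if not quality_gate(tic, max_excluded_fraction):
        return PerfusionParams(tic.node_id, usable=False, excluded_fraction=frac)
    try:
        baseline, t_arr = estimate_baseline_and_arrival(tic, k_sd)
        fit = fit_bolus(tic, baseline, t_arr)
        ttp = compute_ttp(fit)
        t_peak = fit.t_arrival_s + ttp
        wir = compute_wir(tic, fit, fit.t_arrival_s, t_peak, source=wir_source)
    except (NoEnhancementError, FitFailureError, InsufficientDataError):
        return PerfusionParams(tic.node_id, usable=False, excluded_fraction=frac)
    peak_enh = float(fit.predict(np.array([t_peak]))[0] - baseline)
    return PerfusionParams(
        node_id=tic.node_id,
        usable=True,
        excluded_fraction=frac,
        t_arrival_s=fit.t_arrival_s,
        t_peak_s=t_peak,
        ttp_s=ttp,
        wir_au_per_s=wir,
        peak_enhancement_au=peak_enh,
        baseline_au=baseline,
        fit_rmse=fit.rmse,
    )
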