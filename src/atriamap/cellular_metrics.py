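"""Action-potential duration metrics from intracellular microelectrode traces.

APD_f is measured from the maximum-upstroke time (dV/dt surrogate) to the first
post-peak crossing of ``peak - f * amplitude``, with amplitude = peak - resting and
resting taken as the mean over a pre-upstroke window.  The crossing is located with
sub-sample precision: linear interpolation between samples, refined on noisy traces
by a continuous two-segment ("hinge") line fit around the crossing so that the
estimate is robust both to additive noise and to the slope change that piecewise
repolarization waveforms have exactly at the repolarization level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .errors import (
    IncompleteRepolarizationError,
    InvalidParameterError,
    NoActionPotentialError,
)


@dataclass
class APTrace:
    """Uniformly sampled intracellular voltage trace (mV)."""

    voltage_mv: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.voltage_mv.ndim != 1 or self.voltage_mv.size < 3:
            raise InvalidParameterError("trace must be 1-D with at least 3 samples")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.voltage_mv.size) * self.dt_ms


@dataclass
class APDResult:
    apd20_ms: float
    apd50_ms: float
    apd90_ms: float
    activation_time_ms: float
    amplitude_mv: float
    resting_mv: float


def detect_upstroke(trace: APTrace) -> float:
    """Time (ms) of the maximum first difference on the rising limb before the peak.

    The time of the sample at which the steepest rise completes is returned; ties
    resolve to the earliest occurrence.
    """
    v = trace.voltage_mv
    if np.ptp(v) == 0:
        raise NoActionPotentialError("flat trace: no action potential")
    peak_idx = int(np.argmax(v))
    if peak_idx == 0:
        raise NoActionPotentialError("trace starts at its maximum: no rising limb")
    dv = np.diff(v[: peak_idx + 1])
    if dv.max() <= 0:
        raise NoActionPotentialError("no rising limb before the voltage peak")
    i = int(np.argmax(dv))  # argmax returns the earliest maximal index
    return float((i + 1) * trace.dt_ms)


def _noise_sd_estimate(v_pre: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences of the pre-upstroke
    baseline (differencing removes slow drift; MAD resists stray deflections)."""
    if v_pre.size < 4:
        return 0.0
    d = np.diff(v_pre)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _contiguous_run(sel: np.ndarray, anchor_idx: int) -> np.ndarray:
    """Restrict selected sample indices to the contiguous run (gaps of up to two
    samples allowed) containing the index closest to ``anchor_idx``."""
    if sel.size == 0:
        return sel
    breaks = np.nonzero(np.diff(sel) > 3)[0]
    runs = np.split(sel, breaks + 1)
    k = int(np.argmin([np.min(np.abs(run - anchor_idx)) for run in runs]))
    return runs[k]


#: standard repolarization fractions bounding the local fit window of each crossing
_STANDARD_LEVELS = (0.0, 0.2, 0.5, 0.9, 1.0)


def _band_limits(
    fraction: float, peak: float, resting: float, thr: float
) -> tuple[float, float]:
    """Voltage half-widths (above, below) of the crossing fit window.

    The window extends 80% of the way to the adjacent standard repolarization
    levels (70% of the way to rest), where repolarization waveforms may change
    slope, so the local fit sees at most the one slope break that can sit exactly
    at the measured level itself.
    """
    amp = peak - resting
    above = max(s for s in _STANDARD_LEVELS if s < fraction)
    below = min(s for s in _STANDARD_LEVELS if s > fraction)
    b_hi = 0.8 * ((peak - above * amp) - thr)
    b_lo = (0.7 if below >= 1.0 else 0.8) * (thr - (peak - below * amp))
    return b_hi, b_lo


def _hinge_crossing(t: np.ndarray, v: np.ndarray, thr: float, tc0: float) -> float | None:
    """Crossing time of ``thr`` from a local robust line fit.

    A continuous two-segment ("hinge") model v = a + b1 (t-tau)_- + b2 (t-tau)_+
    is fitted with the knot iterated to the crossing itself (a slope break in a
    piecewise repolarization lies exactly at the crossing level); when the slope
    break is not statistically detectable (F-test), the lower-variance single
    line fit supplies the crossing instead.  Returns None when degenerate.
    """
    n = t.size
    if n < 6:
        return None
    X1 = np.column_stack([np.ones(n), t])
    a1, b1 = np.linalg.lstsq(X1, v, rcond=None)[0]
    sse_line = float(np.sum((X1 @ (a1, b1) - v) ** 2))
    tc_line = None if abs(b1) < 1e-12 else float((thr - a1) / b1)

    tc = tc0
    coef = None
    for _ in range(4):
        X = np.column_stack([np.ones(n), np.minimum(t - tc, 0.0), np.maximum(t - tc, 0.0)])
        a, bl, br = np.linalg.lstsq(X, v, rcond=None)[0]
        slope = br if a >= thr else bl
        if abs(slope) < 1e-12:
            coef = None
            break
        tc_new = tc + (thr - a) / slope
        coef = (a, bl, br)
        if abs(tc_new - tc) < 1e-6:
            tc = tc_new
            break
        tc = tc_new
    if coef is None:
        result = tc_line
    else:
        X = np.column_stack([np.ones(n), np.minimum(t - tc, 0.0), np.maximum(t - tc, 0.0)])
        sse_hinge = float(np.sum((X @ coef - v) ** 2))
        f_stat = (sse_line - sse_hinge) / max(sse_hinge / (n - 3), 1e-30)
        result = tc if (f_stat > 8.0 or tc_line is None) else tc_line
    if result is None or not (t[0] - 2.0 <= result <= t[-1] + 2.0):
        return None
    return float(result)


def apd(
    trace: APTrace,
    fraction: float,
    *,
    rest_window_ms: float = 40.0,
) -> float:
    """Action-potential duration at ``fraction`` repolarization (ms).

    Measured from the maximum-upstroke time to the first time after the peak at
    which the voltage, linearly interpolated between samples, falls to
    ``peak - fraction * amplitude``; on noisy traces the crossing is refined by a
    local two-segment line fit over the samples between the adjacent standard
    repolarization levels (see :func:`_hinge_crossing`).
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidParameterError("fraction must lie in (0, 1)")
    v = trace.voltage_mv
    dt = trace.dt_ms
    t = trace.time_ms

    t_up = detect_upstroke(trace)
    i_up = int(round(t_up / dt))

    # resting potential: mean over a pre-upstroke window ending 1 ms before upstroke
    i_hi = max(1, i_up - max(1, int(round(1.0 / dt))))
    i_lo = max(0, i_hi - int(round(rest_window_ms / dt)))
    pre = v[i_lo:i_hi]
    resting = float(np.mean(pre)) if pre.size else float(v[0])
    noise_sd = _noise_sd_estimate(pre)

    peak_idx = int(np.argmax(v))
    if noise_sd > 1e-9 * max(np.ptp(v), 1.0) and v.size >= 5:
        # median filtering suppresses noise without overshooting at the step-like
        # upstroke (a polynomial smoother would)
        peak = float(np.max(medfilt(v, kernel_size=5)))
    else:
        peak = float(v[peak_idx])

    amplitude = peak - resting
    if amplitude <= 0:
        raise NoActionPotentialError("non-positive action-potential amplitude")
    thr = peak - fraction * amplitude

    post = v[peak_idx:]
    below = np.nonzero(post <= thr)[0]
    if below.size == 0:
        raise IncompleteRepolarizationError(
            f"voltage never repolarizes to {fraction:.0%} of the amplitude"
        )
    j = int(below[0])  # first sample at/below threshold
    if j == 0:
        t_cross = t[peak_idx]
    else:
        v1, v2 = post[j - 1], post[j]
        frac_between = (v1 - thr) / (v1 - v2) if v1 != v2 else 0.0
        t_cross = t[peak_idx + j - 1] + frac_between * dt

    if noise_sd > 1e-9 * amplitude:
        # robust refinement: local fit over the samples near the crossing level.
        # Sample selection runs on a median-filtered copy so isolated noisy
        # samples from outside the repolarization limb (high time-leverage
        # points) cannot enter the fit; the fit itself uses the raw samples.
        b_hi, b_lo = _band_limits(fraction, peak, resting, thr)
        v_sel = medfilt(v, kernel_size=5) if v.size >= 5 else v
        sel = np.nonzero(
            (t >= t[peak_idx])
            & (np.abs(t - t_cross) <= 30.0)
            & (v_sel <= thr + b_hi)
            & (v_sel >= thr - b_lo)
        )[0]
        sel = _contiguous_run(sel, int(round(t_cross / dt)))
        if sel.size >= 6:
            refined = _hinge_crossing(t[sel], v[sel], thr, t_cross)
            if refined is not None and refined > t[peak_idx] - dt:
                t_cross = refined

    return float(t_cross - t_up)


def measure_apd(trace: APTrace, fractions: tuple[float, ...] = (0.2, 0.5, 0.9)) -> APDResult:
    """Measure APD at the standard repolarization fractions plus trace descriptors."""
    t_up = detect_upstroke(trace)
    dt = trace.dt_ms
    i_up = int(round(t_up / dt))
    i_hi = max(1, i_up - max(1, int(round(1.0 / dt))))
    i_lo = max(0, i_hi - int(round(20.0 / dt)))
    pre = trace.voltage_mv[i_lo:i_hi]
    resting = float(np.mean(pre)) if pre.size else float(trace.voltage_mv[0])
    peak = float(np.max(trace.voltage_mv))
    values = {f: apd(trace, f) for f in fractions}
    return APDResult(
        apd20_ms=values.get(0.2, np.nan),
        apd50_ms=values.get(0.5, np.nan),
        apd90_ms=values.get(0.9, np.nan),
        activation_time_ms=t_up,
        amplitude_mv=peak - resting,
        resting_mv=resting,
    )
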