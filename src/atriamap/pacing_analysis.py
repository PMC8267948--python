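"""S1-S2 extrastimulus protocol analysis: capture detection and ERP determination.

The effective refractory period (ERP) is the longest S1-S2 coupling interval that
fails to propagate.  The standard protocol is an eight-beat S1 drive train followed
by a premature S2 delivered in 10 ms decrements from a 100 ms coupling interval,
repeated at cycle lengths 100/200/300/400 ms, in triplicate, from two corners of
the plaque (inferior left-atrial appendage, LAA; left-atrial free wall, LAFW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activation_mapping import MappingConfig, DEFAULT_CONFIG, _robust_sd
from .errors import InsufficientDataError, InvalidParameterError, InvalidProtocolError
from .recording_io import Recording, StimulusEvent


@dataclass(frozen=True)
class ProtocolConfig:
    """S1-S2 pacing protocol parameters (times in ms)."""

    cycle_lengths_ms: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)
    n_s1: int = 8
    s2_start_ms: float = 100.0
    s2_decrement_ms: float = 10.0
    n_replicates: int = 3
    corners: tuple[str, ...] = ("LAA", "LAFW")

    def __post_init__(self) -> None:
        if any(cl <= 0 for cl in self.cycle_lengths_ms):
            raise InvalidParameterError("cycle lengths must be positive")
        if self.s2_decrement_ms <= 0:
            raise InvalidParameterError("S2 decrement must be positive")
        if self.s2_start_ms < self.s2_decrement_ms:
            raise InvalidParameterError("S2 start must be >= one decrement")
        if self.n_s1 < 1:
            raise InvalidParameterError("need at least one S1 beat")


def default_protocol() -> ProtocolConfig:
    """The standard protocol: CLs (100, 200, 300, 400) ms, 8 S1 beats, S2 from
    100 ms in 10 ms decrements, three replicates, both corners."""
    return ProtocolConfig()


class BelowResolution:
    """Marker for an ERP below the smallest tested coupling interval (every tested
    S2 captured)."""

    def __init__(self, smallest_tested_ci_ms: float):
        self.smallest_tested_ci_ms = float(smallest_tested_ci_ms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BelowResolution(< {self.smallest_tested_ci_ms:g} ms)"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BelowResolution)
            and other.smallest_tested_ci_ms == self.smallest_tested_ci_ms
        )


@dataclass
class ERPResult:
    """Replicate ERPs and their mean for one corner and cycle length."""

    corner: str
    cycle_length_ms: float
    replicates_ms: list  # floats and/or BelowResolution markers
    mean_ms: float | None


# ---------------------------------------------------------------------------
# capture detection
# ---------------------------------------------------------------------------

def detect_capture(
    rec: Recording,
    stim_time_ms: float,
    search_span_ms: float = 40.0,
    *,
    capture_fraction: float = 0.8,
    config: MappingConfig = DEFAULT_CONFIG,
) -> bool:
    """True iff the fraction of channels showing a supra-threshold deflection in
    ``(stim + blanking, stim + span)`` reaches ``capture_fraction``.

    Uses the same baseline/threshold rule as LAT annotation but without sub-sample
    refinement (a boolean per channel suffices), so it is cheap enough to run on
    every delivered S2.
    """
    dt = rec.dt_ms
    n = rec.n_samples
    i0 = int(np.ceil((stim_time_ms + config.blanking_ms) / dt))
    i1 = int(np.floor((stim_time_ms + search_span_ms) / dt)) + 1
    if i1 > n:
        warnings.warn("capture window truncated at the end of the recording", stacklevel=2)
        i1 = n
    if i0 >= i1 or i0 < 0:
        raise InvalidParameterError("capture window outside the recording")
    b1 = int(np.floor((stim_time_ms - config.blanking_ms) / dt))
    b0 = max(0, b1 - int(round(config.baseline_span_ms / dt)))
    if b1 <= b0:
        raise InvalidParameterError("no pre-stimulus baseline available")

    base = rec.traces[:, b0:b1]
    baseline = np.median(base, axis=1, keepdims=True)
    robust_sd = 1.4826 * np.median(np.abs(base - baseline), axis=1)
    dev = np.abs(rec.traces[:, i0:i1] - baseline).max(axis=1)
    detected = (dev > config.threshold_k * robust_sd) & (dev > 0)
    return bool(detected.mean() >= capture_fraction)


# ---------------------------------------------------------------------------
# ERP logic
# ---------------------------------------------------------------------------

def erp_from_run(
    capture_outcomes: list[tuple[float, bool]],
) -> float | BelowResolution:
    """ERP from one decremental S2 sweep: the largest coupling interval with
    ``captured == False``.  If every tested interval captured, a
    :class:`BelowResolution` marker is returned instead of a fabricated number."""
    if not capture_outcomes:
        raise InvalidProtocolError("empty capture-outcome list")
    cis = [ci for ci, _ in capture_outcomes]
    if any(c2 >= c1 for c1, c2 in zip(cis, cis[1:])):
        raise InvalidProtocolError("coupling intervals must be strictly decreasing")
    failed = [ci for ci, captured in capture_outcomes if not captured]
    if not failed:
        return BelowResolution(min(cis))
    return float(max(failed))


def average_erp(replicates: list) -> float:
    """Arithmetic mean of the finite replicate ERPs; below-resolution markers are
    excluded with a warning."""
    finite = [float(r) for r in replicates if not isinstance(r, BelowResolution)]
    n_markers = len(replicates) - len(finite)
    if not finite:
        raise InsufficientDataError("all replicates below protocol resolution")
    if n_markers:
        warnings.warn(
            f"{n_markers} replicate(s) below protocol resolution excluded from the mean",
            stacklevel=2,
        )
    return float(np.mean(finite))


# ---------------------------------------------------------------------------
# sweep recordings -> outcomes
# ---------------------------------------------------------------------------

def sweep_outcomes(
    rec: Recording,
    *,
    search_span_ms: float = 40.0,
    capture_fraction: float = 0.8,
    config: MappingConfig = DEFAULT_CONFIG,
) -> list[tuple[float, bool]]:
    """Evaluate capture for every S2 in a sweep recording, ordered as delivered."""
    outcomes: list[tuple[float, bool]] = []
    prev: StimulusEvent | None = None
    for ev in rec.stimulus_log:
        if ev.kind == "S2":
            ci = ev.ci_ms
            if ci is None and prev is not None:
                ci = ev.t_ms - prev.t_ms
            captured = detect_capture(
                rec,
                ev.t_ms,
                search_span_ms,
                capture_fraction=capture_fraction,
                config=config,
            )
            outcomes.append((float(ci), captured))
        prev = ev
    if not outcomes:
        raise InvalidProtocolError("recording contains no S2 stimuli")
    return outcomes


def measure_erp(
    sweep_recordings: list[Recording],
    *,
    corner: str,
    cycle_length_ms: float,
    search_span_ms: float = 40.0,
    config: MappingConfig = DEFAULT_CONFIG,
) -> ERPResult:
    """ERP for one corner/cycle length from replicate sweep recordings."""
    reps: list = [
        erp_from_run(sweep_outcomes(r, search_span_ms=search_span_ms, config=config))
        for r in sweep_recordings
    ]
    finite = [r for r in reps if not isinstance(r, BelowResolution)]
    mean = float(np.mean([float(r) for r in finite])) if finite else None
    return ERPResult(
        corner=corner, cycle_length_ms=cycle_length_ms, replicates_ms=reps, mean_ms=mean
    )
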