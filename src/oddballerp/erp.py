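"""Difference-wave ERP measurement: from a two-channel recording to the nine
P300 measures.

Pipeline (all linear steps before the peak search): average the two
prefrontal channels, attribute key presses to stimuli and classify trials,
epoch correct trials on [-200, 800) ms around stimulus onset (250 samples at
250 Hz, onset at index 50), baseline-correct on [-200, 0), average within
condition, smooth each averaged trace with a centered nine-point moving
average, and subtract the standard trace from the target trace.  On the
resulting difference wave:

* ``AMP``/``LAT`` — amplitude and time of the maximum within the 300–600 ms
  attention window (the peak must be positive);
* ``T1``/``T2`` — nearest zero crossings before/after the peak, linearly
  interpolated between samples and searched over the whole epoch (component
  onset may precede 300 ms);
* ``AUC`` — trapezoidal area of the wave between T1 and T2 (µV·ms);
* ``FAL`` — the 50% fractional-area latency, the time at which the cumulative
  area from T1 reaches AUC/2, found exactly under the piecewise-linear signal
  model by inverting the quadratic cumulative within one sample interval;
* ``T2T1``/``FALT1``/``T2FAL`` — interval differences, exactly additive.

A subject without a positive peak or without both crossings inside the epoch
has no dependable difference component and is marked invalid — the
algorithmic counterpart of excluding participants without a discernible
oddball-vs-standard peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientDataError,
    InvariantError,
    ParameterError,
    StructuralError,
)
from .simulate import SessionRecording, StimulusEvent, ResponseEvent

logger = logging.getLogger(__name__)

SAMPLE_RATE_HZ = 250.0
DT_MS = 4.0
EPOCH_START_MS = -200.0
EPOCH_N_SAMPLES = 250
ONSET_INDEX = 50
P300_WINDOW_MS = (300.0, 600.0)
SMOOTHING_TAPS = 9
ATTRIBUTION_WINDOW_MS = (100.0, 1000.0)


def epoch_times() -> np.ndarray:
    """Epoch time axis: [-200, 800) ms in 4 ms steps, onset at 0."""
    return EPOCH_START_MS + DT_MS * np.arange(EPOCH_N_SAMPLES)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One stimulus with its attributed response (if any) and classification."""

    stimulus: StimulusEvent
    response_time_ms: float | None
    classification: str  # hit | omission | correct_rejection | commission

    def __post_init__(self):
        has_resp = self.response_time_ms is not None
        if self.classification in ("hit", "commission") and not has_resp:
            raise ValueError(f"{self.classification} requires a response")
        if self.classification in ("omission", "correct_rejection") and has_resp:
            raise ValueError(f"{self.classification} excludes a response")
        is_target = self.stimulus.kind == "target"
        if self.classification in ("hit", "omission") and not is_target:
            raise ValueError("hit/omission apply only to targets")
        if self.classification in ("commission", "correct_rejection") and is_target:
            raise ValueError("commission/correct_rejection apply only to standards")


@dataclass
class ErpTrace:
    """Condition-averaged waveforms and their difference, on the epoch axis."""

    standard_avg: np.ndarray
    target_avg: np.ndarray
    difference: np.ndarray
    n_standard_trials: int
    n_target_trials: int


@dataclass
class ErpFeatures:
    """The nine difference-wave measures plus a validity flag.

    Invalid subjects carry NaN in the fields that could not be measured and a
    ``reason`` code (``no_correct_target_trials``, ``no_correct_standard_trials``,
    ``no_positive_peak``, ``no_discernible_peak``).
    """

    AMP: float = math.nan
    LAT: float = math.nan
    FAL: float = math.nan
    T1: float = math.nan
    T2: float = math.nan
    AUC: float = math.nan
    T2T1: float = math.nan
    FALT1: float = math.nan
    T2FAL: float = math.nan
    valid: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "AMP": self.AMP, "LAT": self.LAT, "FAL": self.FAL,
            "T1": self.T1, "T2": self.T2, "AUC": self.AUC,
            "T2T1": self.T2T1, "FALT1": self.FALT1, "T2FAL": self.T2FAL,
            "erp_valid": self.valid, "erp_reason": self.reason,
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def average_channels(recording: SessionRecording) -> np.ndarray:
    """Pointwise mean of the two prefrontal channels."""
    fp1 = np.asarray(recording.fp1, dtype=float)
    fp2 = np.asarray(recording.fp2, dtype=float)
    if fp1.shape != fp2.shape:
        raise StructuralError("Fp1 and Fp2 have mismatched lengths")
    return (fp1 + fp2) / 2.0


def attribute_responses(
    stimuli: list[StimulusEvent],
    responses: list[ResponseEvent],
    window_ms: tuple[float, float] = ATTRIBUTION_WINDOW_MS,
) -> tuple[list[TrialRecord], int]:
    """Attribute each press to the most recent stimulus whose onset precedes
    it by a latency inside ``window_ms`` (inclusive); first press per stimulus
    wins, later ones and unattributable presses are counted as stray.

    Returns ``(trials, n_stray)`` with one :class:`TrialRecord` per stimulus.
    """
    lo, hi = window_ms
    onsets = np.array([s.onset_ms for s in stimuli])
    if np.any(np.diff(onsets) <= 0):
        raise StructuralError("stimulus onsets must be strictly increasing")
    press_times = [r.press_time_ms for r in responses]
    if any(b <= a for a, b in zip(press_times, press_times[1:])):
        raise StructuralError("press times must be strictly increasing")

    assigned: dict[int, float] = {}
    n_stray = 0
    for press in press_times:
        idx = int(np.searchsorted(onsets, press - lo, side="right")) - 1
        if idx < 0 or press - onsets[idx] > hi or idx in assigned:
            n_stray += 1
            continue
        assigned[idx] = press - onsets[idx]

    trials = []
    for i, stim in enumerate(stimuli):
        rt = assigned.get(i)
        if stim.kind == "target":
            cls = "hit" if rt is not None else "omission"
        else:
            cls = "commission" if rt is not None else "correct_rejection"
        trials.append(TrialRecord(stimulus=stim, response_time_ms=rt, classification=cls))
    return trials, n_stray


_CORRECT_CLASS = {"standard": "correct_rejection", "target": "hit"}


def extract_epochs(
    signal: np.ndarray,
    trials: list[TrialRecord],
    condition: str,
    sample_rate: float = SAMPLE_RATE_HZ,
) -> np.ndarray:
    """Epochs (rows) of the correct trials of one condition.

    Correct trials are hits for targets and correct rejections for standards;
    commissions and omissions contribute to neither condition.  Trials whose
    [-200, 800) ms window exceeds the recording are skipped with a warning.
    """
    if condition not in _CORRECT_CLASS:
        raise ParameterError(f"condition must be 'standard' or 'target', got {condition!r}")
    want = _CORRECT_CLASS[condition]
    rows = []
    for trial in trials:
        if trial.classification != want:
            continue
        onset_idx = int(round(trial.stimulus.onset_ms * sample_rate / 1000.0))
        start = onset_idx - ONSET_INDEX
        stop = start + EPOCH_N_SAMPLES
        if start < 0 or stop > len(signal):
            logger.warning(
                "epoch for stimulus at %.1f ms exceeds recording bounds; skipped",
                trial.stimulus.onset_ms,
            )
            continue
        rows.append(signal[start:stop])
    if not rows:
        return np.empty((0, EPOCH_N_SAMPLES))
    return np.stack(rows)


def baseline_correct(epoch: np.ndarray) -> np.ndarray:
    """Subtract the mean of the [-200, 0) ms samples (first 50) from the epoch.

    Works on a single epoch (1-D) or a stack of epochs (2-D, epochs in rows).
    """
    epoch = np.asarray(epoch, dtype=float)
    baseline = epoch[..., :ONSET_INDEX].mean(axis=-1, keepdims=True)
    return epoch - baseline


def smooth_trace(trace: np.ndarray, taps: int = SMOOTHING_TAPS) -> np.ndarray:
    """Centered moving average with reflection padding; same length out."""
    if taps < 1 or taps % 2 == 0:
        raise ParameterError("taps must be odd and >= 1")
    trace = np.asarray(trace, dtype=float)
    if taps == 1:
        return trace.copy()
    half = taps // 2
    padded = np.pad(trace, half, mode="reflect")
    return np.convolve(padded, np.full(taps, 1.0 / taps), mode="valid")


def average_erp(epochs: np.ndarray) -> np.ndarray:
    """Pointwise mean across epochs (rows)."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 1:
        epochs = epochs[None, :]
    if epochs.shape[0] == 0:
        raise InsufficientDataError("no epochs to average")
    return epochs.mean(axis=0)


def difference_wave(target_avg: np.ndarray, standard_avg: np.ndarray) -> np.ndarray:
    """Target-average minus standard-average, pointwise."""
    target_avg = np.asarray(target_avg, dtype=float)
    standard_avg = np.asarray(standard_avg, dtype=float)
    if target_avg.shape != standard_avg.shape:
        raise StructuralError("target and standard traces are not aligned")
    return target_avg - standard_avg


# ---------------------------------------------------------------------------
# difference-wave measurement
# ---------------------------------------------------------------------------

def locate_p300(
    difference: np.ndarray,
    times: np.ndarray | None = None,
    window_ms: tuple[float, float] = P300_WINDOW_MS,
) -> tuple[float, float, bool]:
    """Peak amplitude and latency of the difference wave in the P300 window.

    Returns ``(AMP, LAT, peak_found)``; the peak is the global maximum over
    the window's samples and must be strictly positive to count as found.
    """
    difference = np.asarray(difference, dtype=float)
    t = epoch_times() if times is None else np.asarray(times, dtype=float)
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise StructuralError("time axis does not cover the search window")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmax(difference[idx]))]
    amp = float(difference[k])
    return amp, float(t[k]), amp > 0.0


def zero_crossings(
    difference: np.ndarray,
    lat_ms: float,
    times: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Nearest sign changes of the difference wave before and after the peak.

    Crossing times are linearly interpolated between samples; a sample that is
    exactly zero is itself the crossing (tie broken toward the peak).  Returns
    ``(T1, T2, valid)`` with NaN and ``valid=False`` when either crossing is
    absent within the epoch.
    """
    d = np.asarray(difference, dtype=float)
    t = epoch_times() if times is None else np.asarray(times, dtype=float)
    i_peak = int(np.argmin(np.abs(t - lat_ms)))
    if d[i_peak] <= 0:
        raise InvariantError("zero_crossings requires a positive peak at LAT")

    t1 = math.nan
    for i in range(i_peak - 1, -1, -1):
        if d[i] == 0.0:
            t1 = float(t[i])
            break
        if d[i] < 0.0:  # sign change between i and i+1 (d[i+1] > 0)
            t1 = float(t[i] + (t[i + 1] - t[i]) * (0.0 - d[i]) / (d[i + 1] - d[i]))
            break

    t2 = math.nan
    for i in range(i_peak + 1, len(d)):
        if d[i] == 0.0:
            t2 = float(t[i])
            break
        if d[i] < 0.0:  # sign change between i-1 and i (d[i-1] > 0)
            t2 = float(t[i - 1] + (t[i] - t[i - 1]) * (0.0 - d[i - 1]) / (d[i] - d[i - 1]))
            break

    valid = not (math.isnan(t1) or math.isnan(t2))
    return t1, t2, valid


def _wave_nodes(d: np.ndarray, t: np.ndarray, t1: float, t2: float):
    """Piecewise-linear nodes of the wave restricted to [t1, t2]."""
    inner = (t > t1) & (t < t2)
    xs = np.concatenate(([t1], t[inner], [t2]))
    ys = np.concatenate(([np.interp(t1, t, d)], d[inner], [np.interp(t2, t, d)]))
    return xs, ys


def area_features(
    difference: np.ndarray,
    t1: float,
    t2: float,
    times: np.ndarray | None = None,
) -> tuple[float, float]:
    """AUC (µV·ms) of the wave over [T1, T2] and the 50% fractional-area
    latency FAL.

    The wave is treated as piecewise linear through its samples (the same
    model that defines the interpolated crossings).  AUC is the trapezoidal
    integral including the partial end intervals; FAL solves the quadratic
    cumulative-area equation exactly within the bracketing sample interval.
    """
    if not t1 < t2:
        raise InvariantError("area_features requires T1 < T2")
    d = np.asarray(difference, dtype=float)
    t = epoch_times() if times is None else np.asarray(times, dtype=float)
    xs, ys = _wave_nodes(d, t, t1, t2)

    seg_areas = 0.5 * (ys[1:] + ys[:-1]) * np.diff(xs)
    auc = float(seg_areas.sum())
    if auc <= 0:
        raise InvariantError("AUC must be positive between the crossings")

    target = auc / 2.0
    cum = np.concatenate(([0.0], np.cumsum(seg_areas)))
    # first segment whose cumulative end reaches the half-area
    j = int(np.searchsorted(cum, target, side="left")) - 1
    j = min(max(j, 0), len(seg_areas) - 1)
    while cum[j + 1] < target and j < len(seg_areas) - 1:
        j += 1
    x0, x1 = xs[j], xs[j + 1]
    f0, f1 = ys[j], ys[j + 1]
    rem = target - cum[j]
    h = x1 - x0
    slope = (f1 - f0) / h
    if abs(slope) < 1e-15:
        tau = rem / f0 if f0 != 0 else 0.0
    else:
        disc = f0 * f0 + 2.0 * slope * rem
        disc = max(disc, 0.0)
        tau = (-f0 + math.sqrt(disc)) / slope
        if not 0.0 <= tau <= h + 1e-9:
            tau = (-f0 - math.sqrt(disc)) / slope
    fal = float(x0 + min(max(tau, 0.0), h))
    return auc, fal


def derived_intervals(t1: float, t2: float, fal: float) -> tuple[float, float, float]:
    """Interval measures ``(T2T1, FALT1, T2FAL)``; requires T1 < FAL < T2."""
    if not (t1 < fal < t2):
        raise InvariantError(f"need T1 < FAL < T2, got {t1}, {fal}, {t2}")
    return t2 - t1, fal - t1, t2 - fal


# ---------------------------------------------------------------------------
# full per-subject pipeline
# ---------------------------------------------------------------------------

def compute_erp_trace(
    recording: SessionRecording,
    *,
    window_ms: tuple[float, float] = ATTRIBUTION_WINDOW_MS,
    taps: int = SMOOTHING_TAPS,
    trials: list[TrialRecord] | None = None,
) -> ErpTrace:
    """Condition-averaged, baseline-corrected, smoothed traces and their
    difference for one recording.

    Raises :class:`InsufficientDataError` when either condition has no correct
    trial.
    """
    signal = average_channels(recording)
    if trials is None:
        trials, _ = attribute_responses(recording.stimuli, recording.responses, window_ms)
    std_epochs = extract_epochs(signal, trials, "standard", recording.sample_rate)
    tgt_epochs = extract_epochs(signal, trials, "target", recording.sample_rate)
    if tgt_epochs.shape[0] == 0:
        raise InsufficientDataError("no_correct_target_trials")
    if std_epochs.shape[0] == 0:
        raise InsufficientDataError("no_correct_standard_trials")
    std_avg = smooth_trace(average_erp(baseline_correct(std_epochs)), taps)
    tgt_avg = smooth_trace(average_erp(baseline_correct(tgt_epochs)), taps)
    return ErpTrace(
        standard_avg=std_avg,
        target_avg=tgt_avg,
        difference=difference_wave(tgt_avg, std_avg),
        n_standard_trials=std_epochs.shape[0],
        n_target_trials=tgt_epochs.shape[0],
    )


def measure_difference_wave(difference: np.ndarray,
                            times: np.ndarray | None = None) -> ErpFeatures:
    """All nine measures from an already-formed difference wave."""
    amp, lat, found = locate_p300(difference, times)
    if not found:
        return ErpFeatures(AMP=amp, LAT=lat, valid=False, reason="no_positive_peak")
    t1, t2, ok = zero_crossings(difference, lat, times)
    if not ok:
        return ErpFeatures(AMP=amp, LAT=lat, T1=t1, T2=t2,
                           valid=False, reason="no_discernible_peak")
    auc, fal = area_features(difference, t1, t2, times)
    t2t1, falt1, t2fal = derived_intervals(t1, t2, fal)
    return ErpFeatures(AMP=amp, LAT=lat, FAL=fal, T1=t1, T2=t2, AUC=auc,
                       T2T1=t2t1, FALT1=falt1, T2FAL=t2fal, valid=True)


def extract_erp_features(
    recording: SessionRecording,
    *,
    window_ms: tuple[float, float] = ATTRIBUTION_WINDOW_MS,
    taps: int = SMOOTHING_TAPS,
    trials: list[TrialRecord] | None = None,
) -> ErpFeatures:
    """End-to-end: recording -> the nine difference-wave measures."""
    try:
        trace = compute_erp_trace(recording, window_ms=window_ms, taps=taps, trials=trials)
    except InsufficientDataError as exc:
        return ErpFeatures(valid=False, reason=str(exc))
    return measure_difference_wave(trace.difference)
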