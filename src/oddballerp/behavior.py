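"""Task-performance (behavioral) measures from classified oddball trials.

Definitions, with hits = responded targets, omissions = unanswered targets,
commissions = responded standards:

* ``NI``   — number of commission errors;
* ``ER``   — (commissions + omissions) / hits, all errors per correct response;
* ``ACC``  — 100 x hits / n_target, percent of targets answered;
* ``WER``  — mean of the two per-class error rates,
  (commissions/n_standard + omissions/n_target) / 2;
* ``RT``   — mean hit latency (ms);
* ``RTSD`` — sample (n-1) standard deviation of hit latencies (ms).

A subject with zero hits has an undefined ER and is flagged invalid
(``no_target_responses``); one with more errors than hits (ER > 1) is flagged
``extreme_errors``.  Both mirror the inclusion rules the analysis assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .erp import TrialRecord

#: ER above this marks performance too erratic to analyze.
EXTREME_ERROR_RATIO = 1.0


@dataclass
class BehavioralFeatures:
    NI: float = math.nan
    ER: float = math.nan
    ACC: float = math.nan
    WER: float = math.nan
    RT: float = math.nan
    RTSD: float = math.nan
    n_hits: int = 0
    n_omissions: int = 0
    valid: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "NI": self.NI, "ER": self.ER, "ACC": self.ACC, "WER": self.WER,
            "RT": self.RT, "RTSD": self.RTSD,
            "behavior_valid": self.valid, "behavior_reason": self.reason,
        }


def behavioral_from_counts(
    n_hits: int,
    n_omissions: int,
    n_commissions: int,
    n_target: int,
    n_standard: int,
    hit_latencies_ms=None,
) -> BehavioralFeatures:
    """Compute the six measures from trial counts (and optional latencies)."""
    if n_target <= 0 or n_standard <= 0:
        raise ValueError("n_target and n_standard must be positive")
    if n_hits + n_omissions != n_target:
        raise ValueError("hits + omissions must equal the number of targets")

    feats = BehavioralFeatures(
        NI=float(n_commissions),
        ACC=100.0 * n_hits / n_target,
        WER=0.5 * (n_commissions / n_standard + n_omissions / n_target),
        n_hits=n_hits,
        n_omissions=n_omissions,
    )
    if n_hits == 0:
        feats.valid = False
        feats.reason = "no_target_responses"
        return feats

    feats.ER = (n_commissions + n_omissions) / n_hits
    if hit_latencies_ms is not None and len(hit_latencies_ms):
        lat = np.asarray(hit_latencies_ms, dtype=float)
        feats.RT = float(lat.mean())
        feats.RTSD = float(lat.std(ddof=1)) if len(lat) >= 2 else math.nan
    if feats.ER > EXTREME_ERROR_RATIO:
        feats.valid = False
        feats.reason = "extreme_errors"
    else:
        feats.valid = True
    return feats


def compute_behavioral(
    trials: list[TrialRecord],
    n_target: int,
    n_standard: int,
) -> BehavioralFeatures:
    """Compute the six measures from classified trials.

    ``trials`` must cover every stimulus of the session (one record each).
    """
    counted_targets = sum(t.stimulus.kind == "target" for t in trials)
    counted_standards = len(trials) - counted_targets
    if counted_targets != n_target or counted_standards != n_standard:
        raise ValueError(
            f"trials cover {counted_targets} targets / {counted_standards} standards, "
            f"expected {n_target} / {n_standard}"
        )
    hits = [t.response_time_ms for t in trials if t.classification == "hit"]
    n_omissions = sum(t.classification == "omission" for t in trials)
    n_commissions = sum(t.classification == "commission" for t in trials)
    return behavioral_from_counts(
        len(hits), n_omissions, n_commissions, n_target, n_standard, hits
    )
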