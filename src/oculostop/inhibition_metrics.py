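"""Derived behavioral measures: SSRT/TSRT, trial filters, RT binning, and
online gaze-based classification of redirect trials.

The central estimator is the integration method under the independent race
model: sort the no-signal RTs ascending, take the RT at the quantile equal
to the observed respond probability, and subtract the mean tracked delay.
With a staircase holding inhibition near 50%, this recovers the latency of
the covert STOP process (SSRT in the stop-signal task, TSRT in the
search-step task).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .race_model import SessionResult, TrialRecord


@dataclass
class BehavioralSummary:
    """Per-subject behavioral metrics (all times in ms)."""

    mean_rt_no_signal: float
    mean_rt_signal_respond: float
    p_respond: float
    mean_delay: float
    ssrt: float
    mean_rt_compensated: Optional[float] = None
    status: str = "ok"  # "degenerate" when p_respond is 0 or 1

    def to_dict(self) -> dict:
        return {
            "mean_rt_no_signal": self.mean_rt_no_signal,
            "mean_rt_signal_respond": self.mean_rt_signal_respond,
            "mean_rt_compensated": self.mean_rt_compensated,
            "p_respond": self.p_respond,
            "mean_delay": self.mean_delay,
            "ssrt": self.ssrt,
            "status": self.status,
        }


@dataclass
class GazeTrial:
    """A single eye-position trace for online redirect classification.

    ``samples`` are (time_ms, x_deg, y_deg) triples ordered in time with
    position relative to the nominal fixation point; ``t1_direction`` and
    ``t2_direction`` are target directions in degrees in [0, 360).
    """

    samples: np.ndarray  # shape (n, 3): time_ms, x_deg, y_deg
    array_onset: float
    t1_direction: float
    t2_direction: Optional[float] = None
    tsd: Optional[float] = None
    sampling_interval: float = 1000.0 / 60.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise InvalidInputError("samples must be an (n, 3) array")
        if np.any(np.diff(self.samples[:, 0]) < 0):
            raise InvalidInputError("samples must be ordered in time")


def filter_trials(records: Iterable[TrialRecord], min_rt: float = 100.0) -> list[TrialRecord]:
    """Drop responded trials with anticipatory RTs (< ``min_rt`` ms from
    array onset); everything else is kept in order."""
    return [r for r in records if r.rt is None or r.rt >= min_rt]


def integration_ssrt(
    no_signal_rts: Sequence[float], p_respond: float, mean_delay: float
) -> float:
    """Integration-method STOP latency estimate.

    Returns RT_(k) - mean_delay where RT_(k) is the k-th smallest no-signal
    RT with k = clamp(ceil(p_respond * N), 1, N).  No interpolation between
    order statistics.
    """
    rts = np.sort(np.asarray(list(no_signal_rts), dtype=float))
    n = rts.size
    if n == 0:
        raise InvalidInputError("no_signal_rts must be non-empty")
    if not 0.0 <= p_respond <= 1.0:
        raise InvalidInputError("p_respond must lie in [0, 1]")
    k = min(max(math.ceil(p_respond * n), 1), n)
    return float(rts[k - 1] - mean_delay)


def summarize_session(session: SessionResult, min_rt: float = 100.0) -> BehavioralSummary:
    """All per-subject behavioral metrics for one session.

    Anticipatory responses are filtered first; ``mean_delay`` averages the
    delay over all *presented* signal trials (the tracked staircase
    sequence), not only the retained ones.  A session with p_respond of
    exactly 0 or 1 yields a degenerate-flagged summary rather than an
    exception so cohort pipelines keep running.
    """
    presented_signal = [t for t in session.trials if t.trial_type == "signal"]
    kept = filter_trials(session.trials, min_rt=min_rt)
    signal = [t for t in kept if t.trial_type == "signal"]
    no_signal = [t for t in kept if t.trial_type == "no_signal"]
    if not signal or not no_signal:
        raise InvalidInputError("need >= 1 signal and >= 1 no-signal trial after filtering")

    responded = [t for t in signal if t.outcome == "responded"]
    p_respond = len(responded) / len(signal)
    mean_delay = float(np.mean([t.delay for t in presented_signal]))
    no_signal_rts = [t.rt for t in no_signal]

    status = "ok"
    if p_respond in (0.0, 1.0):
        status = "degenerate"
    ssrt = integration_ssrt(no_signal_rts, p_respond, mean_delay)
    return BehavioralSummary(
        mean_rt_no_signal=float(np.mean(no_signal_rts)),
        mean_rt_signal_respond=float(np.mean([t.rt for t in responded])) if responded else float("nan"),
        p_respond=p_respond,
        mean_delay=mean_delay,
        ssrt=ssrt,
        status=status,
    )


def vincentize(rts: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Quantile-bin RTs: sort ascending, split into ``n_bins`` contiguous
    equal-count bins (any remainder spread over the earliest bins) and
    return each bin's mean.  Averaging these across subjects gives the
    group RT distribution without smearing individual differences."""
    rts = np.sort(np.asarray(list(rts), dtype=float))
    n = rts.size
    if n < n_bins:
        raise InvalidInputError(f"need at least {n_bins} RTs, got {n}")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return np.array([rts[edges[i]: edges[i + 1]].mean() for i in range(n_bins)])


def _angular_sep(a: float, b: float) -> float:
    """Absolute angular separation in degrees, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def classify_redirect_trial(
    trial: GazeTrial,
    threshold_deg: float = 2.0,
    min_time: float = 100.0,
    min_samples: int = 2,
) -> str:
    """Online positional classification of a redirect trial.

    Positions are drift-corrected by the mean position in the +/-50 ms
    window around array onset.  The trial is scored from the first run of
    more than ``min_samples`` consecutive samples whose eccentricity
    exceeds ``threshold_deg`` at times more than ``min_time`` after array
    onset: ``compensated`` if the displacement points within 90 deg of T2,
    ``noncompensated`` if within 90 deg of T1, else ``unchanged`` (as when
    the threshold is never crossed).
    """
    if trial.t2_direction is None:
        raise InvalidInputError("redirect trials require a t2_direction")
    t = trial.samples[:, 0]
    if t.size == 0 or t[-1] < trial.array_onset + min_time:
        raise InvalidInputError("samples must cover at least min_time after array onset")

    drift_win = (t >= trial.array_onset - 50.0) & (t <= trial.array_onset + 50.0)
    if not drift_win.any():
        raise InvalidInputError("no samples in the drift-correction window around array onset")
    xy = trial.samples[:, 1:] - trial.samples[drift_win, 1:].mean(axis=0)

    ecc = np.hypot(xy[:, 0], xy[:, 1])
    out = (ecc > threshold_deg) & (t > trial.array_onset + min_time)

    # first run of strictly more than min_samples consecutive out-samples
    run_start, run_len = None, 0
    for i, flag in enumerate(out):
        if flag:
            run_len += 1
            if run_start is None:
                run_start = i
            if run_len > min_samples:
                break
        else:
            run_start, run_len = None, 0
    else:
        return "unchanged"

    run = xy[run_start: run_start + run_len]
    mean_vec = run.mean(axis=0)
    direction = math.degrees(math.atan2(mean_vec[1], mean_vec[0])) % 360.0
    sep_t1 = _angular_sep(direction, trial.t1_direction)
    sep_t2 = _angular_sep(direction, trial.t2_direction)
    if sep_t2 < 90.0 and sep_t2 <= sep_t1:
        return "compensated"
    if sep_t1 < 90.0:
        return "noncompensated"
    return "unchanged"


def compensated_latency(saccade_onset: float, t2_onset: float) -> float:
    """Latency convention for compensated trials: time from T2 onset to the
    (compensating) saccade onset.  No-step and noncompensated latencies are
    measured from array onset instead and need no special helper."""
    lat = saccade_onset - t2_onset
    if lat < 0:
        raise InvalidInputError("saccade onset precedes T2 onset")
    return float(lat)


def cohort_summary_table(
    sessions: Sequence[tuple[str, str, SessionResult]], min_rt: float = 100.0
) -> pd.DataFrame:
    """One BehavioralSummary row per (subject_id, group, session)."""
    rows = []
    for subject, group, session in sessions:
        d = summarize_session(session, min_rt=min_rt).to_dict()
        d.update(subject=subject, group=group)
        rows.append(d)
    cols = ["subject", "group", "mean_rt_no_signal", "mean_rt_signal_respond",
            "mean_rt_compensated", "p_respond", "mean_delay", "ssrt", "status"]
    return pd.DataFrame(rows)[cols]
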