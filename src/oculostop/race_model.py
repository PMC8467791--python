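"""Independent horse-race simulation of saccadic stopping tasks.

The model assumes two racing processes on every signal trial: a GO process
that generates the saccade to the initial target and a STOP process,
triggered after a tracked delay (SSD in the stop-signal task, TSD in the
search-step task), that inhibits it.  The saccade is executed iff the GO
process finishes before the STOP process.  Signal delays follow a
1-up/1-down staircase that converges on 50% successful inhibition.

Latencies are drawn from normal distributions truncated at zero; an
ex-Gaussian option (normal plus exponential tail) is available through the
``go_tau``/``stop_tau`` fields.  ``stop_sd = 0`` gives a constant STOP
latency, which makes the stop latency exactly recoverable by the
integration method and is used throughout the recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

TrialType = Literal["no_signal", "signal"]
Outcome = Literal["responded", "inhibited"]

#: Outcomes that move the staircase up (successful inhibition).
_UP_OUTCOMES = frozenset({"inhibited", "compensated"})
#: Outcomes that move the staircase down (failed inhibition).
_DOWN_OUTCOMES = frozenset({"responded", "noncompensated"})


@dataclass(frozen=True)
class RaceParameters:
    """GO and STOP latency distribution parameters for one subject (ms).

    ``go_tau``/``stop_tau`` > 0 switch the corresponding latency to an
    ex-Gaussian (normal + exponential with mean tau); the default 0 keeps
    the plain truncated normal.
    """

    go_mean: float
    go_sd: float
    stop_mean: float
    stop_sd: float
    go_tau: float = 0.0
    stop_tau: float = 0.0

    def __post_init__(self):
        if self.go_mean <= 0 or self.stop_mean <= 0:
            raise InvalidInputError("latency means must be positive")
        if self.go_sd < 0 or self.stop_sd < 0 or self.go_tau < 0 or self.stop_tau < 0:
            raise InvalidInputError("latency spreads must be non-negative")


@dataclass(frozen=True)
class TaskConfig:
    """Task-variant configuration.

    The stop-signal task uses 30% signal trials, initial delay 225 ms and a
    47 ms staircase step; the search-step task uses 40% redirect trials,
    initial delay 100 ms and a 67 ms step, with delays snapped to screen
    refresh multiples when ``frame_ms`` is set (60 Hz -> 1000/60 ms).
    """

    variant: Literal["stop_signal", "search_step"] = "stop_signal"
    p_signal: float = 0.30
    n_trials: int = 480
    initial_delay: float = 225.0
    step: float = 47.0
    frame_ms: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.p_signal < 1:
            raise InvalidInputError("p_signal must lie strictly in (0, 1)")
        if self.initial_delay < 0:
            raise InvalidInputError("initial_delay must be >= 0")
        if self.step <= 0:
            raise InvalidInputError("step must be positive")
        if self.frame_ms is not None and self.frame_ms <= 0:
            raise InvalidInputError("frame_ms must be positive when given")

    @classmethod
    def stop_signal(cls, n_trials: int = 480, **kw) -> "TaskConfig":
        return cls(variant="stop_signal", p_signal=0.30, n_trials=n_trials,
                   initial_delay=225.0, step=47.0, **kw)

    @classmethod
    def search_step(cls, n_trials: int = 240, frame_snap: bool = False, **kw) -> "TaskConfig":
        return cls(variant="search_step", p_signal=0.40, n_trials=n_trials,
                   initial_delay=100.0, step=67.0,
                   frame_ms=1000.0 / 60.0 if frame_snap else None, **kw)


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial with its latent race finish times."""

    index: int
    trial_type: TrialType
    delay: Optional[float]
    go_finish: float
    stop_finish: Optional[float]
    outcome: Outcome
    rt: Optional[float]


@dataclass
class SessionResult:
    """Ordered trials of one simulated session plus full provenance."""

    trials: list[TrialRecord]
    config: TaskConfig
    params: RaceParameters
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Session as a table with columns index, trial_type, delay_ms, outcome, rt_ms."""
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "trial_type": [t.trial_type for t in self.trials],
                "delay_ms": [t.delay for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "rt_ms": [t.rt for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def meta_json(self) -> str:
        return json.dumps(
            {"params": asdict(self.params), "config": asdict(self.config), "seed": self.seed},
            indent=2,
        )


def session_from_frame(
    frame: pd.DataFrame,
    config: Optional[TaskConfig] = None,
    params: Optional[RaceParameters] = None,
    seed: int = -1,
) -> SessionResult:
    """Rebuild a SessionResult from a session table (as written by
    ``SessionResult.to_csv``).  Latent finish times are not stored in the
    table; responded trials get go_finish = rt and inhibited trials an
    unusable placeholder, which is all the behavioral summaries need."""
    trials = []
    for row in frame.itertuples(index=False):
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        delay = None if pd.isna(row.delay_ms) else float(row.delay_ms)
        trials.append(
            TrialRecord(
                index=int(row.index),
                trial_type=row.trial_type,
                delay=delay,
                go_finish=rt if rt is not None else float("nan"),
                stop_finish=None,
                outcome=row.outcome,
                rt=rt,
            )
        )
    return SessionResult(
        trials=trials,
        config=config or TaskConfig(n_trials=len(trials)),
        params=params or RaceParameters(1.0, 0.0, 1.0, 0.0),
        seed=seed,
    )


def _draw_latency(mean: float, sd: float, tau: float, rng: np.random.Generator) -> float:
    """One latency draw, truncated below at 0 by resampling."""
    for _ in range(1000):
        x = rng.normal(mean, sd) if sd > 0 else mean
        if tau > 0:
            x += rng.exponential(tau)
        if x >= 0:
            return float(x)
    raise InvalidInputError("latency distribution places essentially all mass below 0")


def sample_trial(
    params: RaceParameters,
    trial_type: TrialType,
    delay: Optional[float],
    rng: np.random.Generator,
    index: int = 0,
) -> TrialRecord:
    """Run the race for a single trial.

    On signal trials the STOP process starts at ``delay`` and finishes at
    ``delay`` + STOP latency; the saccade is executed iff the GO finish
    comes strictly first.  No-signal trials always respond with
    rt = go_finish.
    """
    if trial_type == "signal":
        if delay is None:
            raise InvalidInputError("signal trials require a delay")
        if delay < 0:
            raise InvalidInputError(f"negative delay: {delay}")
    elif delay is not None:
        raise InvalidInputError("no-signal trials must not carry a delay")

    go_finish = _draw_latency(params.go_mean, params.go_sd, params.go_tau, rng)
    if trial_type == "no_signal":
        return TrialRecord(index, "no_signal", None, go_finish, None, "responded", go_finish)

    stop_finish = delay + _draw_latency(params.stop_mean, params.stop_sd, params.stop_tau, rng)
    if go_finish < stop_finish:
        return TrialRecord(index, "signal", delay, go_finish, stop_finish, "responded", go_finish)
    return TrialRecord(index, "signal", delay, go_finish, stop_finish, "inhibited", None)


def update_staircase(delay: float, outcome: str, config: TaskConfig) -> float:
    """1-up/1-down tracking update of the signal delay.

    Successful inhibition (``inhibited``/``compensated``) makes the next
    signal harder (+step); a failure (``responded``/``noncompensated``)
    makes it easier (-step).  The delay is clamped at 0 and, when
    ``frame_ms`` is set, rounded to the nearest frame multiple.
    """
    if outcome in _UP_OUTCOMES:
        new = delay + config.step
    elif outcome in _DOWN_OUTCOMES:
        new = delay - config.step
    else:
        raise InvalidInputError(f"unknown outcome {outcome!r}")
    new = max(0.0, new)
    if config.frame_ms is not None:
        new = round(new / config.frame_ms) * config.frame_ms
    return new


def simulate_session(params: RaceParameters, config: TaskConfig, seed: int) -> SessionResult:
    """Simulate a full session: i.i.d. Bernoulli(p_signal) trial
    interleaving with the staircase threaded through signal trials only.
    Fully reproducible from the seed."""
    if config.n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    delay = float(config.initial_delay)
    trials: list[TrialRecord] = []
    for i in range(config.n_trials):
        if rng.random() < config.p_signal:
            trial = sample_trial(params, "signal", delay, rng, index=i)
            delay = update_staircase(delay, trial.outcome, config)
        else:
            trial = sample_trial(params, "no_signal", None, rng, index=i)
        trials.append(trial)
    return SessionResult(trials=trials, config=config, params=params, seed=seed)


def inhibition_function(
    params: RaceParameters,
    delays: Sequence[float],
    n_reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo inhibition function: P(responded | delay) per delay.

    Response probability increases with the delay because later stop
    signals leave the STOP process less time to beat the GO process.
    """
    if len(delays) == 0:
        raise InvalidInputError("delays must be non-empty")
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for d in delays:
        responded = sum(
            sample_trial(params, "signal", float(d), rng).outcome == "responded"
            for _ in range(n_reps)
        )
        rows.append({"delay_ms": float(d), "p_respond": responded / n_reps})
    return pd.DataFrame(rows)
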