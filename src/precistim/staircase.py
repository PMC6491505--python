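"""Interleaved easy/hard adaptive staircase titration and its equilibria.

The staircase adjusts the frequency difference (delta, Hz) between a base
34 Hz vibration and a comparison vibration.  Every incorrect response steps
delta *up* by ``step_fraction`` of its current value.  Correct responses
accumulate a tally that persists through errors; when the tally reaches
``down_count`` (6 for the easy track, 2 for the hard track) delta steps
*down* by ``step_fraction`` and the tally resets.

At equilibrium the expected number of up-steps per trial, ``1 - p``, equals
the expected number of down-steps, ``p / m`` (one down-step per ``m``
correct), so accuracy converges to ``p = m / (m + 1)``: 2/3 for the hard
track and 6/7 ~ 0.857 for the easy track.  The medium difficulty is the
geometric mean of the two converged deltas.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TitrationResult",
    "GaussianObserver",
    "staircase_update",
    "run_staircase",
    "run_titration",
    "medium_difference",
    "equilibrium_accuracy",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """One staircase track's rule parameters."""

    initial_delta: float = 5.0  # Hz
    step_fraction: float = 0.10
    down_count: int = 6  # 6 = easy track, 2 = hard track
    base_frequency: float = 34.0  # Hz

    def __post_init__(self) -> None:
        if not self.initial_delta > 0:
            raise ValueError("initial_delta must be > 0")
        if not (0 < self.step_fraction < 1):
            raise ValueError("step_fraction must be in (0, 1)")
        if self.down_count < 1:
            raise ValueError("down_count must be >= 1")


@dataclass(frozen=True)
class StaircaseState:
    """Current delta, correct-response tally, and history of one track."""

    delta: float
    tally: int = 0
    trial_index: int = 0
    history: tuple = field(default_factory=tuple)  # of (delta, correct)

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if self.tally < 0:
            raise ValueError("tally must be >= 0")


@dataclass(frozen=True)
class TitrationResult:
    easy_delta: float
    hard_delta: float
    medium_delta: float
    easy_track: tuple  # of (delta, correct)
    hard_track: tuple
    easy_accuracy: float  # asymptotic, final third of the track
    hard_accuracy: float
    converged: bool


class GaussianObserver:
    """Stochastic observer with a cumulative-Gaussian psychometric function.

    Probability correct at frequency difference ``delta`` is
    ``Phi(delta / (sd * sqrt(2)))``: the ideal faster-slower decision on two
    percepts each carrying encoding noise ``sd``, which tends to chance (1/2)
    as delta -> 0 and to 1 for large delta.
    """

    def __init__(self, sd: float, rng: np.random.Generator | None = None):
        if sd <= 0:
            raise ValueError("sd must be > 0")
        self.sd = sd
        self.rng = rng if rng is not None else np.random.default_rng()

    def p_correct(self, delta: float) -> float:
        return float(norm.cdf(delta / (self.sd * math.sqrt(2.0))))

    def respond(self, delta: float) -> bool:
        return bool(self.rng.random() < self.p_correct(delta))


def staircase_update(state: StaircaseState, correct: bool,
                     config: StaircaseConfig) -> StaircaseState:
    """Apply one response to a staircase track.

    Incorrect: delta *= 1 + step_fraction, tally untouched (it persists
    through errors).  Correct: tally += 1; on reaching ``down_count`` delta
    *= 1 - step_fraction and the tally resets to zero.
    """
    history = state.history + ((state.delta, bool(correct)),)
    if not correct:
        return replace(state, delta=state.delta * (1.0 + config.step_fraction),
                       trial_index=state.trial_index + 1, history=history)
    tally = state.tally + 1
    if tally >= config.down_count:
        return replace(state, delta=state.delta * (1.0 - config.step_fraction),
                       tally=0, trial_index=state.trial_index + 1,
                       history=history)
    return replace(state, tally=tally, trial_index=state.trial_index + 1,
                   history=history)


def run_staircase(observer, config: StaircaseConfig, n_trials: int,
                  seed: int | None = None) -> list[tuple[float, bool]]:
    """Run a single staircase track for ``n_trials`` trials.

    ``observer`` must expose ``respond(delta) -> bool``; if it has a ``rng``
    attribute and ``seed`` is given, the observer is re-seeded for
    reproducibility.  Returns the (delta, correct) history.

    This avoids the per-trial dataclass copies of :func:`staircase_update`
    (which is the reference single-step rule) for long runs.
    """
    if seed is not None and hasattr(observer, "rng"):
        observer.rng = np.random.default_rng(seed)
    delta = config.initial_delta
    tally = 0
    history: list[tuple[float, bool]] = []
    up = 1.0 + config.step_fraction
    down = 1.0 - config.step_fraction
    for _ in range(n_trials):
        correct = observer.respond(delta)
        history.append((delta, correct))
        if correct:
            tally += 1
            if tally >= config.down_count:
                delta *= down
                tally = 0
        else:
            delta *= up
    return history


def _track_summary(track: list[tuple[float, bool]]) -> tuple[float, float]:
    """(converged delta, asymptotic accuracy) from the final third of a track.

    The converged delta is the geometric mean of delta over the final third;
    accuracy is the proportion correct there.
    """
    tail = track[len(track) - len(track) // 3:]
    deltas = np.array([d for d, _ in tail])
    correct = np.array([c for _, c in tail])
    return float(np.exp(np.mean(np.log(deltas)))), float(np.mean(correct))


def run_titration(observer, config_easy: StaircaseConfig,
                  config_hard: StaircaseConfig, n_trials: int,
                  seed: int | None = None) -> TitrationResult:
    """Run two intermixed staircases and derive the medium difficulty.

    Each trial a track is drawn uniformly at random (the base/comparison
    presentation order is randomized inside the observer's symmetric
    psychometric function and does not alter accuracy).  Converged deltas are
    geometric means over the final third of each track; the medium delta is
    their geometric mean.
    """
    rng = np.random.default_rng(seed)
    if hasattr(observer, "rng"):
        observer.rng = np.random.default_rng(rng.integers(2**31))
    converged = True
    if n_trials < 50:
        warnings.warn("n_trials < 50: convergence estimate unreliable")
        converged = False
    tracks: dict[str, list[tuple[float, bool]]] = {"easy": [], "hard": []}
    state = {"easy": (config_easy.initial_delta, 0),
             "hard": (config_hard.initial_delta, 0)}
    configs = {"easy": config_easy, "hard": config_hard}
    for _ in range(n_trials):
        which = "easy" if rng.random() < 0.5 else "hard"
        delta, tally = state[which]
        cfg = configs[which]
        correct = observer.respond(delta)
        tracks[which].append((delta, correct))
        if correct:
            tally += 1
            if tally >= cfg.down_count:
                delta *= 1.0 - cfg.step_fraction
                tally = 0
        else:
            delta *= 1.0 + cfg.step_fraction
        state[which] = (delta, tally)
    if not tracks["easy"] or not tracks["hard"]:
        raise ValueError("a track received no trials; increase n_trials")
    easy_delta, easy_acc = _track_summary(tracks["easy"])
    hard_delta, hard_acc = _track_summary(tracks["hard"])
    return TitrationResult(
        easy_delta=easy_delta, hard_delta=hard_delta,
        medium_delta=medium_difference(easy_delta, hard_delta),
        easy_track=tuple(tracks["easy"]), hard_track=tuple(tracks["hard"]),
        easy_accuracy=easy_acc, hard_accuracy=hard_acc, converged=converged,
    )


def medium_difference(easy_delta: float, hard_delta: float) -> float:
    """Geometric mean of the easy and hard converged frequency differences."""
    if easy_delta <= 0 or hard_delta <= 0:
        raise ValueError("deltas must be positive")
    return math.sqrt(easy_delta * hard_delta)


def equilibrium_accuracy(down_count: int) -> float:
    """Drift-balance equilibrium accuracy m / (m + 1).

    A step-up occurs on each error (rate 1 - p) and a step-down once per
    ``m`` correct responses (rate p / m); balancing the two gives
    p = m / (m + 1).
    """
    if down_count < 1:
        raise ValueError("down_count must be >= 1")
    return down_count / (down_count + 1.0)


def export_tracks_csv(result: TitrationResult, path_or_buf) -> None:
    """Write both tracks as CSV rows (trial, staircase, delta_hz, correct)."""
    own = isinstance(path_or_buf, (str, bytes))
    fh = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        writer = csv.writer(fh)
        writer.writerow(["trial", "staircase", "delta_hz", "correct"])
        for name, track in (("easy", result.easy_track),
                            ("hard", result.hard_track)):
            for i, (d, c) in enumerate(track):
                writer.writerow([i, name, f"{d:.6f}", int(c)])
    finally:
        if own:
            fh.close()
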