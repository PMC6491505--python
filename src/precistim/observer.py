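"""A precision-weighted observer for flutter discrimination judgments.

Each stimulus is encoded as a Gaussian percept whose mean is the true
frequency (plus a constant bias) and whose standard deviation combines
internal encoding noise ``sigma_p`` with an external term contributed by the
stimulus's temporal roughness.  The faster-slower judgment subtracts the two
percept values and responds on the sign — precision plays no explicit role.
The same-different judgment divides the absolute percept difference by its
believed standard deviation (the precision-weighted rule) and compares the
resulting z-score to a criterion; rougher stimuli widen the believed
standard deviation, so at a fixed criterion the observer demands a larger
raw difference before reporting "different".

On same-noisy trials the two stimuli reuse the identical jitter sequence, so
the external-noise component of the two percepts is one common draw that
cancels from their difference while still inflating the believed SD; this is
what makes the observer *more* accurate on noisy same trials, the signature
crossover of the precision-weighted rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

__all__ = [
    "ObserverParams",
    "Percept",
    "encode_percept",
    "decide_faster",
    "decide_different",
    "simulate_session",
    "dprime",
    "cell_accuracies",
    "stimulus_noise_sd_hz",
]


@dataclass(frozen=True)
class ObserverParams:
    """Free parameters of the simulated observer.

    perceptual_sd : internal encoding noise sigma_p in Hz.
    bias : constant shift of the first percept, Hz.
    stim_noise_coupling : kappa, mapping stimulus roughness to an added
        percept SD (dimensionless; a free parameter of the observer model).
    criterion : same-different decision criterion c; dimensionless z units
        under the precision_weighted rule, Hz under raw_difference.
    rule : "precision_weighted" or "raw_difference".
    """

    perceptual_sd: float = 1.0
    bias: float = 0.0
    stim_noise_coupling: float = 1.0
    criterion: float = 1.0
    rule: str = "precision_weighted"

    def __post_init__(self) -> None:
        if self.perceptual_sd < 0:
            raise ValueError("perceptual_sd must be >= 0")
        if self.stim_noise_coupling < 0:
            raise ValueError("stim_noise_coupling must be >= 0")
        if self.criterion < 0:
            raise ValueError("criterion must be >= 0")
        if self.rule not in ("precision_weighted", "raw_difference"):
            raise ValueError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class Percept:
    """A sampled inferred frequency and the observer's belief about its SD."""

    value: float  # Hz
    known_sd: float  # Hz

    def __post_init__(self) -> None:
        if self.known_sd < 0:
            raise ValueError("known_sd must be >= 0")


def stimulus_noise_sd_hz(frequency: float, noise_fraction: float,
                         duration_ms: float = 512.0,
                         coupling: float = 1.0) -> float:
    """Effective frequency-estimate SD (Hz) contributed by temporal jitter.

    The observer's frequency estimate averages over the ~f*duration cycles
    present, so the SD of the mean period scales the per-cycle roughness by
    1/sqrt(n_cycles); in frequency units this is
    kappa * noise_fraction * frequency / sqrt(n_cycles).
    """
    n_cycles = max(frequency * duration_ms / 1000.0, 1.0)
    return coupling * noise_fraction * frequency / math.sqrt(n_cycles)


def encode_percept(frequency: float, stimulus_noise_sd: float,
                   params: ObserverParams,
                   rng: np.random.Generator) -> Percept:
    """Draw one percept of a stimulus.

    value ~ N(frequency + bias, sqrt(sigma_p^2 + kappa^2 s^2)) where ``s`` is
    the stimulus roughness already expressed in Hz; known_sd is that same
    total SD (the observer knows how rough the stimulus felt).
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if stimulus_noise_sd < 0:
        raise ValueError("stimulus_noise_sd must be >= 0")
    total_sd = math.hypot(params.perceptual_sd,
                          params.stim_noise_coupling * stimulus_noise_sd)
    value = frequency + params.bias + (rng.normal(0.0, total_sd)
                                       if total_sd > 0 else 0.0)
    return Percept(value=value, known_sd=total_sd)


def decide_faster(p1: Percept, p2: Percept,
                  rng: np.random.Generator | None = None) -> bool:
    """Answer "Is the 2nd vibration faster?" by the sign of the difference.

    Exact ties are broken by a fair coin.
    """
    if p2.value > p1.value:
        return True
    if p2.value < p1.value:
        return False
    if rng is None:
        rng = np.random.default_rng()
    return bool(rng.random() < 0.5)


def decide_different(p1: Percept, p2: Percept, params: ObserverParams) -> bool:
    """Answer "Are the vibrations different?".

    precision_weighted: yes iff |p2 - p1| / sqrt(sd1^2 + sd2^2) > c.
    raw_difference:     yes iff |p2 - p1| > c (criterion then in Hz).
    Boundary equality answers "no" (conservative), as does a zero difference
    with zero known SDs.
    """
    diff = abs(p2.value - p1.value)
    if params.rule == "raw_difference":
        return diff > params.criterion
    pooled = math.hypot(p1.known_sd, p2.known_sd)
    if pooled == 0.0:
        return False if diff == 0.0 else True
    return diff / pooled > params.criterion


def simulate_session(schedule, params: ObserverParams,
                     seed: int | None = None) -> pd.DataFrame:
    """Simulate observer responses to every trial of an event schedule.

    ``schedule`` is an :class:`~precistim.synthetic_data.EventSchedule` or a
    DataFrame with columns ``context`` ("fast_slow" | "same_different"),
    ``condition`` ("regular" | "noisy"), ``f1``, ``f2`` (Hz) and
    ``noise_fraction``.  Percepts are drawn independently per stimulus,
    except on same-noisy trials where the external-noise component is one
    common draw (verbatim jitter-sequence reuse), while internal noise stays
    independent.

    Returns the trial table with percept values, choice, correctness and an
    RT placeholder column (reaction times are not modeled).
    """
    df = getattr(schedule, "trials", schedule)
    required = {"context", "condition", "f1", "f2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        ctx, cond = row.context, row.condition
        if ctx not in ("fast_slow", "same_different"):
            raise ValueError(f"row {i}: unknown context {ctx!r}")
        if cond not in ("regular", "noisy"):
            raise ValueError(f"row {i}: unknown condition {cond!r}")
        f1, f2 = float(row.f1), float(row.f2)
        nf = float(getattr(row, "noise_fraction", 0.08)) if cond == "noisy" else 0.0
        s1 = stimulus_noise_sd_hz(f1, nf)
        s2 = stimulus_noise_sd_hz(f2, nf)
        same_trial = f1 == f2
        if same_trial and cond == "noisy":
            # identical jitter sequence for both stimuli: one common
            # external draw; internal noise independent per stimulus
            ext = rng.normal(0.0, params.stim_noise_coupling * s1)
            v1 = f1 + params.bias + ext + rng.normal(0.0, params.perceptual_sd)
            v2 = f2 + ext + rng.normal(0.0, params.perceptual_sd)
            sd1 = math.hypot(params.perceptual_sd, params.stim_noise_coupling * s1)
            p1 = Percept(v1, sd1)
            p2 = Percept(v2, sd1)
        else:
            p1 = encode_percept(f1, s1, params, rng)
            p2 = Percept(
                f2 + (rng.normal(0.0, math.hypot(
                    params.perceptual_sd,
                    params.stim_noise_coupling * s2))
                    if (params.perceptual_sd > 0 or s2 > 0) else 0.0),
                math.hypot(params.perceptual_sd,
                           params.stim_noise_coupling * s2))
        if ctx == "fast_slow":
            truth = "faster" if f2 > f1 else "slower"
            choice_yes = decide_faster(p1, p2, rng)
            choice = "faster" if choice_yes else "slower"
            correct = choice == truth
        else:
            truth = "same" if same_trial else "different"
            choice_yes = decide_different(p1, p2, params)
            choice = "different" if choice_yes else "same"
            correct = choice == truth
        rows.append({
            "trial": i, "context": ctx, "condition": cond,
            "f1": f1, "f2": f2, "truth": truth,
            "percept1": p1.value, "percept2": p2.value,
            "known_sd1": p1.known_sd, "known_sd2": p2.known_sd,
            "choice": choice, "correct": correct,
            "rt": np.nan,  # placeholder; RTs are out of scope
            "seed": seed if seed is not None else -1,
        })
    return pd.DataFrame(rows)


def dprime(hit_rate: float, false_alarm_rate: float,
           n_trials: int | None = None) -> float:
    """Sensitivity d' = z(hit) - z(false alarm).

    Rates of exactly 0 or 1 are corrected log-linearly to 1/(2N) and
    1 - 1/(2N); the trial count ``n_trials`` is then required.
    """
    for name, r in (("hit_rate", hit_rate), ("false_alarm_rate", false_alarm_rate)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if hit_rate in (0.0, 1.0) or false_alarm_rate in (0.0, 1.0):
        if n_trials is None:
            raise ValueError("n_trials required to edge-correct rates of 0 or 1")
        lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
        hit_rate = min(max(hit_rate, lo), hi)
        false_alarm_rate = min(max(false_alarm_rate, lo), hi)
    return float(ndtri(hit_rate) - ndtri(false_alarm_rate))


def cell_accuracies(table: pd.DataFrame) -> dict:
    """Per-cell accuracies, the noise-by-difference interaction, and d'.

    Requires same-different trials in all four noise x difference cells.
    The interaction contrast is
    (same_noisy - same_regular) - (diff_noisy - diff_regular).
    d' is computed per context: for same-different, hits are "different"
    responses on different trials and false alarms "different" responses on
    same trials; for fast-slow, hits are "faster" responses on faster trials
    and false alarms "faster" responses on slower trials.
    """
    sd = table[table.context == "same_different"]
    cells = {}
    for cond in ("regular", "noisy"):
        for truth in ("same", "different"):
            sub = sd[(sd.condition == cond) & (sd.truth == truth)]
            if len(sub) == 0:
                raise ValueError(f"empty cell: condition={cond}, truth={truth}")
            cells[f"{truth}_{cond}"] = float(sub.correct.mean())
    interaction = ((cells["same_noisy"] - cells["same_regular"])
                   - (cells["different_noisy"] - cells["different_regular"]))
    out = dict(cells)
    out["interaction"] = interaction

    diff_trials = sd[sd.truth == "different"]
    same_trials = sd[sd.truth == "same"]
    hit = float((diff_trials.choice == "different").mean())
    fa = float((same_trials.choice == "different").mean())
    out["hit_rate"] = hit
    out["false_alarm_rate"] = fa
    out["dprime_same_different"] = dprime(hit, fa, n_trials=len(sd))

    fs = table[table.context == "fast_slow"]
    if len(fs):
        faster = fs[fs.truth == "faster"]
        slower = fs[fs.truth == "slower"]
        if len(faster) and len(slower):
            h = float((faster.choice == "faster").mean())
            f = float((slower.choice == "faster").mean())
            out["dprime_fast_slow"] = dprime(h, f, n_trials=len(fs))
        out["accuracy_fast_slow"] = float(fs.correct.mean())
    out["accuracy_same_different"] = float(sd.correct.mean())
    return out
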