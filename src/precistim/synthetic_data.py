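"""Event schedules, DCM input streams, HRF utilities, and group datasets.

The schedule generator emulates the study's trial clock: two 512 ms flutter
stimuli separated by a 600 ms ISI, a response window of at most 2 s from the
second-stimulus onset, and inter-trial intervals drawn uniformly from
[6, 12] s (defined here as the gap from second-stimulus offset to the next
trial onset).  Same-different sessions contain exactly half same pairs, and
same-noisy trials carry the identical jitter seed for both stimuli —
verbatim reuse of the pseudorandom wavelength sequence.

Group datasets pair each synthetic subject's schedule with behavioral trials
from the observer model and BOLD series from a known generating DCM with
between-subject parameter variation, all seeded hierarchically so any
subject is reproducible from (master seed, subject index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from precistim.dcm_generative import (
    BOLDSeries,
    DCMModel,
    DCMParams,
    HemoParams,
    InputSet,
    build_model_space,
    default_generating_params,
    simulate_bold,
    stability_check,
)
from precistim.observer import ObserverParams, simulate_session

__all__ = [
    "STIM_DURATION_S",
    "ISI_S",
    "RESPONSE_WINDOW_S",
    "EventSchedule",
    "GroupConfig",
    "SubjectData",
    "GroupDataset",
    "generate_schedule",
    "build_dcm_inputs",
    "generate_group",
    "double_gamma_hrf",
    "convolve_hrf",
]

STIM_DURATION_S = 0.512
ISI_S = 0.600
RESPONSE_WINDOW_S = 2.0
ITI_RANGE_S = (6.0, 12.0)
#: second-stimulus onset relative to trial onset: 512 ms stimulus + 600 ms ISI
F2_ONSET_S = STIM_DURATION_S + ISI_S
TRIAL_SPAN_S = F2_ONSET_S + STIM_DURATION_S  # f1 onset -> f2 offset, 1.624 s


@dataclass
class EventSchedule:
    """Per-trial event table; one row per trial."""

    trials: pd.DataFrame
    context: str  # "same_different" | "fast_slow"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def end_time(self) -> float:
        last = self.trials.onset.iloc[-1]
        return float(last + F2_ONSET_S + RESPONSE_WINDOW_S)

    def to_events_tsv(self, path) -> None:
        """BIDS-style events table: one row per stimulus epoch."""
        rows = []
        for t in self.trials.itertuples(index=False):
            for which, onset, freq, jseed in (
                    ("f1", t.onset, t.f1, t.jitter_seed_f1),
                    ("f2", t.onset + F2_ONSET_S, t.f2, t.jitter_seed_f2)):
                rows.append({
                    "onset": round(onset, 4),
                    "duration": STIM_DURATION_S,
                    "trial_type": f"{t.condition}_{t.truth}",
                    "stimulus": which,
                    "frequency_hz": freq,
                    "context": t.context,
                    "jitter_seed": jseed,
                    "response_window_s": RESPONSE_WINDOW_S,
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GroupConfig:
    """Group-study conditions for the synthetic dataset."""

    n_subjects: int = 16
    session_length_s: float = 360.0
    tr: float = 2.0
    snr: float = 1.0  # noise-free signal SD / observation-noise SD
    between_subject_sd: float = 0.1
    generating_model: str = "Stork3"
    master_seed: int = 0
    dt: float = 0.05  # integration / input grid, s
    base_frequency: float = 34.0
    delta_hz: float = 2.0  # medium titrated frequency difference
    noise_fraction: float = 0.08
    context: str = "same_different"
    lead_in_s: float = 10.0
    tail_s: float = 16.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("session_length_s", "tr", "snr", "dt",
                     "base_frequency", "delta_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class SubjectData:
    index: int
    seed: int
    schedule: EventSchedule
    trials: pd.DataFrame
    inputs: InputSet
    bold: BOLDSeries
    params: DCMParams


@dataclass
class GroupDataset:
    config: GroupConfig
    subjects: list[SubjectData]
    group_means: DCMParams
    metadata: dict = field(default_factory=dict)

    def to_directory(self, path) -> None:
        from precistim.dcm_inversion import vector_from_params
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        model = _model_by_name(build_model_space(), self.config.generating_model)
        for subj in self.subjects:
            d = root / f"sub-{subj.index:02d}"
            d.mkdir(exist_ok=True)
            subj.schedule.to_events_tsv(d / "events.tsv")
            subj.trials.to_csv(d / "trials.csv", index=False)
            subj.bold.to_csv(d / "bold.csv")
            truth = {
                "seed": subj.seed,
                "generating_model": self.config.generating_model,
                "parameters": vector_from_params(model, subj.params).tolist(),
            }
            (d / "truth.json").write_text(json.dumps(truth, indent=1))
        meta = {"master_seed": self.config.master_seed,
                "n_subjects": self.config.n_subjects,
                **self.metadata}
        (root / "group.json").write_text(json.dumps(meta, indent=1))


def generate_schedule(n_trials: int, config: GroupConfig | None = None,
                      seed: int | None = None) -> EventSchedule:
    """Generate one session's trial stream.

    Same-different sessions balance truth (exactly half same — requiring an
    even ``n_trials``) crossed with the noise condition as evenly as
    possible; fast-slow sessions balance noise and the base/comparison
    order.  Per-stimulus jitter seeds are drawn for noisy stimuli, with the
    *same* seed for both stimuli of a same-noisy trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config if config is not None else GroupConfig()
    rng = np.random.default_rng(seed)
    ctx = config.context
    if ctx not in ("same_different", "fast_slow"):
        raise ValueError(f"unknown context {ctx!r}")
    if ctx == "same_different":
        if n_trials % 2:
            raise ValueError(
                "same-different sessions need an even n_trials for an exact "
                "50% same composition")
        half = n_trials // 2
        cells = ([("same", "regular")] * ((half + 1) // 2)
                 + [("same", "noisy")] * (half // 2)
                 + [("different", "regular")] * ((half + 1) // 2)
                 + [("different", "noisy")] * (half // 2))
    else:
        cells = [("different", "regular"), ("different", "noisy")] * \
            ((n_trials + 1) // 2)
        cells = cells[:n_trials]
    order = rng.permutation(len(cells))
    base, delta = config.base_frequency, config.delta_hz
    rows = []
    onset = config.lead_in_s
    for k in order:
        truth, cond = cells[k]
        if truth == "same":
            f1 = f2 = base
        else:
            # pseudorandom base/comparison order
            if rng.random() < 0.5:
                f1, f2 = base, base + delta
            else:
                f1, f2 = base + delta, base
        if cond == "noisy":
            s1 = int(rng.integers(2**31))
            s2 = s1 if truth == "same" else int(rng.integers(2**31))
        else:
            s1 = s2 = -1
        rows.append({
            "onset": onset, "context": ctx, "condition": cond,
            "truth": (truth if ctx == "same_different"
                      else ("faster" if f2 > f1 else "slower")),
            "f1": f1, "f2": f2,
            "noise_fraction": config.noise_fraction if cond == "noisy" else 0.0,
            "jitter_seed_f1": s1, "jitter_seed_f2": s2,
            "response_window_s": RESPONSE_WINDOW_S,
        })
        onset += TRIAL_SPAN_S + rng.uniform(*ITI_RANGE_S)
    return EventSchedule(trials=pd.DataFrame(rows), context=ctx)


def build_dcm_inputs(schedule: EventSchedule, dt: float = 0.01,
                     duration: float | None = None) -> InputSet:
    """Boxcar input streams on the dt grid.

    ``u_stim`` covers both 512 ms stimulus epochs of every trial;
    ``u_regular`` and ``u_different`` are trial-spanning boxcars (first
    stimulus onset to second stimulus offset) on regular-condition and
    different-truth trials respectively.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 s to resolve the stimulus epochs")
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    if duration is None:
        duration = schedule.end_time + 16.0
    T = int(np.ceil(duration / dt))
    u_stim = np.zeros(T)
    u_reg = np.zeros(T)
    u_diff = np.zeros(T)

    def mark(u, t0, t1):
        i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
        u[max(i0, 0):min(i1, T)] = 1.0

    for t in schedule.trials.itertuples(index=False):
        mark(u_stim, t.onset, t.onset + STIM_DURATION_S)
        mark(u_stim, t.onset + F2_ONSET_S, t.onset + F2_ONSET_S + STIM_DURATION_S)
        if t.condition == "regular":
            mark(u_reg, t.onset, t.onset + TRIAL_SPAN_S)
        if t.truth in ("different", "faster", "slower") and t.f1 != t.f2:
            mark(u_diff, t.onset, t.onset + TRIAL_SPAN_S)
    return InputSet(dt=dt, u_stim=u_stim, u_regular=u_reg, u_different=u_diff)


def _model_by_name(space: list[DCMModel], name: str) -> DCMModel:
    for m in space:
        if m.name == name:
            return m
    raise ValueError(f"model {name!r} not in the model space")


def _perturb_params(params: DCMParams, sd: float,
                    rng: np.random.Generator) -> DCMParams:
    """Add Gaussian between-subject deviations to nonzero A/B/C/D means."""
    def jitter(arr):
        out = np.array(arr, dtype=float)
        nz = out != 0
        out[nz] += rng.normal(0.0, sd, size=int(nz.sum()))
        return out
    return DCMParams(
        A=jitter(params.A),
        B={k: jitter(v) for k, v in params.B.items()},
        C=jitter(params.C),
        D={k: jitter(v) for k, v in params.D.items()},
        theta_self=params.theta_self.copy(),
    )


def generate_group(config: GroupConfig,
                   model_space: list[DCMModel] | None = None) -> GroupDataset:
    """Generate a complete group dataset with known ground truth.

    Subject-level DCM parameters are the group means plus Gaussian
    deviations (``between_subject_sd``) on every nonzero A/B/C/D entry,
    resampled if unstable.  Observation noise is Gaussian with SD equal to
    the across-region mean temporal SD of the noise-free BOLD divided by
    ``snr``.  Behavioral trial tables come from the precision-weighted
    observer on the same schedules.  Everything descends from
    ``config.master_seed`` through a numpy SeedSequence tree.
    """
    space = model_space if model_space is not None else build_model_space()
    model = _model_by_name(space, config.generating_model)
    means = default_generating_params(model)
    hemo = HemoParams()
    ss = np.random.SeedSequence(config.master_seed)
    subject_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                     ss.spawn(config.n_subjects)]
    # trials that fit the session: mean spacing = trial span + mean ITI
    mean_spacing = TRIAL_SPAN_S + np.mean(ITI_RANGE_S)
    budget = config.session_length_s - config.lead_in_s - config.tail_s
    n_trials = max(int(budget // mean_spacing) // 2 * 2, 4)
    subjects = []
    resampled = 0
    for si, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        for _ in range(50):
            params = _perturb_params(means, config.between_subject_sd, rng)
            if stability_check(params, model)["stable"]:
                break
            resampled += 1
        else:
            raise RuntimeError("could not sample stable subject parameters")
        sched = generate_schedule(n_trials, config, seed=int(rng.integers(2**31)))
        inputs = build_dcm_inputs(
            sched, dt=config.dt,
            duration=max(config.session_length_s, sched.end_time + config.tail_s))
        clean = simulate_bold(model, params, hemo, inputs, tr=config.tr,
                              noise_sd=0.0)
        signal_sd = float(clean.data.std(axis=1).mean())
        noise_sd = signal_sd / config.snr
        noisy = BOLDSeries(
            data=clean.data + np.random.default_rng(
                int(rng.integers(2**31))).normal(0.0, noise_sd,
                                                 size=clean.data.shape),
            tr=config.tr, nodes=model.nodes,
            provenance={**clean.provenance, "noise_sd": noise_sd,
                        "subject": si})
        trials = simulate_session(sched, ObserverParams(),
                                  seed=int(rng.integers(2**31)))
        subjects.append(SubjectData(index=si, seed=sseed, schedule=sched,
                                    trials=trials, inputs=inputs, bold=noisy,
                                    params=params))
    return GroupDataset(config=config, subjects=subjects, group_means=means,
                        metadata={"resampled": resampled,
                                  "n_trials": n_trials})


def double_gamma_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function on a dt grid.

    h(t) = g(t; 6, 1) - g(t; 16, 1) / 6 with unit-scale gamma densities; the
    kernel integrates to 5/6 over its full support (the undershoot removes
    one sixth of the positive lobe).  Used for decision-locked evoked-
    response regressors (e.g. a 200 ms boxcar before the button press).
    """
    t = np.arange(0.0, duration, dt)
    return gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0


def convolve_hrf(u: np.ndarray, dt: float) -> np.ndarray:
    """Convolve a stimulus/decision stream with the canonical HRF."""
    h = double_gamma_hrf(dt)
    return np.convolve(u, h)[:len(u)] * dt
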