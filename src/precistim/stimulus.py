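"""Synthesis of regular and temporally jittered vibrotactile flutter stimuli.

A flutter stimulus is a unit-amplitude sinusoid in the 10-50 Hz range.
"Noisy" stimuli are built cycle by cycle: the period (wavelength) of each
cycle is the base period plus an independent zero-mean Gaussian deviate whose
standard deviation is ``noise_fraction`` times the base period.  Each cycle is
a complete sine period (zero phase at both ends), so the waveform is
continuous at cycle boundaries; the final partial cycle is truncated at the
requested duration.

Because jitter is applied to the period, the mean *period* is preserved while
the mean instantaneous *frequency* slightly exceeds the nominal frequency
(Jensen's inequality).  This is deliberate and is not corrected.
"""

from __future__ import annotations

import csv
import io
import wave
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSpec",
    "Waveform",
    "CycleStats",
    "synthesize_regular",
    "synthesize_noisy",
    "cycle_stats",
]


class InvalidSpecError(ValueError):
    """Raised for a stimulus specification violating its invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one flutter stimulus.

    Parameters
    ----------
    frequency : float
        Flutter frequency in Hz (nominally 10-50).
    duration : float
        Stimulus duration in ms (default 512).
    noise_fraction : float
        Ratio of the per-cycle period SD to the base period (0 for regular
        stimuli, 0.08 for the standard noisy condition).
    sample_rate : float
        Samples per second (default 8000).
    seed : int or None
        RNG seed for the jitter sequence; None draws fresh entropy.
    """

    frequency: float
    duration: float = 512.0
    noise_fraction: float = 0.0
    sample_rate: float = 8000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.frequency > 0):
            raise InvalidSpecError(f"frequency must be > 0, got {self.frequency}")
        if not (self.duration > 0):
            raise InvalidSpecError(f"duration must be > 0, got {self.duration}")
        if self.noise_fraction < 0:
            raise InvalidSpecError(
                f"noise_fraction must be >= 0, got {self.noise_fraction}"
            )
        if self.sample_rate < 20 * self.frequency:
            raise InvalidSpecError(
                f"sample_rate {self.sample_rate} < 20 x frequency {self.frequency}"
            )

    @property
    def base_period_ms(self) -> float:
        return 1000.0 / self.frequency

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sample_rate / 1000.0)


@dataclass
class Waveform:
    """A sampled stimulus together with its generating per-cycle periods.

    ``cycle_periods`` holds the generated full-cycle periods in ms; the
    truncated final partial cycle (if any) is excluded.
    """

    samples: np.ndarray
    sample_rate: float
    cycle_periods: list[float] = field(default_factory=list)

    def export_wav(self, path: str) -> None:
        """Write as a mono 16-bit PCM WAV file."""
        pcm = np.clip(self.samples, -1.0, 1.0)
        pcm = (pcm * 32767.0).astype("<i2")
        with wave.open(path, "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(2)
            fh.setframerate(int(round(self.sample_rate)))
            fh.writeframes(pcm.tobytes())

    def export_csv(self, path_or_buf) -> None:
        """Write (time_s, amplitude) rows as CSV."""
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            writer = csv.writer(fh)
            writer.writerow(["time_s", "amplitude"])
            t = np.arange(len(self.samples)) / self.sample_rate
            for ti, ai in zip(t, self.samples):
                writer.writerow([f"{ti:.6f}", f"{ai:.6f}"])
        finally:
            if own:
                fh.close()

    def export_periods_csv(self, path_or_buf) -> None:
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            writer = csv.writer(fh)
            writer.writerow(["cycle", "period_ms"])
            for k, p in enumerate(self.cycle_periods):
                writer.writerow([k, f"{p:.6f}"])
        finally:
            if own:
                fh.close()


@dataclass(frozen=True)
class CycleStats:
    """Summary statistics of a waveform's generated cycle periods."""

    mean_period: float  # ms
    sd_period: float  # ms, population (divide-by-N) convention
    n_cycles: int
    sd_ratio: float  # sd_period / base period


def _render_cycles(periods_ms: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Render a concatenation of full sine cycles, truncated at duration.

    Sample i at time t_i falls inside some cycle k; its phase is
    2*pi*(t_i - start_k)/T_k so every cycle is a complete sine period.
    """
    n = spec.n_samples
    t_ms = np.arange(n) * (1000.0 / spec.sample_rate)
    starts = np.concatenate([[0.0], np.cumsum(periods_ms)])
    idx = np.searchsorted(starts, t_ms, side="right") - 1
    idx = np.clip(idx, 0, len(periods_ms) - 1)
    phase = (t_ms - starts[idx]) / periods_ms[idx]
    return np.sin(2.0 * np.pi * phase)


def _draw_periods(spec: StimulusSpec, min_total_ms: float) -> np.ndarray:
    """Draw jittered periods until their cumulative length covers min_total_ms.

    Non-positive draws are rejected and redrawn: at 8% jitter this is a
    ~12.5-sigma event, but the generator must be total for any fraction.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base_period_ms
    sd = spec.noise_fraction * base
    periods: list[float] = []
    total = 0.0
    while total < min_total_ms:
        chunk = base + rng.normal(0.0, sd, size=max(16, int(min_total_ms / base)))
        for p in chunk:
            if p <= 0.0:
                continue  # reject; the redraw is simply the next valid deviate
            periods.append(p)
            total += p
            if total >= min_total_ms:
                break
    return np.asarray(periods)


def synthesize_regular(spec: StimulusSpec) -> Waveform:
    """Synthesize a noise-free (regular) sinusoidal stimulus.

    All stored cycle periods equal the base period 1000/frequency ms.
    """
    if spec.noise_fraction != 0:
        raise InvalidSpecError(
            "synthesize_regular requires noise_fraction == 0; "
            "use synthesize_noisy for jittered stimuli"
        )
    base = spec.base_period_ms
    n_full = int(spec.duration // base)
    periods = np.full(max(n_full, 1), base)
    # render with enough cycles to cover the truncated tail too
    n_cover = int(np.ceil(spec.duration / base)) + 1
    samples = _render_cycles(np.full(n_cover, base), spec)
    return Waveform(samples=samples, sample_rate=spec.sample_rate,
                    cycle_periods=[base] * n_full if n_full else [base])


def synthesize_noisy(spec: StimulusSpec) -> Waveform:
    """Synthesize a temporally jittered ("noisy") stimulus.

    Cycle k has period T_k = T_base + eps_k with eps_k ~ N(0, noise_fraction
    * T_base), drawn independently per cycle.  The stored ``cycle_periods``
    are the generated T_k whose full extent fits within the duration; the
    waveform's final partial cycle is truncated at exactly ``duration``.

    With ``noise_fraction == 0`` the output is sample-identical to
    :func:`synthesize_regular`.
    """
    if spec.noise_fraction == 0:
        reg_spec = StimulusSpec(spec.frequency, spec.duration, 0.0,
                                spec.sample_rate, spec.seed)
        return synthesize_regular(reg_spec)
    periods = _draw_periods(spec, spec.duration + spec.base_period_ms)
    samples = _render_cycles(periods, spec)
    ends = np.cumsum(periods)
    full = periods[ends <= spec.duration]
    stored = list(full) if len(full) else [float(periods[0])]
    return Waveform(samples=samples, sample_rate=spec.sample_rate,
                    cycle_periods=stored)


def cycle_stats(w: Waveform, base_frequency: float) -> CycleStats:
    """Mean/SD/count of a waveform's stored generated periods.

    Statistics come from the stored period list (the generating ground
    truth), never re-estimated from samples.  SD uses the population
    (divide-by-N) convention.
    """
    if not w.cycle_periods:
        raise ValueError("waveform has an empty cycle_periods list")
    p = np.asarray(w.cycle_periods, dtype=float)
    mean = float(p.mean())
    sd = float(p.std(ddof=0))
    base = 1000.0 / base_frequency
    return CycleStats(mean_period=mean, sd_period=sd, n_cycles=len(p),
                      sd_ratio=sd / base)
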