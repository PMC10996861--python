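"""Synthetic sustained vowels and synthetic CPP cohorts.

The study population (children's sustained /a/ recordings with a genetic
diagnosis) is private, so every downstream module is exercised on synthetic
data generated here, along two decoupled paths:

* ``synth_vowel`` builds a sustained-vowel waveform with controllable
  harmonicity — a harmonic series with 1/h amplitude roll-off, per-cycle
  frequency jitter and amplitude shimmer, plus white noise scaled to a
  requested harmonics-to-noise ratio (HNR). Feeding these through the CPP
  extractor gives signal-level fixtures.
* ``synth_cohort`` samples per-speaker CPP value streams directly from
  per-cell Gaussian distributions, mirroring the reference cohort layout:
  24 speakers, 12 affected (label ``SMS``) and 12 controls (``N``), balanced
  3-speaker cells over sex x age group, with affected cells shifted to lower
  CPP and extra overlap in the young-female cell.

What the direct path does NOT emulate: temporal autocorrelation of CPP
within a recording, session effects, and any audio-level artifacts; a green
table-level test therefore establishes protocol correctness, not acoustic
realism.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cpp import REFERENCE_RATE, AudioSignal, CepstralConfig, extract_cpp
from .dataset import AGE_GROUPS, SEXES, Cohort, SpeakerRecord
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VowelSpec:
    """Parameters of one synthetic sustained vowel.

    ``hnr_db = inf`` means noiseless; jitter/shimmer are per-cycle relative
    perturbations in percent. The default f0 of 200 Hz sits in the typical
    child range; the quefrency band implied by the 22-400 sample defaults at
    16 kHz admits f0 of roughly 40-727 Hz.
    """

    f0: float = 200.0
    duration: float = 1.0
    n_harmonics: int = 12
    hnr_db: float = np.inf
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    rate: float = float(REFERENCE_RATE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.duration <= 0 or self.n_harmonics < 1:
            raise ValidationError("f0, duration and n_harmonics must be positive")
        band = CepstralConfig()
        f_lo, f_hi = self.rate / band.tmax, self.rate / band.tmin
        if not (f_lo <= self.f0 <= f_hi):
            warnings.warn(
                f"f0={self.f0} Hz is outside the default quefrency band "
                f"({f_lo:.0f}-{f_hi:.0f} Hz at {self.rate:.0f} Hz): the cepstral "
                "peak will fall outside [tmin, tmax]",
                stacklevel=2,
            )
        if self.duration < 0.5:
            warnings.warn(
                f"duration {self.duration} s is below the 500 ms phonation minimum",
                stacklevel=2,
            )


def synth_vowel(spec: VowelSpec) -> AudioSignal:
    """Render a sustained vowel; reproducible under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))

    # per-cycle instantaneous f0 and amplitude, expanded to per-sample arrays
    inst_f0 = np.empty(n)
    amp = np.empty(n)
    pos = 0
    while pos < n:
        f0_c = spec.f0 * (1.0 + spec.jitter_pct / 100.0 * rng.standard_normal())
        f0_c = max(f0_c, 1.0)
        a_c = max(0.0, 1.0 + spec.shimmer_pct / 100.0 * rng.standard_normal())
        cycle_len = max(1, int(round(spec.rate / f0_c)))
        end = min(pos + cycle_len, n)
        inst_f0[pos:end] = f0_c
        amp[pos:end] = a_c
        pos = end

    phase = 2.0 * np.pi * np.cumsum(inst_f0) / spec.rate
    x = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        x += np.sin(h * phase) / h
    x *= amp

    if np.isfinite(spec.hnr_db):
        signal_power = np.mean(x**2)
        noise_power = signal_power / 10.0 ** (spec.hnr_db / 10.0)
        x = x + rng.standard_normal(n) * np.sqrt(noise_power)

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return AudioSignal(samples=x, rate=spec.rate)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

Cell = tuple[str, str, str]  # (label, sex, age_group)


def default_cell_means() -> dict[Cell, float]:
    """Per-cell CPP means: controls near 0.050, affected near 0.030, with the
    young-female affected cell raised to emulate the greater overlap there."""
    means: dict[Cell, float] = {}
    for sex in SEXES:
        for group in AGE_GROUPS:
            means[("N", sex, group)] = 0.050
            means[("SMS", sex, group)] = 0.030
    means[("SMS", "female", "young")] = 0.036
    return means


@dataclass(frozen=True)
class CohortSpec:
    """Layout and distribution parameters of a synthetic CPP cohort.

    ``within_sd`` is the sd of CPP values within one speaker, ``speaker_sd``
    the sd of per-speaker mean offsets (a speaker random effect); counts per
    speaker are drawn uniformly from ``samples_per_speaker`` (inclusive).
    """

    cell_means: dict[Cell, float] = field(default_factory=default_cell_means)
    within_sd: float = 0.004
    speaker_sd: float = 0.002
    speakers_per_cell: int = 3
    samples_per_speaker: tuple[int, int] = (40, 110)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_sd <= 0 or self.speaker_sd < 0:
            raise ValidationError("standard deviations must be positive")
        if self.speakers_per_cell < 1:
            raise ValidationError("speakers_per_cell must be >= 1")
        lo, hi = self.samples_per_speaker
        if not (3 <= lo <= hi):
            raise ValidationError("samples_per_speaker must satisfy 3 <= lo <= hi")
        for sex in SEXES:
            for group in AGE_GROUPS:
                sms = self.cell_means.get(("SMS", sex, group))
                ctrl = self.cell_means.get(("N", sex, group))
                if sms is None or ctrl is None:
                    raise ValidationError(f"missing cell mean for ({sex}, {group})")
                if not sms < ctrl:
                    raise ValidationError(
                        f"affected cell mean must be below the control mean "
                        f"for ({sex}, {group}): {sms} vs {ctrl}"
                    )


_AGE_RANGES = {"young": (5, 7), "older": (8, 12)}


def synth_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Sample a cohort; the default layout is 24 speakers, 12 per class,
    3 per (label, sex, age-group) cell."""
    rng = np.random.default_rng(spec.seed)
    records = []
    counters = {"SMS": 0, "N": 0}
    lo, hi = spec.samples_per_speaker
    for label in ("N", "SMS"):
        for group in AGE_GROUPS:
            for sex in SEXES:
                mean = spec.cell_means[(label, sex, group)]
                for _ in range(spec.speakers_per_cell):
                    counters[label] += 1
                    speaker_mean = mean + spec.speaker_sd * rng.standard_normal()
                    count = int(rng.integers(lo, hi + 1))
                    values = speaker_mean + spec.within_sd * rng.standard_normal(count)
                    a_lo, a_hi = _AGE_RANGES[group]
                    records.append(
                        SpeakerRecord(
                            speaker_id=f"{label}{counters[label]}",
                            sex=sex,
                            age=float(rng.integers(a_lo, a_hi + 1)),
                            age_group=group,
                            label=label,
                            cpp_values=values,
                        )
                    )
    return Cohort(records)


def mini_cohort() -> Cohort:
    """Canned 3-speaker cohort with per-speaker counts [14, 21, 24] — the
    worked windowing example (the 24-value speaker is ``SMS3``)."""
    rng = np.random.default_rng(12345)
    specs = [("SP1", "N", 14), ("SP2", "N", 21), ("SMS3", "SMS", 24)]
    records = []
    for speaker_id, label, count in specs:
        mean = 0.05 if label == "N" else 0.03
        records.append(
            SpeakerRecord(
                speaker_id=speaker_id,
                sex="male",
                age=6.0,
                age_group="young",
                label=label,
                cpp_values=mean + 0.004 * rng.standard_normal(count),
            )
        )
    return Cohort(records)


def cohort_from_audio(
    speakers_per_class: int = 2,
    duration: float = 1.0,
    seed: int = 0,
) -> Cohort:
    """End-to-end fixture path: synthesize vowels (clean for controls, noisy
    and jittery for affected speakers) and pool their extracted CPP values."""
    rng = np.random.default_rng(seed)
    records = []
    for label, hnr, jitter in (("N", 25.0, 0.3), ("SMS", 5.0, 2.0)):
        for i in range(speakers_per_class):
            f0 = float(rng.uniform(180, 280))
            vowel = synth_vowel(
                VowelSpec(
                    f0=f0,
                    duration=duration,
                    hnr_db=hnr,
                    jitter_pct=jitter,
                    shimmer_pct=jitter,
                    seed=int(rng.integers(2**31)),
                )
            )
            series = extract_cpp(vowel)
            records.append(
                SpeakerRecord(
                    speaker_id=f"{label}{i + 1}",
                    sex="female" if i % 2 else "male",
                    age=6.0,
                    age_group="young",
                    label=label,
                    cpp_values=series.smoothed,
                )
            )
    return Cohort(records)
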