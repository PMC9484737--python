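"""Synthetic EEG, expert annotations, and simulated rater streams.

The generator provides ground-truthed inputs for every stage of the
pipeline: (a) background EEG with superimposed rhythmic seizure discharges
visible on a subset of channels, (b) several imperfect per-second expert
annotations derived from the true events, and (c) simulated detector
probability streams with known per-rater sensitivity/specificity for
validating label-aggregation schemes.

The background is per-channel colored (1/f-like) Gaussian noise scaled to a
plausible ±100 µV range so the 16-bit rescaling step is exercised.  Seizure
events add a 1-4 Hz rhythmic discharge with harmonics and an on/off
amplitude ramp on a random channel subset.  This emulates the gross
time-frequency structure a detector keys on, not physiologically realistic
neonatal EEG morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .annotations import AnnotationSet, EventList, events_to_mask
from .preprocess import Recording

__all__ = [
    "SynthConfig",
    "RaterSimConfig",
    "generate_recording",
    "generate_expert_annotations",
    "simulate_raters",
    "generate_patient",
]

MIN_EVENT_GAP_S = 10.0  # forbids ambiguity when predicted events are merged


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the public training corpus: roughly hour-long
    recordings at 256 Hz acquisition rate, three annotating experts, and a
    moderate seizure burden with events tens of seconds long.
    """

    n_patients: int = 10
    duration_s: float = 3600.0
    n_channels: int = 18
    sample_rate_hz: float = 256.0
    seizure_rate_per_hour: float = 6.0
    seizure_duration_s: tuple[float, float] = (20.0, 120.0)
    seizure_channel_fraction: float = 0.5
    n_experts: int = 3
    expert_boundary_jitter_s: float = 2.0
    expert_miss_prob: float = 0.1
    background_rms_uv: float = 30.0
    seizure_amp_uv: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_channels < 1 or self.n_experts < 1:
            raise ValueError("counts must be >= 1")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and rates must be positive")
        lo, hi = self.seizure_duration_s
        if not (0 < lo <= hi):
            raise ValueError("seizure_duration_s must satisfy 0 < min <= max")
        for p in (self.seizure_channel_fraction, self.expert_miss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.seizure_rate_per_hour > 0 and self.duration_s < lo:
            raise ValueError(
                "recording too short to host one event of minimum length"
            )


@dataclass
class RaterSimConfig:
    """Ground truth for simulated detector/rater streams."""

    n_items: int = 1000
    n_raters: int = 3
    prevalence: float = 0.3
    sensitivities: tuple[float, ...] = (0.9, 0.8, 0.7)
    specificities: tuple[float, ...] = (0.95, 0.85, 0.75)
    prob_noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sensitivities) != self.n_raters or len(
            self.specificities
        ) != self.n_raters:
            raise ValueError("sensitivities/specificities must have length n_raters")
        for p in (self.prevalence, *self.sensitivities, *self.specificities):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _patient_rng(cfg: SynthConfig, patient_index: int, stream: int = 0) -> np.random.Generator:
    # Seed derivation keyed by (seed, patient, stream) so per-patient
    # generation is independent of call order.
    ss = np.random.SeedSequence([int(cfg.rng_seed), int(patient_index), int(stream)])
    return np.random.default_rng(ss)


def _colored_background(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    rms_uv: float,
    cutoff_hz: float = 8.0,
) -> np.ndarray:
    """Band-limited 1/f-like noise, independently per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    # first-order lowpass gives the spectral tilt of scalp EEG
    b, a = sps.butter(1, cutoff_hz, fs=fs)
    colored = sps.lfilter(b, a, white, axis=1)
    std = colored.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return colored / std * rms_uv


def _draw_events(rng: np.random.Generator, cfg: SynthConfig) -> EventList:
    """Poisson-like event count with non-overlapping placement.

    Placement uses rejection sampling with a minimum 10 s gap between
    events; if the recording cannot host the drawn number of events the
    count is truncated to what fits.
    """
    lo, hi = cfg.seizure_duration_s
    if cfg.seizure_rate_per_hour <= 0:
        return EventList(events=[], source="truth")
    lam = cfg.seizure_rate_per_hour * cfg.duration_s / 3600.0
    n_target = int(rng.poisson(lam))
    events: list[tuple[float, float]] = []
    attempts = 0
    while len(events) < n_target and attempts < 1000 * max(n_target, 1):
        attempts += 1
        dur = float(rng.uniform(lo, hi))
        start = float(rng.uniform(0.0, max(cfg.duration_s - dur, 0.0)))
        end = start + dur
        if end > cfg.duration_s:
            continue
        ok = all(
            end + MIN_EVENT_GAP_S <= a or b + MIN_EVENT_GAP_S <= start
            for a, b in events
        )
        if ok:
            events.append((start, end))
    return EventList(events=sorted(events), source="truth")


def generate_recording(
    cfg: SynthConfig, patient_index: int
) -> tuple[Recording, EventList]:
    """Synthesize one patient's recording plus its exact ground-truth events.

    Each seizure adds a rhythmic 1-4 Hz discharge with two harmonics and a
    raised-cosine amplitude ramp on ``ceil(fraction × n_channels)`` randomly
    chosen channels.  The discharge fundamental and the background spectral
    tilt are drawn once per patient (events then jitter around the patient
    value), emulating the cohort-to-cohort variability that makes detectors
    trained on a few patients generalize differently to unseen ones.
    Identical seed and patient index give bit-identical output.
    """
    if patient_index >= cfg.n_patients:
        raise ValueError("patient_index out of range")
    rng = _patient_rng(cfg, patient_index)
    fs = cfg.sample_rate_hz
    n_samples = int(round(cfg.duration_s * fs))
    patient_f0 = float(rng.uniform(1.0, 4.0))
    patient_cutoff = float(rng.uniform(5.0, 12.0))
    sig = _colored_background(
        rng, cfg.n_channels, n_samples, fs, cfg.background_rms_uv,
        cutoff_hz=patient_cutoff,
    )
    events = _draw_events(rng, cfg)
    n_active = int(np.ceil(cfg.seizure_channel_fraction * cfg.n_channels))
    t = np.arange(n_samples) / fs
    for start, end in events:
        chans = rng.choice(cfg.n_channels, size=n_active, replace=False)
        f0 = float(np.clip(patient_f0 + rng.uniform(-0.3, 0.3), 1.0, 4.0))
        i0, i1 = int(start * fs), int(end * fs)
        tt = t[i0:i1] - start
        dur = end - start
        ramp_len = min(2.0, dur / 4.0)
        env = np.ones_like(tt)
        rise = tt < ramp_len
        fall = tt > dur - ramp_len
        env[rise] = 0.5 * (1 - np.cos(np.pi * tt[rise] / ramp_len))
        env[fall] = 0.5 * (1 - np.cos(np.pi * (dur - tt[fall]) / ramp_len))
        phase = float(rng.uniform(0, 2 * np.pi))
        wave = (
            np.sin(2 * np.pi * f0 * tt + phase)
            + 0.5 * np.sin(2 * np.pi * 2 * f0 * tt + phase)
            + 0.25 * np.sin(2 * np.pi * 3 * f0 * tt + phase)
        )
        for c in chans:
            gain = cfg.seizure_amp_uv * float(rng.uniform(0.8, 1.2))
            sig[c, i0:i1] += gain * env * wave
    rec = Recording(
        patient_id=f"synth{patient_index:03d}",
        signals=sig,
        sample_rate_hz=fs,
        channel_names=[f"ch{i}" for i in range(cfg.n_channels)],
    )
    return rec, events


def generate_expert_annotations(
    true_events: EventList,
    cfg: SynthConfig,
    patient_index: int = 0,
    duration_s: float | None = None,
) -> AnnotationSet:
    """Imperfect per-second labels from each simulated expert.

    Each expert keeps a true event with probability ``1 − miss_prob``; kept
    events get independent Gaussian start/end jitter truncated to the
    recording.  Labels are emitted at 1 s resolution.
    """
    duration = cfg.duration_s if duration_s is None else duration_s
    n_seconds = int(np.floor(duration))
    rng = _patient_rng(cfg, patient_index, stream=1)
    labels = np.zeros((cfg.n_experts, n_seconds), dtype=np.uint8)
    for e in range(cfg.n_experts):
        kept: list[tuple[float, float]] = []
        for a, b in true_events:
            if rng.uniform() < cfg.expert_miss_prob:
                continue
            ja = a + rng.normal(0, cfg.expert_boundary_jitter_s)
            jb = b + rng.normal(0, cfg.expert_boundary_jitter_s)
            ja = float(np.clip(ja, 0, duration))
            jb = float(np.clip(jb, 0, duration))
            if jb > ja:
                kept.append((ja, jb))
        mask = np.zeros(n_seconds, dtype=np.uint8)
        for ja, jb in kept:  # direct rasterize; jittered events may overlap
            lo, hi = int(np.floor(ja)), min(n_seconds, int(np.ceil(jb)))
            mask[lo:hi] = 1
        labels[e] = mask
    return AnnotationSet(patient_id=f"synth{patient_index:03d}", labels=labels)


def generate_patient(
    cfg: SynthConfig, patient_index: int
) -> tuple[Recording, EventList, AnnotationSet]:
    """Recording, truth events and expert annotations for one patient."""
    rec, events = generate_recording(cfg, patient_index)
    ann = generate_expert_annotations(events, cfg, patient_index)
    return rec, events, ann


def simulate_raters(cfg: RaterSimConfig):
    """Simulated detector outputs with known confusion rates.

    True label ``z_i ~ Bernoulli(prevalence)``; rater ``j`` emits a hard
    label via its sensitivity/specificity and a probability near the hard
    label (Gaussian spread ``prob_noise_sd``, clipped to [0, 1] such that
    thresholding at 0.5 recovers the hard label whenever the spread is
    below 0.5).

    Returns
    -------
    pm : PredictionMatrix
    z : ndarray of true 0/1 labels
    """
    from .ensemble import PredictionMatrix

    rng = np.random.default_rng(cfg.rng_seed)
    z = (rng.uniform(size=cfg.n_items) < cfg.prevalence).astype(np.int8)
    sens = np.asarray(cfg.sensitivities)
    spec = np.asarray(cfg.specificities)
    u = rng.uniform(size=(cfg.n_items, cfg.n_raters))
    y = np.where(
        z[:, None] == 1,
        (u < sens[None, :]).astype(np.int8),
        (u < 1 - spec[None, :]).astype(np.int8),
    )
    noise = np.abs(rng.normal(0, cfg.prob_noise_sd, size=y.shape))
    noise = np.minimum(noise, 0.499)  # keep the 0.5 threshold faithful
    p = np.where(y == 1, 1.0 - noise, noise)
    pm = PredictionMatrix(
        p=p,
        segment_ids=np.arange(cfg.n_items),
        model_ids=[f"rater{j}" for j in range(cfg.n_raters)],
    )
    return pm, z
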