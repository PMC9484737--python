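"""Raw EEG to classifier-ready segments.

The pipeline mirrors standard neonatal seizure-detection preprocessing:
bipolar montage derivation, 6th-order Chebyshev type II band-pass
(0.5-16 Hz), downsampling to 32 Hz, 16-bit integer rescaling, and
segmentation into 16 s windows with 12 s overlap (4 s stride).  Segments
containing more than 1 s of exactly-zero voltage on any channel (detached
electrode, recording pause) are flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "MontageSpec",
    "SegmentSet",
    "MONTAGE_18CH",
    "MONTAGE_3CH",
    "derive_montage",
    "filter_and_resample",
    "rescale_int16",
    "segment",
    "flag_zero_voltage",
    "preprocess_recording",
    "TARGET_RATE_HZ",
    "WINDOW_S",
    "STRIDE_S",
]

TARGET_RATE_HZ = 32
WINDOW_S = 16
STRIDE_S = 4  # 16 s window with 12 s overlap
FULL_SCALE_UV = 500.0  # default ±full-scale for the 16-bit mapping


@dataclass
class Recording:
    """Multi-channel EEG signal.

    ``signals`` is ``(n_channels, n_samples)`` in µV (float) or raw int16
    units with the µV scale recorded in ``scale_uv``.
    """

    patient_id: str
    signals: np.ndarray
    sample_rate_hz: float
    channel_names: list[str]
    scale_uv: float | None = None  # µV per int16 unit, set after rescaling

    def __post_init__(self) -> None:
        sig = np.atleast_2d(np.asarray(self.signals))
        if sig.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match signal rows")
        self.signals = sig

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class MontageSpec:
    """Ordered bipolar derivations as (anode, cathode) electrode pairs."""

    pairs: list[tuple[str, str]]

    @property
    def channel_names(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


# The standard 18-channel neonatal double-banana montage.
MONTAGE_18CH = MontageSpec(
    pairs=[
        ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
        ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
        ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
        ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
        ("Fz", "Cz"), ("Cz", "Pz"),
    ]
)

# Reduced 3-channel montage used with 4-electrode long-term monitoring.
MONTAGE_3CH = MontageSpec(pairs=[("F3", "P3"), ("F4", "P4"), ("P3", "P4")])


class MissingElectrodeError(KeyError):
    """A montage references an electrode absent from the recording."""


def derive_montage(rec: Recording, montage: MontageSpec) -> Recording:
    """Derive bipolar channels: output k = anode_k − cathode_k, sample-wise."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    rows = []
    for anode, cathode in montage.pairs:
        for el in (anode, cathode):
            if el not in index:
                raise MissingElectrodeError(
                    f"electrode {el!r} not present in recording "
                    f"(channels: {rec.channel_names})"
                )
        rows.append(rec.signals[index[anode]] - rec.signals[index[cathode]])
    return replace(
        rec,
        signals=np.asarray(rows),
        channel_names=montage.channel_names,
    )


def filter_and_resample(
    rec: Recording,
    band_hz: tuple[float, float] = (0.5, 16.0),
    order: int = 6,
    stop_atten_db: float = 40.0,
    target_rate_hz: int = TARGET_RATE_HZ,
) -> Recording:
    """Band-pass filter and downsample to the target rate.

    A 6th-order Chebyshev type II band-pass is applied forward-backward
    (zero phase, so event timing is preserved for annotation alignment),
    then the signal is resampled with a polyphase filter.  The stop-band
    attenuation of the Chebyshev design is configurable; 40 dB default.
    """
    if rec.sample_rate_hz < target_rate_hz:
        raise ValueError(
            f"input rate {rec.sample_rate_hz} Hz below target {target_rate_hz} Hz"
        )
    sos = sps.cheby2(
        order // 2,
        stop_atten_db,
        band_hz,
        btype="bandpass",
        fs=rec.sample_rate_hz,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, rec.signals, axis=1)
    from fractions import Fraction

    frac = Fraction(target_rate_hz, 1) / Fraction(rec.sample_rate_hz).limit_denominator()
    out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    n_expected = int(np.floor(rec.n_samples * target_rate_hz / rec.sample_rate_hz))
    out = out[:, :n_expected]
    return replace(rec, signals=out, sample_rate_hz=float(target_rate_hz))


def rescale_int16(rec: Recording, full_scale_uv: float = FULL_SCALE_UV) -> Recording:
    """Linearly map ±full_scale_uv to ±32767 with clipping.

    The scale factor (µV per integer unit) is stored on the recording so the
    voltage can be recovered to within one quantization step.
    """
    if full_scale_uv <= 0:
        raise ValueError("full_scale_uv must be positive")
    if not np.isfinite(rec.signals).all():
        raise ValueError("signals contain non-finite samples")
    scaled = np.clip(rec.signals / full_scale_uv * 32767.0, -32768, 32767)
    return replace(
        rec,
        signals=np.round(scaled).astype(np.int16),
        scale_uv=full_scale_uv / 32767.0,
    )


@dataclass
class SegmentSet:
    """Overlapped fixed-length windows cut from one recording.

    ``data`` is ``(n_segments, n_channels, window_samples)`` int16; starts
    lie on the stride grid anchored at recording start.
    """

    patient_id: str
    start_s: np.ndarray
    data: np.ndarray
    valid: np.ndarray
    window_s: int = WINDOW_S
    stride_s: int = STRIDE_S
    sample_rate_hz: int = TARGET_RATE_HZ
    scale_uv: float | None = None

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.start_s) != len(self.data) or len(self.valid) != len(self.data):
            raise ValueError("start_s, data and valid must have equal length")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def window_samples(self) -> int:
        return self.window_s * self.sample_rate_hz


def segment(rec: Recording) -> SegmentSet:
    """Cut a 32 Hz recording into 16 s windows on a 4 s stride grid.

    Windows start at 0, 4, 8, ... s; the last start is ≤ duration − 16 s.
    Recordings shorter than one window yield an empty set.
    """
    if rec.sample_rate_hz != TARGET_RATE_HZ:
        raise ValueError(f"expected a {TARGET_RATE_HZ} Hz recording")
    win = WINDOW_S * TARGET_RATE_HZ
    hop = STRIDE_S * TARGET_RATE_HZ
    n = rec.n_samples
    if n < win:
        starts = np.array([], dtype=float)
        data = np.empty((0, rec.n_channels, win), dtype=rec.signals.dtype)
    else:
        n_seg = (n - win) // hop + 1
        starts = np.arange(n_seg) * STRIDE_S
        data = np.stack(
            [rec.signals[:, i * hop : i * hop + win] for i in range(n_seg)]
        )
    return SegmentSet(
        patient_id=rec.patient_id,
        start_s=starts,
        data=data,
        valid=np.ones(len(starts), dtype=bool),
        scale_uv=rec.scale_uv,
    )


def _max_zero_run(x: np.ndarray) -> int:
    """Longest run of exactly-zero samples along the last axis."""
    z = (x == 0)
    if not z.any():
        return 0
    best = 0
    for row in np.atleast_2d(z):
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        if len(starts):
            best = max(best, int((ends - starts).max()))
    return best


def flag_zero_voltage(seg_set: SegmentSet, max_zero_s: float = 1.0) -> SegmentSet:
    """Invalidate segments with a zero-voltage run longer than ``max_zero_s``.

    A segment is invalid iff any channel contains a contiguous run of
    exactly-zero samples strictly longer than the threshold (at 32 Hz,
    > 32 consecutive zeros for the 1 s default).  Invalid segments are
    excluded from training and evaluation downstream.
    """
    limit = int(round(max_zero_s * seg_set.sample_rate_hz))
    valid = seg_set.valid.copy()
    for i in range(len(seg_set)):
        if valid[i] and _max_zero_run(seg_set.data[i]) > limit:
            valid[i] = False
    return replace(seg_set, valid=valid)


def preprocess_recording(
    rec: Recording,
    montage: MontageSpec | None = None,
    full_scale_uv: float = FULL_SCALE_UV,
) -> SegmentSet:
    """Full chain: optional montage → filter/resample → int16 → segments → flags."""
    if montage is not None:
        rec = derive_montage(rec, montage)
    rec = filter_and_resample(rec)
    rec = rescale_int16(rec, full_scale_uv)
    return flag_zero_voltage(segment(rec))
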