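"""Expert seizure annotations, consensus, and event extraction.

Annotations are per-second binary labels (1 = seizure) from one or more
experts.  The *consensus* mask marks seconds where every expert agrees on
seizure; it is the intersection of the experts' positive sets.  Time is
measured in seconds from recording start and all intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationSet",
    "EventList",
    "consensus_mask",
    "mask_to_events",
    "events_to_mask",
    "label_segments",
    "has_long_consensus_seizure",
    "SEG_SEIZURE",
    "SEG_NONSEIZURE",
    "SEG_EXCLUDED",
]

# per-segment training/evaluation classes
SEG_SEIZURE = 1
SEG_NONSEIZURE = 0
SEG_EXCLUDED = -1


@dataclass
class EventList:
    """Sorted, non-overlapping seizure intervals in seconds.

    ``source`` records provenance: ``"truth"``, ``"expert<k>"``,
    ``"consensus"`` or ``"detector"``.
    """

    events: list[tuple[float, float]] = field(default_factory=list)
    source: str = "truth"

    def __post_init__(self) -> None:
        ev = sorted((float(a), float(b)) for a, b in self.events)
        for a, b in ev:
            if not b > a:
                raise ValueError(f"event ({a}, {b}) has non-positive duration")
        for (_, b0), (a1, _) in zip(ev, ev[1:]):
            if a1 < b0:
                raise ValueError("events overlap")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.events], dtype=float)

    def total_duration(self) -> float:
        return float(self.durations().sum()) if self.events else 0.0

    def to_frame(self, patient_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": patient_id,
                "source": self.source,
                "start_s": [a for a, _ in self.events],
                "end_s": [b for _, b in self.events],
            }
        )


@dataclass
class AnnotationSet:
    """Per-second 0/1 labels from each expert for one patient.

    ``labels`` has shape ``(n_experts, n_seconds)``.
    """

    patient_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D (n_experts, n_seconds)")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        self.labels = lab.astype(np.uint8)

    @property
    def n_experts(self) -> int:
        return self.labels.shape[0]

    @property
    def n_seconds(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (patient_id, expert_id, second_index, label)."""
        e, s = np.meshgrid(
            np.arange(self.n_experts), np.arange(self.n_seconds), indexing="ij"
        )
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "expert_id": e.ravel(),
                "second_index": s.ravel(),
                "label": self.labels.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, patient_id: str) -> "AnnotationSet":
        sub = df[df["patient_id"] == patient_id]
        experts = np.sort(sub["expert_id"].unique())
        n_seconds = int(sub["second_index"].max()) + 1
        lab = np.zeros((len(experts), n_seconds), dtype=np.uint8)
        for i, e in enumerate(experts):
            rows = sub[sub["expert_id"] == e]
            lab[i, rows["second_index"].to_numpy()] = rows["label"].to_numpy()
        return cls(patient_id=patient_id, labels=lab)


def consensus_mask(ann: AnnotationSet) -> np.ndarray:
    """Per-second mask that is 1 iff *every* expert labels the second seizure."""
    if ann.n_experts < 1:
        raise ValueError("need at least one expert")
    return ann.labels.min(axis=0).astype(np.uint8)


def mask_to_events(mask: np.ndarray, source: str = "consensus") -> EventList:
    """Turn maximal runs of 1s in a per-second mask into events."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 1:
        raise ValueError("mask must be 1-D")
    padded = np.concatenate(([False], m, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return EventList(
        events=[(float(a), float(b)) for a, b in zip(starts, ends)], source=source
    )


def events_to_mask(events: EventList, n_seconds: int) -> np.ndarray:
    """Rasterize events at 1 s resolution; second s is 1 iff [s, s+1) ⊆ covered.

    A second is marked seizure when the event covers any part of it after
    rounding: start is floored, end is ceiled to whole seconds, matching the
    convention that experts label the second containing seizure activity.
    """
    mask = np.zeros(n_seconds, dtype=np.uint8)
    for a, b in events:
        lo = max(0, int(np.floor(a)))
        hi = min(n_seconds, int(np.ceil(b)))
        if hi > lo:
            mask[lo:hi] = 1
    return mask


def label_segments(
    starts_s: np.ndarray,
    ann: AnnotationSet,
    window_s: int = 16,
) -> np.ndarray:
    """Assign each window a training/evaluation class.

    A window starting at ``t`` covers annotation seconds ``t .. t+window-1``.
    It is a consensus seizure iff all experts label every covered second 1,
    consensus non-seizure iff all experts label every covered second 0, and
    excluded otherwise (any disagreement or partial seizure).
    """
    starts = np.asarray(starts_s)
    out = np.full(len(starts), SEG_EXCLUDED, dtype=np.int8)
    for i, t in enumerate(starts):
        t0 = int(round(t))
        t1 = t0 + window_s
        if t1 > ann.n_seconds:
            raise ValueError(
                f"annotation ({ann.n_seconds} s) shorter than segment end ({t1} s)"
            )
        window = ann.labels[:, t0:t1]
        if (window == 1).all():
            out[i] = SEG_SEIZURE
        elif (window == 0).all():
            out[i] = SEG_NONSEIZURE
    return out


def has_long_consensus_seizure(ann: AnnotationSet, min_s: float = 16.0) -> bool:
    """True iff the consensus event list contains an event strictly longer
    than ``min_s`` seconds.  Used to select the training patient pool."""
    ev = mask_to_events(consensus_mask(ann))
    return bool(any((b - a) > min_s for a, b in ev))
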