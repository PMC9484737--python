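"""Segment-based, event-based, and agreement metrics.

Because 16 s segments are cut on a 4 s stride, each interior 4 s frame is
covered by four overlapping segments; the frame prediction is the mean of
the covering segments' probabilities.  Thresholded frames become seizure
events; events shorter than 10 s are discarded as noise (by definition a
seizure lasts at least 10 s).

Segment metrics (SE, SP, AUC) are computed per patient on segments with a
full-window expert consensus only.  Event metrics: a consensus seizure
counts as detected if any predicted event overlaps it (SDR); a predicted
event that overlaps no seizure marked by *any* expert is a false detection
(FD/h, MFDD).  Detector agreement is summarized with Gwet's first-order
agreement coefficient AC1, which is robust to class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import EventList
from .preprocess import STRIDE_S, WINDOW_S

__all__ = [
    "FramePrediction",
    "overlap_average",
    "frames_to_events",
    "segment_metrics",
    "event_metrics",
    "gwet_ac1",
    "summarize",
    "auc_score",
]


@dataclass
class FramePrediction:
    """Per-4 s-frame probabilities on the stride grid, with validity flags."""

    prob: np.ndarray
    valid: np.ndarray
    stride_s: int = STRIDE_S

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.prob.shape != self.valid.shape:
            raise ValueError("prob and valid must have the same shape")


def overlap_average(
    seg_probs: np.ndarray,
    starts_s: np.ndarray,
    duration_s: float,
    seg_valid: np.ndarray | None = None,
    window_s: int = WINDOW_S,
    stride_s: int = STRIDE_S,
) -> FramePrediction:
    """Average overlapping segment predictions onto the 4 s frame grid.

    A frame ``[k·stride, (k+1)·stride)`` is covered by every valid segment
    whose window contains it — four in the interior, fewer at the edges.
    Frames covered by no valid segment are marked invalid.
    """
    seg_probs = np.asarray(seg_probs, dtype=float)
    starts = np.asarray(starts_s, dtype=float)
    if seg_valid is None:
        seg_valid = np.ones(len(seg_probs), dtype=bool)
    n_frames = int(np.floor(duration_s / stride_s))
    acc = np.zeros(n_frames)
    cnt = np.zeros(n_frames, dtype=int)
    per_win = window_s // stride_s
    for p, t0, ok in zip(seg_probs, starts, seg_valid):
        if not ok:
            continue
        k0 = int(round(t0 / stride_s))
        k1 = min(k0 + per_win, n_frames)
        acc[k0:k1] += p
        cnt[k0:k1] += 1
    valid = cnt > 0
    prob = np.zeros(n_frames)
    prob[valid] = acc[valid] / cnt[valid]
    return FramePrediction(prob=prob, valid=valid, stride_s=stride_s)


def frames_to_events(
    fp: FramePrediction,
    thresh: float = 0.5,
    min_dur_s: float = 10.0,
) -> EventList:
    """Threshold frames, extract runs, and drop events shorter than 10 s.

    Invalid frames terminate runs.  The duration filter is strict: an event
    of exactly ``min_dur_s`` survives.
    """
    mask = (fp.prob >= thresh) & fp.valid
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    events = []
    for k0, k1 in zip(starts, ends):
        a, b = k0 * fp.stride_s, k1 * fp.stride_s
        if (b - a) >= min_dur_s:
            events.append((float(a), float(b)))
    return EventList(events=events, source="detector")


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic (ties half credit)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, scores))


def segment_metrics(
    mu: np.ndarray,
    labels: np.ndarray,
    thresh: float = 0.5,
) -> dict[str, float]:
    """SE, SP and AUC on consensus-labelled segments of one patient.

    ``labels`` uses the segment classes from :mod:`eegensemble.annotations`;
    excluded segments (value −1) are dropped.  With a single class present
    the AUC is undefined and reported as NaN (the patient is then left out
    of cross-patient summaries).
    """
    mu = np.asarray(mu, dtype=float)
    labels = np.asarray(labels)
    keep = labels >= 0
    mu, lab = mu[keep], labels[keep].astype(int)
    if len(lab) == 0:
        return {"se": np.nan, "sp": np.nan, "auc": np.nan}
    pred = (mu >= thresh).astype(int)
    tp = int(((pred == 1) & (lab == 1)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    se = tp / (tp + fn) if (tp + fn) else np.nan
    sp = tn / (tn + fp) if (tn + fp) else np.nan
    auc = auc_score(lab, mu) if len(np.unique(lab)) == 2 else np.nan
    return {"se": se, "sp": sp, "auc": auc}


def _overlap_len(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def event_metrics(
    pred: EventList,
    consensus: EventList,
    any_expert: EventList,
    duration_h: float,
) -> dict[str, float]:
    """SDR, FD/h and MFDD of a predicted event list.

    * SDR — fraction of consensus events overlapped by ≥ 1 predicted event
      (NaN when there are no consensus events).
    * false detection — a predicted event with zero overlap against the
      union of *all* experts' events (an event overlapping only a
      single-expert seizure is neither a detection nor a false detection).
    * FD/h — false detections per hour of recording.
    * MFDD — mean duration in seconds of the false detections (0 when none).
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if len(consensus) == 0:
        sdr = np.nan
    else:
        detected = sum(
            1
            for c0, c1 in consensus
            if any(_overlap_len(c0, c1, p0, p1) > 0 for p0, p1 in pred)
        )
        sdr = detected / len(consensus)
    false_durs = [
        p1 - p0
        for p0, p1 in pred
        if not any(_overlap_len(p0, p1, e0, e1) > 0 for e0, e1 in any_expert)
    ]
    fd_per_h = len(false_durs) / duration_h
    mfdd = float(np.mean(false_durs)) if false_durs else 0.0
    return {"sdr": sdr, "fd_per_h": fd_per_h, "mfdd": mfdd}


def gwet_ac1(labels: np.ndarray) -> float:
    """Gwet's first-order agreement coefficient for binary ratings.

    ``labels`` is N items × R raters of 0/1 values.  With ``n1_i`` positive
    ratings on item i:

        a_i = [n1_i(n1_i−1) + n0_i(n0_i−1)] / [R(R−1)]
        pa  = mean_i a_i
        π̂  = mean_i n1_i / R
        pe  = 2 π̂ (1−π̂)
        AC1 = (pa − pe) / (1 − pe)

    For binary data pe ≤ 0.5, so the denominator never vanishes.
    """
    y = np.asarray(labels)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need an N × R matrix with R >= 2 raters")
    n, r = y.shape
    n1 = y.sum(axis=1).astype(float)
    n0 = r - n1
    a = (n1 * (n1 - 1) + n0 * (n0 - 1)) / (r * (r - 1))
    pa = float(a.mean())
    pi_hat = float((n1 / r).mean())
    pe = 2 * pi_hat * (1 - pi_hat)
    return (pa - pe) / (1 - pe)


def summarize(per_patient: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Mean and median across patients, skipping undefined (NaN) values."""
    metrics: dict[str, list[float]] = {}
    for vals in per_patient.values():
        for k, v in vals.items():
            metrics.setdefault(k, []).append(v)
    out: dict[str, dict[str, float]] = {"mean": {}, "median": {}}
    for k, vs in metrics.items():
        arr = np.asarray(vs, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) == 0:
            out["mean"][k] = np.nan
            out["median"][k] = np.nan
        else:
            out["mean"][k] = float(arr.mean())
            out["median"][k] = float(np.median(arr))
    return out
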