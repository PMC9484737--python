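"""File exchange: array containers, annotation/event/prediction tables.

Recordings and segment sets travel in the package's own ``.npz`` container;
annotations, events and predictions travel as plain CSV so they can be
inspected and produced by other tools.  Model exchange with the trusted
agent is plain file exchange of saved models (see
:func:`eegensemble.detector.save_model`).  EDF reading is available through
:mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, EventList
from .ensemble import PredictionMatrix
from .preprocess import Recording, SegmentSet

__all__ = [
    "save_recording",
    "load_recording",
    "save_segments",
    "load_segments",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_events_csv",
    "read_events_csv",
    "write_predictions_csv",
    "read_predictions_csv",
    "read_edf",
]


def save_recording(rec: Recording, path) -> None:
    np.savez(
        path,
        signals=rec.signals,
        sample_rate_hz=rec.sample_rate_hz,
        channel_names=np.array(rec.channel_names),
        patient_id=np.array(rec.patient_id),
        scale_uv=np.array(np.nan if rec.scale_uv is None else rec.scale_uv),
    )


def load_recording(path) -> Recording:
    with np.load(path) as d:
        scale = float(d["scale_uv"])
        return Recording(
            patient_id=str(d["patient_id"]),
            signals=d["signals"],
            sample_rate_hz=float(d["sample_rate_hz"]),
            channel_names=[str(c) for c in d["channel_names"]],
            scale_uv=None if np.isnan(scale) else scale,
        )


def save_segments(seg: SegmentSet, path) -> None:
    np.savez(
        path,
        data=seg.data,
        start_s=seg.start_s,
        valid=seg.valid,
        patient_id=np.array(seg.patient_id),
        meta=np.array(
            json.dumps(
                {
                    "window_s": seg.window_s,
                    "stride_s": seg.stride_s,
                    "sample_rate_hz": seg.sample_rate_hz,
                    "scale_uv": seg.scale_uv,
                }
            )
        ),
    )


def load_segments(path) -> SegmentSet:
    with np.load(path) as d:
        meta = json.loads(str(d["meta"]))
        return SegmentSet(
            patient_id=str(d["patient_id"]),
            start_s=d["start_s"],
            data=d["data"],
            valid=d["valid"],
            **meta,
        )


def write_annotations_csv(ann: AnnotationSet, path) -> None:
    """Columns: patient_id, expert_id, second_index, label."""
    ann.to_frame().to_csv(path, index=False)


def read_annotations_csv(path, patient_id: str) -> AnnotationSet:
    return AnnotationSet.from_frame(pd.read_csv(path), patient_id)


def write_events_csv(events: EventList, path, patient_id: str = "") -> None:
    """Columns: patient_id, source, start_s, end_s."""
    events.to_frame(patient_id).to_csv(path, index=False)


def read_events_csv(path, source: str | None = None) -> EventList:
    df = pd.read_csv(path)
    if source is not None:
        df = df[df["source"] == source]
    src = df["source"].iloc[0] if len(df) else (source or "truth")
    return EventList(
        events=list(zip(df["start_s"], df["end_s"])), source=str(src)
    )


def write_predictions_csv(pm: PredictionMatrix, path) -> None:
    """Long format: segment_id, model_id, probability."""
    rows = []
    for j, mid in enumerate(pm.model_ids):
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": pm.segment_ids,
                    "model_id": mid,
                    "probability": pm.p[:, j],
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False)


def read_predictions_csv(path) -> PredictionMatrix:
    df = pd.read_csv(path)
    wide = df.pivot(index="segment_id", columns="model_id", values="probability")
    wide = wide.sort_index()
    return PredictionMatrix(
        p=wide.to_numpy(),
        segment_ids=wide.index.to_numpy(),
        model_ids=[str(c) for c in wide.columns],
    )


def read_edf(path, patient_id: str | None = None) -> Recording:
    """Load an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        patient_id=patient_id or Path(path).stem,
        signals=raw.get_data() * 1e6,  # volts → µV
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
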