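"""Generate a ground-truthed synthetic EEG patient and save the artifacts.

Creates one recording (background noise + rhythmic discharges on a channel
subset), the exact true seizure events, and three imperfect expert
annotations, then writes them to an npz container and CSV tables.
"""

from pathlib import Path

from eegensemble import SynthConfig, consensus_mask, generate_patient, mask_to_events
from eegensemble import io

cfg = SynthConfig(
    n_patients=1,
    duration_s=1200.0,
    n_channels=8,
    seizure_rate_per_hour=9.0,
    rng_seed=42,
)
rec, truth, ann = generate_patient(cfg, 0)

print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s @ {rec.sample_rate_hz:.0f} Hz")
print(f"true seizure events ({len(truth)}):")
for a, b in truth:
    print(f"  {a:7.1f} - {b:7.1f} s  ({b - a:5.1f} s)")

cons = mask_to_events(consensus_mask(ann))
print(f"experts: {ann.n_experts}; consensus events after miss/jitter: {len(cons)}")

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)
io.save_recording(rec, out / "recording.npz")
io.write_annotations_csv(ann, out / "annotations.csv")
io.write_events_csv(truth, out / "truth_events.csv", patient_id=rec.patient_id)
print(f"wrote {out}/recording.npz, annotations.csv, truth_events.csv")
# The consensus list is a subset of every expert's events: the intersection
# of all experts' per-second labels defines what counts as a seizure below.
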