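"""Experiment design: institutions, folds, repeats, and the full harness.

The study protocol: patients with a long consensus seizure form the pool;
the pool is randomly partitioned into ``k = 3..10`` disjoint institution
subsets (≥ 3 patients each), one local detector is trained per
institution, and their predictions on held-out patients are aggregated.
Evaluation uses leave-one-subject-out (LOSO) cross-validation, repeated
with re-randomized partitions.  One randomly chosen institution is held
out of the weighted-mean ensemble; its data trains the stacking weights,
so the weighted mean combines ``R − 1`` detectors while the other schemes
use all ``R``.

``count_jobs`` reproduces the design arithmetic in closed form; at full
scale (10 repeats, 38 LOSO folds, k = 3..10) the LOSO plan enumerates
19 760 local-detector trainings and 3 040 stacking fits, and the
external-test plan 521 detectors and 80 stacking fits.

``run_experiment`` executes a (typically scaled-down, synthetic) instance
of the protocol end to end, with optional job-level caching and a dry-run
mode that enumerates jobs without training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotations import (
    AnnotationSet,
    EventList,
    SEG_EXCLUDED,
    consensus_mask,
    label_segments,
    mask_to_events,
)
from .detector import (
    ArchitectureConfig,
    LocalModel,
    NsdaModel,
    SMALL_ARCHITECTURE,
    TrainConfig,
    balance_training_set,
    build_nsda,
    train_nsda,
)
from .ensemble import (
    PredictionMatrix,
    StackingWeights,
    dawid_skene,
    fit_stacking,
    majority_vote,
    mean_probability,
    weighted_mean,
)
from .evaluation import (
    event_metrics,
    frames_to_events,
    gwet_ac1,
    overlap_average,
    segment_metrics,
    summarize,
)
from .preprocess import SegmentSet

__all__ = [
    "ExperimentPlan",
    "JobCount",
    "PatientData",
    "partition_patients",
    "loso_folds",
    "select_stacking_institution",
    "count_jobs",
    "run_experiment",
]

MIN_INSTITUTION_SIZE = 3


@dataclass(frozen=True)
class ExperimentPlan:
    """The enumerable experiment design.

    With ``loso=True`` every fold leaves one pool patient out; otherwise a
    single external-test plan is enumerated (one fold, full pool for
    training, plus one baseline detector trained once).
    """

    pool: tuple[str, ...]
    k_values: tuple[int, ...] = tuple(range(3, 11))
    n_repeats: int = 10
    loso: bool = True
    seed: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.pool) if self.loso else 1

    def folds(self) -> list[tuple[str | None, tuple[str, ...]]]:
        """(left-out patient or None, training pool) per fold."""
        if self.loso:
            return [
                (p, tuple(q for q in self.pool if q != p)) for p in self.pool
            ]
        return [(None, self.pool)]

    def enumerate_jobs(self) -> list[dict]:
        """One entry per local-detector training job."""
        jobs = []
        for rep in range(self.n_repeats):
            for fold_i, (left_out, train_pool) in enumerate(self.folds()):
                for k in self.k_values:
                    seed = _job_seed(self.seed, rep, fold_i, k)
                    subsets = partition_patients(train_pool, k, seed)
                    for inst, patients in enumerate(subsets):
                        jobs.append(
                            {
                                "repeat": rep,
                                "fold": fold_i,
                                "left_out": left_out,
                                "k": k,
                                "institution": inst,
                                "patients": patients,
                            }
                        )
        return jobs

    def enumerate_stacking_fits(self) -> list[dict]:
        return [
            {"repeat": rep, "fold": f, "k": k}
            for rep in range(self.n_repeats)
            for f in range(self.n_folds)
            for k in self.k_values
        ]


@dataclass(frozen=True)
class JobCount:
    n_local_models: int
    n_stacking_fits: int
    n_baseline_models: int

    @property
    def n_models_total(self) -> int:
        return self.n_local_models + self.n_baseline_models


def _job_seed(master: int, *parts: int) -> int:
    """Derive a stable 31-bit seed for one job from the master seed."""
    h = hashlib.sha256(("/".join(map(str, (master, *parts)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def partition_patients(
    pool, k: int, seed: int | np.random.Generator
) -> list[tuple[str, ...]]:
    """Random partition of the pool into k disjoint subsets of size ≥ 3.

    The pool is shuffled, three patients are dealt to every subset, and the
    remainder is assigned uniformly at random — sizes are therefore unequal
    in general, which is the source of the local detectors' differing
    generalization strength.
    """
    pool = list(pool)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(pool) < MIN_INSTITUTION_SIZE * k:
        raise ValueError(
            f"pool of {len(pool)} cannot fill {k} subsets of "
            f">= {MIN_INSTITUTION_SIZE} patients"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = [pool[i] for i in rng.permutation(len(pool))]
    subsets: list[list[str]] = [[] for _ in range(k)]
    for i, p in enumerate(order[: MIN_INSTITUTION_SIZE * k]):
        subsets[i % k].append(p)
    for p in order[MIN_INSTITUTION_SIZE * k :]:
        subsets[int(rng.integers(k))].append(p)
    return [tuple(sorted(s)) for s in subsets]


def loso_folds(pool) -> list[tuple[str, tuple[str, ...]]]:
    """One fold per patient: (test patient, training pool without them)."""
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("need at least two patients for LOSO")
    return [(p, tuple(q for q in pool if q != p)) for p in pool]


def select_stacking_institution(
    n_institutions: int, seed: int | np.random.Generator
) -> tuple[int, list[int]]:
    """Pick the institution whose data trains the stacking weights.

    Its detector is excluded from the weighted-mean ensemble (which then
    has ``R − 1`` members); the other schemes keep all ``R`` detectors.
    """
    if n_institutions < 2:
        raise ValueError("weighted mean needs at least two institutions")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    held = int(rng.integers(n_institutions))
    return held, [j for j in range(n_institutions) if j != held]


def count_jobs(plan: ExperimentPlan) -> JobCount:
    """Closed-form job counts; equals the enumeration length by construction.

    LOSO: local models = repeats × folds × Σk, stacking fits =
    repeats × folds × |{k}|, one baseline per fold.  External test: local
    models = repeats × Σk, stacking fits = repeats × |{k}|, one baseline.
    """
    sum_k = sum(plan.k_values)
    n_k = len(plan.k_values)
    f = plan.n_folds
    return JobCount(
        n_local_models=plan.n_repeats * f * sum_k,
        n_stacking_fits=plan.n_repeats * f * n_k,
        n_baseline_models=f,
    )


# ---------------------------------------------------------------------------
# end-to-end harness
# ---------------------------------------------------------------------------


def benefit_study_config(rng_seed: int):
    """Study conditions for the scaled-down ensemble-benefit experiment.

    Eleven patients (nine training — three institutions of three — plus two
    held out for testing) of 45 min each, recorded on four channels at
    64 Hz with a seizure burden high enough that every institution holds a
    few hundred consensus seizure segments (~2 000 segments per
    institution in total).  The discharge amplitude is the generator
    default, twice the background RMS, giving a clearly separable task on
    which detector quality is limited by cohort coverage rather than by
    signal visibility.
    """
    from .synth import SynthConfig

    return SynthConfig(
        n_patients=11,
        duration_s=2700.0,
        n_channels=4,
        sample_rate_hz=64.0,
        seizure_rate_per_hour=20.0,
        seizure_duration_s=(20.0, 60.0),
        expert_miss_prob=0.05,
        expert_boundary_jitter_s=1.0,
        rng_seed=rng_seed,
    )


def run_benefit_experiment(master_seed: int, cache_dir=None) -> dict:
    """One repeat of the ensemble-benefit experiment at one master seed.

    Generates the synthetic corpus, trains k=3 local detectors on the
    nine-patient pool (reduced architecture, 10 epochs), and evaluates all
    four aggregation schemes on the two held-out patients.
    """
    cfg = benefit_study_config(master_seed)
    dataset = build_synthetic_dataset(cfg)
    pids = sorted(dataset)
    return run_experiment(
        dataset,
        k=3,
        test_patients=pids[-2:],
        seed=master_seed,
        cache_dir=cache_dir,
    )


def build_synthetic_dataset(cfg) -> dict[str, "PatientData"]:
    """Generate, preprocess and annotate every patient of a synthetic corpus."""
    from .preprocess import preprocess_recording
    from .synth import generate_patient

    out: dict[str, PatientData] = {}
    for i in range(cfg.n_patients):
        rec, _events, ann = generate_patient(cfg, i)
        seg = preprocess_recording(rec)
        out[rec.patient_id] = PatientData(
            patient_id=rec.patient_id, segments=seg, annotations=ann
        )
    return out


@dataclass
class PatientData:
    """Preprocessed segments plus expert annotations for one patient."""

    patient_id: str
    segments: SegmentSet
    annotations: AnnotationSet

    @property
    def duration_s(self) -> float:
        return float(self.annotations.n_seconds)

    def segment_labels(self) -> np.ndarray:
        """Per-segment consensus class; invalid segments forced to excluded."""
        lab = label_segments(self.segments.start_s, self.annotations)
        lab[~self.segments.valid] = SEG_EXCLUDED
        return lab

    def consensus_events(self) -> EventList:
        return mask_to_events(consensus_mask(self.annotations), source="consensus")

    def any_expert_events(self) -> EventList:
        return mask_to_events(
            self.annotations.labels.max(axis=0), source="any_expert"
        )


def _nanmean(vals) -> float:
    arr = np.asarray(vals, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if len(arr) else float("nan")


def _gather_training_set(
    dataset: dict[str, PatientData], patients
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for pid in patients:
        pd_ = dataset[pid]
        lab = pd_.segment_labels()
        keep = lab != SEG_EXCLUDED
        xs.append(pd_.segments.data[keep])
        ys.append(lab[keep])
    return np.concatenate(xs), np.concatenate(ys)


def _cache_key(patients, arch: ArchitectureConfig, cfg: TrainConfig, seed: int) -> str:
    blob = json.dumps(
        {
            "patients": sorted(patients),
            "arch": asdict(arch),
            "train": asdict(cfg),
            "seed": seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _train_local_model(
    dataset: dict[str, PatientData],
    patients,
    institution_id: str,
    arch: ArchitectureConfig,
    train_cfg: TrainConfig,
    seed: int,
    cache_dir: Path | None,
) -> LocalModel:
    key = _cache_key(patients, arch, train_cfg, seed)
    if cache_dir is not None:
        path = Path(cache_dir) / f"model_{key}.npz"
        if path.exists():
            from .detector import load_model

            cached = load_model(path)
            cached.institution_id = institution_id
            return cached
    x, y = _gather_training_set(dataset, patients)
    rng = np.random.default_rng(seed)
    idx = balance_training_set(y, rng)
    model = build_nsda(arch, seed=seed)
    cfg = TrainConfig(**{**asdict(train_cfg), "rng_seed": seed})
    history = train_nsda(model, x[idx], y[idx], cfg)
    local = LocalModel(
        institution_id=institution_id,
        model=model,
        patient_ids=tuple(sorted(patients)),
        history=history,
    )
    if cache_dir is not None:
        from .detector import save_model

        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        save_model(local, Path(cache_dir) / f"model_{key}.npz")
    return local


def _predict_matrix(
    models: list[LocalModel], pd_: PatientData
) -> tuple[PredictionMatrix, np.ndarray]:
    """Probabilities of every model on the patient's valid segments."""
    idx = np.flatnonzero(pd_.segments.valid)
    cols = [m.model.predict_proba(pd_.segments.data[idx]) for m in models]
    pm = PredictionMatrix(
        p=np.column_stack(cols),
        segment_ids=idx,
        model_ids=[m.institution_id for m in models],
    )
    return pm, idx


def _evaluate_stream(
    mu: np.ndarray, idx: np.ndarray, pd_: PatientData
) -> dict[str, float]:
    """Segment + event metrics for one aggregated probability stream."""
    lab = pd_.segment_labels()[idx]
    seg = segment_metrics(mu, lab)
    fp = overlap_average(
        mu,
        pd_.segments.start_s[idx],
        duration_s=pd_.duration_s,
    )
    pred_events = frames_to_events(fp)
    ev = event_metrics(
        pred_events,
        pd_.consensus_events(),
        pd_.any_expert_events(),
        duration_h=pd_.duration_s / 3600.0,
    )
    n_false = round(ev["fd_per_h"] * pd_.duration_s / 3600.0)
    if n_false == 0:
        ev["mfdd"] = np.nan  # no false detections: skip in cross-patient mean
    return {**seg, **ev}


def run_experiment(
    dataset: dict[str, PatientData],
    k: int,
    test_patients,
    seed: int = 0,
    arch: ArchitectureConfig = SMALL_ARCHITECTURE,
    train_cfg: TrainConfig | None = None,
    cache_dir=None,
    dry_run: bool = False,
) -> dict:
    """One repeat of the protocol: partition, train, aggregate, evaluate.

    Patients in ``test_patients`` are excluded from the training pool; each
    is evaluated separately and metrics are summarized across them.  The
    report contains per-scheme metrics (``mv``, ``mean``, ``wmean``,
    ``ds``), the average individual local-detector metrics
    (``local_mean``), and the mean pairwise AC1 agreement between local
    detectors.

    ``dry_run=True`` returns the job table without training anything.
    """
    train_cfg = train_cfg or TrainConfig(epochs=10)
    test_patients = list(test_patients)
    pool = sorted(p for p in dataset if p not in test_patients)
    subsets = partition_patients(pool, k, _job_seed(seed, 0))
    jobs = [
        {"institution": i, "patients": s, "seed": _job_seed(seed, 1, i)}
        for i, s in enumerate(subsets)
    ]
    if dry_run:
        return {"jobs": jobs, "n_jobs": len(jobs)}

    models = [
        _train_local_model(
            dataset,
            job["patients"],
            institution_id=f"inst{job['institution']}",
            arch=arch,
            train_cfg=train_cfg,
            seed=job["seed"],
            cache_dir=cache_dir,
        )
        for job in jobs
    ]

    # stacking: held-out institution's own data, predicted by the others
    held, rest = select_stacking_institution(k, _job_seed(seed, 2))
    ens_models = [models[j] for j in rest]
    held_x, held_y = _gather_training_set(dataset, models[held].patient_ids)
    held_pm = PredictionMatrix(
        p=np.column_stack([m.model.predict_proba(held_x) for m in ens_models])
    )
    weights = fit_stacking(held_pm, held_y)

    schemes = ["mv", "mean", "wmean", "ds"]
    per_patient: dict[str, dict[str, dict[str, float]]] = {s: {} for s in schemes}
    per_patient["local_mean"] = {}
    ac1_values = []
    for pid in test_patients:
        pd_ = dataset[pid]
        pm_all, idx = _predict_matrix(models, pd_)
        pm_rest = PredictionMatrix(
            p=pm_all.p[:, rest],
            segment_ids=pm_all.segment_ids,
            model_ids=[pm_all.model_ids[j] for j in rest],
        )
        mu = {
            "mv": majority_vote(pm_all),
            "mean": mean_probability(pm_all),
            "wmean": weighted_mean(pm_rest, weights),
            "ds": dawid_skene(pm_all).posteriors,
        }
        for s in schemes:
            per_patient[s][pid] = _evaluate_stream(mu[s], idx, pd_)
        local_metrics = [
            _evaluate_stream(pm_all.p[:, j], idx, pd_)
            for j in range(pm_all.n_models)
        ]
        per_patient["local_mean"][pid] = {
            key: _nanmean([m[key] for m in local_metrics])
            for key in local_metrics[0]
        }
        if pm_all.n_models >= 2:
            ac1_values.append(gwet_ac1(pm_all.y))

    report = {
        "k": k,
        "seed": seed,
        "institutions": [list(s) for s in subsets],
        "stacking_institution": held,
        "stacking_weights": weights.w.tolist(),
        "per_patient": per_patient,
        "summary": {s: summarize(per_patient[s]) for s in per_patient},
        "ac1_mean": float(np.mean(ac1_values)) if ac1_values else np.nan,
    }
    return report
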