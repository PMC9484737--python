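"""The neonatal seizure detection algorithm (NSDA) and its training protocol.

The network has three components: a per-channel 1-D convolutional feature
extractor applied identically to every EEG channel, a channel-attention
layer that collapses the per-channel feature vectors into a single weighted
feature vector, and a fully connected output layer with two softmax nodes.
Because the attention scoring depends only on the feature dimension, the
parameter count — and hence a trained model — is independent of the number
of input channels: a detector trained on an 18-channel montage runs
unchanged on a 3-channel one.

The reference configuration (four conv blocks of 16, 16, 64, 64 filters,
kernel 5, batch norm, 2× max pooling, global average pooling; attention
bottleneck of 27 units; 64→2 output) has exactly 29 352 learnable
parameters.

Training: consensus-labelled 16 s segments only, class-balanced by
subsampling the majority class, cross-entropy loss, Adam with initial
learning rate 0.001 halved every 10 epochs, 30 epochs, mini-batches of 32.
Runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .annotations import SEG_NONSEIZURE, SEG_SEIZURE
from .preprocess import SegmentSet

__all__ = [
    "ArchitectureConfig",
    "FIG_ARCHITECTURE",
    "SMALL_ARCHITECTURE",
    "TrainConfig",
    "NsdaModel",
    "LocalModel",
    "build_nsda",
    "count_parameters",
    "balance_training_set",
    "train_nsda",
    "predict_segments",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyper-parameters of the NSDA network."""

    conv_channels: tuple[int, ...] = (16, 16, 64, 64)
    kernel: int = 5
    pool: int = 2
    batchnorm: bool = True
    attention_hidden: int = 27
    n_classes: int = 2
    input_samples: int = 512  # 16 s at 32 Hz

    @property
    def feature_dim(self) -> int:
        return self.conv_channels[-1]


#: Reference architecture (29 352 learnable parameters).
FIG_ARCHITECTURE = ArchitectureConfig()

#: Reduced architecture for fast experiments on synthetic data.
SMALL_ARCHITECTURE = ArchitectureConfig(
    conv_channels=(8, 16), kernel=5, pool=4, attention_hidden=8
)


@dataclass
class TrainConfig:
    """Optimization protocol of the NSDA."""

    lr0: float = 1e-3
    lr_halving_every: int = 10
    epochs: int = 30
    batch_size: int = 32
    rng_seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * 0.5 ** (epoch // self.lr_halving_every)


class NsdaModel:
    """A built (possibly trained) NSDA network.

    Input segments are ``(N, C, input_samples)`` int16 (or float µV); each
    channel of each segment is standardized to zero mean and unit variance
    before entering the CNN, so predictions do not depend on the int16
    scale factor.
    """

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator):
        if arch.input_samples < arch.kernel:
            raise ValueError("input shorter than one convolution kernel")
        self.arch = arch
        layers: list[nn.Layer] = []
        c_in = 1
        length = arch.input_samples
        for c_out in arch.conv_channels:
            layers.append(nn.Conv1d(c_in, c_out, arch.kernel, rng))
            length = length - arch.kernel + 1
            if arch.batchnorm:
                layers.append(nn.BatchNorm1d(c_out))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool1d(arch.pool))
            length //= arch.pool
            c_in = c_out
            if length < 1:
                raise ValueError("architecture pools the signal away entirely")
        layers.append(nn.GlobalAvgPool())
        self.extractor = nn.Sequential(layers)
        self.attention = nn.ChannelAttention(arch.feature_dim, arch.attention_hidden, rng)
        self.head = nn.Linear(arch.feature_dim, arch.n_classes, rng)

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self) -> list[nn.Layer]:
        return [*self.extractor.layers, self.attention, self.head]

    def count_parameters(self) -> int:
        return sum(l.n_params() for l in self._all_layers())

    @staticmethod
    def standardize(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        mean = x.mean(axis=-1, keepdims=True)
        std = x.std(axis=-1, keepdims=True)
        return (x - mean) / np.maximum(std, 1e-8)

    # -- forward/backward -------------------------------------------------
    def forward(self, segments: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.atleast_3d(np.asarray(segments))
        n, c, length = x.shape
        if length != self.arch.input_samples:
            raise ValueError(
                f"segment length {length} != expected {self.arch.input_samples}"
            )
        if c < 1:
            raise ValueError("need at least one channel")
        x = self.standardize(x)
        feats = self.extractor.forward(x.reshape(n * c, 1, length), train)
        feats = feats.reshape(n, c, self.arch.feature_dim)
        pooled = self.attention.forward(feats, train)
        self._shape = (n, c)
        return self.head.forward(pooled, train)

    def backward(self, glogits: np.ndarray) -> None:
        n, c = self._shape
        g = self.head.backward(glogits)
        g = self.attention.backward(g)
        g = g.reshape(n * c, self.arch.feature_dim)
        self.extractor.backward(g)

    def predict_proba(self, segments: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Seizure probability (softmax of the class-1 node) per segment."""
        x = np.atleast_3d(np.asarray(segments))
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(nn.softmax(logits)[:, 1])
        return np.concatenate(out) if out else np.empty(0)

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._all_layers()):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            for k, v in layer.buffers.items():
                state[f"layer{i}.buf.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._all_layers()):
            for k in layer.params:
                layer.params[k] = np.asarray(state[f"layer{i}.{k}"])
            for k in layer.buffers:
                layer.buffers[k] = np.asarray(state[f"layer{i}.buf.{k}"])


@dataclass
class LocalModel:
    """One institution's trained detector plus its training provenance."""

    institution_id: str
    model: NsdaModel
    patient_ids: tuple[str, ...] = ()
    history: dict = field(default_factory=dict)


def build_nsda(
    arch: ArchitectureConfig = FIG_ARCHITECTURE, seed: int = 0
) -> NsdaModel:
    """Instantiate an NSDA with fan-in-scaled random initial weights."""
    return NsdaModel(arch, np.random.default_rng(seed))


def count_parameters(arch: ArchitectureConfig = FIG_ARCHITECTURE) -> int:
    """Total learnable parameters of the architecture."""
    return build_nsda(arch, seed=0).count_parameters()


def balance_training_set(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced subset (majority class subsampled).

    All minority-class segments are kept; the majority class is sampled
    without replacement down to the same count.  Raises when either class is
    absent — an institution with no consensus seizure segments cannot train
    a detector.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == SEG_SEIZURE)
    neg = np.flatnonzero(labels == SEG_NONSEIZURE)
    if len(pos) == 0:
        raise ValueError("no consensus seizure segments to train on")
    if len(neg) == 0:
        raise ValueError("no consensus non-seizure segments to train on")
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, neg]))


def train_nsda(
    model: NsdaModel,
    segments: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> dict:
    """Train in place on a balanced set; returns the loss history.

    The epoch-``e`` learning rate is ``lr0 · 0.5^⌊e/10⌋``.  Shuffling and
    any subsampling are driven by ``cfg.rng_seed``, so two runs with the
    same seed produce identical final weights.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(segments)
    y = np.asarray(labels).astype(int)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.rng_seed)
    opt = nn.Adam(
        [*model.extractor.layers, model.attention, model.head], lr=cfg.lr0
    )
    losses = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, glogits = nn.cross_entropy_with_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            model.backward(glogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    return {"loss": losses}


def predict_segments(model: NsdaModel, seg_set: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Seizure probabilities for the *valid* segments of a recording.

    Returns ``(probabilities, indices_of_valid_segments)``.
    """
    if seg_set.data.shape[1] < 1:
        raise ValueError("segments have zero channels")
    idx = np.flatnonzero(seg_set.valid)
    probs = model.predict_proba(seg_set.data[idx])
    return probs, idx


def save_model(local: LocalModel, path) -> None:
    """Serialize weights + architecture manifest + provenance to one npz."""
    import json

    meta = {
        "institution_id": local.institution_id,
        "patient_ids": list(local.patient_ids),
        "arch": asdict(local.model.arch),
    }
    state = local.model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path) -> LocalModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    arch_d = meta["arch"]
    arch_d["conv_channels"] = tuple(arch_d["conv_channels"])
    arch = ArchitectureConfig(**arch_d)
    model = build_nsda(arch, seed=0)
    model.load_state_dict(state)
    return LocalModel(
        institution_id=meta["institution_id"],
        model=model,
        patient_ids=tuple(meta["patient_ids"]),
    )
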