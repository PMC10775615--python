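"""Training loops for the autoencoder and the cleavage classifiers.

The published protocol is followed: Adam with learning rate 0.005 and
weight decay 0.001, mini-batches of 20, at most 50 classifier epochs with
early stopping, binary cross entropy for the binary task and a
class-weighted negative log likelihood (weight 0.5 on the negative class)
for the multi-class task; the autoencoder is trained separately for 10
epochs with mean squared reconstruction error and then frozen. 20% of the
training patterns form a fixed validation set; after every epoch the model
is snapshotted, and the ``keep_top_k`` snapshots with the highest
validation accuracy are returned (best first).

The early-stopping rule — patience on the best validation accuracy seen —
is this package's own choice and is configurable.

Structure embeddings are computed once per distinct pre-miRNA through the
frozen encoder and shared by all windows of that molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ValidationError
from .models import (
    Checkpoint,
    ClassifierSpec,
    build_classifier,
    build_autoencoder,
    AutoencoderSpec,
    checkpoint_from_model,
)
from .structure import encode_pattern, encode_structure

__all__ = [
    "TrainConfig",
    "TrainLog",
    "encode_rows",
    "compute_embeddings",
    "train_autoencoder",
    "train_classifier",
    "predict",
]


@dataclass
class TrainConfig:
    batch_size: int = 20
    lr: float = 0.005
    weight_decay: float = 0.001
    max_epochs: int = 50
    ae_epochs: int = 10
    val_fraction: float = 0.2
    early_stop_patience: int = 5
    class_weights: dict = field(default_factory=lambda: {0: 0.5, 1: 1.0, 2: 1.0})
    seed: int = 0
    keep_top_k: int = 3

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValidationError("val_fraction must lie in (0, 1)")
        for name in ("batch_size", "lr", "weight_decay", "early_stop_patience",
                     "keep_top_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class TrainLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    stopping_epoch: int = 0
    kept_epochs: list = field(default_factory=list)

    def n_epochs(self) -> int:
        return len(self.train_loss)


def encode_rows(rows) -> tuple[np.ndarray, np.ndarray]:
    """Stack window encodings and labels of dataset rows: (N,13,14), (N,)."""
    X = np.stack([encode_pattern(r) for r in rows])
    y = np.array([r.label for r in rows], dtype=np.int64)
    return X, y


def compute_embeddings(rows, ae_checkpoint: Checkpoint) -> np.ndarray:
    """One frozen-encoder embedding per row, computed once per pre-miRNA."""
    ae = ae_checkpoint.build()
    cache: dict[str, np.ndarray] = {}
    out = np.zeros((len(rows), ae.spec.embedding_dim))
    for i, r in enumerate(rows):
        if r.id not in cache:
            cache[r.id] = ae.embed(encode_structure(r.dotseq))
        out[i] = cache[r.id]
    return out


def train_autoencoder(corpus: np.ndarray, cfg: TrainConfig | None = None,
                      spec: AutoencoderSpec | None = None
                      ) -> tuple[Checkpoint, TrainLog]:
    """Train the structure autoencoder for ``cfg.ae_epochs`` epochs.

    ``corpus`` is an (N, 4, 200) stack of one-hot structure encodings.
    No early stopping is applied; with ``ae_epochs=0`` the returned
    checkpoint equals the seeded initialisation.
    """
    cfg = cfg or TrainConfig()
    corpus = np.asarray(corpus, dtype=np.float64)
    if corpus.ndim != 3 or corpus.shape[0] == 0:
        raise ValidationError("autoencoder corpus must be a non-empty (N,4,W) stack")
    rng = np.random.default_rng(cfg.seed)
    model = build_autoencoder(spec, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    log = TrainLog()
    n = corpus.shape[0]
    for _ in range(cfg.ae_epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            batch = corpus[order[lo:lo + cfg.batch_size]]
            opt.zero_grad()
            _, recon = model.forward(nn.Tensor(batch))
            loss = nn.mse_loss(recon, batch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.train_loss.append(float(np.mean(losses)))
    log.stopping_epoch = log.n_epochs()
    return checkpoint_from_model(model, cfg.seed), log


def _accuracy(probs: np.ndarray, y: np.ndarray, task: str) -> float:
    return float(np.mean(_hard_labels(probs, task) == y))


def _hard_labels(probs: np.ndarray, task: str) -> np.ndarray:
    if task == "binary":
        return (probs.ravel() >= 0.5).astype(np.int64)
    return probs.argmax(axis=1)


def _forward_probs(model, X: np.ndarray, emb: np.ndarray | None,
                   training: bool = False, rng=None) -> nn.Tensor:
    e = None if emb is None else nn.Tensor(emb)
    return model.forward(nn.Tensor(X), e, training=training, rng=rng)


def train_classifier(rows, cfg: TrainConfig, spec: ClassifierSpec,
                     ae_checkpoint: Checkpoint | None = None
                     ) -> tuple[list[Checkpoint], TrainLog]:
    """Train one classifier; returns the top-k epoch snapshots (best first).

    ``rows`` are dataset rows whose label set must match the task (0/1 for
    binary, 0/1/2 for multi-class). Unless the variant is ``no_embedding``,
    a trained autoencoder checkpoint must be supplied.
    """
    labels = sorted({r.label for r in rows})
    if spec.task == "binary" and not set(labels) <= {0, 1}:
        raise ValidationError(f"binary task but labels {labels} present")
    if spec.task == "multi" and not set(labels) <= {0, 1, 2}:
        raise ValidationError(f"multi task but labels {labels} present")
    if spec.variant != "no_embedding" and ae_checkpoint is None:
        raise ValidationError(
            f"variant {spec.variant!r} needs an autoencoder checkpoint"
        )

    X, y = encode_rows(rows)
    emb = (None if spec.variant == "no_embedding"
           else compute_embeddings(rows, ae_checkpoint))

    rng = np.random.default_rng(cfg.seed)
    n = len(rows)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]

    model = build_classifier(spec, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    weights = np.array([cfg.class_weights.get(k, 1.0) for k in range(3)])

    def batch_loss(idx, training):
        probs = _forward_probs(model, X[idx],
                               None if emb is None else emb[idx],
                               training=training, rng=rng)
        if spec.task == "binary":
            return probs, nn.bce_loss(probs.reshape(len(idx)), y[idx])
        return probs, nn.weighted_nll_loss(probs, y[idx], weights)

    log = TrainLog()
    snapshots: list[tuple[float, int, Checkpoint]] = []
    best_acc = -np.inf
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(tr_idx))
        losses = []
        for lo in range(0, len(tr_idx), cfg.batch_size):
            idx = tr_idx[perm[lo:lo + cfg.batch_size]]
            opt.zero_grad()
            _, loss = batch_loss(idx, training=True)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        vprobs, vloss = batch_loss(val_idx, training=False)
        vacc = _accuracy(vprobs.data, y[val_idx], spec.task)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(float(vloss.data))
        log.val_accuracy.append(vacc)
        snapshots.append(
            (vacc, epoch,
             checkpoint_from_model(model, cfg.seed, val_accuracy=vacc,
                                   val_indices=val_idx))
        )
        snapshots.sort(key=lambda t: (-t[0], t[1]))
        snapshots = snapshots[:cfg.keep_top_k]
        if vacc > best_acc:
            best_acc = vacc
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    log.stopping_epoch = log.n_epochs()
    log.kept_epochs = [e for _, e, _ in snapshots]
    return [c for _, _, c in snapshots], log


def predict(rows, checkpoint: Checkpoint,
            ae_checkpoint: Checkpoint | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels for dataset rows under a trained model.

    Binary: probabilities of shape (N,), labels by threshold 0.5.
    Multi-class: probabilities of shape (N, 3), labels by argmax.
    """
    model = checkpoint.build()
    spec = model.spec
    X, _ = encode_rows(rows)
    emb = None
    if spec.variant != "no_embedding":
        if ae_checkpoint is None:
            raise ValidationError(
                f"variant {spec.variant!r} needs an autoencoder checkpoint"
            )
        emb = compute_embeddings(rows, ae_checkpoint)
    probs = _forward_probs(model, X, emb).data
    if spec.task == "binary":
        probs = probs.ravel()
    return probs, _hard_labels(probs, spec.task)
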