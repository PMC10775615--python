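"""The structure autoencoder and the two-module cleavage classifier.

Autoencoder (fully connected): the 4 x 200 one-hot structure matrix is
flattened to 800, encoded through 800 -> 256 -> 64 into a 64-dimensional
embedding, and decoded through the mirrored stack back to 4 x 200. Trained
with mean squared reconstruction error.

Classifier: two modules, each built from a stack of three residual
convolution units (CU1: channel-preserving same-padding conv + ReLU, with
an additive skip around each unit), a pair of batch-normalised convolution
units (CU2: 16 then 32 filters, conv + BN + ReLU), and a fully connected
head with dropout that maps the flattened features to a 64-vector. The
first module reads the 13 x 14 window encoding; its 64-vector output is
stacked with the 64-d structure embedding into a 2 x 64 tensor (2 channels
of width 64) and passed through the second module, which ends in a sigmoid
(binary, 1 output) or softmax (multi-class, 3 outputs) head. The
multi-class second module inserts one extra conv(64 filters) + BN +
max-pool(2) + ReLU stage after CU2.

Ablation variants: ``no_embedding`` feeds the first module's output to the
second module alone (a 1 x 64 tensor, no autoencoder input);
``no_cu1`` removes every CU1 stack from both modules.

Checkpoints are self-describing ``.npz`` containers holding the spec, the
channel-order metadata, the seed, and all parameter/buffer arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import CheckpointError, ValidationError
from .structure import (
    MAX_STRUCT_LEN,
    PATTERN_ALPHABET,
    PATTERN_STRUCT_ALPHABET,
    STRUCTURE_ALPHABET,
)

__all__ = [
    "AutoencoderSpec",
    "ClassifierSpec",
    "StructureAutoencoder",
    "CleavageClassifier",
    "Checkpoint",
    "build_autoencoder",
    "build_classifier",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1

CHANNEL_ORDER = {
    "pattern": PATTERN_ALPHABET,
    "pattern_structure": PATTERN_STRUCT_ALPHABET,
    "structure": STRUCTURE_ALPHABET,
}

VARIANTS = ("full", "no_embedding", "no_cu1")
TASKS = ("binary", "multi")


@dataclass
class AutoencoderSpec:
    input_shape: tuple[int, int] = (4, MAX_STRUCT_LEN)
    embedding_dim: int = 64
    hidden_dims: tuple[int, ...] = (256,)

    @property
    def input_dim(self) -> int:
        return self.input_shape[0] * self.input_shape[1]


@dataclass
class ClassifierSpec:
    task: str = "binary"
    variant: str = "full"
    kernel_size: int = 3
    dropout_rate: float = 0.5
    cu1_units: int = 3
    cu2_filters: tuple[int, int] = (16, 32)
    multi_extra_filters: int = 64
    fc_dim: int = 64
    input_shape: tuple[int, int] = (13, 14)
    embedding_dim: int = 64

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")

    @property
    def n_outputs(self) -> int:
        return 1 if self.task == "binary" else 3


class _CU1(nn.Module):
    """Residual convolution stack: n units of x <- ReLU(conv(x)) + x."""

    def __init__(self, channels: int, kernel: int, n_units: int,
                 rng: np.random.Generator):
        self.convs = [nn.Conv1d(channels, channels, kernel, rng)
                      for _ in range(n_units)]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.relu(conv.forward(x)) + x
        return x


class _CU2(nn.Module):
    """Two conv + BN + ReLU units with 16 and 32 filters (by default)."""

    def __init__(self, c_in: int, filters: tuple[int, int], kernel: int,
                 rng: np.random.Generator):
        f1, f2 = filters
        self.conv1 = nn.Conv1d(c_in, f1, kernel, rng)
        self.bn1 = nn.BatchNorm1d(f1)
        self.conv2 = nn.Conv1d(f1, f2, kernel, rng)
        self.bn2 = nn.BatchNorm1d(f2)

    def forward(self, x: nn.Tensor, training: bool) -> nn.Tensor:
        x = nn.relu(self.bn1.forward(self.conv1.forward(x), training))
        x = nn.relu(self.bn2.forward(self.conv2.forward(x), training))
        return x


class _FC(nn.Module):
    """Flatten -> dropout -> linear -> ReLU head producing a fixed-size vector."""

    def __init__(self, n_in: int, n_out: int, dropout_rate: float,
                 rng: np.random.Generator):
        self.linear = nn.Linear(n_in, n_out, rng)
        self.dropout_rate = dropout_rate

    def forward(self, x: nn.Tensor, training: bool,
                rng: np.random.Generator | None) -> nn.Tensor:
        b = x.data.shape[0]
        flat = x.reshape(b, -1)
        flat = nn.dropout(flat, self.dropout_rate, rng, training)
        return nn.relu(self.linear.forward(flat))


class StructureAutoencoder(nn.Module):
    """Fully connected autoencoder over flattened 4 x 200 structure encodings."""

    def __init__(self, spec: AutoencoderSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_dims, spec.embedding_dim]
        self.encoder_layers = [
            nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])
        ]
        rev = dims[::-1]
        self.decoder_layers = [
            nn.Linear(a, b, rng) for a, b in zip(rev[:-1], rev[1:])
        ]

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        b = x.data.shape[0]
        h = x.reshape(b, -1)
        for i, layer in enumerate(self.encoder_layers):
            h = layer.forward(h)
            if i < len(self.encoder_layers) - 1:
                h = nn.relu(h)
        return h

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Returns (embedding (B, 64), reconstruction (B, 4, 200))."""
        emb = self.encode(x)
        h = emb
        for i, layer in enumerate(self.decoder_layers):
            h = layer.forward(h)
            if i < len(self.decoder_layers) - 1:
                h = nn.relu(h)
        recon = h.reshape(x.data.shape)
        return emb, recon

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Deterministic embedding of a (B, 4, 200) or (4, 200) array."""
        arr = np.asarray(x, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        emb = self.encode(nn.Tensor(arr)).data
        return emb[0] if single else emb


class CleavageClassifier(nn.Module):
    """Two-module convolutional classifier over 13 x 14 window encodings."""

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator):
        self.spec = spec
        c_in, width = spec.input_shape
        k = spec.kernel_size
        use_cu1 = spec.variant != "no_cu1"

        self.cu1_a = _CU1(c_in, k, spec.cu1_units, rng) if use_cu1 else None
        self.cu2_a = _CU2(c_in, spec.cu2_filters, k, rng)
        self.fc_a = _FC(spec.cu2_filters[1] * width, spec.fc_dim,
                        spec.dropout_rate, rng)

        stack_channels = 1 if spec.variant == "no_embedding" else 2
        self.cu1_b = (_CU1(stack_channels, k, spec.cu1_units, rng)
                      if use_cu1 else None)
        self.cu2_b = _CU2(stack_channels, spec.cu2_filters, k, rng)
        width_b = spec.fc_dim
        c_b = spec.cu2_filters[1]
        if spec.task == "multi":
            self.extra_conv = nn.Conv1d(c_b, spec.multi_extra_filters, k, rng)
            self.extra_bn = nn.BatchNorm1d(spec.multi_extra_filters)
            c_b = spec.multi_extra_filters
            width_b //= 2  # max-pool with width 2
        else:
            self.extra_conv = None
            self.extra_bn = None
        self.fc_b = _FC(c_b * width_b, spec.fc_dim, spec.dropout_rate, rng)
        self.out = nn.Linear(spec.fc_dim, spec.n_outputs, rng)

    # -- the two modules ---------------------------------------------------

    def module1(self, x: nn.Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        """13 x 14 window encoding -> 64-vector of window features."""
        if self.cu1_a is not None:
            x = self.cu1_a.forward(x)
        x = self.cu2_a.forward(x, training)
        return self.fc_a.forward(x, training, rng)

    def module2(self, stacked: nn.Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        """(B, 2, 64) stacked features -> class probabilities."""
        x = stacked
        if self.cu1_b is not None:
            x = self.cu1_b.forward(x)
        x = self.cu2_b.forward(x, training)
        if self.extra_conv is not None:
            x = self.extra_bn.forward(self.extra_conv.forward(x), training)
            x = nn.relu(nn.maxpool1d(x, 2))
        h = self.fc_b.forward(x, training, rng)
        logits = self.out.forward(h)
        if self.spec.task == "binary":
            return nn.sigmoid(logits)
        return nn.softmax(logits)

    def forward(self, x: nn.Tensor, embedding: nn.Tensor | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        """Full forward pass; ``embedding`` is (B, 64) from the autoencoder.

        The ``no_embedding`` variant rejects an embedding; every other
        variant requires one.
        """
        if self.spec.variant == "no_embedding":
            if embedding is not None:
                raise ValidationError(
                    "the no_embedding variant takes no structure embedding"
                )
        elif embedding is None:
            raise ValidationError(
                f"variant {self.spec.variant!r} requires a structure embedding"
            )
        feats = self.module1(x, training, rng)  # (B, 64)
        b = feats.data.shape[0]
        if embedding is None:
            stacked = feats.reshape(b, 1, self.spec.fc_dim)
        else:
            stacked = nn.concat(
                [feats.reshape(b, 1, self.spec.fc_dim),
                 embedding.reshape(b, 1, self.spec.embedding_dim)],
                axis=1,
            )
        return self.module2(stacked, training, rng)


def build_autoencoder(spec: AutoencoderSpec | None = None,
                      seed: int = 0) -> StructureAutoencoder:
    """Seeded construction: the same seed gives identical initial parameters."""
    return StructureAutoencoder(spec or AutoencoderSpec(),
                                np.random.default_rng(seed))


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> CleavageClassifier:
    return CleavageClassifier(spec, np.random.default_rng(seed))


# -- checkpoints -----------------------------------------------------------


@dataclass
class Checkpoint:
    kind: str  # "autoencoder" | "classifier"
    spec: AutoencoderSpec | ClassifierSpec
    arrays: list
    seed: int
    channel_order: dict = field(default_factory=lambda: dict(CHANNEL_ORDER))
    val_accuracy: float | None = None
    val_indices: list | None = None
    version: int = CHECKPOINT_VERSION

    def build(self):
        """Instantiate the model and load the saved parameters into it."""
        if self.kind == "autoencoder":
            model = build_autoencoder(self.spec, self.seed)
        else:
            model = build_classifier(self.spec, self.seed)
        model.load_state_arrays(self.arrays)
        return model


def checkpoint_from_model(model, seed: int, val_accuracy: float | None = None,
                          val_indices=None) -> Checkpoint:
    kind = ("autoencoder" if isinstance(model, StructureAutoencoder)
            else "classifier")
    return Checkpoint(
        kind=kind,
        spec=model.spec,
        arrays=[a.copy() for a in model.state_arrays()],
        seed=seed,
        val_accuracy=val_accuracy,
        val_indices=None if val_indices is None else list(map(int, val_indices)),
    )


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    spec_dict = asdict(ckpt.spec)
    meta = {
        "version": ckpt.version,
        "kind": ckpt.kind,
        "spec": spec_dict,
        "seed": ckpt.seed,
        "channel_order": ckpt.channel_order,
        "val_accuracy": ckpt.val_accuracy,
        "val_indices": ckpt.val_indices,
        "n_arrays": len(ckpt.arrays),
    }
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(ckpt.arrays)}
    with open(path, "wb") as fh:  # keep the exact path (no .npz suffix munging)
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path) -> Checkpoint:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"arr_{i:04d}"] for i in range(meta["n_arrays"])]
    except (KeyError, OSError, ValueError) as exc:
        raise CheckpointError(f"{path}: not a readable checkpoint: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"{path}: checkpoint version {meta.get('version')} is not "
            f"supported (expected {CHECKPOINT_VERSION})"
        )
    if meta["kind"] == "autoencoder":
        spec = AutoencoderSpec(**{
            **meta["spec"],
            "input_shape": tuple(meta["spec"]["input_shape"]),
            "hidden_dims": tuple(meta["spec"]["hidden_dims"]),
        })
    elif meta["kind"] == "classifier":
        spec = ClassifierSpec(**{
            **meta["spec"],
            "cu2_filters": tuple(meta["spec"]["cu2_filters"]),
            "input_shape": tuple(meta["spec"]["input_shape"]),
        })
    else:
        raise CheckpointError(f"{path}: unknown checkpoint kind {meta['kind']!r}")
    return Checkpoint(
        kind=meta["kind"],
        spec=spec,
        arrays=arrays,
        seed=meta["seed"],
        channel_order=meta["channel_order"],
        val_accuracy=meta["val_accuracy"],
        val_indices=meta["val_indices"],
        version=meta["version"],
    )
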