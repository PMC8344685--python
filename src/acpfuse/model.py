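"""The dual-channel peptide classifier and its single-channel ablations.

The network has three parts. The handcrafted-feature channel (M1) passes a
composition descriptor vector through dense layers of 128 and 64 units with
dropout 0.2 between them. The CNN channel (M2) embeds the integer-encoded
sequence (21 symbols: 20 residues + padding 0), applies a 1-D convolution
(32 filters, kernel 16), max pooling (window 8) and a 64-unit dense layer.
The classification module (M3) concatenates the channel outputs and maps
them through a 64-unit dense layer to a single sigmoid output; a
probability strictly greater than 0.5 is called an anticancer peptide.

Single-channel variants drop the concatenation and feed one channel's
output straight into M3. Hidden layers use ReLU. Training minimises binary
cross-entropy with Adam, with optional early stopping on a held-out
validation split; all randomness flows from the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _network as nn
from .encoding import DEFAULT_ALPHABET, DEFAULT_MAX_LEN, AlphabetMap, encode_dataset
from .features import SCHEME_DIMS, featurize_dataset
from .sequence_io import LabelledDataset

CHANNEL_MODES = ("dual", "cnn_only", "hf_only")
HF_SCHEMES = ("AAC", "DPC", "CKSAAGP", "none")


@dataclass
class ModelConfig:
    """All architectural and training hyperparameters.

    Layer sizes default to the published architecture (conv 32x16, pool 8,
    channel dense 64, handcrafted dense 128/64 with dropout 0.2, fusion
    dense 64, threshold 0.5). The embedding width, optimizer, learning
    rate, batch size and epoch budget are conventional defaults for data of
    this scale and are all exposed here.
    """

    max_len: int = DEFAULT_MAX_LEN
    vocab_size: int = 21
    embedding_dim: int = 32
    conv_filters: tuple[int, ...] = (32,)
    conv_kernel: int = 16
    pool_size: int = 8
    cnn_dense_units: int = 64
    hf_dense_units: tuple[int, int] = (128, 64)
    hf_dropout: float = 0.2
    fusion_dense_units: int = 64
    threshold: float = 0.5
    hf_scheme: str = "CKSAAGP"
    channels: str = "dual"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in (
            self.conv_filters if isinstance(self.conv_filters, (tuple, list)) else (self.conv_filters,)
        ))
        if not self.conv_filters or len(self.conv_filters) > 2 or any(f <= 0 for f in self.conv_filters):
            raise ValueError("conv_filters must be one or two positive layer sizes")
        if not 0.0 <= self.hf_dropout < 1.0:
            raise ValueError("hf_dropout must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.channels not in CHANNEL_MODES:
            raise ValueError(f"channels must be one of {CHANNEL_MODES}")
        if self.hf_scheme not in HF_SCHEMES:
            raise ValueError(f"hf_scheme must be one of {HF_SCHEMES}")
        if self.channels in ("dual", "hf_only") and self.hf_scheme == "none":
            raise ValueError(f"channels={self.channels!r} requires a handcrafted feature scheme")

    @property
    def uses_sequence(self) -> bool:
        return self.channels in ("dual", "cnn_only")

    @property
    def uses_features(self) -> bool:
        return self.channels in ("dual", "hf_only")

    @property
    def hf_dim(self) -> int:
        return 0 if self.hf_scheme == "none" else SCHEME_DIMS[self.hf_scheme]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        d["hf_dense_units"] = list(self.hf_dense_units)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["hf_dense_units"] = tuple(d["hf_dense_units"])
        return cls(**d)


class PeptideClassifier:
    """The dual-channel network with fit/predict over prepared arrays.

    Use :func:`build_model` (or the constructor) for an untrained model,
    :meth:`fit` to train, and :meth:`predict_proba` / :meth:`predict` for
    inference. ``training_history`` holds per-epoch losses after fitting.
    """

    def __init__(self, config: ModelConfig, alphabet: AlphabetMap = DEFAULT_ALPHABET):
        self.config = config
        self.alphabet = alphabet
        self.fitted = False
        self.training_history: list[dict] = []
        self.rng = np.random.default_rng(config.seed)
        self._build()

    def _build(self) -> None:
        cfg = self.config
        rng = self.rng
        self._layers: list = []
        fusion_in = 0

        if cfg.uses_sequence:
            self.embedding = nn.Embedding(rng, cfg.vocab_size, cfg.embedding_dim)
            self.convs = []
            c_in, length = cfg.embedding_dim, cfg.max_len
            for f in cfg.conv_filters:
                self.convs.append(nn.Conv1D(rng, c_in, f, cfg.conv_kernel))
                c_in, length = f, length - cfg.conv_kernel + 1
            self.pool = nn.MaxPool1D(cfg.pool_size)
            pooled = length // cfg.pool_size
            self.cnn_dense = nn.Dense(rng, pooled * c_in, cfg.cnn_dense_units)
            self._layers += [self.embedding, *self.convs, self.cnn_dense]
            fusion_in += cfg.cnn_dense_units

        if cfg.uses_features:
            u1, u2 = cfg.hf_dense_units
            self.hf_dense1 = nn.Dense(rng, cfg.hf_dim, u1)
            self.hf_dropout = nn.Dropout(cfg.hf_dropout, rng)
            self.hf_dense2 = nn.Dense(rng, u1, u2)
            self._layers += [self.hf_dense1, self.hf_dense2]
            fusion_in += u2

        self.fusion_dense = nn.Dense(rng, fusion_in, cfg.fusion_dense_units)
        self.out_dense = nn.Dense(rng, cfg.fusion_dense_units, 1, relu=False)
        self._layers += [self.fusion_dense, self.out_dense]

    @property
    def params(self) -> list[nn.Param]:
        return [p for layer in self._layers for p in layer.params]

    # ------------------------------------------------------------------ forward/backward

    def _check_inputs(self, X_seq, X_hf, n: int | None = None):
        cfg = self.config
        if cfg.uses_sequence:
            if X_seq is None:
                raise ValueError("this model's configuration requires encoded sequences")
            X_seq = np.asarray(X_seq)
            if X_seq.ndim != 2 or X_seq.shape[1] != cfg.max_len:
                raise ValueError(f"encoded sequences must have shape (n, {cfg.max_len})")
        if cfg.uses_features:
            if X_hf is None:
                raise ValueError(f"this model's configuration requires {cfg.hf_scheme} feature vectors")
            X_hf = np.asarray(X_hf, dtype=np.float32)
            if X_hf.ndim != 2 or X_hf.shape[1] != cfg.hf_dim:
                raise ValueError(
                    f"feature width {X_hf.shape[1] if X_hf.ndim == 2 else '?'} does not match "
                    f"{cfg.hf_scheme} (expected {cfg.hf_dim})"
                )
        sizes = {a.shape[0] for a in (X_seq, X_hf) if a is not None}
        if len(sizes) != 1:
            raise ValueError("sequence and feature inputs have different numbers of rows")
        return X_seq, X_hf

    def _forward(self, X_seq, X_hf, train: bool) -> np.ndarray:
        cfg = self.config
        parts = []
        if cfg.uses_sequence:
            h = self.embedding.forward(X_seq, train)
            for conv in self.convs:
                h = conv.forward(h, train)
            h = self.pool.forward(h, train)
            self._pool_out_shape = h.shape
            h = h.reshape(h.shape[0], -1)
            parts.append(self.cnn_dense.forward(h, train))
        if cfg.uses_features:
            g = self.hf_dense1.forward(X_hf, train)
            g = self.hf_dropout.forward(g, train)
            parts.append(self.hf_dense2.forward(g, train))
        fused = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)
        z = self.fusion_dense.forward(fused, train)
        return self.out_dense.forward(z, train)[:, 0]

    def _backward(self, dlogit: np.ndarray) -> None:
        cfg = self.config
        d = self.out_dense.backward(dlogit[:, None])
        d = self.fusion_dense.backward(d)
        offset = 0
        if cfg.uses_sequence:
            d_cnn = d[:, offset : offset + cfg.cnn_dense_units]
            offset += cfg.cnn_dense_units
            h = self.cnn_dense.backward(d_cnn).reshape(self._pool_out_shape)
            h = self.pool.backward(h)
            for conv in reversed(self.convs):
                h = conv.backward(h)
            self.embedding.backward(h)
        if cfg.uses_features:
            g = self.hf_dense2.backward(d[:, offset:])
            g = self.hf_dropout.backward(g)
            self.hf_dense1.backward(g)

    # ------------------------------------------------------------------ training

    def fit(self, X_seq, X_hf, y) -> "PeptideClassifier":
        """Train with Adam on binary cross-entropy.

        A stratification-free random validation split (``validation_fraction``)
        drives early stopping with the configured patience; the best
        validation-loss weights are restored. With too few samples for a
        meaningful split, the full epoch budget runs on the training loss.
        """
        cfg = self.config
        y = np.asarray(y, dtype=np.float64).ravel()
        X_seq, X_hf = self._check_inputs(X_seq, X_hf)
        n = y.size
        if n == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")

        perm = self.rng.permutation(n)
        n_val = int(round(cfg.validation_fraction * n))
        use_val = n_val >= 4 and len(np.unique(y[perm[:n_val]])) == 2
        val_idx, tr_idx = (perm[:n_val], perm[n_val:]) if use_val else (None, perm)

        def take(idx):
            return (
                X_seq[idx] if X_seq is not None else None,
                X_hf[idx] if X_hf is not None else None,
                y[idx],
            )

        Xs_tr, Xh_tr, y_tr = take(tr_idx)
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        best_loss, best_weights, patience_left = np.inf, None, cfg.patience
        self.training_history = []

        for epoch in range(cfg.epochs):
            order = self.rng.permutation(tr_idx.size)
            epoch_loss = 0.0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                logits = self._forward(
                    Xs_tr[batch] if Xs_tr is not None else None,
                    Xh_tr[batch] if Xh_tr is not None else None,
                    train=True,
                )
                loss, dlogit = nn.bce_with_logits(logits, y_tr[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: loss={loss}, "
                        f"lr={cfg.learning_rate}, batch={batch.size}"
                    )
                epoch_loss += loss * batch.size
                opt.zero_grad()
                self._backward(dlogit)
                opt.step()
            record = {"epoch": epoch, "train_loss": epoch_loss / order.size}

            monitor = record["train_loss"]
            if use_val:
                val_logits = self._forward(*take(val_idx)[:2], train=False)
                record["val_loss"], _ = nn.bce_with_logits(val_logits, y[val_idx])
                monitor = record["val_loss"]
            self.training_history.append(record)

            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_weights = [p.value.copy() for p in self.params]
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

        if best_weights is not None:
            for p, w in zip(self.params, best_weights):
                p.value[...] = w
        self.fitted = True
        return self

    # ------------------------------------------------------------------ inference

    def predict_proba(self, X_seq, X_hf) -> np.ndarray:
        """Per-record probability of the positive (anticancer) class."""
        if not self.fitted:
            warnings.warn("predicting with an untrained model", stacklevel=2)
        X_seq, X_hf = self._check_inputs(X_seq, X_hf)
        return nn.sigmoid(self._forward(X_seq, X_hf, train=False))

    def predict(self, X_seq, X_hf) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and hard labels (1 iff probability > threshold)."""
        proba = self.predict_proba(X_seq, X_hf)
        return proba, (proba > self.config.threshold).astype(np.int64)

    # ------------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        """Save weights (``.npz``) with a JSON sidecar of config + alphabet."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **{f"p{i}": p.value for i, p in enumerate(self.params)})
        sidecar = {
            "config": self.config.to_dict(),
            "alphabet": self.alphabet.letter_to_code,
            "fitted": self.fitted,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PeptideClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig.from_dict(sidecar["config"])
        model = cls(config, alphabet=AlphabetMap(sidecar["alphabet"]))
        weights = np.load(path.with_suffix(".npz"))
        if len(weights.files) != len(model.params):
            raise ValueError("checkpoint does not match the configured architecture")
        for i, p in enumerate(model.params):
            saved = weights[f"p{i}"]
            if saved.shape != p.value.shape:
                raise ValueError("checkpoint does not match the configured architecture")
            p.value[...] = saved
        model.fitted = sidecar.get("fitted", True)
        return model


def build_model(config: ModelConfig, alphabet: AlphabetMap = DEFAULT_ALPHABET) -> PeptideClassifier:
    """Construct the untrained network described by ``config``."""
    return PeptideClassifier(config, alphabet=alphabet)


def prepare_inputs(
    dataset: LabelledDataset, config: ModelConfig, alphabet: AlphabetMap = DEFAULT_ALPHABET
) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Encode and featurize a dataset per the model's channel configuration."""
    X_seq = encode_dataset(dataset, alphabet=alphabet, max_len=config.max_len) if config.uses_sequence else None
    X_hf = None
    if config.uses_features:
        X_hf, _, _ = featurize_dataset(dataset, config.hf_scheme)
    y = np.asarray(dataset.labels, dtype=np.int64)
    return X_seq, X_hf, y


def train_on_dataset(config: ModelConfig, dataset: LabelledDataset) -> PeptideClassifier:
    """Build and fit a classifier on a labelled dataset."""
    model = build_model(config)
    model.fit(*prepare_inputs(dataset, config, model.alphabet))
    return model


def predict_records(model: PeptideClassifier, records: Sequence) -> pd.DataFrame:
    """Order-preserving per-record predictions as ``(id, probability, label)``.

    ``records`` may be a :class:`~acpfuse.sequence_io.LabelledDataset` or any
    sequence of :class:`~acpfuse.sequence_io.PeptideRecord` (labels unused).
    """
    cfg = model.config
    X_seq = X_hf = None
    if cfg.uses_sequence:
        from .encoding import encode

        X_seq = np.stack([
            encode(r.sequence, alphabet=model.alphabet, max_len=cfg.max_len).codes for r in records
        ])
    if cfg.uses_features:
        from .features import featurize

        X_hf = np.stack([featurize(r.sequence, cfg.hf_scheme).values for r in records])
    proba, labels = model.predict(X_seq, X_hf)
    return pd.DataFrame({"id": [r.id for r in records], "probability": proba, "label": labels})
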