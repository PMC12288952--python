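"""The SM / HM / DHM model family for m6A site prediction.

Three architectures share one convolutional trunk over the one-hot encoded
window (two ReLU Conv1D stages, each followed by max-pooling and dropout,
then a flatten):

* **SM (Simple Model)** — the CNN trunk alone feeds the sigmoid output.
* **HM (Hybrid Model)** — the raw 4^k k-mer composition vector is
  concatenated with the CNN features before the output layer.
* **DHM (Deep Hybrid Model)** — the k-mer vector first passes through a
  ReLU dense layer (64 units) and the resulting deep k-mer embedding is
  concatenated with the CNN features.

With the default geometry (L=2001, conv (64,k23) and (128,k33) with
length-preserving padding, pool 15) the trunk flattens to 1024 features,
giving fused widths 2048 (HM) and 1088 (DHM).  Training uses Adam
(lr 0.001), batch size 64, binary cross-entropy, 70 epochs by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoding import FeatureBundle
from .nn import (
    Adam,
    ArchitectureError,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    bce_with_logits,
    sigmoid,
)

VARIANTS = ("SM", "HM", "DHM")


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Architecture hyperparameters; defaults reproduce the reference
    geometry at L=2001."""

    variant: str = "HM"
    L: int = 2001
    conv1_filters: int = 64
    conv1_kernel: int = 23
    conv2_filters: int = 128
    conv2_kernel: int = 33
    pool_size: int = 15
    dropout: float = 0.5
    kmer_dim: int = 1024
    dhm_dense_units: int = 64
    batch_norm: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ArchitectureError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        # validate the pooled-length chain eagerly
        self.layer_table()

    @property
    def uses_kmer(self) -> bool:
        return self.variant in ("HM", "DHM")

    @property
    def cnn_flat_width(self) -> int:
        return (self.L // self.pool_size // self.pool_size) * self.conv2_filters

    @property
    def fused_width(self) -> int:
        if self.variant == "SM":
            return self.cnn_flat_width
        if self.variant == "HM":
            return self.cnn_flat_width + self.kmer_dim
        return self.cnn_flat_width + self.dhm_dense_units

    def layer_table(self) -> list[tuple[str, tuple[int, ...]]]:
        """Layer-by-layer (name, output shape) chain for introspection."""
        L, p = self.L, self.pool_size
        L1, L2 = L // p, L // p // p
        if L2 == 0:
            raise ArchitectureError(
                f"L={L} collapses under two pool-{p} stages "
                f"(length chain {L} -> {L1} -> {L2}); reduce pool_size or increase L"
            )
        if L < max(self.conv1_kernel, self.conv2_kernel):
            raise ArchitectureError(f"L={L} smaller than a convolution kernel")
        rows: list[tuple[str, tuple[int, ...]]] = [("Input 1", (L, 4))]
        if self.uses_kmer:
            rows.append(("Input 2", (self.kmer_dim,)))
        rows += [
            (f"Conv1D ({self.conv1_filters},{self.conv1_kernel},1)", (L, self.conv1_filters)),
            (f"MaxPooling1D (size={p})", (L1, self.conv1_filters)),
            (f"Dropout ({self.dropout})", (L1, self.conv1_filters)),
            (f"Conv1D ({self.conv2_filters},{self.conv2_kernel},1)", (L1, self.conv2_filters)),
            (f"MaxPooling1D (size={p})", (L2, self.conv2_filters)),
            (f"Dropout ({self.dropout})", (L2, self.conv2_filters)),
            ("Flatten", (self.cnn_flat_width,)),
        ]
        if self.variant == "HM":
            rows.append(("Flatten k-mer", (self.kmer_dim,)))
            rows.append(("Concatenate", (self.fused_width,)))
        elif self.variant == "DHM":
            rows.append((f"Dense ({self.dhm_dense_units}, relu)", (self.dhm_dense_units,)))
            rows.append(("Concatenate", (self.fused_width,)))
        rows.append((f"Dropout ({self.dropout})", (self.fused_width,)))
        rows.append(("Dense (1, sigmoid)", (1,)))
        return rows

    @classmethod
    def fast(cls, variant: str = "HM", L: int = 201, **overrides) -> "ModelSpec":
        """Desk-scale profile for tests and demos: shorter windows, smaller
        kernels and pool 5 (length chain 201 -> 40 -> 8) while keeping the
        full-scale filter counts, so the CNN flatten width stays 1024."""
        kw = dict(
            variant=variant,
            L=L,
            conv1_filters=64,
            conv1_kernel=11,
            conv2_filters=128,
            conv2_kernel=11,
            pool_size=5,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the reference regimen."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 70
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.epochs <= 0:
            raise TrainingError(f"epochs must be positive, got {self.epochs}")
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise TrainingError("batch_size and learning_rate must be positive")


class NeuralModel:
    """A built (possibly trained) instance of one architecture variant."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = spec
        self.cnn = [
            Conv1D(4, s.conv1_filters, s.conv1_kernel, rng),
            MaxPool1D(s.pool_size),
            Dropout(s.dropout),
            Conv1D(s.conv1_filters, s.conv2_filters, s.conv2_kernel, rng),
            MaxPool1D(s.pool_size),
            Dropout(s.dropout),
            Flatten(),
        ]
        self.kmer_path: list = []
        if s.variant == "DHM":
            self.kmer_path = [Dense(s.kmer_dim, s.dhm_dense_units, "relu", rng)]
        self.post: list = [Dropout(s.dropout)]
        if s.batch_norm:
            self.post.append(BatchNorm(s.fused_width))
        self.post.append(Dense(s.fused_width, 1, None, rng))
        self.history: dict[str, list[float]] = {}

    # -- introspection -----------------------------------------------------
    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Shape chain derived from the *built* layers (not the spec)."""
        s = self.spec
        rows: list[tuple[str, tuple[int, ...]]] = [("Input 1", (s.L, 4))]
        if s.uses_kmer:
            rows.append(("Input 2", (s.kmer_dim,)))
        shape: tuple[int, ...] = (s.L, 4)
        for layer in self.cnn:
            shape = layer.out_shape(shape)
            rows.append((type(layer).__name__, shape))
        cnn_shape = shape
        if s.variant == "HM":
            rows.append(("Flatten k-mer", (s.kmer_dim,)))
            shape = (cnn_shape[0] + s.kmer_dim,)
            rows.append(("Concatenate", shape))
        elif s.variant == "DHM":
            kshape: tuple[int, ...] = (s.kmer_dim,)
            for layer in self.kmer_path:
                kshape = layer.out_shape(kshape)
            rows.append(("Dense k-mer", kshape))
            shape = (cnn_shape[0] + kshape[0],)
            rows.append(("Concatenate", shape))
        for layer in self.post:
            shape = layer.out_shape(shape)
            rows.append((type(layer).__name__, shape))
        return rows

    def params(self):
        out = []
        for layer in self.cnn + self.kmer_path + self.post:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward ------------------------------------------------
    def _check_shapes(self, bundle: FeatureBundle):
        s = self.spec
        if bundle.onehot is None:
            raise TrainingError("feature bundle lacks one-hot features (required)")
        if bundle.onehot.shape[1:] != (s.L, 4):
            raise TrainingError(
                f"one-hot shape mismatch: expected (n, {s.L}, 4), got {bundle.onehot.shape}"
            )
        if s.uses_kmer:
            if bundle.kmer is None:
                raise TrainingError(f"variant {s.variant} requires k-mer features")
            if bundle.kmer.shape[1] != s.kmer_dim:
                raise TrainingError(
                    f"k-mer width mismatch: expected {s.kmer_dim}, got {bundle.kmer.shape[1]}"
                )

    def _forward(self, onehot, kmer, training, rng, taps: dict | None = None):
        h = onehot
        for layer in self.cnn:
            h = layer.forward(h, training, rng)
        if taps is not None:
            taps["cnn"] = h
        if self.spec.variant == "SM":
            fused = h
        else:
            km = kmer
            for layer in self.kmer_path:
                km = layer.forward(km, training, rng)
            if taps is not None:
                taps["kmer_deep" if self.kmer_path else "kmer_flat"] = km
            fused = np.concatenate([h, km], axis=1)
            if taps is not None:
                taps["fused"] = fused
        z = fused
        for layer in self.post:
            z = layer.forward(z, training, rng)
        return z

    def _backward(self, dz):
        g = dz
        for layer in reversed(self.post):
            g = layer.backward(g)
        if self.spec.variant == "SM":
            gcnn = g
        else:
            cnn_w = self.spec.cnn_flat_width
            gcnn, gk = g[:, :cnn_w], g[:, cnn_w:]
            for layer in reversed(self.kmer_path):
                gk = layer.backward(gk)
        for layer in reversed(self.cnn):
            gcnn = layer.backward(gcnn)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn = [l for l in self.post if isinstance(l, BatchNorm)]
        if bn:
            arrays["run_mean"] = bn[0].run_mean
            arrays["run_var"] = bn[0].run_var
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"spec": asdict(self.spec), "seed": self.seed, "history": self.history}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "NeuralModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelSpec(**meta["spec"]), seed=meta["seed"])
        model.history = meta["history"]
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p.value = data[f"p{i}"]
        bn = [l for l in model.post if isinstance(l, BatchNorm)]
        if bn and "run_mean" in data:
            bn[0].run_mean = data["run_mean"]
            bn[0].run_var = data["run_var"]
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> NeuralModel:
    """Construct an untrained model for ``spec`` with seeded initialization."""
    return NeuralModel(spec, seed)


def train(
    model: NeuralModel,
    bundle: FeatureBundle,
    cfg: TrainConfig,
    validation: FeatureBundle | None = None,
) -> NeuralModel:
    """Train in place with Adam + binary cross-entropy; returns the model.

    The history records mean training loss per epoch (and validation loss
    when a validation bundle is supplied).  Under a fixed seed the run is
    bit-for-bit reproducible.
    """
    model._check_shapes(bundle)
    y = np.asarray(bundle.labels, dtype=np.float64).reshape(-1, 1)
    if not np.isin(y, (0.0, 1.0)).all():
        raise TrainingError("labels must be binary")
    n = len(bundle)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"loss": []}
    if validation is not None:
        history["val_loss"] = []
    onehot = bundle.onehot.astype(np.float32)
    kmer = None if bundle.kmer is None else bundle.kmer.astype(np.float32)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = onehot[idx]
            kb = None if kmer is None else kmer[idx]
            z = model._forward(xb, kb, training=True, rng=rng)
            loss, dz = bce_with_logits(z, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged: non-finite loss at epoch {epoch + 1}")
            model._backward(dz)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        history["loss"].append(float(np.average(losses, weights=weights)))
        if validation is not None:
            zv = _forward_batched(model, validation)
            vloss, _ = bce_with_logits(zv, np.asarray(validation.labels, dtype=np.float64).reshape(-1, 1))
            history["val_loss"].append(vloss)
    model.history = history
    return model


def _forward_batched(model: NeuralModel, bundle: FeatureBundle, batch: int = 256, taps=None):
    model._check_shapes(bundle)
    rng = np.random.default_rng(0)  # unused at inference (dropout off)
    outs = []
    tap_rows: dict[str, list] = {}
    for start in range(0, len(bundle), batch):
        sl = slice(start, start + batch)
        kb = None if bundle.kmer is None else bundle.kmer[sl].astype(np.float32)
        t: dict | None = {} if taps is not None else None
        z = model._forward(bundle.onehot[sl].astype(np.float32), kb, training=False, rng=rng, taps=t)
        outs.append(z)
        if t is not None:
            for k, v in t.items():
                tap_rows.setdefault(k, []).append(v)
    z = np.concatenate(outs, axis=0)
    if taps is not None:
        taps.update({k: np.concatenate(v, axis=0) for k, v in tap_rows.items()})
    return z


def predict(model: NeuralModel, bundle: FeatureBundle) -> np.ndarray:
    """Per-record probability of being an m6A site, strictly inside (0,1)."""
    z = _forward_batched(model, bundle)
    p = sigmoid(z).ravel()
    return np.clip(p, 1e-7, 1 - 1e-7)


def extract_features(model: NeuralModel, bundle: FeatureBundle, tap: str) -> np.ndarray:
    """Per-record embedding at a named internal layer.

    ``kmer_raw`` — the input k-mer vectors (any variant carrying them);
    ``kmer_deep`` — the DHM dense k-mer embedding (DHM only);
    ``cnn`` — the flattened CNN trunk output;
    ``fused`` — the concatenated feature vector (HM/DHM only).
    """
    v = model.spec.variant
    if tap == "kmer_raw":
        if bundle.kmer is None:
            raise TrainingError("bundle carries no k-mer features")
        return np.asarray(bundle.kmer)
    if tap == "kmer_deep" and v != "DHM":
        raise TrainingError(f"tap 'kmer_deep' requires DHM, not {v}")
    if tap == "fused" and v == "SM":
        raise TrainingError("tap 'fused' requires HM or DHM")
    if tap not in {"cnn", "kmer_deep", "fused"}:
        raise TrainingError(f"unknown tap {tap!r}")
    taps: dict = {}
    _forward_batched(model, bundle, taps=taps)
    return taps[tap]
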