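"""End-to-end multi-input 1D-CNN regression of beam parameters.

One convolutional encoder per selected profile: each encoder is a stack of
L convolution blocks (two length-preserving kernel-3 convolutions with
ReLU, then window-2 max pooling) with 16, 32, 64, ... filters in
consecutive blocks, terminated by a single unit-size-filter convolution.
The block count is tied to the input length N by L = floor(log2(N)/3), so
an encoder never produces fewer than 3 features.  Encoder outputs are
flattened, concatenated and passed through two ReLU dense layers of width
100 into a linear 4-output head giving (E, sigma_E, s, alpha).

Training: Adam at a constant learning rate 1e-4, mean-squared-error loss
on standardized targets, 300 epochs, a seeded 20% validation split, and
the checkpoint with the lowest validation loss is kept.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .params import PARAM_NAMES, BeamParameters
from .profiles import ProfileSet
from .svr import Prediction

__all__ = [
    "DeepModelSpec",
    "MultiEncoderNet",
    "TrainedDeepModel",
    "encoder_depth",
    "build_model",
    "train_deep",
    "predict_deep",
    "save_deep",
    "load_deep",
]

_FORMAT_VERSION = 1


def encoder_depth(n: int) -> int:
    """Number of convolution blocks for an input of length ``n``:
    L = floor(log2(n) / 3); inputs shorter than 8 are rejected (L would be 0)."""
    if n < 8:
        raise ValueError(f"encoder input length must be >= 8, got {n}")
    return int(math.floor(math.log2(n) / 3.0))


@dataclass(frozen=True)
class DeepModelSpec:
    """Architecture + training configuration of the multi-encoder CNN."""

    input_lengths: tuple  # N_i per selected profile
    profile_labels: tuple = ()
    base_filters: int = 16  # doubled in each consecutive block
    kernel: int = 3
    pool: int = 2
    head_widths: tuple = (100, 100)
    n_outputs: int = 4
    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 32
    val_fraction: float = 0.2

    @property
    def encoder_depths(self) -> tuple:
        return tuple(encoder_depth(n) for n in self.input_lengths)

    def filter_counts(self, i: int) -> tuple:
        """Filters of the consecutive convolution blocks of encoder ``i``."""
        return tuple(self.base_filters * 2**b for b in range(self.encoder_depths[i]))

    @property
    def encoder_output_lengths(self) -> tuple:
        return tuple(
            n // self.pool**depth
            for n, depth in zip(self.input_lengths, self.encoder_depths)
        )

    @property
    def concat_length(self) -> int:
        return sum(self.encoder_output_lengths)


def _build_encoder(n: int, spec: DeepModelSpec, rng) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    c_in = 1
    for filters in (spec.base_filters * 2**b for b in range(encoder_depth(n))):
        layers += [
            nn.Conv1D(c_in, filters, spec.kernel, rng),
            nn.ReLU(),
            nn.Conv1D(filters, filters, spec.kernel, rng),
            nn.ReLU(),
            nn.MaxPool1D(),
        ]
        c_in = filters
    layers += [nn.Conv1D(c_in, 1, 1, rng), nn.Flatten()]
    return layers


class MultiEncoderNet:
    """The assembled network: per-profile encoders + shared dense head."""

    def __init__(self, spec: DeepModelSpec, seed: int = 0):
        for n, out_len in zip(spec.input_lengths, spec.encoder_output_lengths):
            if out_len < 3:
                raise ValueError(
                    f"encoder output length {out_len} < 3 for input length {n}"
                )
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.encoders = [_build_encoder(n, spec, rng) for n in spec.input_lengths]
        widths = [spec.concat_length, *spec.head_widths]
        self.head: list[nn.Layer] = []
        for w_in, w_out in zip(widths[:-1], widths[1:]):
            self.head += [nn.Dense(w_in, w_out, rng), nn.ReLU()]
        self.head.append(nn.Dense(widths[-1], spec.n_outputs, rng))

    def params(self) -> list[nn.Param]:
        out = []
        for enc in self.encoders:
            for layer in enc:
                out += layer.params()
        for layer in self.head:
            out += layer.params()
        return out

    def forward(self, inputs: list[np.ndarray]) -> np.ndarray:
        if len(inputs) != len(self.encoders):
            raise ValueError(
                f"model expects {len(self.encoders)} profile inputs, got {len(inputs)}"
            )
        encoded = []
        self._split = []
        for x, enc, n in zip(inputs, self.encoders, self.spec.input_lengths):
            if x.shape[1] != n:
                raise ValueError(f"input length {x.shape[1]} does not match spec {n}")
            h = x[:, :, None]
            for layer in enc:
                h = layer.forward(h)
            encoded.append(h)
            self._split.append(h.shape[1])
        h = np.concatenate(encoded, axis=1)
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.head):
            dy = layer.backward(dy)
        pos = 0
        for enc, width in zip(self.encoders, self._split):
            d = dy[:, pos : pos + width]
            for layer in reversed(enc):
                d = layer.backward(d)
            pos += width

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(p.value.tobytes())
        return h.hexdigest()


@dataclass
class TrainedDeepModel:
    """A trained network plus the input/target scalers and provenance."""

    net: MultiEncoderNet
    input_centers: list  # per profile: mean training shape (N_i,)
    input_scales: list  # per profile: scalar SD of centred training doses
    target_mean: np.ndarray
    target_scale: np.ndarray
    hypercube: np.ndarray  # (4, 2)
    profile_labels: tuple
    history: list = field(default_factory=list)  # per-epoch train/val loss
    best_epoch: int = -1

    @property
    def spec(self) -> DeepModelSpec:
        return self.net.spec


def build_model(spec: DeepModelSpec, seed: int = 0) -> MultiEncoderNet:
    """Instantiate the network with seeded He-normal weight initialization."""
    return MultiEncoderNet(spec, seed=seed)


def _profile_matrix(profile_sets: list[ProfileSet], index: int) -> np.ndarray:
    return np.stack([ps[index].doses for ps in profile_sets])


def train_deep(
    profile_sets: list[ProfileSet],
    targets: np.ndarray,
    hypercube: np.ndarray,
    spec: DeepModelSpec | None = None,
    seed: int = 0,
    **spec_overrides,
) -> TrainedDeepModel:
    """Train the CNN on per-node profile sets and their parameter tuples.

    ``targets`` has shape (n_samples, 4) in (E, sigma_E, s, alpha) order.
    Inputs are centred on the training mean shape and scaled by a per-profile
    scalar SD; targets are z-scored (both undone at prediction).  A seeded
    20% validation split monitors training and the weights with the lowest
    validation loss are restored at the end.
    """
    if len(profile_sets) < 10:
        raise ValueError(f"need at least 10 training rows, got {len(profile_sets)}")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (len(profile_sets), 4):
        raise ValueError(f"targets shape {targets.shape} != ({len(profile_sets)}, 4)")
    labels = tuple(p.spec.label() for p in profile_sets[0])
    lengths = tuple(p.spec.n_points for p in profile_sets[0])
    for ps in profile_sets:
        if tuple(p.spec.label() for p in ps) != labels:
            raise ValueError("profile sets have inconsistent profile selections")
    if spec is None:
        spec = DeepModelSpec(
            input_lengths=lengths, profile_labels=labels, **spec_overrides
        )

    X = [_profile_matrix(profile_sets, i) for i in range(len(labels))]
    centers, scales, Xz = [], [], []
    for xi in X:
        c = xi.mean(axis=0)
        s = float((xi - c).std())
        s = s if s > 0 else 1.0
        centers.append(c)
        scales.append(s)
        Xz.append(((xi - c) / s).astype(np.float32))
    t_mean = targets.mean(axis=0)
    t_scale = targets.std(axis=0, ddof=1)
    t_scale[t_scale == 0] = 1.0
    Yz = (targets - t_mean) / t_scale

    rng = np.random.default_rng(seed)
    net = MultiEncoderNet(spec, seed=seed)
    opt = nn.Adam(net.params(), lr=spec.learning_rate)

    n = len(profile_sets)
    perm = rng.permutation(n)
    n_val = max(1, int(round(spec.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xval = [xi[val_idx] for xi in Xz]
    Yval = Yz[val_idx]

    history = []
    best_val, best_weights, best_epoch = np.inf, net.get_weights(), -1
    for epoch in range(spec.epochs):
        order = rng.permutation(tr_idx)
        train_loss, n_batches = 0.0, 0
        for start in range(0, len(order), spec.batch_size):
            batch = order[start : start + spec.batch_size]
            opt.zero_grad()
            pred = net.forward([xi[batch] for xi in Xz])
            loss, dl = nn.mse_loss(pred, Yz[batch].astype(np.float32))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}: {loss}"
                )
            net.backward(dl)
            opt.step()
            train_loss += loss
            n_batches += 1
        val_pred = net.forward(Xval)
        val_loss, _ = nn.mse_loss(val_pred, Yval.astype(np.float32))
        history.append(
            {"epoch": epoch + 1, "train_loss": train_loss / max(n_batches, 1),
             "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val, best_weights, best_epoch = val_loss, net.get_weights(), epoch + 1
    net.set_weights(best_weights)
    return TrainedDeepModel(
        net=net,
        input_centers=centers,
        input_scales=scales,
        target_mean=t_mean,
        target_scale=t_scale,
        hypercube=np.asarray(hypercube, dtype=float),
        profile_labels=labels,
        history=history,
        best_epoch=best_epoch,
    )


def predict_deep(model: TrainedDeepModel, profile_set: ProfileSet) -> Prediction:
    """Predict (E, sigma_E, s, alpha) from raw profiles; clipped into H.

    Inputs are positional: the profile selection and lattices must match
    the training configuration exactly.
    """
    labels = tuple(p.spec.label() for p in profile_set)
    if labels != model.profile_labels:
        raise ValueError(
            f"profile selection {labels} does not match the model's "
            f"training selection {model.profile_labels}"
        )
    inputs = []
    for p, c, s, n in zip(
        profile_set, model.input_centers, model.input_scales, model.spec.input_lengths
    ):
        if p.spec.n_points != n:
            raise ValueError(
                f"profile {p.spec.label()}: lattice length {p.spec.n_points} "
                f"does not match training length {n}"
            )
        inputs.append(((p.doses - c) / s)[None, :].astype(np.float32))
    raw = model.net.forward(inputs)[0]
    vals = raw * model.target_scale + model.target_mean
    lo, hi = model.hypercube[:, 0], model.hypercube[:, 1]
    clipped_vals = np.clip(vals, lo, hi)
    flags = {
        name: bool(abs(clipped_vals[j] - vals[j]) > 0)
        for j, name in enumerate(PARAM_NAMES)
    }
    return Prediction(params=BeamParameters.from_array(clipped_vals), clipped=flags)


def save_deep(model: TrainedDeepModel, path) -> None:
    """Persist weights + architecture/scaler metadata as a single .npz."""
    spec = model.spec
    meta = {
        "format": "beamtune-deep",
        "version": _FORMAT_VERSION,
        "spec": {
            "input_lengths": list(spec.input_lengths),
            "profile_labels": list(spec.profile_labels),
            "base_filters": spec.base_filters,
            "kernel": spec.kernel,
            "pool": spec.pool,
            "head_widths": list(spec.head_widths),
            "n_outputs": spec.n_outputs,
            "epochs": spec.epochs,
            "learning_rate": spec.learning_rate,
            "batch_size": spec.batch_size,
            "val_fraction": spec.val_fraction,
        },
        "profile_labels": list(model.profile_labels),
        "input_scales": list(model.input_scales),
        "best_epoch": model.best_epoch,
        "history": model.history,
    }
    arrays = {
        "target_mean": model.target_mean,
        "target_scale": model.target_scale,
        "hypercube": model.hypercube,
    }
    for i, c in enumerate(model.input_centers):
        arrays[f"center_{i}"] = c
    for i, w in enumerate(model.net.get_weights()):
        arrays[f"w_{i}"] = w
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_deep(path) -> TrainedDeepModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format") != "beamtune-deep":
            raise ValueError(f"{path}: not a beamtune deep-model file")
        if meta.get("version") != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported version {meta.get('version')}")
        s = meta["spec"]
        spec = DeepModelSpec(
            input_lengths=tuple(s["input_lengths"]),
            profile_labels=tuple(s["profile_labels"]),
            base_filters=s["base_filters"],
            kernel=s["kernel"],
            pool=s["pool"],
            head_widths=tuple(s["head_widths"]),
            n_outputs=s["n_outputs"],
            epochs=s["epochs"],
            learning_rate=s["learning_rate"],
            batch_size=s["batch_size"],
            val_fraction=s["val_fraction"],
        )
        net = MultiEncoderNet(spec, seed=0)
        weights = [data[f"w_{i}"] for i in range(len(net.params()))]
        net.set_weights(weights)
        centers = [data[f"center_{i}"] for i in range(len(spec.input_lengths))]
        return TrainedDeepModel(
            net=net,
            input_centers=centers,
            input_scales=list(meta["input_scales"]),
            target_mean=data["target_mean"],
            target_scale=data["target_scale"],
            hypercube=data["hypercube"],
            profile_labels=tuple(meta["profile_labels"]),
            history=meta["history"],
            best_epoch=meta["best_epoch"],
        )
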