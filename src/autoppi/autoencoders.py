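"""Fully-connected autoencoders over protein-pair feature vectors.

Three architectures reconstruct a pair (p, p') given its 2k-dimensional
feature representation:

* ``joint_joint`` — a plain autoencoder on the concatenated pair vector:
  encoder 2k -> 600 -> 600 -> 300, mirrored decoder back to 2k.
* ``siamese_joint`` — a shared (siamese) encoder k -> 600 -> 600 -> 300 maps
  each protein to a latent code (z, z'); the decoder reconstructs the full 2k
  pair from the 600-wide concatenation [z | z'].
* ``siamese_siamese`` — shared encoder as above; the combined code
  ẑ = z ⊙ z' (element-wise product) is concatenated with each protein's own
  code and a shared decoder reconstructs p from [z | ẑ] and p' from [z' | ẑ].

All hidden layers use SELU with LeCun-normal initialization; outputs are
linear (features are real-valued).  Training minimizes mean squared
reconstruction error with Adam (initial learning rate 5e-4, batch size 64),
halving the learning rate after 5 epochs without validation-loss improvement
down to a floor of 1e-5.  Everything is implemented in float32 NumPy and is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

ARCHITECTURES = ("joint_joint", "siamese_joint", "siamese_siamese")

_SELU_ALPHA = 1.6732632423543772848170429916717
_SELU_SCALE = 1.0507009873554804934193349852946

DTYPE = np.float32


class ModelError(ValueError):
    """Raised for invalid architecture tags, dimension mismatches, or
    training failures (non-finite loss)."""


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x)).astype(x.dtype)


class _MLP:
    """A dense stack with SELU hidden activations.

    ``out_selu`` controls whether the final layer is also SELU (used for the
    encoder bottleneck) or linear (reconstruction outputs).
    """

    def __init__(self, widths: Sequence[int], rng: np.random.Generator, out_selu: bool):
        self.widths = list(widths)
        self.out_selu = out_selu
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # LeCun normal: the init SELU's self-normalization assumes
            std = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.normal(0.0, std, size=(fan_in, fan_out)).astype(DTYPE))
            self.b.append(np.zeros(fan_out, dtype=DTYPE))
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def set_params(self, arrays: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [a.astype(DTYPE) for a in arrays[:n]]
        self.b = [a.astype(DTYPE) for a in arrays[n:]]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = []
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = x @ W + b
            activated = self.out_selu or i < last
            y = selu(z) if activated else z
            if train:
                self._cache.append((x, z))
            x = y
        return x

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop through the cached forward pass; returns (dx, grads)
        with grads ordered like :meth:`params`."""
        dW: list[np.ndarray] = [None] * len(self.W)  # type: ignore[list-item]
        db: list[np.ndarray] = [None] * len(self.b)  # type: ignore[list-item]
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            x, z = self._cache[i]
            activated = self.out_selu or i < last
            dz = dy * selu_grad(z) if activated else dy
            dW[i] = x.T @ dz
            db[i] = dz.sum(axis=0)
            dy = dz @ self.W[i].T
        return dy, [*dW, *db]


@dataclass
class AutoencoderModel:
    """A built (possibly trained) autoencoder for one pair class.

    ``k`` is the per-protein feature length; the model consumes row matrices
    of pair vectors of width 2k regardless of architecture (siamese variants
    split the halves internally).
    """

    architecture: str
    k: int
    hidden: tuple[int, int] = (600, 600)
    bottleneck: int = 300
    seed: int = 0
    _nets: dict = field(default_factory=dict, repr=False)

    def params(self) -> list[np.ndarray]:
        out = []
        for net in self._nets.values():
            out.extend(net.params())
        return out

    # ------------------------------------------------------------------ forward
    def _check_input(self, pairs: np.ndarray) -> np.ndarray:
        pairs = np.asarray(pairs, dtype=DTYPE)
        if pairs.ndim == 1:
            pairs = pairs[None, :]
        if pairs.shape[1] != 2 * self.k:
            raise ModelError(
                f"expected pair vectors of width {2 * self.k}, got {pairs.shape[1]}"
            )
        return pairs

    def reconstruct(self, pairs: np.ndarray, train: bool = False) -> np.ndarray:
        """Reconstruct pair vectors; output shape matches input (n, 2k)."""
        X = self._check_input(pairs)
        k, B = self.k, X.shape[0]
        if self.architecture == "joint_joint":
            return self._nets["net"].forward(X, train=train)
        Xa, Xb = X[:, :k], X[:, k:]
        enc = self._nets["enc"]
        Z = enc.forward(np.vstack([Xa, Xb]), train=train)
        za, zb = Z[:B], Z[B:]
        if self.architecture == "siamese_joint":
            return self._nets["dec"].forward(np.hstack([za, zb]), train=train)
        # siamese_siamese: combined code ẑ = z ⊙ z'
        zh = za * zb
        dec_in = np.vstack([np.hstack([za, zh]), np.hstack([zb, zh])])
        R = self._nets["dec"].forward(dec_in, train=train)
        if train:
            self._ss_cache = (za, zb)
        return np.hstack([R[:B], R[B:]])

    def losses(self, pairs: np.ndarray) -> np.ndarray:
        """Per-pair mean squared reconstruction error (vector of length n)."""
        X = self._check_input(pairs)
        R = self.reconstruct(X)
        return np.mean((R.astype(np.float64) - X) ** 2, axis=1)

    # ----------------------------------------------------------------- backward
    def loss_and_grads(self, pairs: np.ndarray) -> tuple[float, list[np.ndarray]]:
        """Batch-mean MSE and its gradient w.r.t. every parameter."""
        X = self._check_input(pairs)
        k, B = self.k, X.shape[0]
        R = self.reconstruct(X, train=True)
        diff = R - X
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dR = (2.0 / diff.size) * diff  # d(mean sq err)/dR

        if self.architecture == "joint_joint":
            _, grads = self._nets["net"].backward(dR)
            return loss, grads

        enc, dec = self._nets["enc"], self._nets["dec"]
        if self.architecture == "siamese_joint":
            dIn, dec_g = dec.backward(dR)
            dZ = np.vstack([dIn[:, : self.bottleneck], dIn[:, self.bottleneck :]])
            _, enc_g = enc.backward(dZ)
            return loss, enc_g + dec_g

        # siamese_siamese: undo the [Ra | Rb] hstack, then the ẑ product
        za, zb = self._ss_cache
        dR_stacked = np.vstack([dR[:, :k], dR[:, k:]])
        dIn, dec_g = dec.backward(dR_stacked)
        m = self.bottleneck
        dIa, dIb = dIn[:B], dIn[B:]
        dzh = dIa[:, m:] + dIb[:, m:]
        dza = dIa[:, :m] + dzh * zb
        dzb = dIb[:, :m] + dzh * za
        _, enc_g = enc.backward(np.vstack([dza, dzb]))
        return loss, enc_g + dec_g

    def set_params(self, arrays: list[np.ndarray]) -> None:
        i = 0
        for net in self._nets.values():
            n = len(net.params())
            net.set_params(arrays[i : i + n])
            i += n


def build_autoencoder(
    arch: str,
    k: int,
    seed: int,
    hidden: tuple[int, int] = (600, 600),
    bottleneck: int = 300,
) -> AutoencoderModel:
    """Construct an untrained autoencoder with seeded LeCun-normal weights.

    ``hidden``/``bottleneck`` default to the full-size (600, 600)/300 stack
    and may be narrowed for small-feature experiments.
    """
    if arch not in ARCHITECTURES:
        raise ModelError(f"unknown architecture {arch!r}; expected one of {ARCHITECTURES}")
    if k < 1:
        raise ModelError("k must be >= 1")
    rng = np.random.default_rng(seed)
    h1, h2 = hidden
    m = bottleneck
    model = AutoencoderModel(architecture=arch, k=k, hidden=(h1, h2), bottleneck=m, seed=seed)
    if arch == "joint_joint":
        model._nets["net"] = _MLP(
            [2 * k, h1, h2, m, h2, h1, 2 * k], rng, out_selu=False
        )
    else:
        model._nets["enc"] = _MLP([k, h1, h2, m], rng, out_selu=True)
        out_dim = 2 * k if arch == "siamese_joint" else k
        model._nets["dec"] = _MLP([2 * m, h2, h1, out_dim], rng, out_selu=False)
    return model


def reconstruction_loss(model: AutoencoderModel, pair: np.ndarray) -> float:
    """MSE reconstruction loss of a single pair vector (the L of the
    probability formula).  For the siamese-siamese variant this equals the
    mean of the two per-protein MSEs."""
    return float(model.losses(np.asarray(pair))[0])


# --------------------------------------------------------------------- training


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    Defaults are the full-scale settings (2000 epochs, batch 64, Adam at
    5e-4, halve-on-plateau after 5 stagnant epochs down to 1e-5, 10%
    validation split).  Use :data:`DESK_SCALE` for quick experiments.
    """

    epochs: int = 2000
    batch_size: int = 64
    initial_learning_rate: float = 5e-4
    plateau_patience: int = 5
    lr_reduction_factor: float = 2.0
    min_learning_rate: float = 1e-5
    validation_fraction: float = 0.10
    seed: int = 0
    checkpoint_best: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ModelError("validation_fraction must be in (0, 1)")
        if self.min_learning_rate > self.initial_learning_rate:
            raise ModelError("min_learning_rate exceeds initial_learning_rate")
        for name in ("epochs", "batch_size", "plateau_patience"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be a positive integer")


#: Reduced-epoch preset for desk-scale experiments (layer widths unchanged).
DESK_SCALE = TrainingConfig(epochs=50)


class _Adam:
    def __init__(self, params: list[np.ndarray]):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)


def train_autoencoder(
    model: AutoencoderModel,
    data: np.ndarray,
    config: TrainingConfig,
) -> tuple[AutoencoderModel, list[dict]]:
    """Train in place; returns the model and a per-epoch log.

    The log rows carry ``epoch``, ``train_loss``, ``val_loss`` and ``lr``.
    A seeded validation split drives the plateau schedule ("improvement" =
    strictly lower validation loss than the best seen).  Final-epoch weights
    are kept unless ``config.checkpoint_best`` restores the best-validation
    snapshot.
    """
    X = np.asarray(data, dtype=DTYPE)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[0] == 0:
        raise ModelError("training data is empty")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    if 0 < n_val < n:
        val, train = X[perm[:n_val]], X[perm[n_val:]]
    else:  # too few rows to carve a split: validate on the training data
        val, train = X[perm], X[perm]

    params = model.params()
    opt = _Adam(params)
    lr = config.initial_learning_rate
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stagnant = 0
    log: list[dict] = []

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train.shape[0])
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, train.shape[0], config.batch_size):
            batch = train[order[start : start + config.batch_size]]
            loss, grads = model.loss_and_grads(batch)
            if not np.isfinite(loss):
                raise ModelError(f"non-finite training loss at epoch {epoch}")
            opt.step(params, grads, lr)
            epoch_loss += loss
            n_batches += 1
        val_loss = float(np.mean(model.losses(val)))
        if not np.isfinite(val_loss):
            raise ModelError(f"non-finite validation loss at epoch {epoch}")
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "val_loss": val_loss,
                "lr": lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            stagnant = 0
            if config.checkpoint_best:
                best_params = [p.copy() for p in params]
        else:
            stagnant += 1
            if stagnant >= config.plateau_patience:
                lr = max(lr / config.lr_reduction_factor, config.min_learning_rate)
                stagnant = 0

    if config.checkpoint_best and best_params is not None:
        model.set_params(best_params)
    return model, log


# ------------------------------------------------------------------ checkpoints

_CHECKPOINT_VERSION = 1


def save_checkpoint(
    model: AutoencoderModel, path: str | Path, fingerprint: str = ""
) -> None:
    """Single-file .npz archive: versioned metadata header plus weights."""
    meta = {
        "version": _CHECKPOINT_VERSION,
        "architecture": model.architecture,
        "k": model.k,
        "hidden": list(model.hidden),
        "bottleneck": model.bottleneck,
        "seed": model.seed,
        "fingerprint": fingerprint,
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[AutoencoderModel, str]:
    """Inverse of :func:`save_checkpoint`; returns (model, fingerprint)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ModelError(f"unsupported checkpoint version {meta['version']}")
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    model = build_autoencoder(
        meta["architecture"],
        meta["k"],
        meta["seed"],
        hidden=tuple(meta["hidden"]),
        bottleneck=meta["bottleneck"],
    )
    model.set_params(arrays)
    return model, meta["fingerprint"]


def desk_scale_config(**overrides) -> TrainingConfig:
    """A copy of :data:`DESK_SCALE` with field overrides."""
    return replace(DESK_SCALE, **overrides)
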