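"""Two-autoencoder interaction classifier.

One autoencoder (AE+) is trained only on interacting pairs, the other (AE-)
only on non-interacting pairs.  A new pair (p, p') is scored by both; with
L+ and L- the per-pair mean squared reconstruction errors, the probability
that the pair does NOT interact is

    pr-(p, p') = 0.5 + (L+ - L-) / (2 * (L+ + L-)),      pr+ = 1 - pr-.

A pair is called interacting exactly when L+ < L- (pr+ > 0.5); ties —
including the degenerate L+ = L- = 0 where the ratio is 0/0 and symmetry
forces pr = 0.5 — are called non-interacting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoders import (
    AutoencoderModel,
    ModelError,
    TrainingConfig,
    build_autoencoder,
    load_checkpoint,
    save_checkpoint,
    train_autoencoder,
)


@dataclass(frozen=True)
class PredictionResult:
    """Per-pair losses, class probabilities and the decided label."""

    id_a: str
    id_b: str
    loss_pos: float
    loss_neg: float
    pr_pos: float
    pr_neg: float
    label: bool  # True = interacting


@dataclass
class AutoPPIModel:
    """The trained (AE+, AE-) ensemble plus the descriptor fingerprint it
    expects its inputs to be featurized under."""

    ae_pos: AutoencoderModel
    ae_neg: AutoencoderModel
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.ae_pos.architecture != self.ae_neg.architecture:
            raise ModelError("the two autoencoders must share an architecture")
        if self.ae_pos.k != self.ae_neg.k:
            raise ModelError("the two autoencoders must share the feature length k")

    @property
    def architecture(self) -> str:
        return self.ae_pos.architecture

    @property
    def k(self) -> int:
        return self.ae_pos.k


def pair_probabilities(loss_pos: float, loss_neg: float) -> tuple[float, float]:
    """Closed-form class probabilities (pr_pos, pr_neg) from the two losses.

    Defined for any L+, L- >= 0; the 0/0 case at L+ = L- = 0 resolves to
    (0.5, 0.5) by symmetry.
    """
    if loss_pos < 0 or loss_neg < 0:
        raise ValueError("reconstruction losses must be non-negative")
    total = loss_pos + loss_neg
    if total == 0.0:
        return 0.5, 0.5
    pr_neg = 0.5 + (loss_pos - loss_neg) / (2.0 * total)
    pr_neg = min(max(pr_neg, 0.0), 1.0)  # clamp float round-off at the edges
    return 1.0 - pr_neg, pr_neg


def fit(
    train_pos: np.ndarray,
    train_neg: np.ndarray,
    arch: str,
    tconfig: TrainingConfig,
    k: int | None = None,
    fingerprint: str = "",
    hidden: tuple[int, int] = (600, 600),
    bottleneck: int = 300,
) -> tuple[AutoPPIModel, dict]:
    """Train AE+ on the positive pair vectors and AE- on the negative ones.

    Both autoencoders get the same hyperparameters and architecture but
    independent validation splits (derived seeds).  Returns the model and a
    dict of the two training logs.
    """
    train_pos = np.asarray(train_pos)
    train_neg = np.asarray(train_neg)
    if train_pos.size == 0 or train_neg.size == 0:
        raise ModelError("both the positive and negative class need training pairs")
    if k is None:
        k = train_pos.shape[1] // 2

    seeds = np.random.SeedSequence(tconfig.seed).spawn(2)
    logs = {}
    models = []
    for name, data, ss in (("pos", train_pos, seeds[0]), ("neg", train_neg, seeds[1])):
        seed = int(ss.generate_state(1)[0] % (2**31))
        ae = build_autoencoder(arch, k, seed, hidden=hidden, bottleneck=bottleneck)
        cfg = TrainingConfig(**{**tconfig.__dict__, "seed": seed})
        ae, log = train_autoencoder(ae, data, cfg)
        models.append(ae)
        logs[name] = log
    return AutoPPIModel(ae_pos=models[0], ae_neg=models[1], fingerprint=fingerprint), logs


def predict_proba(
    model: AutoPPIModel,
    pair: np.ndarray,
    id_a: str = "",
    id_b: str = "",
    fingerprint: str | None = None,
) -> PredictionResult:
    """Score one featurized pair; label is interacting iff L+ < L-."""
    if fingerprint is not None and model.fingerprint and fingerprint != model.fingerprint:
        raise ModelError(
            "pair was featurized under a different descriptor config than the model"
        )
    loss_pos = float(model.ae_pos.losses(pair)[0])
    loss_neg = float(model.ae_neg.losses(pair)[0])
    pr_pos, pr_neg = pair_probabilities(loss_pos, loss_neg)
    return PredictionResult(
        id_a=id_a,
        id_b=id_b,
        loss_pos=loss_pos,
        loss_neg=loss_neg,
        pr_pos=pr_pos,
        pr_neg=pr_neg,
        label=loss_pos < loss_neg,
    )


def predict_batch(
    model: AutoPPIModel,
    pairs: np.ndarray,
    ids: list[tuple[str, str]] | None = None,
) -> list[PredictionResult]:
    """Vectorized scoring of a pair matrix (rows = pairs), order preserved."""
    pairs = np.asarray(pairs)
    if pairs.size == 0:
        return []
    if pairs.ndim == 1:
        pairs = pairs[None, :]
    if ids is None:
        ids = [("", "")] * pairs.shape[0]
    lp = model.ae_pos.losses(pairs)
    ln = model.ae_neg.losses(pairs)
    out = []
    for (ia, ib), a, b in zip(ids, lp, ln):
        pr_pos, pr_neg = pair_probabilities(float(a), float(b))
        out.append(
            PredictionResult(
                id_a=ia,
                id_b=ib,
                loss_pos=float(a),
                loss_neg=float(b),
                pr_pos=pr_pos,
                pr_neg=pr_neg,
                label=a < b,
            )
        )
    return out


def predictions_to_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "idA": [r.id_a for r in results],
            "idB": [r.id_b for r in results],
            "loss_pos": [r.loss_pos for r in results],
            "loss_neg": [r.loss_neg for r in results],
            "pr_pos": [r.pr_pos for r in results],
            "pr_neg": [r.pr_neg for r in results],
            "label": [int(r.label) for r in results],
        }
    )


def write_predictions(results: list[PredictionResult], path: str | Path) -> None:
    predictions_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.8g")


def save_model(model: AutoPPIModel, directory: str | Path) -> None:
    """Model bundle: two checkpoints plus a shared metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model.ae_pos, directory / "ae_pos.npz", model.fingerprint)
    save_checkpoint(model.ae_neg, directory / "ae_neg.npz", model.fingerprint)
    (directory / "metadata.json").write_text(
        json.dumps(
            {
                "architecture": model.architecture,
                "k": model.k,
                "fingerprint": model.fingerprint,
            },
            indent=2,
        )
    )


def load_model(directory: str | Path) -> AutoPPIModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    ae_pos, fp = load_checkpoint(directory / "ae_pos.npz")
    ae_neg, _ = load_checkpoint(directory / "ae_neg.npz")
    model = AutoPPIModel(ae_pos=ae_pos, ae_neg=ae_neg, fingerprint=fp)
    if model.architecture != meta["architecture"] or model.k != meta["k"]:
        raise ModelError("bundle metadata disagrees with its checkpoints")
    return model
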