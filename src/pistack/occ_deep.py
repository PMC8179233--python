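"""Deep one-class model: permutation-invariant set encoder + fixed-center hypersphere.

The encoder treats a pair as a *set* of two molecule vectors: a shared
per-molecule MLP (phi) embeds each molecule, the embeddings are mean-pooled
(the source of exact order invariance) and a head MLP (rho) maps the pooled
embedding to the latent space.  Training follows the two-phase protocol:

1. pretrain as an autoencoder (permutation-minimal reconstruction loss),
   then fix the hypersphere center as the mean latent representation of the
   training pairs;
2. fine-tune the encoder alone to minimize the mean squared Euclidean
   distance of latent representations to that fixed center.

Collapse guards: the closing encoder layer has no bias, the center is never
trainable, and weight decay regularizes the weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Linear, Sequential, Tanh


@dataclass
class EncoderConfig:
    """Architecture and training settings for the deep one-class model.

    ``n_features`` is the per-molecule descriptor count d (a pair vector has
    length 2d).  Defaults are deliberately small so the model trains on one
    CPU in seconds-to-minutes.
    """

    n_features: int
    hidden_dim: int = 64
    latent_dim: int = 16
    epochs_pretrain: int = 100
    epochs_train: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


class CollapseWarning(UserWarning):
    """Raised as a warning when the latent representation has collapsed."""


class SetEncoder:
    """Shared phi, symmetric pooling [mean, |difference|], head rho.

    Both pooling statistics are symmetric in the two set elements, so the
    latent representation is *exactly* invariant under swapping the molecules;
    the absolute-difference channel exposes cross-co-former structure that a
    mean alone would wash out.  The closing rho layer carries no bias
    (collapse guard).
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d, h, z = config.n_features, config.hidden_dim, config.latent_dim
        self.config = config
        self.phi = Sequential([Linear(d, h, rng), Tanh(), Linear(h, h, rng), Tanh()])
        self.rho = Sequential([Linear(2 * h, h, rng), Tanh(), Linear(h, z, rng, bias=False)])

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (n, 2, d) -> latent (n, latent_dim). Caches for backward."""
        n = X.shape[0]
        emb = self.phi.forward(X.reshape(2 * n, -1)).reshape(n, 2, -1)
        diff = emb[:, 0, :] - emb[:, 1, :]
        self._diff_sign = np.sign(diff)
        pooled = np.concatenate([emb.mean(axis=1), np.abs(diff)], axis=1)
        return self.rho.forward(pooled)

    def backward(self, grad_z: np.ndarray) -> None:
        grad_pooled = self.rho.backward(grad_z)
        h = grad_pooled.shape[1] // 2
        g_mean, g_absdiff = grad_pooled[:, :h], grad_pooled[:, h:]
        n = grad_z.shape[0]
        grad_emb = np.empty((n, 2, h))
        grad_emb[:, 0, :] = g_mean / 2.0 + g_absdiff * self._diff_sign
        grad_emb[:, 1, :] = g_mean / 2.0 - g_absdiff * self._diff_sign
        self.phi.backward(grad_emb.reshape(2 * n, h))

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent representations for (n, 2, d) or flat (n, 2d) inputs."""
        return self.forward(as_pair_sets(X, self.config.n_features))

    def modules(self):
        return [self.phi, self.rho]


class SetDecoder:
    """Latent -> reconstruction of the two molecule vectors (n, 2, d)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d, h, z = config.n_features, config.hidden_dim, config.latent_dim
        self.n_features = d
        self.net = Sequential([Linear(z, h, rng), Tanh(), Linear(h, 2 * d, rng)])

    def forward(self, Z: np.ndarray) -> np.ndarray:
        out = self.net.forward(Z)
        return out.reshape(Z.shape[0], 2, self.n_features)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad.reshape(grad.shape[0], -1))

    def modules(self):
        return [self.net]


@dataclass
class HypersphereModel:
    """Fitted deep one-class model: encoder + frozen center + training report."""

    encoder: SetEncoder
    center: np.ndarray
    pretrain_losses: list[float] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)

    def distance(self, X: np.ndarray) -> np.ndarray:
        """Squared Euclidean distance of latent representations to the center."""
        Z = self.encoder.encode(X)
        return np.sum((Z - self.center) ** 2, axis=1)

    def raw_score(self, X: np.ndarray) -> np.ndarray:
        """Oriented raw score = -distance (higher = more inlier)."""
        return -self.distance(X)

    def manifest(self) -> str:
        cfg = self.encoder.config
        return json.dumps(
            {
                "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
                "center": self.center.tolist(),
                "final_pretrain_loss": self.pretrain_losses[-1] if self.pretrain_losses else None,
                "final_train_loss": self.train_losses[-1] if self.train_losses else None,
            }
        )


def as_pair_sets(X: np.ndarray, n_features: int) -> np.ndarray:
    """Reshape flat (n, 2d) pair vectors into (n, 2, d) sets; pass (n,2,d) through."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        if X.shape[1:] != (2, n_features):
            raise ValueError(f"expected (n, 2, {n_features}), got {X.shape}")
        return X
    if X.ndim == 2 and X.shape[1] == 2 * n_features:
        return X.reshape(X.shape[0], 2, n_features)
    raise ValueError(f"cannot interpret shape {X.shape} as pairs of {n_features}-vectors")


def _iter_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def pretrain_autoencoder(
    config: EncoderConfig, pairs_X: np.ndarray
) -> tuple[SetEncoder, SetDecoder, list[float]]:
    """Phase 1: train encoder+decoder to reconstruct the two molecule vectors.

    The reconstruction loss is the minimum over the two possible assignments
    of decoder outputs to set elements, so the objective itself is
    order-invariant.  Returns (encoder, decoder, per-epoch MSE losses); with
    ``epochs_pretrain=0`` the initialized, untrained state is returned with a
    single reported loss.
    """
    X = as_pair_sets(pairs_X, config.n_features)
    rng = np.random.default_rng(config.seed)
    encoder = SetEncoder(config, rng)
    decoder = SetDecoder(config, rng)
    opt = Adam(
        encoder.modules() + decoder.modules(),
        lr=config.lr,
        weight_decay=config.weight_decay,
    )
    losses: list[float] = []
    if config.epochs_pretrain == 0:
        losses.append(_recon_loss(encoder, decoder, X))
        return encoder, decoder, losses
    for _ in range(config.epochs_pretrain):
        epoch_loss = 0.0
        for idx in _iter_minibatches(X.shape[0], config.batch_size, rng):
            xb = X[idx]
            z = encoder.forward(xb)
            recon = decoder.forward(z)
            err_id = np.sum((recon - xb) ** 2, axis=(1, 2))
            err_sw = np.sum((recon - xb[:, ::-1, :]) ** 2, axis=(1, 2))
            swap = err_sw < err_id
            target = np.where(swap[:, None, None], xb[:, ::-1, :], xb)
            loss = float(np.minimum(err_id, err_sw).sum())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite pretraining loss (lr={config.lr}, "
                    f"batch_size={config.batch_size})"
                )
            grad = 2.0 * (recon - target) / (xb.shape[0] * xb.shape[1] * xb.shape[2])
            encoder.backward(decoder.backward(grad))
            opt.step()
            epoch_loss += loss
        losses.append(epoch_loss / X.size)
    return encoder, decoder, losses


def _recon_loss(encoder: SetEncoder, decoder: SetDecoder, X: np.ndarray) -> float:
    recon = decoder.forward(encoder.forward(X))
    err_id = np.sum((recon - X) ** 2, axis=(1, 2))
    err_sw = np.sum((recon - X[:, ::-1, :]) ** 2, axis=(1, 2))
    return float(np.minimum(err_id, err_sw).sum() / X.size)


def compute_center(encoder: SetEncoder, pairs_X: np.ndarray) -> np.ndarray:
    """Hypersphere center = mean latent representation of the training pairs."""
    X = as_pair_sets(pairs_X, encoder.config.n_features)
    if X.shape[0] == 0:
        raise ValueError("cannot compute the center of an empty training set")
    return encoder.encode(X).mean(axis=0)


def train_one_class(
    encoder: SetEncoder,
    center: np.ndarray,
    pairs_X: np.ndarray,
    config: EncoderConfig | None = None,
    pretrain_losses: list[float] | None = None,
) -> HypersphereModel:
    """Phase 2: minimize mean squared latent distance to the fixed center.

    The decoder is discarded; the center is frozen.  Emits a
    :class:`CollapseWarning` if the representation collapses (all training
    distances ~ 0).
    """
    config = config or encoder.config
    X = as_pair_sets(pairs_X, config.n_features)
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(encoder.modules(), lr=config.lr, weight_decay=config.weight_decay)
    losses: list[float] = []
    for _ in range(config.epochs_train):
        epoch_loss = 0.0
        for idx in _iter_minibatches(X.shape[0], config.batch_size, rng):
            xb = X[idx]
            z = encoder.forward(xb)
            diff = z - center
            loss = float(np.sum(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite hypersphere loss (lr={config.lr}, "
                    f"batch_size={config.batch_size})"
                )
            encoder.backward(2.0 * diff / xb.shape[0])
            opt.step()
            epoch_loss += loss
        losses.append(epoch_loss / X.shape[0])
    model = HypersphereModel(
        encoder=encoder,
        center=center,
        pretrain_losses=list(pretrain_losses or []),
        train_losses=losses,
    )
    if float(np.mean(model.distance(X))) < 1e-10:
        warnings.warn(
            "latent representation may have collapsed (training distances ~ 0); "
            "lower weight decay / epochs or check planted-outlier distances",
            CollapseWarning,
            stacklevel=2,
        )
    return model


def fit_deep_one_class(config: EncoderConfig, pairs_X: np.ndarray) -> HypersphereModel:
    """Convenience: pretrain, fix the center, fine-tune; returns the fitted model."""
    encoder, _, pre_losses = pretrain_autoencoder(config, pairs_X)
    center = compute_center(encoder, pairs_X)
    return train_one_class(encoder, center, pairs_X, config, pretrain_losses=pre_losses)


def score_deep(
    model: HypersphereModel,
    pairs_X: np.ndarray,
    reference_X: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized deep scores in [0,1]: min-max of (-distance) over a reference.

    1 = closest-to-center point of the reference set, 0 = farthest.  The
    reference defaults to the scored pairs; by convention it is the union of
    labelled + candidate pairs.  Scores are symmetric under orientation swap
    by architecture.
    """
    raw = model.raw_score(pairs_X)
    ref = raw if reference_X is None else model.raw_score(reference_X)
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        warnings.warn("constant reference distances; mapping all to 0.5", stacklevel=2)
        return np.full(raw.shape, 0.5)
    return (raw - lo) / (hi - lo)
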