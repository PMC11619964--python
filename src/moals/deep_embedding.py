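"""Variational-autoencoder deep embedding over concatenated omics blocks.

All omics layers are min-max scaled to [0,1] (statistics learned on
training samples only), concatenated, and encoded by a fully connected
network into a Gaussian posterior q(z|x) = N(mu(x), diag(sigma(x)^2)). A
mirrored decoder ends in a sigmoid so the reconstruction loss can be
binary cross-entropy per block. The embedding loss is

    L_embed = (1/M) sum_j BCE(x_j, x_j') + KL(N(mu, sigma) || N(0, I))

with M omics blocks, BCE averaged over elements within each block, and the
closed-form Gaussian KL averaged over the batch. Sampling uses the
reparameterization z = mu + sigma * eps with eps ~ N(0, I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import MLP, Dense, ReLU
from .io_formats import OmicsBlock


# ---------------------------------------------------------------------------
# input scaling


class MinMaxClipScaler(TransformerMixin, BaseEstimator):
    """Per-feature min-max scaling into [0,1] with clipping of unseen values.

    Features constant on the training data map to 0.5 everywhere (no scale
    information to preserve, and 0.5 is the BCE-neutral midpoint).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        constant = span == 0.0
        safe_span = np.where(constant, 1.0, span)
        out = np.clip((X - self.data_min_) / safe_span, 0.0, 1.0)
        out[:, constant] = 0.5
        return out


def fit_minmax_scaler(block: OmicsBlock, training_sample_ids: Sequence[str]
                      ) -> MinMaxClipScaler:
    """Fit the scaler on a block restricted to the training samples."""
    ids = list(training_sample_ids)
    if not ids:
        raise ValueError("training sample set is empty")
    missing = set(ids) - set(block.samples)
    if missing:
        raise ValueError(f"training ids absent from block: {sorted(missing)[:3]}")
    idx = [block.samples.index(s) for s in ids]
    return MinMaxClipScaler().fit(block.values[idx])


# ---------------------------------------------------------------------------
# probabilistic pieces


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   eps: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I) (or injected for tests)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.standard_normal(mu.shape)
    return mu + sigma * np.asarray(eps, dtype=float)


def kl_closed_form(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag(sigma^2)) || N(0, I) ), closed form.

    KL = 1/2 sum_d (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2). For a 2-D
    input (batch x dim) the per-sample KLs are averaged.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per = 0.5 * (mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=-1)
    return float(np.mean(per))


def bce(x: np.ndarray, p: np.ndarray) -> float:
    """Element-averaged binary cross-entropy of targets x in [0,1] against
    predicted probabilities p in (0,1)."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("BCE targets must lie in [0,1]")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("reconstructions must lie strictly inside (0,1)")
    return float(-np.mean(x * np.log(p) + (1 - x) * np.log1p(-p)))


def embedding_loss(blocks_x: Sequence[np.ndarray],
                   blocks_recon: Sequence[np.ndarray],
                   mu: np.ndarray, sigma: np.ndarray,
                   reduction: str = "sum") -> float:
    """Per-block-averaged BCE reconstruction loss plus the Gaussian KL.

    With ``reduction='sum'`` (default) each block's BCE is the Bernoulli
    negative log-likelihood summed over the block's features and averaged
    over the batch, which keeps the reconstruction term on the same nat
    scale as the KL (the variational bound's likelihood term is a sum
    over dimensions — an element-averaged reconstruction is dominated by
    the KL and drives the posterior to collapse). ``reduction='mean'``
    gives the per-element average instead.
    """
    if len(blocks_x) != len(blocks_recon):
        raise ValueError("mismatched block lists")
    M = len(blocks_x)
    recon = 0.0
    for x, p in zip(blocks_x, blocks_recon):
        per_element = bce(x, p)
        if reduction == "sum":
            width = np.atleast_2d(np.asarray(x)).shape[-1]
            recon += per_element * width / M
        elif reduction == "mean":
            recon += per_element / M
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
    return recon + kl_closed_form(mu, sigma)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# the encoder/decoder network


@dataclass
class EncoderSpec:
    """Architecture of the embedding network."""

    block_widths: dict[str, int]
    hidden_dims: tuple[int, ...] = (512, 256)
    latent_dim: int = 128
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.activation != "relu":
            raise ValueError("only relu is supported")

    @property
    def input_dim(self) -> int:
        return sum(self.block_widths.values())


class VAE:
    """Encoder/decoder pair with hand-written forward and backward passes.

    The encoder trunk is a ReLU MLP whose final hidden representation
    feeds two affine layers producing mu and the half log-variance
    (sigma = exp(logvar / 2), strictly positive by construction). The
    decoder mirrors the trunk and outputs logits; sigmoid is fused into
    the reconstruction loss for stability.
    """

    def __init__(self, spec: EncoderSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d, h, p = spec.input_dim, spec.hidden_dims, spec.latent_dim
        self.trunk = MLP([d, *h], rng)
        self.trunk.layers.append(ReLU())  # activation after the last hidden layer
        self.mu_layer = Dense(h[-1], p, rng)
        self.logvar_layer = Dense(h[-1], p, rng)
        self.decoder = MLP([p, *reversed(h), d], rng)

    # -- forward -----------------------------------------------------------
    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma) for a batch; deterministic."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(f"input width {x.shape[1]} != expected {self.spec.input_dim}")
        hrep = self.trunk.forward(x)
        mu = self.mu_layer.forward(hrep)
        logvar = self.logvar_layer.forward(hrep)
        return mu, np.exp(0.5 * np.minimum(logvar, 60.0))

    def decode_logits(self, z: np.ndarray) -> np.ndarray:
        return self.decoder.forward(np.atleast_2d(z))

    def decode(self, z: np.ndarray) -> np.ndarray:
        return sigmoid(self.decode_logits(z))

    # -- parameter plumbing -------------------------------------------------
    def encoder_params(self):
        return self.trunk.params() + self.mu_layer.params() + self.logvar_layer.params()

    def params(self):
        return self.encoder_params() + self.decoder.params()

    def zero_grad(self) -> None:
        self.trunk.zero_grad()
        self.mu_layer.zero_grad()
        self.logvar_layer.zero_grad()
        self.decoder.zero_grad()

    # -- training-step helpers ----------------------------------------------
    def vae_step(self, x: np.ndarray, block_slices: Sequence[slice],
                 rng: np.random.Generator, backprop: bool = True,
                 kl_weight: float = 1.0) -> tuple[float, np.ndarray, np.ndarray]:
        """One embedding-loss evaluation (and backward pass) on a batch.

        Returns (loss, mu, sigma). Gradients accumulate into the layer
        buffers when ``backprop``; the caller owns zero_grad and the
        optimizer step. ``kl_weight`` scales the KL term: warm-up
        schedules anneal it from 0 to 1 early in unsupervised training to
        avoid posterior collapse (at 1 the loss is the plain embedding
        loss).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        hrep = self.trunk.forward(x)
        mu = self.mu_layer.forward(hrep)
        logvar = self.logvar_layer.forward(hrep)
        sigma = np.exp(0.5 * np.minimum(logvar, 60.0))
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        logits = self.decoder.forward(z)
        p = sigmoid(logits)
        M = len(block_slices)
        recon = 0.0
        dlogits = np.empty_like(logits)
        for sl in block_slices:
            xb, pb = x[:, sl], p[:, sl]
            with np.errstate(divide="ignore"):
                recon += float(-np.sum(
                    xb * np.log(np.clip(pb, 1e-300, None))
                    + (1 - xb) * np.log(np.clip(1 - pb, 1e-300, None)))) / (n * M)
            dlogits[:, sl] = (pb - xb) / (n * M)
        kl = kl_closed_form(mu, sigma)
        loss = recon + kl_weight * kl
        if backprop:
            dz = self.decoder.backward(dlogits)
            dmu = dz + kl_weight * mu / n
            # dKL/dlogvar = (sigma^2 - 1)/(2n); dz flows via sigma = e^{lv/2}
            dlogvar = dz * eps * sigma * 0.5 + kl_weight * (sigma ** 2 - 1.0) / (2.0 * n)
            dh = self.mu_layer.backward(dmu) + self.logvar_layer.backward(dlogvar)
            self.trunk.backward(dh)
        return loss, mu, sigma
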