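"""Three-stage training of the multi-task embedding model with GradNorm.

Stage 1 trains the variational autoencoder alone (unsupervised embedding
loss). Stage 2 freezes the embedding and trains the downstream heads on
the weighted joint loss L_down = (1/K) sum_k W_k L_k. Stage 3 fine-tunes
everything on L_embed + L_down while GradNorm re-balances the task
weights each iteration: with G_k the gradient norm of W_k L_k at the last
encoding layer, Gbar their mean, and r_k the relative inverse training
rate (current loss over initial loss, normalized across tasks),

    L_grad = sum_k | G_k - Gbar * r_k^alpha |

is minimized by a gradient step on the W_k only, after which the weights
are renormalized to sum to K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam
from .deep_embedding import EncoderSpec, VAE, MinMaxClipScaler, fit_minmax_scaler
from .downstream_tasks import (SurvivalLabel, TimeGrid, classification_loss,
                               encode_survival_label, inverse_frequency_weights,
                               make_time_grid, predict_survival_curve,
                               regression_loss, risk_score, survival_loss)
from .io_formats import OmicsBlock, SampleTable

TASKS = ("classification", "regression", "survival")


@dataclass
class TaskWeights:
    """GradNorm state: per-task weights, initial losses, and strength alpha."""

    weights: np.ndarray
    initial_losses: np.ndarray
    alpha: float = 1.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.initial_losses = np.asarray(self.initial_losses, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("task weights must be positive")


@dataclass
class TrainingSchedule:
    """Epoch counts, optimizer settings and the seed for the three stages."""

    stage1_epochs: int = 50     # unsupervised embedding
    stage2_epochs: int = 100    # supervised heads, embedding frozen
    stage3_epochs: int = 50     # joint fine-tuning with GradNorm
    learning_rate: float = 1e-3
    batch_size: int = 32
    gradnorm_alpha: float = 1.5
    gradnorm_lr: float = 0.025
    use_gradnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stage1_epochs, self.stage2_epochs, self.stage3_epochs) < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


# ---------------------------------------------------------------------------
# GradNorm pieces (pure functions)


def joint_downstream_loss(task_losses: Sequence[float],
                          weights: Sequence[float]) -> float:
    """(1/K) sum_k W_k L_k."""
    L = np.asarray(task_losses, dtype=float)
    W = np.asarray(weights, dtype=float)
    if L.shape != W.shape:
        raise ValueError("losses and weights differ in length")
    return float((W * L).mean())


def task_gradient_norms(last_layer_input: np.ndarray,
                        dmu_per_task: Sequence[np.ndarray | None],
                        weights: Sequence[float]) -> np.ndarray:
    """Norm of the gradient of W_k L_k at the last encoding layer, per task.

    ``last_layer_input`` is the cached input of that affine layer;
    ``dmu_per_task`` the gradient of the *unweighted* task loss w.r.t. the
    layer's output. A None entry means the task's loss is detached from
    the embedding, which is an error.
    """
    h = np.atleast_2d(last_layer_input)
    G = np.empty(len(dmu_per_task))
    for k, (dmu, w) in enumerate(zip(dmu_per_task, weights)):
        if dmu is None:
            raise ValueError(f"task {k}: loss not connected through the embedding")
        g = w * np.atleast_2d(dmu)
        gW = h.T @ g
        gb = g.sum(axis=0)
        G[k] = np.sqrt(float((gW ** 2).sum() + (gb ** 2).sum()))
    return G


def gradnorm_loss(G: Sequence[float], initial_losses: Sequence[float],
                  current_losses: Sequence[float], alpha: float = 1.5
                  ) -> tuple[float, np.ndarray]:
    """GradNorm objective and its constant targets Gbar * r_k^alpha.

    The targets are treated as constants (no gradient) in the weight
    update.
    """
    G = np.asarray(G, dtype=float)
    L0 = np.asarray(initial_losses, dtype=float)
    L = np.asarray(current_losses, dtype=float)
    if np.any(L0 <= 0):
        raise ValueError("initial task losses must be positive")
    Ltilde = L / L0
    r = Ltilde / Ltilde.mean()
    targets = G.mean() * r ** alpha
    return float(np.abs(G - targets).sum()), targets


def gradnorm_weight_gradients(G: np.ndarray, targets: np.ndarray,
                              weights: np.ndarray) -> np.ndarray:
    """d L_grad / d W_k with targets constant; G_k is linear in W_k, so
    dG_k/dW_k = G_k / W_k."""
    return np.sign(G - targets) * G / np.asarray(weights, dtype=float)


def update_task_weights(weights: np.ndarray, gradnorm_gradients: np.ndarray,
                        lr_w: float) -> np.ndarray:
    """Gradient step on the W_k only, clipped positive, renormalized to
    sum to K."""
    W = np.asarray(weights, dtype=float) - lr_w * np.asarray(gradnorm_gradients, dtype=float)
    W = np.maximum(W, 1e-4)
    return W * len(W) / W.sum()


# ---------------------------------------------------------------------------
# the estimator


class MoalsNetwork(BaseEstimator):
    """Multi-task variational-autoencoder model over aligned omics blocks.

    ``fit`` consumes a list of OmicsBlocks plus a SampleTable and runs the
    three-stage protocol; prediction methods score new blocks that carry
    the same features. The onset-age regression target is standardized
    internally (stored mean/sd restore the year scale at prediction).

    Parameters mirror the published hyperparameters where stated: latent
    dimension 128, learning rate 1e-3, batch size 32, 50 unsupervised and
    100 supervised epochs.
    """

    def __init__(self, latent_dim: int = 128, hidden_dims: tuple[int, ...] = (512, 256),
                 head_hidden: tuple[int, ...] = (64,), m_intervals: int = 10,
                 grid_strategy: str = "quantile", class_weighted: bool = False,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 stage1_epochs: int = 50, stage2_epochs: int = 100,
                 stage3_epochs: int = 50, gradnorm_alpha: float = 1.5,
                 gradnorm_lr: float = 0.025, use_gradnorm: bool = True,
                 random_state: int = 0):
        self.latent_dim = latent_dim
        self.hidden_dims = hidden_dims
        self.head_hidden = head_hidden
        self.m_intervals = m_intervals
        self.grid_strategy = grid_strategy
        self.class_weighted = class_weighted
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.stage1_epochs = stage1_epochs
        self.stage2_epochs = stage2_epochs
        self.stage3_epochs = stage3_epochs
        self.gradnorm_alpha = gradnorm_alpha
        self.gradnorm_lr = gradnorm_lr
        self.use_gradnorm = use_gradnorm
        self.random_state = random_state

    # -- data plumbing ------------------------------------------------------
    def _scale_blocks(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        parts = []
        for name in self.block_names_:
            block = next((b for b in blocks if b.name == name), None)
            if block is None:
                raise ValueError(f"missing omics block {name!r}")
            if list(block.features) != self.block_features_[name]:
                raise ValueError(f"block {name!r}: feature list differs from training")
            parts.append(self.scalers_[name].transform(block.values))
        return np.concatenate(parts, axis=1)

    # -- fitting ------------------------------------------------------------
    def fit(self, blocks: Sequence[OmicsBlock], samples: SampleTable):
        blocks = [b.reindex_samples(samples.samples) for b in blocks]
        self.block_names_ = [b.name for b in blocks]
        self.block_features_ = {b.name: list(b.features) for b in blocks}
        self.scalers_ = {b.name: MinMaxClipScaler().fit(b.values) for b in blocks}
        widths = {b.name: len(b.features) for b in blocks}
        self.block_slices_ = []
        start = 0
        for name in self.block_names_:
            self.block_slices_.append(slice(start, start + widths[name]))
            start += widths[name]

        X = self._scale_blocks(blocks)
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)

        spec = EncoderSpec(block_widths=widths, hidden_dims=tuple(self.hidden_dims),
                           latent_dim=self.latent_dim,
                           seed=int(rng.integers(2**31)))
        self.encoder_spec_ = spec
        self.vae_ = VAE(spec)

        # targets
        self.classes_ = list(samples.label_names)
        y_class = samples.label
        self.class_weights_ = (inverse_frequency_weights(y_class, len(self.classes_))
                               if self.class_weighted else None)
        onset = samples.onset_age
        onset_mask = np.isfinite(onset)
        self.onset_mean_ = float(onset[onset_mask].mean()) if onset_mask.any() else 0.0
        self.onset_sd_ = float(onset[onset_mask].std()) or 1.0
        y_onset = (onset - self.onset_mean_) / self.onset_sd_

        surv_mask = np.isfinite(samples.time)
        self.grid_ = make_time_grid(samples.time[surv_mask], self.m_intervals,
                                    strategy=self.grid_strategy,
                                    events=samples.event[surv_mask])
        surv_labels: list[SurvivalLabel | None] = [None] * n
        for i in np.flatnonzero(surv_mask):
            surv_labels[i] = encode_survival_label(samples.time[i], samples.event[i],
                                                   self.grid_)

        heads = {
            "classification": MLP([self.latent_dim, *self.head_hidden, len(self.classes_)], rng),
            "regression": MLP([self.latent_dim, *self.head_hidden, 1], rng),
            "survival": MLP([self.latent_dim, *self.head_hidden, self.grid_.m], rng),
        }
        self.heads_ = heads
        K = len(TASKS)
        self.task_weights_ = TaskWeights(weights=np.ones(K),
                                         initial_losses=np.ones(K),
                                         alpha=self.gradnorm_alpha)
        self.history_ = {"stage1": [], "stage2": [], "stage3": [], "task_weights": []}

        targets = {"class": y_class, "onset": y_onset, "onset_mask": onset_mask,
                   "surv": surv_labels, "surv_mask": surv_mask}

        self._stage1(X, rng)
        self._stage2(X, targets, rng)
        self._stage3(X, targets, rng)
        return self

    # -- per-task forward/backward helpers ----------------------------------
    def _task_losses(self, mu: np.ndarray, idx: np.ndarray, targets: dict,
                     backprop: bool, loss_scale: np.ndarray | None = None
                     ) -> tuple[np.ndarray, list[np.ndarray | None]]:
        """Forward (and optionally backward) all heads on embedding ``mu``
        of the batch rows ``idx``.

        Returns per-task losses and the gradient of each *unweighted* task
        loss w.r.t. mu. ``loss_scale[k]`` scales task k's gradients during
        head/embedding backprop (W_k / K in the joint stages).
        """
        K = len(TASKS)
        scale = np.ones(K) if loss_scale is None else loss_scale
        losses = np.zeros(K)
        dmu_unweighted: list[np.ndarray | None] = [None] * K

        # classification: every sample has a label
        logits = self.heads_["classification"].forward(mu)
        cw = self.class_weights_
        loss_c, g_c = classification_loss(targets["class"][idx], logits,
                                          class_weights=cw, return_grad=True)
        losses[0] = loss_c
        if backprop:
            dmu_unweighted[0] = self.heads_["classification"].backward(g_c * scale[0])
            if scale[0] != 0:
                dmu_unweighted[0] = dmu_unweighted[0] / scale[0]

        # regression: masked to observed onset ages
        mask_r = targets["onset_mask"][idx]
        pred_r = self.heads_["regression"].forward(mu).ravel()
        if mask_r.any():
            loss_r, g_r = regression_loss(targets["onset"][idx][mask_r],
                                          pred_r[mask_r], return_grad=True)
            losses[1] = loss_r
            if backprop:
                g_full = np.zeros_like(pred_r)
                g_full[mask_r] = g_r
                dmu = self.heads_["regression"].backward(g_full[:, None] * scale[1])
                dmu_unweighted[1] = dmu / scale[1] if scale[1] != 0 else dmu

        # survival: masked to samples with survival data
        mask_s = targets["surv_mask"][idx]
        scores = self.heads_["survival"].forward(mu)
        if mask_s.any():
            labs = [targets["surv"][i] for i in idx[mask_s]]
            loss_s, g_s = survival_loss(labs, scores[mask_s], return_grad=True)
            losses[2] = loss_s
            if backprop:
                g_full = np.zeros_like(scores)
                g_full[mask_s] = g_s
                dmu = self.heads_["survival"].backward(g_full * scale[2])
                dmu_unweighted[2] = dmu / scale[2] if scale[2] != 0 else dmu

        return losses, dmu_unweighted

    def _check_finite(self, loss: float, stage: str, epoch: int) -> None:
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss in {stage}, epoch {epoch}")

    def _batches(self, n: int, rng: np.random.Generator):
        order = rng.permutation(n)
        for start in range(0, n, self.batch_size):
            yield order[start:start + self.batch_size]

    # -- stages --------------------------------------------------------------
    def _stage1(self, X: np.ndarray, rng: np.random.Generator) -> None:
        opt = Adam(self.vae_.params(), lr=self.learning_rate)
        # KL warm-up over the first half of the unsupervised epochs guards
        # against posterior collapse; the final objective is unchanged
        warmup = max(1, self.stage1_epochs // 2)
        for epoch in range(self.stage1_epochs):
            beta = min(1.0, (epoch + 1) / warmup)
            total, count = 0.0, 0
            for idx in self._batches(X.shape[0], rng):
                self.vae_.zero_grad()
                loss, _, _ = self.vae_.vae_step(X[idx], self.block_slices_, rng,
                                                kl_weight=beta)
                opt.step()
                total += loss * idx.size
                count += idx.size
            mean_loss = total / count
            self._check_finite(mean_loss, "stage 1", epoch)
            self.history_["stage1"].append(mean_loss)

    def _stage2(self, X: np.ndarray, targets: dict, rng: np.random.Generator) -> None:
        head_params = [p for h in self.heads_.values() for p in h.params()]
        opt = Adam(head_params, lr=self.learning_rate)
        W = self.task_weights_.weights
        K = len(TASKS)
        for epoch in range(self.stage2_epochs):
            total, count = 0.0, 0
            for idx in self._batches(X.shape[0], rng):
                for h in self.heads_.values():
                    h.zero_grad()
                mu, _ = self.vae_.encode(X[idx])  # frozen embedding
                losses, _ = self._task_losses(mu, idx, targets, backprop=True,
                                              loss_scale=W / K)
                opt.step()
                total += joint_downstream_loss(losses, W) * idx.size
                count += idx.size
            mean_loss = total / count
            self._check_finite(mean_loss, "stage 2", epoch)
            self.history_["stage2"].append(mean_loss)

    def _full_task_losses(self, X: np.ndarray, targets: dict) -> np.ndarray:
        mu, _ = self.vae_.encode(X)
        losses, _ = self._task_losses(mu, np.arange(X.shape[0]), targets,
                                      backprop=False)
        return losses

    def _stage3(self, X: np.ndarray, targets: dict, rng: np.random.Generator) -> None:
        if self.stage3_epochs == 0:
            return
        all_params = self.vae_.params() + [p for h in self.heads_.values()
                                           for p in h.params()]
        opt = Adam(all_params, lr=self.learning_rate)
        K = len(TASKS)
        tw = self.task_weights_
        tw.initial_losses = np.maximum(self._full_task_losses(X, targets), 1e-8)
        for epoch in range(self.stage3_epochs):
            total, count = 0.0, 0
            for idx in self._batches(X.shape[0], rng):
                self.vae_.zero_grad()
                for h in self.heads_.values():
                    h.zero_grad()
                embed_loss, mu, _ = self.vae_.vae_step(X[idx], self.block_slices_, rng)
                losses, dmu_unweighted = self._task_losses(
                    mu, idx, targets, backprop=True, loss_scale=tw.weights / K)
                # route the downstream gradients through the encoder
                dmu_total = np.zeros_like(mu)
                for k, dmu in enumerate(dmu_unweighted):
                    if dmu is not None:
                        dmu_total += tw.weights[k] / K * dmu
                dh = self.vae_.mu_layer.backward(dmu_total)
                self.vae_.trunk.backward(dh)
                opt.step()

                if self.use_gradnorm and all(d is not None for d in dmu_unweighted):
                    hrep = self.vae_.mu_layer._x
                    G = task_gradient_norms(hrep, dmu_unweighted, tw.weights)
                    if np.all(G > 0) and np.all(losses > 0):
                        _, gn_targets = gradnorm_loss(G, tw.initial_losses, losses,
                                                      tw.alpha)
                        gW = gradnorm_weight_gradients(G, gn_targets, tw.weights)
                        tw.weights = update_task_weights(tw.weights, gW,
                                                         self.gradnorm_lr)
                total += (embed_loss + joint_downstream_loss(losses, tw.weights)) * idx.size
                count += idx.size
            mean_loss = total / count
            self._check_finite(mean_loss, "stage 3", epoch)
            self.history_["stage3"].append(mean_loss)
            self.history_["task_weights"].append(tw.weights.copy())

    # -- prediction ----------------------------------------------------------
    def transform(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        """Latent embedding (posterior mean) of new samples."""
        X = self._scale_blocks(blocks)
        mu, _ = self.vae_.encode(X)
        return mu

    def predict_proba(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        mu = self.transform(blocks)
        logits = self.heads_["classification"].forward(mu)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        return self.predict_proba(blocks).argmax(axis=1)

    def predict_onset(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        mu = self.transform(blocks)
        z = self.heads_["regression"].forward(mu).ravel()
        return z * self.onset_sd_ + self.onset_mean_

    def predict_survival_scores(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        mu = self.transform(blocks)
        return self.heads_["survival"].forward(mu)

    def predict_survival_curves(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        scores = self.predict_survival_scores(blocks)
        return np.stack([predict_survival_curve(s, self.grid_) for s in scores])

    def predict_risk(self, blocks: Sequence[OmicsBlock]) -> np.ndarray:
        scores = self.predict_survival_scores(blocks)
        return np.array([risk_score(s, self.grid_) for s in scores])

    # -- checkpointing -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Serialize architecture, scaler state, grid and parameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": self.get_params(),
            "block_names": self.block_names_,
            "block_features": self.block_features_,
            "classes": self.classes_,
            "onset_mean": self.onset_mean_,
            "onset_sd": self.onset_sd_,
            "grid": self.grid_.boundaries.tolist(),
            "task_weights": self.task_weights_.weights.tolist(),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for i, (p, _) in enumerate(self.vae_.params()):
            arrays[f"vae_{i}"] = p
        for name, head in self.heads_.items():
            for i, (p, _) in enumerate(head.params()):
                arrays[f"head_{name}_{i}"] = p
        for name, scaler in self.scalers_.items():
            arrays[f"scaler_{name}_min"] = scaler.data_min_
            arrays[f"scaler_{name}_max"] = scaler.data_max_
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "MoalsNetwork":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in meta["params"].items()})
        data = np.load(directory / "weights.npz")
        model.block_names_ = meta["block_names"]
        model.block_features_ = meta["block_features"]
        model.classes_ = meta["classes"]
        model.onset_mean_ = meta["onset_mean"]
        model.onset_sd_ = meta["onset_sd"]
        model.grid_ = TimeGrid(np.asarray(meta["grid"]))
        model.task_weights_ = TaskWeights(np.asarray(meta["task_weights"]),
                                          np.ones(len(TASKS)),
                                          alpha=model.gradnorm_alpha)
        widths = {n: len(f) for n, f in model.block_features_.items()}
        model.block_slices_ = []
        start = 0
        for n in model.block_names_:
            model.block_slices_.append(slice(start, start + widths[n]))
            start += widths[n]
        rng = np.random.default_rng(0)
        model.encoder_spec_ = EncoderSpec(block_widths=widths,
                                          hidden_dims=tuple(model.hidden_dims),
                                          latent_dim=model.latent_dim, seed=0)
        model.vae_ = VAE(model.encoder_spec_)
        model.heads_ = {
            "classification": MLP([model.latent_dim, *model.head_hidden,
                                   len(model.classes_)], rng),
            "regression": MLP([model.latent_dim, *model.head_hidden, 1], rng),
            "survival": MLP([model.latent_dim, *model.head_hidden, model.grid_.m], rng),
        }
        for i, (p, _) in enumerate(model.vae_.params()):
            p[...] = data[f"vae_{i}"]
        for name, head in model.heads_.items():
            for i, (p, _) in enumerate(head.params()):
                p[...] = data[f"head_{name}_{i}"]
        model.scalers_ = {}
        for name in model.block_names_:
            sc = MinMaxClipScaler()
            sc.data_min_ = data[f"scaler_{name}_min"]
            sc.data_max_ = data[f"scaler_{name}_max"]
            sc.n_features_in_ = sc.data_min_.size
            model.scalers_[name] = sc
        return model


def train(blocks: Sequence[OmicsBlock], samples: SampleTable,
          schedule: TrainingSchedule | None = None,
          **model_kwargs) -> MoalsNetwork:
    """Functional wrapper: build a MoalsNetwork from a schedule and fit it."""
    schedule = schedule or TrainingSchedule()
    model = MoalsNetwork(
        stage1_epochs=schedule.stage1_epochs,
        stage2_epochs=schedule.stage2_epochs,
        stage3_epochs=schedule.stage3_epochs,
        learning_rate=schedule.learning_rate,
        batch_size=schedule.batch_size,
        gradnorm_alpha=schedule.gradnorm_alpha,
        gradnorm_lr=schedule.gradnorm_lr,
        use_gradnorm=schedule.use_gradnorm,
        random_state=schedule.seed,
        **model_kwargs,
    )
    return model.fit(blocks, samples)
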