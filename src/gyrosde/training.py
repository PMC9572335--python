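"""ELBO construction and the joint training loop.

For a window of L frames x_0..x_{L-1} (L = T + 1) the objective is the
sequential evidence lower bound

    ELBO = sum_{t=0}^{T-1} E_{z_t ~ q} log p(xbar_{t+1} | z_t)
         - KL(q(z_0|x_0) || p(z_0))
         - sum_{t=1}^{T-1} E_{z_{t-1} ~ q} KL(q(z_t|x_0:t) || p(z_t|z_{t-1})),

with xbar_{t+1} = (x_t + x_{t+1})/2, all q factors isotropic Gaussians
whose means come from one causal-transformer pass, the transition prior
the Euler-Maruyama Gaussian of the latent SDE, and the initial prior the
PCA-anchored N(mu_0, sigma_0^2 I). Outer expectations use a single
reparameterized sample per step by default (mc_samples configurable);
transition KLs are closed-form given the sampled z_{t-1}.

An optional contrastive term scores (observation, latent) pairs with an
MLP discriminator so same-user pairs score high and cross-user pairs low;
its gradients reach the discriminator (omega) and the posterior (phi) but
not the generative parameters (theta), which the term never touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .exceptions import InvalidArgumentError, OptimizationFailureError
from .generative import LATENT_DIM, OBS_DIM, GenerativeModel, PCAPrior
from .inference import GPT2Posterior
from .nn import MLP, AdamW, Module

_LOG_2PI = float(np.log(2.0 * np.pi))


def gaussian_kl(mu_q, sd_q: float, mu_p, sd_p: float) -> float:
    """KL(N(mu_q, sd_q^2 I_k) || N(mu_p, sd_p^2 I_k)), closed form.

    k is inferred from the mean vectors; scalars count as k = 1.
    """
    if sd_q <= 0 or sd_p <= 0:
        raise InvalidArgumentError("standard deviations must be positive")
    mu_q = np.atleast_1d(np.asarray(mu_q, dtype=float))
    mu_p = np.atleast_1d(np.asarray(mu_p, dtype=float))
    if mu_q.shape != mu_p.shape:
        raise InvalidArgumentError("mean shapes differ")
    k = mu_q.shape[-1]
    val = (k * np.log(sd_p / sd_q)
           + (k * sd_q ** 2 + np.sum((mu_q - mu_p) ** 2, axis=-1))
           / (2.0 * sd_p ** 2)
           - 0.5 * k)
    return float(max(val, 0.0)) if np.ndim(val) == 0 else np.maximum(val, 0.0)


def _kl_iso_t(mu_q: Tensor, sd_q: Tensor, mu_p: Tensor, sd_p: Tensor,
              k: int) -> Tensor:
    """Tensor version of the isotropic-Gaussian KL; reduces the last axis,
    returning per-position KLs. sd arguments are (broadcastable) scalars."""
    diff = mu_q - mu_p
    return (k * (sd_p.log() - sd_q.log())
            + (k * sd_q ** 2.0 + (diff * diff).sum(axis=-1))
            / (2.0 * sd_p ** 2.0)
            - 0.5 * k)


@dataclass
class ElboBreakdown:
    """Per-window-averaged ELBO components (nats)."""

    recon: float
    kl_initial: float
    kl_transitions: float
    contrast: float = 0.0

    @property
    def elbo(self) -> float:
        return self.recon - self.kl_initial - self.kl_transitions

    def check_finite(self) -> None:
        for name in ("recon", "kl_initial", "kl_transitions", "contrast"):
            if not np.isfinite(getattr(self, name)):
                raise OptimizationFailureError(
                    f"non-finite loss term: {name} = {getattr(self, name)}")


def elbo_objective(windows: np.ndarray, gen: GenerativeModel,
                   post: GPT2Posterior, prior: PCAPrior,
                   seed: int, mc_samples: int = 1,
                   sample_noise: bool = True):
    """Negative-ELBO objective for a batch of windows (B, L, 4).

    Returns ``(loss, breakdown, z_samples)`` where ``loss`` is a scalar
    Tensor (mean negative ELBO per window), ``breakdown`` the averaged
    components as floats, and ``z_samples`` the last reparameterized
    latent draws (B, L-1, 2) as a Tensor for optional reuse by the
    contrastive term.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise InvalidArgumentError("windows must be (B, L, 4)")
    B, L, _ = windows.shape
    if L < 2:
        raise InvalidArgumentError("windows need at least 2 frames")
    S = L - 1  # latent steps per window
    rng = np.random.default_rng(seed)
    dt = gen.config.dt

    means = post.forward(Tensor(windows))  # (B, L, 2)
    mu = means[:, :S, :]
    sd_q = post.q_log_sd.exp()
    sigma_theta = gen.sigma_theta_t()
    sd_trans = sigma_theta * float(np.sqrt(dt))
    obs_sd = gen.obs_log_sd.exp()

    targets = 0.5 * (windows[:, :-1] + windows[:, 1:])  # (B, S, 4), constant
    mu0_prior = Tensor(prior.project(windows[:, 0, :]))  # (B, 2)

    recon_acc = None
    kltr_acc = None
    z_last = None
    for _ in range(mc_samples):
        eps = rng.standard_normal((B, S, LATENT_DIM)) if sample_noise \
            else np.zeros((B, S, LATENT_DIM))
        z = mu + sd_q * Tensor(eps)  # (B, S, 2) reparameterized
        dec_mean = gen.decode_t(z)  # (B, S, 4)
        resid = (Tensor(targets) - dec_mean) / obs_sd
        logp = (-0.5 * (resid * resid).sum(axis=-1)
                - OBS_DIM * (gen.obs_log_sd + 0.5 * _LOG_2PI))
        recon_m = logp.sum(axis=-1)  # (B,)
        prior_mean = z[:, :-1, :] + gen.drift_t(z[:, :-1, :]) * dt
        kltr_m = _kl_iso_t(mu[:, 1:, :], sd_q, prior_mean, sd_trans,
                           LATENT_DIM).sum(axis=-1)  # (B,)
        recon_acc = recon_m if recon_acc is None else recon_acc + recon_m
        kltr_acc = kltr_m if kltr_acc is None else kltr_acc + kltr_m
        z_last = z
    recon = recon_acc * (1.0 / mc_samples)
    kl_trans = kltr_acc * (1.0 / mc_samples)
    kl_init = _kl_iso_t(mu[:, 0, :], sd_q, mu0_prior,
                        Tensor(prior.sigma0), LATENT_DIM)  # (B,)

    elbo = recon - kl_init - kl_trans
    loss = -(elbo.mean())
    breakdown = ElboBreakdown(
        recon=float(recon.data.mean()),
        kl_initial=float(kl_init.data.mean()),
        kl_transitions=float(kl_trans.data.mean()),
    )
    return loss, breakdown, z_last


class ContrastNet(Module):
    """C_omega: an MLP scoring (observation, latent) pairs in R^{4+2}."""

    def __init__(self, rng: np.random.Generator, hidden: tuple = (64,)):
        self.net = MLP(OBS_DIM + LATENT_DIM, hidden, 1, rng,
                       activation="tanh")

    def logits(self, x, z) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
        out = self.net(concat([x, z], axis=-1))
        return out.reshape(out.shape[:-1])

    def probabilities(self, x, z) -> np.ndarray:
        """sigma(C(x, z)) — same-user probability per step."""
        return self.logits(x, z).sigmoid().data


def _log_sigmoid(t: Tensor) -> Tensor:
    # log sigma(x) = -softplus(-x), numerically stable
    return -((-t).softplus())


def contrast_loss(xs: list, zs: list, net: ContrastNet,
                  literal_form: bool = False) -> Tensor:
    """Mean discriminator loss over ordered user pairs and time steps.

    ``xs[a]`` and ``zs[a]`` are user a's observation and latent sequences
    (aligned by step; trailing steps beyond the shortest user are
    dropped). Positive pairs (x^a, z^a) should score high, negative pairs
    (x^a, z^b), b != a, low. Default form: -[log sigma(C+) +
    log(1 - sigma(C-))]; ``literal_form`` instead evaluates
    log sigma(1 - C-) for the negative term.
    """
    if len(xs) < 2 or len(xs) != len(zs):
        raise InvalidArgumentError("need aligned sequences for >= 2 users")
    n = min(min(len(np.asarray(x.data if isinstance(x, Tensor) else x))
                for x in xs),
            min(z.shape[0] if isinstance(z, Tensor)
                else len(np.asarray(z)) for z in zs))
    total = None
    count = 0
    U = len(xs)
    for a in range(U):
        x_a = xs[a][:n] if isinstance(xs[a], Tensor) \
            else Tensor(np.asarray(xs[a], dtype=float)[:n])
        z_a = zs[a][:n] if isinstance(zs[a], Tensor) \
            else Tensor(np.asarray(zs[a], dtype=float)[:n])
        pos = _log_sigmoid(net.logits(x_a, z_a)).sum()
        for b in range(U):
            if b == a:
                continue
            z_b = zs[b][:n] if isinstance(zs[b], Tensor) \
                else Tensor(np.asarray(zs[b], dtype=float)[:n])
            c_neg = net.logits(x_a, z_b)
            if literal_form:
                neg = _log_sigmoid(1.0 - c_neg).sum()
            else:
                neg = _log_sigmoid(-c_neg).sum()  # log(1 - sigma(c))
            term = pos + neg
            total = term if total is None else total + term
            count += n
    return -(total * (1.0 / count))


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    n_epochs: int = 100
    seed: int = 0
    contrast_weight: float = 0.0
    literal_contrast: bool = False
    mc_samples: int = 1

    def __post_init__(self):
        if self.batch_size < 1 or self.mc_samples < 1 or self.n_epochs < 1:
            raise InvalidArgumentError("batch_size, mc_samples, n_epochs >= 1")
        if self.contrast_weight < 0:
            raise InvalidArgumentError("contrast_weight must be >= 0")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    recon: list = field(default_factory=list)
    kl_initial: list = field(default_factory=list)
    kl_transitions: list = field(default_factory=list)
    contrast: list = field(default_factory=list)


def _contrast_groups(z: Tensor, windows: np.ndarray, user_ids: np.ndarray):
    """Flatten per-user (x, z) pairs aligned by (window, step)."""
    xs, zs = [], []
    S = z.shape[1]
    for uid in np.unique(user_ids):
        idx = np.nonzero(user_ids == uid)[0]
        z_u = z[idx]  # (n_u, S, 2) Tensor slice
        xs.append(Tensor(windows[idx][:, :S, :].reshape(-1, OBS_DIM)))
        zs.append(z_u.reshape(len(idx) * S, LATENT_DIM))
    return xs, zs


def train(gen: GenerativeModel, post: GPT2Posterior, prior: PCAPrior,
          train_windows: np.ndarray, val_windows: np.ndarray | None,
          config: TrainConfig, contrast_net: ContrastNet | None = None,
          user_ids: np.ndarray | None = None,
          callback=None) -> TrainHistory:
    """Joint stochastic optimization of (theta, phi[, omega]) by AdamW.

    Minimizes mean negative ELBO plus ``contrast_weight`` times the
    contrastive loss. Validation loss is the deterministic (noise-free
    reparameterization) negative ELBO on ``val_windows``, recorded every
    epoch as the overfitting monitor. Fixed seed => bit-identical history.
    """
    train_windows = np.asarray(train_windows, dtype=float)
    if len(train_windows) == 0:
        raise InvalidArgumentError("empty training set")
    use_contrast = config.contrast_weight > 0
    if use_contrast:
        if contrast_net is None or user_ids is None:
            raise InvalidArgumentError(
                "contrastive training needs contrast_net and user_ids")
        if len(np.unique(user_ids)) < 2:
            raise InvalidArgumentError(
                "contrastive training needs >= 2 users in the dataset")

    params = gen.parameters() + post.parameters()
    if use_contrast:
        params = params + contrast_net.parameters()
    opt = AdamW(params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    n = len(train_windows)

    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_break = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = train_windows[idx]
            mb_seed = int(rng.integers(2 ** 31))
            loss, bd, z = elbo_objective(
                batch, gen, post, prior, seed=mb_seed,
                mc_samples=config.mc_samples)
            if use_contrast:
                uid_b = user_ids[idx]
                if len(np.unique(uid_b)) >= 2:
                    xs, zs = _contrast_groups(z, batch, uid_b)
                    closs = contrast_loss(xs, zs, contrast_net,
                                          literal_form=config.literal_contrast)
                    bd.contrast = float(closs.data)
                    loss = loss + config.contrast_weight * closs
            bd.check_finite()
            if not np.isfinite(loss.data):
                raise OptimizationFailureError(
                    f"non-finite total loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            epoch_break += (bd.recon, bd.kl_initial, bd.kl_transitions,
                            bd.contrast)
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        for name, val in zip(("recon", "kl_initial", "kl_transitions",
                              "contrast"), epoch_break / n_batches):
            getattr(history, name).append(float(val))
        if val_windows is not None and len(val_windows):
            vloss, _, _ = elbo_objective(val_windows, gen, post, prior,
                                         seed=0, sample_noise=False)
            history.val_loss.append(float(vloss.data))
        if callback is not None:
            callback(epoch, history)
    return history


def detect_overfitting(val_trace, patience: int = 10,
                       min_rise: float = 0.0) -> tuple[bool, int]:
    """Fires when the validation loss stops decreasing and then tends to
    increase: the running best is at least ``patience`` epochs old and the
    trace has risen above it since.

    Returns ``(fired, best_epoch)``.
    """
    trace = np.asarray(val_trace, dtype=float)
    if patience < 1:
        raise InvalidArgumentError("patience must be >= 1")
    if len(trace) == 0:
        return False, -1
    best = int(np.argmin(trace))
    tail = trace[best + 1:]
    fired = (len(tail) >= patience
             and bool(np.all(tail >= trace[best]))
             and float(tail[-1]) > trace[best] + min_rise)
    return fired, best
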