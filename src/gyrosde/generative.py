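"""Generative component: latent SDE transition, Gaussian decoder, PCA prior.

The latent state z_t lives in R^2 and follows the simplified neural SDE

    dz = mu_theta(z) dt + sigma_theta dW,

discretized by Euler-Maruyama with one substep per 30 Hz sample (dt = 1;
the time unit is absorbed into the learned drift and diffusion). The drift
is a small tanh MLP; the diffusion is a single positive scalar
(softplus-parameterized). The decoder is an MLP mapping z_t to the mean of
an isotropic Gaussian over the 4-channel midpoint target (x_t + x_{t+1})/2
with one shared learned observation sd. The initial-state prior is
N(mu_0, sigma_0^2 I) with mu_0 the 2-component PCA projection of x_0 and
sigma_0 = 0.2 fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .autodiff import Tensor
from .exceptions import InvalidArgumentError, NotFittedError
from .nn import MLP, Module

LATENT_DIM = 2
OBS_DIM = 4


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _inv_softplus(y: float) -> float:
    # inverse of log(1 + e^x); valid for y > 0
    return float(np.log(np.expm1(y)))


@dataclass
class GenerativeConfig:
    drift_hidden: tuple = (64, 64)
    decoder_hidden: tuple = (64, 64)
    dt: float = 1.0
    sigma0: float = 0.2
    init_sigma_theta: float = 0.1
    init_obs_sd: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.sigma0 <= 0:
            raise InvalidArgumentError("sigma0 must be positive")


class GenerativeModel(Module):
    """theta: drift net, diffusion scalar, decoder net, observation sd.

    The drift output layer is zero-initialized so the untrained transition
    is an identity-mean random walk — a neutral starting point for ELBO
    training.
    """

    def __init__(self, config: GenerativeConfig, rng: np.random.Generator):
        self.config = config
        self.drift_net = MLP(LATENT_DIM, config.drift_hidden, LATENT_DIM,
                             rng, activation="tanh", zero_last=True)
        self.decoder_net = MLP(LATENT_DIM, config.decoder_hidden, OBS_DIM,
                               rng, activation="tanh")
        self.diffusion_raw = Tensor(
            _inv_softplus(config.init_sigma_theta), requires_grad=True)
        self.obs_log_sd = Tensor(
            float(np.log(config.init_obs_sd)), requires_grad=True)

    # -- scalars --------------------------------------------------------
    @property
    def sigma_theta(self) -> float:
        """Diffusion magnitude (always > 0)."""
        return _softplus(float(self.diffusion_raw.data))

    def sigma_theta_t(self) -> Tensor:
        return self.diffusion_raw.softplus()

    @property
    def obs_sd(self) -> float:
        return float(np.exp(self.obs_log_sd.data))

    # -- drift ----------------------------------------------------------
    def drift_t(self, z: Tensor) -> Tensor:
        return self.drift_net(z)

    def drift(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise InvalidArgumentError("z contains non-finite values")
        return self.drift_net(Tensor(z)).data

    # -- transition -----------------------------------------------------
    def euler_maruyama_step(self, z, noise, dt: float | None = None):
        """z' = z + mu(z) dt + sigma sqrt(dt) eps."""
        dt = self.config.dt if dt is None else dt
        if dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        z = np.asarray(z, dtype=float)
        noise = np.asarray(noise, dtype=float)
        return z + self.drift(z) * dt + self.sigma_theta * np.sqrt(dt) * noise

    def transition_density(self, z_prev, dt: float | None = None):
        """Euler-Maruyama transition: N(z + mu(z) dt, sigma^2 dt I)."""
        dt = self.config.dt if dt is None else dt
        if dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        z_prev = np.asarray(z_prev, dtype=float)
        mean = z_prev + self.drift(z_prev) * dt
        cov = self.sigma_theta ** 2 * dt * np.eye(LATENT_DIM)
        return mean, cov

    def sample_trajectory(self, z0, n_steps: int, seed: int,
                          dt: float | None = None) -> np.ndarray:
        """Iterated Euler-Maruyama; returns (n_steps + 1, 2) incl. z0."""
        if n_steps < 1:
            raise InvalidArgumentError("n_steps must be >= 1")
        rng = np.random.default_rng(seed)
        z = np.asarray(z0, dtype=float)
        traj = np.empty((n_steps + 1, LATENT_DIM))
        traj[0] = z
        for i in range(n_steps):
            z = self.euler_maruyama_step(
                z, rng.standard_normal(LATENT_DIM), dt=dt)
            traj[i + 1] = z
        return traj

    # -- decoder --------------------------------------------------------
    def decode_t(self, z: Tensor) -> Tensor:
        return self.decoder_net(z)

    def decode(self, z):
        """Gaussian over R^4: returns (mean, sd)."""
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise InvalidArgumentError("z contains non-finite values")
        return self.decoder_net(Tensor(z)).data, self.obs_sd

    def decode_logpdf(self, x, z) -> np.ndarray:
        mean, sd = self.decode(z)
        return gaussian_logpdf_iso(np.asarray(x, dtype=float), mean, sd)


def gaussian_logpdf_iso(x: np.ndarray, mean: np.ndarray,
                        sd: float) -> np.ndarray:
    """Log density of an isotropic Gaussian, summed over the last axis."""
    d = x.shape[-1]
    resid = (x - mean) / sd
    return -0.5 * np.sum(resid * resid, axis=-1) \
        - d * (np.log(sd) + 0.5 * np.log(2.0 * np.pi))


class PCAPrior:
    """Prior over z_0: N(P(x_0), sigma_0^2 I) with P a fitted 2-component
    PCA projection of the 4-channel training frames.

    Sign convention: the largest-magnitude loading of each component is
    made positive, removing PCA's sign ambiguity.
    """

    def __init__(self, sigma0: float = 0.2, m: int = 0):
        if sigma0 <= 0:
            raise InvalidArgumentError("sigma0 must be positive")
        if m != 0:
            raise InvalidArgumentError(
                "only m=0 (single-frame history) is supported")
        self.sigma0 = float(sigma0)
        self.m = m
        self.components_: np.ndarray | None = None  # (2, 4), orthonormal rows
        self.mean_: np.ndarray | None = None  # (4,)

    def fit(self, frames: np.ndarray) -> "PCAPrior":
        frames = np.asarray(frames, dtype=float)
        pca = PCA(n_components=LATENT_DIM).fit(frames)
        comps = pca.components_.copy()
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.mean_ = pca.mean_.copy()
        return self

    @property
    def fitted(self) -> bool:
        return self.components_ is not None

    def project(self, x) -> np.ndarray:
        """mu_0 = projection of the frame(s) onto the leading components."""
        if not self.fitted:
            raise NotFittedError("PCA prior has not been fit")
        x = np.asarray(x, dtype=float)
        return (x - self.mean_) @ self.components_.T

    def prior_mean(self, x_history) -> np.ndarray:
        """mu_0 from the history x_{-m:0}; with m=0 this is the projection
        of the single frame x_0."""
        x_history = np.atleast_2d(np.asarray(x_history, dtype=float))
        return self.project(x_history[-1])
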