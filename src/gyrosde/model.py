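"""Model/Results facade tying the pipeline together.

:class:`MotionSDE` holds prepared windowed data plus the model
configuration; :meth:`MotionSDE.fit` trains generative and inference
parameters jointly by ELBO maximization and returns a
:class:`MotionSDEResults` carrying the fitted parameter bundle, the loss
history, and the derived quantities (latent trajectories, attention maps,
simulated rollouts, summary table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, NotFittedError
from .generative import GenerativeConfig, GenerativeModel, PCAPrior
from .inference import GPT2Posterior, TransformerConfig
from .preprocessing import (NormalizationStats, apply_zscore,
                            prepare_recordings, recording_to_frames)
from .synthetic import SensorRecording
from .training import (ContrastNet, TrainConfig, TrainHistory, train)


@dataclass
class ModelConfig:
    """Everything needed to rebuild the model architecture."""

    T: int = 90
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    contrast_hidden: tuple = (64,)

    def __post_init__(self):
        if self.transformer.max_len < self.T + 1:
            raise InvalidArgumentError(
                f"max_len {self.transformer.max_len} cannot hold a "
                f"{self.T + 1}-frame window")


class MotionSDE:
    """Latent neural-SDE model of windowed gyroscope observations.

    Parameters
    ----------
    train_windows, val_windows : (B, T+1, 4) arrays of normalized frames.
    stats : the z-score statistics the windows were normalized with
        (kept so results can preprocess raw recordings consistently).
    user_ids : optional per-window user index, required for the
        contrastive term.
    """

    def __init__(self, train_windows, val_windows=None, *,
                 stats: NormalizationStats | None = None,
                 user_ids=None, config: ModelConfig | None = None):
        self.train_windows = np.asarray(train_windows, dtype=float)
        if self.train_windows.ndim != 3:
            raise InvalidArgumentError("train_windows must be (B, L, 4)")
        self.val_windows = None if val_windows is None \
            else np.asarray(val_windows, dtype=float)
        self.stats = stats
        self.user_ids = None if user_ids is None else np.asarray(user_ids)
        self.config = config or ModelConfig(
            T=self.train_windows.shape[1] - 1)
        if self.train_windows.shape[1] != self.config.T + 1:
            raise InvalidArgumentError(
                f"windows have {self.train_windows.shape[1]} frames; "
                f"config expects {self.config.T + 1}")

    @classmethod
    def from_recordings(cls, recordings: list[SensorRecording],
                        T: int = 90, stride: int | None = None,
                        train_fraction: float = 0.8,
                        config: ModelConfig | None = None,
                        user_key: str = "subject_id") -> "MotionSDE":
        """Build from raw recordings: magnitude feature, chronological
        80/20 split, pooled z-scoring on the training segments, windowing.

        ``user_key`` ('subject_id' or 'motion') controls which recording
        attribute defines a "user" for the contrastive term.
        """
        train_ds, test_ds, stats, train_rec_ids, _ = prepare_recordings(
            recordings, T=T, stride=stride, train_fraction=train_fraction)
        keys = [getattr(r, user_key) for r in recordings]
        uniq = sorted(set(keys))
        uid_of_rec = np.asarray([uniq.index(k) for k in keys])
        user_ids = uid_of_rec[train_rec_ids]
        if config is None:
            config = ModelConfig(T=T)
        return cls(train_ds.windows,
                   None if test_ds is None else test_ds.windows,
                   stats=stats, user_ids=user_ids, config=config)

    def fit(self, train_config: TrainConfig | None = None,
            seed: int | None = None, n_epochs: int | None = None,
            callback=None) -> "MotionSDEResults":
        """Train (theta, phi[, omega]) jointly; returns the Results."""
        cfg = train_config or TrainConfig()
        if seed is not None or n_epochs is not None:
            from dataclasses import replace
            cfg = replace(cfg,
                          **({"seed": seed} if seed is not None else {}),
                          **({"n_epochs": n_epochs} if n_epochs is not None
                             else {}))
        rng = np.random.default_rng(cfg.seed)
        gen = GenerativeModel(self.config.generative, rng)
        post = GPT2Posterior(self.config.transformer, rng)
        contrast = ContrastNet(rng, hidden=self.config.contrast_hidden)
        prior = PCAPrior(sigma0=self.config.generative.sigma0)
        prior.fit(self.train_windows.reshape(-1, self.train_windows.shape[-1]))
        history = train(gen, post, prior, self.train_windows,
                        self.val_windows, cfg,
                        contrast_net=contrast, user_ids=self.user_ids,
                        callback=callback)
        return MotionSDEResults(model=self, gen=gen, post=post, prior=prior,
                                contrast=contrast, history=history,
                                train_config=cfg)


class MotionSDEResults:
    """Fitted parameters plus derived quantities."""

    def __init__(self, model: MotionSDE | None, gen: GenerativeModel,
                 post: GPT2Posterior, prior: PCAPrior,
                 contrast: ContrastNet | None, history: TrainHistory | None,
                 train_config: TrainConfig | None,
                 stats: NormalizationStats | None = None,
                 config: ModelConfig | None = None):
        self.model = model
        self.gen = gen
        self.post = post
        self.prior = prior
        self.contrast = contrast
        self.history = history
        self.train_config = train_config
        self.stats = stats if stats is not None else (
            model.stats if model is not None else None)
        self.config = config if config is not None else (
            model.config if model is not None else None)

    # -- preprocessing glue --------------------------------------------
    def normalize(self, recording: SensorRecording) -> np.ndarray:
        """Raw recording -> normalized (N, 4) frames with the training
        statistics."""
        if self.stats is None:
            raise NotFittedError("no normalization statistics attached")
        return apply_zscore(recording_to_frames(recording), self.stats)

    # -- latent extraction ---------------------------------------------
    def latent_means(self, window) -> np.ndarray:
        """Posterior means mu_0..mu_{L-1} for one normalized window."""
        return self.post.posterior_means(window)

    def latent_trajectory(self, frames_or_recording) -> np.ndarray:
        """Causal latent trajectory z-hat_t = mu(x_{0:t}) for a sequence
        of any length.

        For t < max_len the means come from the first window; longer
        sequences slide a dense (stride-1) window and keep the last
        position, so every estimate uses at most max_len past frames.
        """
        if isinstance(frames_or_recording, SensorRecording):
            frames = self.normalize(frames_or_recording)
        else:
            frames = np.asarray(frames_or_recording, dtype=float)
        n = len(frames)
        L = self.post.config.max_len
        if n <= L:
            return self.post.posterior_means(frames)
        head = self.post.posterior_means(frames[:L])
        starts = np.arange(1, n - L + 1)
        tails = np.stack([frames[s:s + L] for s in starts])
        # batch the dense windows to bound memory
        out = [head]
        for i in range(0, len(tails), 256):
            means = self.post.posterior_means(tails[i:i + 256])
            out.append(means[:, -1, :])
        return np.concatenate(out)

    def attention_heatmap(self, window, layer_index: int = 0,
                          row_span: tuple | None = None) -> np.ndarray:
        return self.post.attention_heatmap(window, layer_index=layer_index,
                                           row_span=row_span)

    # -- simulation -----------------------------------------------------
    def simulate(self, z0, n_steps: int, seed: int = 0):
        """Roll the fitted SDE forward and decode: returns (latents,
        decoded observation means)."""
        traj = self.gen.sample_trajectory(z0, n_steps, seed)
        dec_mean, _ = self.gen.decode(traj)
        return traj, dec_mean

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        lines = ["Latent neural-SDE motion model", "=" * 38]
        if self.config is not None:
            tc = self.config.transformer
            lines += [
                f"window length T+1        : {self.config.T + 1}",
                f"latent dimension         : 2",
                f"transformer              : {tc.n_layers} layers, "
                f"{tc.n_heads} head(s), embed {tc.embed_dim}",
            ]
        if self.model is not None:
            lines.append(
                f"training windows         : {len(self.model.train_windows)}")
            if self.model.val_windows is not None:
                lines.append(
                    f"validation windows       : {len(self.model.val_windows)}")
        lines += [
            f"diffusion sigma_theta    : {self.gen.sigma_theta:.4f}",
            f"observation sd           : {self.gen.obs_sd:.4f}",
            f"posterior sd             : {self.post.q_sd:.4f}",
            f"prior sigma_0            : {self.prior.sigma0:.2f}",
        ]
        if self.history is not None and self.history.train_loss:
            lines += [
                f"epochs                   : {len(self.history.train_loss)}",
                f"final train loss (-ELBO) : {self.history.train_loss[-1]:.3f}",
            ]
            if self.history.val_loss:
                lines.append(
                    f"final validation loss    : {self.history.val_loss[-1]:.3f}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        from .io import save_bundle
        save_bundle(self, path)

    @classmethod
    def load(cls, path) -> "MotionSDEResults":
        from .io import load_bundle
        return load_bundle(path)
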