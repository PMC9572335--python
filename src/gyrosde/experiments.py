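"""Reference experiments: scaled-down replications of the study's analyses
on synthetic cohorts.

These functions wire the full pipeline together at sizes chosen to run in
minutes on one CPU (see docs/methods.md for the rationale behind the
sizes) and return the headline quantities: latent-frequency preservation,
normal-region self-membership, motion-switch detection, initial-state
optimization gain, and contrastive user identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .analysis import (detect_motion_switch, dominant_period,
                       fit_latent_region, optimize_initial_state,
                       region_membership, user_identification_score)
from .generative import GenerativeConfig
from .inference import TransformerConfig
from .io import derive_seed
from .model import ModelConfig, MotionSDE, MotionSDEResults
from .training import TrainConfig

#: Architecture used by the reference experiments: full-size windows
#: (T = 90) with compact networks — limit cycles in R^2 need little
#: capacity, and the experiments stay fast on one CPU.
STUDY_CONFIG = ModelConfig(
    T=90,
    generative=GenerativeConfig(drift_hidden=(32, 32),
                                decoder_hidden=(32, 32)),
    transformer=TransformerConfig(n_layers=2, n_heads=1, embed_dim=32,
                                  max_len=91),
)

TRANSIENT = 30  # initial latent steps dropped (encoder warm-up)


def _strongest_period(z: np.ndarray) -> float:
    """Dominant period of the latent coordinate with the larger non-DC
    spectral peak."""
    z = z - z.mean(axis=0)
    peaks = [np.abs(np.fft.rfft(z[:, i]))[1:].max() for i in range(2)]
    return dominant_period(z[:, int(np.argmax(peaks))])


@dataclass
class MultiMotionStudy:
    results: MotionSDEResults
    recordings: list
    subject: synthetic.SubjectProfile
    latent_period: dict  # motion -> dominant latent period (samples)
    input_period: dict  # motion -> dominant input period (samples)
    self_membership: dict  # motion -> fraction of training latents inside
    n_switches: int
    switch_error: float  # |detected - true| in steps
    init_discrepancy_ratio: float  # optimized / PCA-initialized
    train_loss_first: float
    train_loss_last: float


def run_multimotion_study(seed: int = 0, n_epochs: int = 800,
                          contrast_weight: float = 300.0,
                          n_steps: int = 1500,
                          switch_step: int = 600) -> MultiMotionStudy:
    """Walking + running pooled into one shared latent space.

    One subject performs both motions; the model is trained on the
    chronological first 80% of each recording with the motion-contrast
    term separating the two motions' latent regions. The held-out 20%
    yields the frequency-preservation measurements; per-motion KDE
    regions support the self-membership and motion-switching analyses;
    the walking held-out segment provides the pre-window for
    initial-state optimization.

    The subject walks at the nominal tempo (period scale 1.0, so the
    fundamentals sit at exactly 1/30 and 1/20 cycles per sample);
    amplitude and phase individuality are drawn from the cohort ranges.
    """
    rng = np.random.default_rng(derive_seed(seed, "subjects"))
    subject = synthetic.SubjectProfile(
        "subject01",
        period_scale=1.0,
        amplitude_scale=float(rng.uniform(0.7, 1.3)),
        phase_offsets=tuple(rng.uniform(0.0, 2.0 * np.pi, size=3)),
    )
    motions = ("walking", "running")
    recordings = [
        synthetic.generate_recording(
            synthetic.archetype(m), subject, n_steps,
            derive_seed(seed, f"recording:{m}"))
        for m in motions
    ]
    model = MotionSDE.from_recordings(recordings, T=STUDY_CONFIG.T,
                                      config=STUDY_CONFIG,
                                      user_key="motion")
    results = model.fit(TrainConfig(
        n_epochs=n_epochs, seed=derive_seed(seed, "train"),
        contrast_weight=contrast_weight))

    n_train = int(0.8 * n_steps)
    latent_period, input_period, self_membership = {}, {}, {}
    regions = []
    for rec in recordings:
        frames = results.normalize(rec)
        z_train = results.latent_trajectory(frames[:n_train])[TRANSIENT:]
        region = fit_latent_region(z_train, rec.motion, percentile=5.0)
        member, _ = region_membership(z_train, region)
        self_membership[rec.motion] = float(member.mean())
        regions.append(region)
        z_test = results.latent_trajectory(frames[n_train:])[TRANSIENT:]
        latent_period[rec.motion] = _strongest_period(z_test)
        input_period[rec.motion] = dominant_period(
            frames[n_train:][TRANSIENT:, 0])

    # motion switching: walking -> running, phase-continuous
    sw = synthetic.generate_switching_recording(
        synthetic.archetype("walking"), synthetic.archetype("running"),
        switch_step, subject, 2 * switch_step,
        derive_seed(seed, "switch"))
    z_sw = results.latent_trajectory(results.normalize(sw))
    det = detect_motion_switch(z_sw[TRANSIENT:], regions, window=5)
    if len(det.switch_indices) == 1:
        switch_error = float(abs(det.switch_indices[0] + TRANSIENT
                                 - switch_step))
    else:
        switch_error = float("nan")

    # initial-state optimization on a held-out walking pre-window
    frames_w = results.normalize(recordings[0])
    pre = frames_w[n_train:n_train + 31]  # T0 = 30
    init = optimize_initial_state(pre, results.gen, results.prior,
                                  n_iter=300, lr=1e-2)
    ratio = init.final_discrepancy / init.trace[0]

    return MultiMotionStudy(
        results=results,
        recordings=recordings,
        subject=subject,
        latent_period=latent_period,
        input_period=input_period,
        self_membership=self_membership,
        n_switches=int(len(det.switch_indices)),
        switch_error=switch_error,
        init_discrepancy_ratio=float(ratio),
        train_loss_first=results.history.train_loss[0],
        train_loss_last=results.history.train_loss[-1],
    )


@dataclass
class IdentificationStudy:
    results: MotionSDEResults
    accuracy_trained: float
    accuracy_untrained: float


def run_identification_study(seed: int = 0, n_epochs: int = 600,
                             contrast_weight: float = 100.0,
                             n_steps: int = 1500) -> IdentificationStudy:
    """Two walking users with well-separated tempo (period scales 0.85 vs
    1.15); training includes the user-contrast term, and accuracy is
    measured on held-out pairings against an untrained (zero-output)
    scorer at chance level."""
    rng = np.random.default_rng(derive_seed(seed, "id-phases"))
    subjects = [
        synthetic.SubjectProfile("userA", period_scale=0.85,
                                 phase_offsets=tuple(
                                     rng.uniform(0, 2 * np.pi, 3))),
        synthetic.SubjectProfile("userB", period_scale=1.15,
                                 phase_offsets=tuple(
                                     rng.uniform(0, 2 * np.pi, 3))),
    ]
    arch = synthetic.archetype("walking")
    recordings = [
        synthetic.generate_recording(arch, s, n_steps,
                                     derive_seed(seed, f"id-rec:{i}"))
        for i, s in enumerate(subjects)
    ]
    model = MotionSDE.from_recordings(recordings, T=STUDY_CONFIG.T,
                                      config=STUDY_CONFIG,
                                      user_key="subject_id")
    results = model.fit(TrainConfig(
        n_epochs=n_epochs, seed=derive_seed(seed, "id-train"),
        contrast_weight=contrast_weight))

    n_train = int(0.8 * n_steps)
    fa = results.normalize(recordings[0])[n_train:]
    fb = results.normalize(recordings[1])[n_train:]
    za = results.latent_trajectory(fa)
    zb = results.latent_trajectory(fb)
    n = min(len(za), len(zb))

    def _accuracy(net):
        sa = user_identification_score(fa[:n], za[:n], zb[:n], net)
        sb = user_identification_score(fb[:n], zb[:n], za[:n], net)
        return 0.5 * (sa.accuracy + sb.accuracy)

    from .training import ContrastNet
    untrained = ContrastNet(np.random.default_rng(0),
                            hidden=STUDY_CONFIG.contrast_hidden)
    untrained.net.layers[-1].w.data[:] = 0.0
    untrained.net.layers[-1].b.data[:] = 0.0

    return IdentificationStudy(
        results=results,
        accuracy_trained=float(_accuracy(results.contrast)),
        accuracy_untrained=float(_accuracy(untrained)),
    )
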