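"""Post-training analyses: initial-state optimization, latent regions,
motion-switch detection, and contrastive user identification.

All analyses operate on the fitted objects from
:class:`~gyrosde.model.MotionSDEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .autodiff import Tensor
from .exceptions import (DegenerateDataError, InvalidArgumentError,
                         NotFittedError, OptimizationFailureError)
from .generative import GenerativeModel, PCAPrior
from .nn import AdamW
from .preprocessing import midpoint_targets
from .training import ContrastNet

ABNORMAL = "abnormal"


# ---------------------------------------------------------------------
# Initial-state optimization
# ---------------------------------------------------------------------

@dataclass
class InitStateResult:
    """Outcome of optimizing the pre-window start state z_{-T0}."""

    z_init_star: np.ndarray  # optimized latent at time -T0
    z0_estimate: np.ndarray  # propagated state at time 0
    final_discrepancy: float
    trace: np.ndarray  # best-so-far discrepancy per iteration
    used_fallback: bool = False  # True if PCA start was never improved


def _rollout_discrepancy(z: Tensor, gen: GenerativeModel,
                         targets: np.ndarray) -> Tensor:
    """Sum of squared errors between the decoded noise-free rollout means
    and the observed midpoint targets. The rollout uses the drift only
    (sigma_theta plays no role), which keeps the objective deterministic."""
    dt = gen.config.dt
    total = None
    state = z
    for t in range(len(targets)):
        dec = gen.decode_t(state)
        resid = dec - Tensor(targets[t])
        sq = (resid * resid).sum()
        total = sq if total is None else total + sq
        state = state + gen.drift_t(state) * dt
    return total


def optimize_initial_state(frames_pre: np.ndarray, gen: GenerativeModel,
                           prior: PCAPrior, n_iter: int = 500,
                           lr: float = 1e-2) -> InitStateResult:
    """Find z*_{-T0} whose deterministic rollout best reproduces the
    pre-window observations x_{-T0:0}.

    ``frames_pre`` holds the T0+1 normalized frames x_{-T0}..x_0; the
    objective is the squared discrepancy between decoded rollout means and
    the T0 midpoint targets. Optimization is adaptive-moment gradient
    descent from the PCA projection of x_{-T0}; the returned state is the
    best iterate, so the result is never worse than the PCA
    initialization (``used_fallback`` marks the degenerate case where no
    iterate improved on it).
    """
    frames_pre = np.asarray(frames_pre, dtype=float)
    if frames_pre.ndim != 2 or len(frames_pre) < 2:
        raise InvalidArgumentError("need at least 2 pre-window frames (T0 >= 1)")
    if n_iter < 0 or lr <= 0:
        raise InvalidArgumentError("n_iter must be >= 0 and lr > 0")
    targets = midpoint_targets(frames_pre)
    z0_pca = prior.project(frames_pre[0])
    z = Tensor(np.asarray(z0_pca, dtype=float).copy(), requires_grad=True)
    opt = AdamW([z], lr=lr, weight_decay=0.0)
    best_z = z.data.copy()
    best_val = float(_rollout_discrepancy(Tensor(best_z), gen, targets).data)
    start_val = best_val
    trace = [best_val]
    for _ in range(n_iter):
        opt.zero_grad()
        obj = _rollout_discrepancy(z, gen, targets)
        val = float(obj.data)
        if not np.isfinite(val):
            raise OptimizationFailureError("discrepancy became non-finite")
        if val < best_val:
            best_val = val
            best_z = z.data.copy()
        obj.backward()
        opt.step()
        trace.append(best_val)
    # propagate the best start forward to time 0
    state = best_z.copy()
    for _ in range(len(targets)):
        state = state + gen.drift(state) * gen.config.dt
    return InitStateResult(
        z_init_star=best_z,
        z0_estimate=state,
        final_discrepancy=best_val,
        trace=np.asarray(trace),
        used_fallback=bool(best_val >= start_val),
    )


# ---------------------------------------------------------------------
# Latent regions (KDE)
# ---------------------------------------------------------------------

class _IsotropicKDE:
    """Product-of-isotropic-Gaussian-kernels density with a forced
    bandwidth h; used when the caller fixes the kernel width explicitly
    (scipy's estimator scales data covariance, which is undefined for
    degenerate point sets)."""

    def __init__(self, points: np.ndarray, h: float):
        if h <= 0:
            raise InvalidArgumentError("bandwidth must be positive")
        self.points = np.asarray(points, dtype=float)
        self.h = float(h)

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d2 = ((x[:, None, :] - self.points[None, :, :]) ** 2).sum(axis=-1)
        k = np.exp(-0.5 * d2 / self.h ** 2) / (2.0 * np.pi * self.h ** 2)
        return k.mean(axis=1)


@dataclass
class LatentRegion:
    """A motion's normal region in latent space: a fitted kernel density
    plus a membership threshold on the density value."""

    label: str
    threshold: float
    kde: object  # scipy gaussian_kde or _IsotropicKDE
    points: np.ndarray = field(repr=False, default=None)

    def density(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        pts = np.atleast_2d(z)
        if isinstance(self.kde, gaussian_kde):
            d = self.kde(pts.T)
        else:
            d = self.kde(pts)
        return float(d[0]) if single else d


def fit_latent_region(points: np.ndarray, label: str,
                      percentile: float = 5.0,
                      isotropic_bandwidth: float | None = None
                      ) -> LatentRegion:
    """Gaussian KDE over latent points with a percentile threshold.

    Default: scipy's estimator with Scott's-rule bandwidth; the
    membership threshold is the ``percentile``-th percentile of the
    density evaluated at the fitting points, so ~(100 - percentile)% of
    them are members. ``isotropic_bandwidth`` forces a fixed isotropic
    kernel width instead (any number of points >= 1 allowed).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if isotropic_bandwidth is not None:
        kde = _IsotropicKDE(points, isotropic_bandwidth)
        dens = kde(points)
    else:
        if len(points) < 10:
            raise InvalidArgumentError(
                f"need >= 10 points to fit a region, got {len(points)}")
        if np.allclose(points.std(axis=0), 0.0):
            raise DegenerateDataError("all latent points identical")
        try:
            kde = gaussian_kde(points.T)  # Scott's rule
        except np.linalg.LinAlgError as err:
            raise DegenerateDataError(
                f"degenerate latent point set: {err}") from err
        dens = kde(points.T)
    threshold = float(np.percentile(dens, percentile))
    return LatentRegion(label=label, threshold=threshold, kde=kde,
                        points=points)


def region_membership(z, region: LatentRegion):
    """Member iff density(z) >= threshold; returns (member, density)."""
    d = region.density(z)
    return (d >= region.threshold), d


def region_integral_box(region: LatentRegion, low, high) -> float:
    """Integral of the region density over an axis-aligned box (scipy
    backend only) — a normalization check."""
    if not isinstance(region.kde, gaussian_kde):
        raise InvalidArgumentError("box integration needs the scipy backend")
    return float(region.kde.integrate_box(np.asarray(low), np.asarray(high)))


# ---------------------------------------------------------------------
# Trajectory smoothing and motion switching
# ---------------------------------------------------------------------

def smooth_trajectory(latents: np.ndarray, window: int = 5) -> np.ndarray:
    """Trailing (causal) moving average; the first window-1 entries
    average over the shrinking available history. Length is preserved."""
    if window < 1:
        raise InvalidArgumentError("window must be >= 1")
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    n = len(latents)
    csum = np.vstack([np.zeros((1, latents.shape[1])),
                      np.cumsum(latents, axis=0)])
    start = np.maximum(np.arange(n) - window + 1, 0)
    counts = (np.arange(n) - start + 1).astype(float)
    return (csum[np.arange(n) + 1] - csum[start]) / counts[:, None]


@dataclass
class SwitchDetection:
    labels: list  # per-step label: a motion name or 'abnormal'
    switch_indices: np.ndarray  # steps where the active motion changes
    label_changes: np.ndarray  # steps where the raw label changes (any)
    densities: np.ndarray  # (n_steps, n_regions)


def detect_motion_switch(latents: np.ndarray, regions: list[LatentRegion],
                         window: int = 5,
                         min_run: int = 5) -> SwitchDetection:
    """Label each smoothed latent step by the highest-density region;
    steps below every region's threshold are 'abnormal'.

    A *motion switch* is a change of the active motion. A motion becomes
    active only after a run of at least ``min_run`` consecutive steps
    carry its label — isolated one- or two-step labels inside the
    transition zone (where the encoder's history window still mixes both
    motions) are noise, not activity. The switch is timed one step past
    the previous motion's last confirmed run: leaving the normal region
    is the promptly observable event, while settling into the next
    region lags by the encoder's history. Excursions into 'abnormal' are
    anomaly events, not switches — they neither change the active motion
    nor appear in ``switch_indices`` (raw label changes, including
    abnormal flicker, are reported in ``label_changes``).
    """
    if not regions:
        raise InvalidArgumentError("need at least one fitted region")
    if min_run < 1:
        raise InvalidArgumentError("min_run must be >= 1")
    z = smooth_trajectory(latents, window=window)
    dens = np.column_stack([r.density(z) for r in regions])
    best = np.argmax(dens, axis=1)
    labels = []
    for i, b in enumerate(best):
        if dens[i, b] >= regions[b].threshold:
            labels.append(regions[b].label)
        else:
            labels.append(ABNORMAL)
    changes = np.asarray(
        [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]],
        dtype=int)
    # runs of identical labels; a motion run of >= min_run confirms it
    runs = []  # (label, start, end_inclusive)
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    switches = []
    active = None
    active_end = -1
    for lab, s, e in runs:
        if lab == ABNORMAL or (e - s + 1) < min_run:
            continue
        if active is not None and lab != active:
            switches.append(active_end + 1)
        active = lab
        active_end = e
    return SwitchDetection(labels=labels,
                           switch_indices=np.asarray(switches, dtype=int),
                           label_changes=changes, densities=dens)


# ---------------------------------------------------------------------
# User identification
# ---------------------------------------------------------------------

@dataclass
class UserIdScore:
    probabilities_same: np.ndarray
    probabilities_other: np.ndarray
    accuracy: float


def user_identification_score(x: np.ndarray, z_same: np.ndarray,
                              z_other: np.ndarray,
                              net: ContrastNet) -> UserIdScore:
    """Score the discriminator on held-out pairings.

    Positive pairs couple observations x with the same user's latents,
    negative pairs with another user's latents (aligned by step).
    Accuracy credits p > 0.5 on positives and p < 0.5 on negatives, with
    half credit for exact ties, so an all-0.5 (untrained) scorer sits at
    chance level 0.5.
    """
    if net is None:
        raise NotFittedError("no contrast network provided")
    x = np.asarray(x, dtype=float)
    n = min(len(x), len(z_same), len(z_other))
    if n < 1:
        raise InvalidArgumentError("empty pairing set")
    p_pos = net.probabilities(x[:n], np.asarray(z_same)[:n])
    p_neg = net.probabilities(x[:n], np.asarray(z_other)[:n])
    acc_pos = np.mean(p_pos > 0.5) + 0.5 * np.mean(p_pos == 0.5)
    acc_neg = np.mean(p_neg < 0.5) + 0.5 * np.mean(p_neg == 0.5)
    return UserIdScore(probabilities_same=p_pos, probabilities_other=p_neg,
                       accuracy=float(0.5 * (acc_pos + acc_neg)))


# ---------------------------------------------------------------------
# Spectral helper (frequency-preservation checks)
# ---------------------------------------------------------------------

def dominant_period(signal: np.ndarray) -> float:
    """Dominant discrete-Fourier period (samples) of a 1-D signal,
    excluding the DC component."""
    signal = np.asarray(signal, dtype=float)
    signal = signal - signal.mean()
    spec = np.abs(np.fft.rfft(signal))
    if len(spec) < 2:
        raise InvalidArgumentError("signal too short for a spectrum")
    k = 1 + int(np.argmax(spec[1:]))
    return len(signal) / k
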