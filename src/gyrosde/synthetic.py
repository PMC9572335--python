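"""Synthetic multi-subject gyroscope recordings with known structure.

Real thigh-worn gyroscope traces of repetitive motion are dominated by a
fundamental at the stride/repetition frequency plus a few harmonics, with
subject-specific tempo, amplitude and phase. The generator emulates exactly
that: each axis is a harmonic series of a motion-specific fundamental
(walking ~30 samples/cycle at 30 Hz, running ~20), modulated per subject
and corrupted by white Gaussian noise. Ground truth (period, switch point,
subject tempo) is known exactly, which makes every downstream stage of the
pipeline testable without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

MOTION_NAMES = ("walking", "running", "squats", "jumping_jacks")


@dataclass(frozen=True)
class MotionArchetype:
    """A repetitive motion's spectral fingerprint.

    ``period_samples`` is the fundamental period in samples at 30 Hz;
    ``amplitude_profile`` gives per-axis base amplitudes in rad/s;
    ``harmonic_weights`` are relative amplitudes of successive harmonics
    (first entry = fundamental).
    """

    name: str
    period_samples: int
    amplitude_profile: tuple = (1.2, 0.8, 0.5)
    harmonic_weights: tuple = (1.0, 0.4, 0.15)

    def __post_init__(self):
        if self.period_samples < 2:
            raise InvalidArgumentError("period_samples must be >= 2")
        amps = np.asarray(self.amplitude_profile, dtype=float)
        if amps.shape != (3,) or not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise InvalidArgumentError(
                "amplitude_profile must be 3 finite non-negative values"
            )
        if len(self.harmonic_weights) < 1:
            raise InvalidArgumentError("need at least one harmonic weight")


#: Default archetypes. Walking/running periods follow the observed stride
#: rates (1/30 and 1/20 cycles per sample at 30 Hz); squats are slower and
#: jumping jacks comparable to running. Amplitudes are plausible thigh-worn
#: gyroscope magnitudes in rad/s.
ARCHETYPES: dict[str, MotionArchetype] = {
    "walking": MotionArchetype("walking", 30, (1.2, 0.8, 0.5)),
    "running": MotionArchetype("running", 20, (2.5, 1.6, 1.0)),
    "squats": MotionArchetype("squats", 45, (0.9, 0.5, 0.4)),
    "jumping_jacks": MotionArchetype("jumping_jacks", 25, (1.8, 1.2, 0.9)),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject modulation of an archetype."""

    subject_id: str
    period_scale: float = 1.0
    amplitude_scale: float = 1.0
    phase_offsets: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.05

    def __post_init__(self):
        for name in ("period_scale", "amplitude_scale"):
            v = getattr(self, name)
            if not (0.5 < v < 2.0):
                raise InvalidArgumentError(f"{name}={v} outside (0.5, 2.0)")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise InvalidArgumentError("noise_sd must be finite and >= 0")
        if len(self.phase_offsets) != 3:
            raise InvalidArgumentError("phase_offsets must have 3 entries")


@dataclass
class SensorRecording:
    """A single-motion gyroscope log: timestamps (s) and omega (rad/s)."""

    subject_id: str
    motion: str
    sample_rate: float
    timestamps: np.ndarray  # (n,)
    omega: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if len(self.timestamps) != len(self.omega):
            raise InvalidArgumentError("timestamps and omega lengths differ")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


def _axis_signals(phase: np.ndarray, archetype: MotionArchetype,
                  subject: SubjectProfile) -> np.ndarray:
    """Harmonic series per axis given the (accumulated) fundamental phase."""
    amps = np.asarray(archetype.amplitude_profile) * subject.amplitude_scale
    out = np.zeros((len(phase), 3))
    for axis in range(3):
        theta = phase + subject.phase_offsets[axis]
        for h, w in enumerate(archetype.harmonic_weights, start=1):
            out[:, axis] += amps[axis] * w * np.sin(h * theta)
    return out


def _validate_steps(n_steps, sample_rate) -> None:
    if not isinstance(n_steps, (int, np.integer)) or n_steps <= 0:
        raise InvalidArgumentError("n_steps must be a positive integer")
    if sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be positive")


def generate_recording(archetype: MotionArchetype, subject: SubjectProfile,
                       n_steps: int, seed: int,
                       sample_rate: float = 30.0) -> SensorRecording:
    """Generate one noisy harmonic recording; deterministic in all args."""
    _validate_steps(n_steps, sample_rate)
    effective_period = archetype.period_samples * subject.period_scale
    if n_steps < 2 * effective_period:
        raise InvalidArgumentError(
            f"n_steps={n_steps} must cover at least two cycles "
            f"({2 * effective_period:.0f} samples)"
        )
    phase = 2.0 * np.pi / effective_period * np.arange(n_steps)
    signal = _axis_signals(phase, archetype, subject)
    rng = np.random.default_rng(seed)
    signal = signal + rng.normal(0.0, subject.noise_sd, size=(n_steps, 3))
    return SensorRecording(
        subject_id=subject.subject_id,
        motion=archetype.name,
        sample_rate=sample_rate,
        timestamps=np.arange(n_steps) / sample_rate,
        omega=signal,
    )


def generate_switching_recording(arch_a: MotionArchetype,
                                 arch_b: MotionArchetype,
                                 switch_step: int,
                                 subject: SubjectProfile,
                                 n_steps: int, seed: int,
                                 sample_rate: float = 30.0) -> SensorRecording:
    """Recording that follows ``arch_a`` before ``switch_step`` and
    ``arch_b`` from it on, phase-continuous at the switch.

    Phase continuity is enforced by accumulating the per-step phase
    increment of whichever archetype is active, so the fundamental has no
    discontinuity spike at the switch; only frequency and amplitudes jump.
    """
    _validate_steps(n_steps, sample_rate)
    if not (0 <= switch_step <= n_steps):
        raise InvalidArgumentError(
            f"switch_step={switch_step} outside [0, {n_steps}]"
        )
    inc_a = 2.0 * np.pi / (arch_a.period_samples * subject.period_scale)
    inc_b = 2.0 * np.pi / (arch_b.period_samples * subject.period_scale)
    # accumulated phase in closed form: inc_a up to the switch, inc_b after
    t = np.arange(n_steps, dtype=float)
    phase = np.where(t <= switch_step, inc_a * t,
                     inc_a * switch_step + inc_b * (t - switch_step))
    sig_a = _axis_signals(phase, arch_a, subject)
    sig_b = _axis_signals(phase, arch_b, subject)
    mask = (np.arange(n_steps) < switch_step)[:, None]
    signal = np.where(mask, sig_a, sig_b)
    rng = np.random.default_rng(seed)
    signal = signal + rng.normal(0.0, subject.noise_sd, size=(n_steps, 3))
    motion = f"{arch_a.name}->{arch_b.name}" if arch_a.name != arch_b.name \
        else arch_a.name
    return SensorRecording(
        subject_id=subject.subject_id,
        motion=motion,
        sample_rate=sample_rate,
        timestamps=np.arange(n_steps) / sample_rate,
        omega=signal,
    )


def draw_subjects(n_subjects: int, seed: int,
                  noise_sd: float = 0.05) -> list[SubjectProfile]:
    """Draw reproducible subject profiles.

    Tempo ~ U(0.85, 1.15), amplitude ~ U(0.7, 1.3), per-axis phases
    ~ U(0, 2pi): identifiable but overlapping subjects.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        subjects.append(SubjectProfile(
            subject_id=f"subject{i + 1:02d}",
            period_scale=float(rng.uniform(0.85, 1.15)),
            amplitude_scale=float(rng.uniform(0.7, 1.3)),
            phase_offsets=tuple(rng.uniform(0.0, 2.0 * np.pi, size=3)),
            noise_sd=noise_sd,
        ))
    return subjects


def generate_cohort(n_subjects: int, motions: list[MotionArchetype],
                    n_steps: int, seed: int, noise_sd: float = 0.05,
                    sample_rate: float = 30.0) -> list[SensorRecording]:
    """One recording per (subject, motion); profiles and per-recording
    noise seeds all derive deterministically from ``seed``."""
    if not motions:
        raise InvalidArgumentError("motions list must not be empty")
    subjects = draw_subjects(n_subjects, seed, noise_sd=noise_sd)
    children = np.random.SeedSequence(seed).spawn(n_subjects * len(motions))
    recordings = []
    for i, subject in enumerate(subjects):
        for j, arch in enumerate(motions):
            rec_seed = int(children[i * len(motions) + j].generate_state(1)[0]
                           % (2 ** 31))
            recordings.append(
                generate_recording(arch, subject, n_steps, rec_seed,
                                   sample_rate=sample_rate)
            )
    return recordings


def archetype(name: str) -> MotionArchetype:
    """Look up a default archetype by motion name."""
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown motion {name!r}; choose from {sorted(ARCHETYPES)}"
        ) from None
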