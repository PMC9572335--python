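"""File formats: sensor CSV logs, run configuration, model bundles.

Sensor logs are plain CSV with header ``timestamp,omega_x,omega_y,omega_z``
(seconds, rad/s), one row per sample. Model bundles are a single JSON
document (weights as nested lists; Python floats round-trip bit-exactly
through JSON), so reloading a bundle reproduces inference bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ParseError
from .generative import GenerativeConfig, GenerativeModel, PCAPrior
from .inference import GPT2Posterior, TransformerConfig
from .model import ModelConfig, MotionSDEResults
from .preprocessing import NormalizationStats
from .synthetic import SensorRecording
from .training import ContrastNet, TrainConfig

SENSOR_COLUMNS = ["timestamp", "omega_x", "omega_y", "omega_z"]
BUNDLE_VERSION = 1


# ---------------------------------------------------------------------
# Sensor CSV
# ---------------------------------------------------------------------

def write_sensor_csv(recording: SensorRecording, path) -> None:
    df = pd.DataFrame({
        "timestamp": recording.timestamps,
        "omega_x": recording.omega[:, 0],
        "omega_y": recording.omega[:, 1],
        "omega_z": recording.omega[:, 2],
    })
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_sensor_csv(path, subject_id: str | None = None,
                    motion: str | None = None) -> SensorRecording:
    """Read a sensor log; lenient about extra columns (warned, ignored),
    strict about missing columns, non-numeric cells and timestamp order."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in SENSOR_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring extra column(s) {extra}",
                      stacklevel=2)
    values = {}
    for col in SENSOR_COLUMNS:
        try:
            # numpy's parser is correctly rounded (exact round trips)
            values[col] = df[col].to_numpy(dtype=float)
        except (TypeError, ValueError):
            parsed = pd.to_numeric(df[col], errors="coerce")
            row = int(parsed.isna().idxmax())
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r} "
                f"at data row {row}") from None
        if np.isnan(values[col]).any():
            row = int(np.isnan(values[col]).argmax())
            raise ParseError(
                f"{path.name}: missing/non-numeric value in column "
                f"{col!r} at data row {row}")
    ts = values["timestamp"]
    if len(ts) > 1 and np.any(np.diff(ts) <= 0):
        raise FormatError(f"{path.name}: timestamps are not strictly "
                          "increasing")
    spacing = np.median(np.diff(ts)) if len(ts) > 1 else 1.0 / 30.0
    omega = np.column_stack([values["omega_x"], values["omega_y"],
                             values["omega_z"]])
    return SensorRecording(
        subject_id=subject_id or path.stem,
        motion=motion or "unknown",
        sample_rate=1.0 / spacing,
        timestamps=ts,
        omega=omega,
    )


def write_latents_csv(latents: np.ndarray, path) -> None:
    """Latent trajectory as CSV with columns t, z1, z2."""
    latents = np.asarray(latents, dtype=float)
    df = pd.DataFrame({"t": np.arange(len(latents)),
                       "z1": latents[:, 0], "z2": latents[:, 1]})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------
# Run configuration (flat YAML, unknown keys rejected)
# ---------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat, human-editable configuration for whole-pipeline runs.

    One global ``seed`` deterministically derives every module seed
    (see :func:`derive_seed`), so a run is reproducible from this file
    alone.
    """

    data_dir: str = "data"
    out_dir: str = "out"
    T: int = 90
    stride: int | None = None
    train_fraction: float = 0.8
    embed_dim: int = 32
    n_layers: int = 2
    n_heads: int = 1
    drift_hidden: tuple = (64, 64)
    decoder_hidden: tuple = (64, 64)
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 128
    n_epochs: int = 100
    contrast_weight: float = 0.0
    T0: int = 30
    kde_percentile: float = 5.0
    smooth_window: int = 5
    seed: int = 0


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a flat key-value document")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise FormatError(f"unknown config key(s): {unknown}")
    for key in ("drift_hidden", "decoder_hidden"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    data = asdict(config)
    for key in ("drift_hidden", "decoder_hidden"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def derive_seed(global_seed: int, purpose: str) -> int:
    """Deterministic per-purpose seed below 2^31 from one global seed."""
    h = hashlib.sha256(f"{global_seed}:{purpose}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_config_to_model_config(cfg: RunConfig) -> ModelConfig:
    return ModelConfig(
        T=cfg.T,
        generative=GenerativeConfig(drift_hidden=tuple(cfg.drift_hidden),
                                    decoder_hidden=tuple(cfg.decoder_hidden)),
        transformer=TransformerConfig(n_layers=cfg.n_layers,
                                      n_heads=cfg.n_heads,
                                      embed_dim=cfg.embed_dim,
                                      max_len=cfg.T + 1),
    )


def run_config_to_train_config(cfg: RunConfig) -> TrainConfig:
    return TrainConfig(batch_size=cfg.batch_size,
                       learning_rate=cfg.learning_rate,
                       weight_decay=cfg.weight_decay,
                       n_epochs=cfg.n_epochs,
                       seed=derive_seed(cfg.seed, "train"),
                       contrast_weight=cfg.contrast_weight)


# ---------------------------------------------------------------------
# Model bundle (JSON)
# ---------------------------------------------------------------------

def _arrays_to_lists(arrays: list[np.ndarray]) -> list:
    return [a.tolist() for a in arrays]


def _lists_to_arrays(lists: list) -> list[np.ndarray]:
    return [np.asarray(a, dtype=float) for a in lists]


def save_bundle(results: MotionSDEResults, path) -> None:
    cfg = results.config
    doc = {
        "version": BUNDLE_VERSION,
        "model_config": {
            "T": cfg.T,
            "generative": asdict(cfg.generative),
            "transformer": asdict(cfg.transformer),
            "contrast_hidden": list(cfg.contrast_hidden),
        },
        "train_config": (asdict(results.train_config)
                         if results.train_config else None),
        "stats": (None if results.stats is None else {
            "mean": results.stats.mean.tolist(),
            "sd": results.stats.sd.tolist(),
        }),
        "prior": {
            "sigma0": results.prior.sigma0,
            "components": results.prior.components_.tolist(),
            "mean": results.prior.mean_.tolist(),
        },
        "generative_state": _arrays_to_lists(results.gen.state_arrays()),
        "posterior_state": _arrays_to_lists(results.post.state_arrays()),
        "contrast_state": (None if results.contrast is None else
                           _arrays_to_lists(results.contrast.state_arrays())),
        "history": (None if results.history is None else {
            "train_loss": results.history.train_loss,
            "val_loss": results.history.val_loss,
        }),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path) -> MotionSDEResults:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != BUNDLE_VERSION:
        raise FormatError(f"unsupported bundle version {doc.get('version')}")
    mc = doc["model_config"]
    gen_cfg = GenerativeConfig(**{**mc["generative"],
                                  "drift_hidden": tuple(mc["generative"]["drift_hidden"]),
                                  "decoder_hidden": tuple(mc["generative"]["decoder_hidden"])})
    tr_cfg = TransformerConfig(**mc["transformer"])
    config = ModelConfig(T=mc["T"], generative=gen_cfg, transformer=tr_cfg,
                         contrast_hidden=tuple(mc["contrast_hidden"]))
    rng = np.random.default_rng(0)  # weights are overwritten below
    gen = GenerativeModel(gen_cfg, rng)
    gen.load_state_arrays(_lists_to_arrays(doc["generative_state"]))
    post = GPT2Posterior(tr_cfg, rng)
    post.load_state_arrays(_lists_to_arrays(doc["posterior_state"]))
    contrast = None
    if doc.get("contrast_state") is not None:
        contrast = ContrastNet(rng, hidden=config.contrast_hidden)
        contrast.load_state_arrays(_lists_to_arrays(doc["contrast_state"]))
    prior = PCAPrior(sigma0=doc["prior"]["sigma0"])
    prior.components_ = np.asarray(doc["prior"]["components"], dtype=float)
    prior.mean_ = np.asarray(doc["prior"]["mean"], dtype=float)
    stats = None
    if doc.get("stats") is not None:
        stats = NormalizationStats(mean=np.asarray(doc["stats"]["mean"]),
                                   sd=np.asarray(doc["stats"]["sd"]))
    tc = None
    if doc.get("train_config"):
        tc = TrainConfig(**doc["train_config"])
    return MotionSDEResults(model=None, gen=gen, post=post, prior=prior,
                            contrast=contrast, history=None,
                            train_config=tc, stats=stats, config=config)
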