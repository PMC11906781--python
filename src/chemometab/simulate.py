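"""Synthetic untargeted LC-MS feature tables with known ground truth.

The generator emulates the statistical structure of a four-group cell
metabolomics experiment (control, extract, oxidant, extract+oxidant):
log-normal feature intensities, a subset of class-informative features,
technical replicates nested in biological replicates, pooled QC samples,
a rank-one batch/systematic-noise component and per-sample dilution.

The additive model on the log10 scale is

    log10 x_ij = baseline_j + shift(class_i, j) + t_i * v_j + eps_ij

with intensities 10**(log10 x) multiplied by a per-sample dilution factor.
``t`` (batch scores) and ``v`` (unit-norm batch loading) form the planted
rank-one artifact that the PCA reconstruction stage is meant to remove.
The returned :class:`GroundTruth` is the oracle for every recovery test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASS_LABELS, FeatureTable, rng_for


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    All scales are on the log10-intensity axis except ``dilution_range``,
    which is multiplicative on raw intensities.
    """

    n_classes: int = 4
    n_bio_per_class: int = 5
    n_tech_reps: int = 3
    n_qc: int = 6
    n_features: int = 150
    n_informative: int = 30
    effect_size: float = 0.8
    batch_sd: float = 0.8
    dilution_range: tuple[float, float] = (0.7, 1.3)
    noise_sd: float = 0.1
    baseline_mean: float = 5.0
    baseline_sd: float = 0.8
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_classes": self.n_classes,
            "n_bio_per_class": self.n_bio_per_class,
            "n_tech_reps": self.n_tech_reps,
            "n_features": self.n_features,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.n_qc < 0:
            raise ConfigurationError("n_qc must be >= 0")
        if not (0 <= self.n_informative <= self.n_features):
            raise ConfigurationError("n_informative must lie in [0, n_features]")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise ConfigurationError("dilution_range must satisfy 0 < lo <= hi")
        for name in ("effect_size", "batch_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 1 <= self.n_classes <= len(CLASS_LABELS):
            raise ConfigurationError(f"n_classes must be in [1, {len(CLASS_LABELS)}]")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return CLASS_LABELS[: self.n_classes]


@dataclass
class GroundTruth:
    """True simulation parameters, the oracle for downstream recovery tests."""

    informative_ids: list[str]
    class_shift_matrix: np.ndarray  # classes x informative, log10 shifts
    batch_loading: np.ndarray  # unit vector over features
    batch_scores: np.ndarray  # per sample
    dilution_factors: np.ndarray  # per sample, > 0
    baselines: np.ndarray = field(default=None)  # type: ignore[assignment]
    class_labels: tuple[str, ...] = CLASS_LABELS

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _class_shifts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign each informative feature one affected treated class, +-effect_size.

    Features are allocated round-robin over the non-control classes so every
    class is marked by a dedicated feature block; signs are random.  With a
    single class everything stays zero (nothing to contrast).
    """
    shifts = np.zeros((cfg.n_classes, cfg.n_informative))
    if cfg.n_classes < 2 or cfg.n_informative == 0:
        return shifts
    treated = np.arange(1, cfg.n_classes)
    for j in range(cfg.n_informative):
        c = treated[j % len(treated)]
        shifts[c, j] = cfg.effect_size * rng.choice([-1.0, 1.0])
    return shifts


def generate_dataset(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table and its ground truth.

    Intensities are strictly positive by construction; identical seeds give
    bit-identical output.  QC samples are drawn from the global baseline
    profile (no class shift) but do receive batch, noise and dilution.
    """
    cfg = config
    rng = rng_for(cfg.seed, "simulate")

    feature_ids = [f"F{j:04d}" for j in range(cfg.n_features)]
    informative_idx = np.arange(cfg.n_informative)
    informative_ids = [feature_ids[j] for j in informative_idx]

    baselines = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(cfg.n_features)
    shifts = _class_shifts(cfg, rng)

    v = rng.standard_normal(cfg.n_features)
    v /= np.linalg.norm(v)

    rows, meta = [], []
    for ci, cls in enumerate(cfg.class_labels):
        for b in range(cfg.n_bio_per_class):
            for t in range(cfg.n_tech_reps):
                meta.append((f"{cls}_b{b + 1}_t{t + 1}", cls, f"{cls}_b{b + 1}", t + 1, False))
                rows.append(ci)
    for q in range(cfg.n_qc):
        meta.append((f"QC_{q + 1}", "QC", f"QC_{q + 1}", 1, True))
        rows.append(-1)  # no class shift

    n = len(meta)
    batch_scores = cfg.batch_sd * rng.standard_normal(n)
    lo, hi = cfg.dilution_range
    dilution = rng.uniform(lo, hi, size=n)
    noise = cfg.noise_sd * rng.standard_normal((n, cfg.n_features))

    log10x = np.tile(baselines, (n, 1))
    for i, ci in enumerate(rows):
        if ci >= 0 and cfg.n_informative:
            log10x[i, informative_idx] += shifts[ci]
    log10x += np.outer(batch_scores, v) + noise
    X = (10.0 ** log10x) * dilution[:, None]

    if cfg.dropout_rate > 0:
        drop = rng.random(X.shape) < cfg.dropout_rate
        X = np.where(drop, 0.0, X)

    sample_meta = pd.DataFrame(
        meta, columns=["sample_id", "class", "bio_rep", "tech_rep", "qc"]
    ).set_index("sample_id")
    sample_meta["injection_order"] = rng.permutation(n) + 1

    feature_meta = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    feature_meta["mz"] = np.round(rng.uniform(70, 800, cfg.n_features), 5)
    feature_meta["rt_min"] = np.round(rng.uniform(0.5, 7.5, cfg.n_features), 3)
    feature_meta["hmdb_id"] = ""
    # the first informative features mimic annotated metabolites so the
    # VIP -> HMDB -> pathway chain can run end to end on simulated data
    from .annotate import bundled_annotations

    ann = bundled_annotations()
    for j, (_, rec) in zip(informative_idx[: len(ann)], ann.iterrows()):
        feature_meta.iloc[j, feature_meta.columns.get_loc("hmdb_id")] = rec["hmdb_id"]
        feature_meta.iloc[j, feature_meta.columns.get_loc("mz")] = rec["observed_mz"]
        feature_meta.iloc[j, feature_meta.columns.get_loc("rt_min")] = rec["rt_min"]

    intensities = pd.DataFrame(X, index=sample_meta.index, columns=feature_meta.index)
    table = FeatureTable(intensities, sample_meta, feature_meta)
    truth = GroundTruth(
        informative_ids=informative_ids,
        class_shift_matrix=shifts,
        batch_loading=v,
        batch_scores=batch_scores,
        dilution_factors=dilution,
        baselines=baselines,
        class_labels=cfg.class_labels,
    )
    return table, truth


def qc_drift(table: FeatureTable, drift_sd: float, seed: int) -> FeatureTable:
    """Overlay a monotone injection-order multiplicative drift.

    The drift multiplier is exp(g * u_i) where u_i is the injection-order
    fraction in [0, 1] and g is a positive random magnitude of scale
    ``drift_sd``; drift_sd = 0 leaves the table unchanged.
    """
    if drift_sd < 0:
        raise ConfigurationError("drift_sd must be >= 0")
    if not table.is_qc.any():
        raise ValueError("qc_drift requires at least one QC sample in the table")
    if drift_sd == 0:
        return table.copy_with(table.intensities.copy())
    rng = rng_for(seed, "qc_drift")
    g = drift_sd * float(rng.lognormal(mean=0.0, sigma=0.25))
    order = table.sample_meta["injection_order"].to_numpy(dtype=float)
    u = (order - order.min()) / max(order.max() - order.min(), 1.0)
    factors = np.exp(g * u)
    return table.copy_with(table.values() * factors[:, None])
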