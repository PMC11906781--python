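"""Shared data model for the metabolomics workflow.

The central container is :class:`FeatureTable`: a samples x features
intensity matrix with sample metadata (treatment class, biological and
technical replicate structure, QC flag, injection order) and feature
metadata (m/z, retention time, optional HMDB annotation).  Every pipeline
stage consumes and returns this object, so validation lives here.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Treatment groups of the cell-stress study design: untreated control,
#: extract alone (M), oxidant alone (H2O2), and their combination.
CLASS_LABELS = ("CTRL", "M", "H2O2", "M+H2O2")

SAMPLE_META_COLUMNS = ["sample_id", "class", "bio_rep", "tech_rep", "qc", "injection_order"]


class FeatureTableError(ValueError):
    """Raised when a feature table violates its structural contract."""


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from one master seed.

    Sub-streams are independent because each stage label is hashed into the
    seed sequence; the same (seed, label) pair always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())]))


@dataclass
class FeatureTable:
    """Intensity matrix plus sample and feature metadata.

    Parameters
    ----------
    intensities
        DataFrame of non-negative intensities, indexed by ``sample_id`` with
        feature ids as columns.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``class``,
        ``bio_rep``, ``tech_rep``, ``qc`` (bool) and ``injection_order``.
    feature_meta
        DataFrame indexed by ``feature_id``; optional columns ``mz``,
        ``rt_min``, ``hmdb_id``.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.intensities.columns)
            self.feature_meta.index.name = "feature_id"
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        X = self.intensities
        if X.shape[0] == 0:
            raise FeatureTableError("feature table has zero samples")
        if X.shape[1] == 0:
            raise FeatureTableError("feature table has zero features")
        if X.index.duplicated().any():
            dups = X.index[X.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample ids: {dups}")
        if X.columns.duplicated().any():
            dups = X.columns[X.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicate feature ids: {dups}")
        neg = np.asarray(X) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise FeatureTableError(
                f"negative intensity at sample {X.index[i]!r}, feature {X.columns[j]!r}"
            )
        if not X.index.equals(self.sample_meta.index):
            raise FeatureTableError("sample metadata index does not match intensity rows")
        if not X.columns.equals(self.feature_meta.index):
            raise FeatureTableError("feature metadata index does not match intensity columns")
        if "class" in self.sample_meta and "qc" in self.sample_meta:
            bad = set(self.sample_meta.loc[~self.sample_meta["qc"].astype(bool), "class"]) - set(CLASS_LABELS)
            if bad:
                raise FeatureTableError(f"unknown class labels: {sorted(bad)}")

    @classmethod
    def _unchecked(cls, intensities: pd.DataFrame, sample_meta: pd.DataFrame, feature_meta: pd.DataFrame) -> "FeatureTable":
        """Build without validation, for transformed (e.g. autoscaled) tables
        whose values legitimately go negative."""
        obj = object.__new__(cls)
        obj.intensities = intensities
        obj.sample_meta = sample_meta
        obj.feature_meta = feature_meta
        return obj

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> pd.Series:
        return self.sample_meta["class"]

    @property
    def is_qc(self) -> np.ndarray:
        return self.sample_meta["qc"].astype(bool).to_numpy()

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    def copy_with(self, intensities: pd.DataFrame | np.ndarray) -> "FeatureTable":
        """Return a new table with replaced intensities, same metadata."""
        if isinstance(intensities, np.ndarray):
            intensities = pd.DataFrame(
                intensities, index=self.intensities.index, columns=self.intensities.columns
            )
        return FeatureTable._unchecked(intensities, self.sample_meta.copy(), self.feature_meta.copy())

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable._unchecked(
            self.intensities.loc[mask], self.sample_meta.loc[mask], self.feature_meta.copy()
        )


# -- CSV round trip --------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path, feature_meta_path: str | Path | None = None) -> None:
    """Write the table as one CSV: metadata prefix columns, then features."""
    df = table.sample_meta.reset_index()
    wide = pd.concat([df, table.intensities.reset_index(drop=True)], axis=1)
    wide.to_csv(path, index=False)
    if feature_meta_path is not None:
        table.feature_meta.to_csv(feature_meta_path)


def read_feature_table(path: str | Path, feature_meta_path: str | Path | None = None) -> FeatureTable:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    wide = pd.read_csv(path)
    missing = [c for c in SAMPLE_META_COLUMNS if c not in wide.columns]
    if missing:
        raise FeatureTableError(f"{path}: missing metadata columns {missing}")
    meta = wide[SAMPLE_META_COLUMNS].set_index("sample_id")
    meta["qc"] = meta["qc"].astype(bool)
    feats = wide.drop(columns=SAMPLE_META_COLUMNS).set_index(wide["sample_id"])
    feats.index.name = "sample_id"
    feats.columns.name = "feature_id"
    fmeta = pd.read_csv(feature_meta_path, index_col=0) if feature_meta_path else None
    return FeatureTable(feats.astype(float), meta, fmeta)
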