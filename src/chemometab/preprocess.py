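"""Normalization and scaling for LC-MS feature tables.

The pipeline applies, in order and each exactly once:

1. median-by-row normalization (each sample divided by its own median),
2. probabilistic quotient normalization (PQN) against the element-wise
   median spectrum of the control group,
3. log10 transform (with an optional pseudo-intensity offset for zeros),
4. autoscaling (per-feature mean 0, sample-SD 1).

All fitted constants live in :class:`PreprocessState` so the identical
transform can be applied to held-out cross-validation folds without
information leaking from them into the normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureTable

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessRecipe:
    do_row_median: bool = True
    do_pqn: bool = True
    pqn_reference_class: str = "CTRL"
    log_offset: float = 0.0
    scale_mode: str = "autoscale"
    zero_policy: str = "offset"  # or "error"

    def __post_init__(self) -> None:
        if self.log_offset < 0:
            raise PreprocessError("log_offset must be >= 0")
        if self.scale_mode not in ("autoscale", "none"):
            raise PreprocessError(f"unknown scale_mode {self.scale_mode!r}")
        if self.zero_policy not in ("offset", "error"):
            raise PreprocessError(f"unknown zero_policy {self.zero_policy!r}")


@dataclass
class PreprocessState:
    """Constants fitted on training data, reapplicable to new samples."""

    row_medians: np.ndarray | None = None
    reference_spectrum: np.ndarray | None = None
    pqn_factors: np.ndarray | None = None
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None
    offset: float = 0.0
    kept_features: np.ndarray | None = None  # mask of non-constant columns
    recipe: PreprocessRecipe = field(default_factory=PreprocessRecipe)


# -- elementary operations --------------------------------------------------

def median_row_normalize(X: np.ndarray, sample_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Divide each sample (row) by its own median intensity.

    Output rows all have median 1; a row with median <= 0 is an error that
    names the offending sample.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1)
    bad = np.where(med <= 0)[0]
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise PreprocessError(f"sample {name} has non-positive median intensity")
    return X / med[:, None], med


def pqn_normalize(
    X: np.ndarray, classes, reference_class: str = "CTRL"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probabilistic quotient normalization.

    The reference spectrum r_j is the element-wise median over the
    reference-class samples; each sample is divided by the median of its
    quotients x_ij / r_j.  Features with r_j = 0 are excluded from the
    quotient median (with a warning).  Returns (normalized X, r, s).
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    ref_mask = classes == reference_class
    if not ref_mask.any():
        raise PreprocessError(f"no samples in PQN reference class {reference_class!r}")
    r = np.median(X[ref_mask], axis=0)
    usable = r > 0
    if not usable.any():
        raise PreprocessError("PQN reference spectrum is all zero")
    if not usable.all():
        warnings.warn(
            f"PQN: excluding {int((~usable).sum())} features with zero reference median",
            stacklevel=2,
        )
    s = pqn_factors(X, r)
    return X / s[:, None], r, s


def pqn_factors(X: np.ndarray, reference_spectrum: np.ndarray) -> np.ndarray:
    """Per-sample quotient medians against a fixed reference spectrum."""
    r = np.asarray(reference_spectrum, dtype=float)
    usable = r > 0
    if not usable.any():
        raise PreprocessError("PQN reference spectrum is all zero")
    q = np.asarray(X, dtype=float)[:, usable] / r[usable]
    s = np.median(q, axis=1)
    if (s <= 0).any():
        raise PreprocessError("non-positive PQN quotient median encountered")
    return s


def log_transform(X: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Element-wise log10(x + offset); errors if any shifted value is <= 0."""
    X = np.asarray(X, dtype=float)
    shifted = X + offset
    if (shifted <= 0).any():
        raise PreprocessError("log10 of non-positive value; raise log_offset or fix zeros")
    return np.log10(shifted)


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to sample SD 1 (n-1 denominator).

    Constant columns cannot be scaled; the caller decides their fate via
    :func:`constant_feature_mask`.  Here an all-constant matrix is an error.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    tol = _constant_tol(mu)
    if (sd <= tol).all():
        raise PreprocessError("all columns are constant; nothing to autoscale")
    if (sd <= tol).any():
        raise PreprocessError(
            "constant columns present; drop them (see preprocess_table) before autoscaling"
        )
    return (X - mu) / sd, mu, sd


def _constant_tol(mu: np.ndarray) -> np.ndarray:
    """SD threshold below which a column counts as constant (relative to its mean)."""
    return np.sqrt(np.finfo(float).eps) * np.maximum(np.abs(mu), 1.0)


def inverse_autoscale(Z: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return np.asarray(Z) * sd + mu


# -- pipeline ---------------------------------------------------------------

def preprocess_table(table: FeatureTable, recipe: PreprocessRecipe | None = None) -> tuple[FeatureTable, PreprocessState]:
    """Apply the full normalization sequence to a feature table.

    Returns the transformed table (autoscaled log10 intensities; constant
    features dropped with a warning) and the fitted state.
    """
    recipe = recipe or PreprocessRecipe()
    X = table.values()
    state = PreprocessState(recipe=recipe)

    if (X == 0).any():
        if recipe.zero_policy == "error":
            raise PreprocessError("zero intensities present and zero_policy='error'")
        nonzero = X[X > 0]
        state.offset = float(nonzero.min() / 2.0)
        X = X + state.offset
        log.info("zero intensities offset by %g (half the smallest non-zero value)", state.offset)

    ids = table.intensities.index.to_numpy()
    if recipe.do_row_median:
        X, state.row_medians = median_row_normalize(X, ids)
    if recipe.do_pqn:
        classes = table.classes.to_numpy()
        if not (classes == recipe.pqn_reference_class).any():
            raise PreprocessError(
                f"PQN reference class {recipe.pqn_reference_class!r} absent from table"
            )
        X, state.reference_spectrum, state.pqn_factors = pqn_normalize(
            X, classes, recipe.pqn_reference_class
        )
    X = log_transform(X, recipe.log_offset)

    if recipe.scale_mode == "autoscale":
        sd = X.std(axis=0, ddof=1)
        keep = sd > _constant_tol(X.mean(axis=0))
        if not keep.any():
            raise PreprocessError("all features constant after transformation")
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant features", stacklevel=2)
        state.kept_features = keep
        X = X[:, keep]
        X, state.col_means, state.col_sds = autoscale(X)
        cols = table.intensities.columns[keep]
    else:
        state.kept_features = np.ones(X.shape[1], dtype=bool)
        cols = table.intensities.columns

    out = pd.DataFrame(X, index=table.intensities.index, columns=cols)
    return (
        FeatureTable._unchecked(out, table.sample_meta.copy(), table.feature_meta.loc[cols].copy()),
        state,
    )


def apply_state(X: np.ndarray, state: PreprocessState) -> np.ndarray:
    """Transform held-out raw intensities with constants fitted on training data.

    Row medians and PQN quotient factors are per-sample quantities and are
    recomputed for the new samples, but the PQN *reference spectrum* and the
    autoscaling constants come from the stored training state, so no
    information flows from held-out samples into the model.
    """
    recipe = state.recipe
    X = np.asarray(X, dtype=float) + state.offset
    if recipe.do_row_median:
        X, _ = median_row_normalize(X)
    if recipe.do_pqn:
        s = pqn_factors(X, state.reference_spectrum)
        X = X / s[:, None]
    X = log_transform(X, recipe.log_offset)
    X = X[:, state.kept_features]
    if recipe.scale_mode == "autoscale":
        X = (X - state.col_means) / state.col_sds
    return X
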