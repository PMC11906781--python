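"""PCA exploration: scores, Hotelling ellipses, noise-component removal.

Beyond a plain SVD decomposition this module implements the two exploratory
manoeuvres of the workflow: per-group Hotelling T-squared confidence
ellipses on 2-D score plots, and removal of a designated systematic-noise
component (e.g. a batch effect) followed by data reconstruction, after
which technical replicates are averaged and the PCA refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureTable


class PCAError(ValueError):
    pass


@dataclass
class PCAModel:
    """Scores T (n x A), orthonormal loadings P (p x A), variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    n_components: int
    feature_ids: np.ndarray | None = None
    sample_ids: np.ndarray | None = None


@dataclass
class EllipseSpec:
    group: str
    center: np.ndarray
    semi_axes: np.ndarray
    angle: float  # radians, orientation of the major axis
    confidence: float
    # internals for membership tests
    cov: np.ndarray = None  # type: ignore[assignment]
    critical_value: float = 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of 2-D points inside the ellipse (Mahalanobis test)."""
        d = np.asarray(points, dtype=float) - self.center
        icov = np.linalg.inv(self.cov)
        md2 = np.einsum("ij,jk,ik->i", d, icov, d)
        return md2 <= self.critical_value


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Singular-value PCA of an (already centered/autoscaled) matrix.

    explained_fraction[a] = s_a^2 / sum(s^2).  Sign convention: for every
    component, the loading element with the largest magnitude is positive,
    which makes loadings and quadrant calls reproducible across runs.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise PCAError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise PCAError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * max(n, p) * np.finfo(float).eps).sum()) if s.size else 0
    if n_components > rank:
        raise PCAError(f"n_components={n_components} exceeds matrix rank {rank}")
    P = Vt[:n_components].T
    # deterministic signs
    flip = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    P = P * flip
    T = X @ P
    frac = (s**2 / (s**2).sum())[:n_components]
    return PCAModel(scores=T, loadings=P, explained_fraction=frac, n_components=n_components)


def hotelling_ellipse(scores2d: np.ndarray, confidence: float = 0.95, group: str = "") -> EllipseSpec:
    """Hotelling T-squared confidence ellipse of a 2-D score cloud.

    Critical value c = 2(n-1)/(n-2) * F(confidence; 2, n-2); the ellipse is
    the Mahalanobis contour of the group's score covariance at c, with
    semi-axes sqrt(eigenvalue_k * c).
    """
    Y = np.asarray(scores2d, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise PCAError("hotelling_ellipse expects an n x 2 score matrix")
    n = Y.shape[0]
    if n < 4:
        raise PCAError(f"need at least 4 samples for a Hotelling ellipse, got {n}")
    if not 0 < confidence < 1:
        raise PCAError("confidence must lie in (0, 1)")
    center = Y.mean(axis=0)
    cov = np.cov(Y, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        raise PCAError("singular score covariance; ellipse undefined")
    c = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(confidence, 2, n - 2)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return EllipseSpec(
        group=group,
        center=center,
        semi_axes=np.sqrt(evals * c),
        angle=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        confidence=confidence,
        cov=cov,
        critical_value=c,
    )


def group_ellipses(scores2d: np.ndarray, classes, confidence: float = 0.95) -> dict[str, EllipseSpec]:
    """One ellipse per class, each computed independently."""
    classes = np.asarray(classes)
    return {
        g: hotelling_ellipse(scores2d[classes == g], confidence, group=str(g))
        for g in pd.unique(classes)
    }


def remove_components_and_reconstruct(
    X: np.ndarray, model: PCAModel, drop: set[int] | list[int]
) -> np.ndarray:
    """Subtract the chosen score*loading products from the data.

    ``drop`` uses 1-based component indices (PC1 = 1).  Only the dropped
    components are removed; variance beyond the modelled components is kept,
    which is the minimal intervention consistent with reconstructing the
    data after excising one artifact direction.
    """
    if model is None or model.n_components == 0:
        raise PCAError("empty PCA model")
    drop = sorted(set(int(d) for d in drop))
    if any(d < 1 or d > model.n_components for d in drop):
        raise PCAError(f"drop indices {drop} outside 1..{model.n_components}")
    X_rec = np.asarray(X, dtype=float).copy()
    for d in drop:
        a = d - 1
        X_rec -= np.outer(model.scores[:, a], model.loadings[:, a])
    return X_rec


def average_replicates(table: FeatureTable, group_col: str = "bio_rep") -> FeatureTable:
    """Collapse technical replicates to their arithmetic mean.

    One output row per replicate group; class labels must be consistent
    within a group.  QC samples keep their own (singleton) groups.
    """
    groups = table.sample_meta[group_col]
    if groups.isna().any():
        raise PCAError("every sample needs a replicate-group id")
    n_cls = table.sample_meta.groupby(group_col)["class"].nunique()
    bad = n_cls[n_cls > 1]
    if len(bad):
        raise PCAError(f"conflicting class labels within replicate group(s) {bad.index.tolist()}")
    X = table.intensities.groupby(groups).mean()
    meta = table.sample_meta.groupby(group_col).first()
    meta = meta.drop(columns=["tech_rep"], errors="ignore")
    meta["n_tech_averaged"] = table.sample_meta.groupby(group_col).size()
    X.index.name = "sample_id"
    meta.index.name = "sample_id"
    # negative reconstructed values are legitimate here (autoscaled space)
    return FeatureTable._unchecked(X.loc[meta.index], meta, table.feature_meta.copy())


QUADRANT_SYMBOLS = {(1, 1): "up", (-1, -1): "down", (1, -1): "right", (-1, 1): "left"}


@dataclass
class LoadingSelection:
    feature_ids: list[str]
    quadrants: dict[str, str]  # feature -> up/down/right/left
    associated_class: dict[str, str]
    loadings: pd.DataFrame  # selected features x [pc1, pc2]


def select_loadings(
    model: PCAModel,
    feature_ids,
    rel_threshold: float = 0.5,
    class_means: pd.DataFrame | None = None,
    components: tuple[int, int] = (1, 2),
) -> LoadingSelection:
    """Select influential loadings on a 2-D component pair.

    A feature is kept when its |loading| on either displayed component
    reaches ``rel_threshold`` times that component's maximum |loading|.
    Quadrant symbols follow the score-plot reading: up = positive on both
    components, down = negative on both, right = PC1-positive/PC2-negative,
    left = PC1-negative/PC2-positive.  The associated class is the one whose
    (autoscaled) group mean for the feature is largest in magnitude.
    """
    if model.n_components < 2:
        raise PCAError("need at least two components to select 2-D loadings")
    if not 0 < rel_threshold <= 1:
        raise PCAError("rel_threshold must lie in (0, 1]")
    a, b = components[0] - 1, components[1] - 1
    p1, p2 = model.loadings[:, a], model.loadings[:, b]
    feature_ids = np.asarray(feature_ids)
    m1, m2 = np.abs(p1).max(), np.abs(p2).max()
    if m1 == 0 and m2 == 0:
        return LoadingSelection([], {}, {}, pd.DataFrame(columns=["pc1", "pc2"]))
    sel = np.zeros(len(feature_ids), dtype=bool)
    if m1 > 0:
        sel |= np.abs(p1) >= rel_threshold * m1
    if m2 > 0:
        sel |= np.abs(p2) >= rel_threshold * m2
    ids = feature_ids[sel]
    quadrants = {
        fid: QUADRANT_SYMBOLS[(1 if x >= 0 else -1, 1 if y >= 0 else -1)]
        for fid, x, y in zip(ids, p1[sel], p2[sel])
    }
    assoc: dict[str, str] = {}
    if class_means is not None:
        for fid in ids:
            assoc[fid] = class_means[fid].abs().idxmax()
    frame = pd.DataFrame({"pc1": p1[sel], "pc2": p2[sel]}, index=pd.Index(ids, name="feature_id"))
    return LoadingSelection(list(ids), quadrants, assoc, frame)


def rank_components_by_correlation(model: PCAModel, covariate: np.ndarray) -> pd.DataFrame:
    """Diagnostic helper: |Pearson r| of each PC's scores with a nuisance covariate.

    Ranks candidates for removal (batch score, injection order); it never
    drops anything itself -- the choice stays explicit.
    """
    covariate = np.asarray(covariate, dtype=float)
    rows = []
    for a in range(model.n_components):
        r = np.corrcoef(model.scores[:, a], covariate)[0, 1]
        rows.append({"component": a + 1, "abs_correlation": abs(float(r))})
    return pd.DataFrame(rows).sort_values("abs_correlation", ascending=False, ignore_index=True)
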