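"""End-to-end orchestration of the chemometric workflow.

``run_pipeline`` chains: simulate (or load) -> normalize (row-median, PQN,
log10, autoscale) -> initial PCA -> removal of designated noise components
and reconstruction -> technical-replicate averaging -> final PCA with
Hotelling ellipses and loading selection -> PLS-DA rDCV + permutation test
-> VIP-based metabolite selection -> pathway over-representation.  Every
intermediate artifact is written to the output directory and a JSON report
summarizes the run; identical config + seed reproduces all numbers.

Ground-truth files produced by the simulator are written for reference but
never read back by any stage: they exist for external validation only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FeatureTable, read_feature_table, write_feature_table
from .pca import (
    average_replicates,
    fit_pca,
    group_ellipses,
    remove_components_and_reconstruct,
    select_loadings,
)
from .pathways import PathwayLibrary, bundled_library, enrich, results_frame
from .plsda import permutation_test, rdcv
from .preprocess import PreprocessRecipe, preprocess_table
from .simulate import SimulationConfig, generate_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a reproducible run needs; the seed is mandatory."""

    seed: int
    out_dir: str | Path = "pipeline_out"
    input_table: str | Path | None = None  # CSV; when None, simulate
    feature_meta: str | Path | None = None
    simulation: SimulationConfig | None = None
    recipe: PreprocessRecipe = field(default_factory=PreprocessRecipe)
    n_pcs: int = 5
    drop_pcs: tuple[int, ...] = ()  # noise-PC removal is an explicit analyst decision
    refit_autoscale: bool = False  # final PCA refit without re-autoscaling
    include_qc_final: bool = False
    loading_threshold: float = 0.5
    ellipse_confidence: float = 0.95
    outer: int = 10
    inner: int = 10
    repeats: int = 50
    max_A: int = 5
    n_permutations: int = 0  # 0 skips the permutation stage
    vip_threshold: float = 1.0
    vip_frequency_cutoff: float = 0.5
    alpha: float = 0.05
    pathway_library: str | Path | None = None  # JSON/GMT; None -> bundled

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PipelineError("seed is mandatory")
        if self.input_table is not None and not Path(self.input_table).exists():
            raise PipelineError(f"input table {self.input_table} does not exist")
        if self.pathway_library is not None and not Path(self.pathway_library).exists():
            raise PipelineError(f"pathway library {self.pathway_library} does not exist")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return inner

    return wrap


def _load_library(cfg: RunConfig) -> PathwayLibrary:
    if cfg.pathway_library is None:
        return bundled_library()
    path = Path(cfg.pathway_library)
    if path.suffix.lower() == ".gmt":
        return PathwayLibrary.from_gmt(path)
    return PathwayLibrary.from_json(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__, "stages": [], "artifacts": {}}

    def artifact(key: str, path: Path) -> None:
        report["artifacts"][key] = str(path)

    # 1. input data ---------------------------------------------------------
    if cfg.input_table is not None:
        table = _stage("read")(read_feature_table)(cfg.input_table, cfg.feature_meta)
    else:
        sim = cfg.simulation or SimulationConfig(seed=cfg.seed)
        if sim.seed != cfg.seed:
            sim = dataclasses.replace(sim, seed=cfg.seed)
        table, truth = _stage("simulate")(generate_dataset)(sim)
        write_feature_table(table, out / "feature_table.csv", out / "feature_meta.csv")
        truth.to_json(out / "ground_truth.json")  # for external checks; never read below
        artifact("feature_table", out / "feature_table.csv")
    report["stages"].append("input")
    report["n_samples"], report["n_features"] = table.n_samples, table.n_features

    # 2. normalization ------------------------------------------------------
    pre, state = _stage("preprocess")(preprocess_table)(table, cfg.recipe)
    report["stages"].append("preprocess")
    report["preprocess"] = {
        "row_median": cfg.recipe.do_row_median,
        "pqn": cfg.recipe.do_pqn,
        "pqn_reference_class": cfg.recipe.pqn_reference_class,
        "zero_offset": state.offset,
        "n_features_kept": int(state.kept_features.sum()),
    }

    # 3. initial PCA + noise-component removal ------------------------------
    Z = pre.values()
    n_pcs = min(cfg.n_pcs, Z.shape[0] - 1, Z.shape[1])
    model0 = _stage("pca")(fit_pca)(Z, n_pcs)
    Z_rec = _stage("reconstruct")(remove_components_and_reconstruct)(Z, model0, cfg.drop_pcs)
    rec_table = pre.copy_with(Z_rec)
    report["stages"] += ["pca_initial", "reconstruct"]
    report["initial_explained_fraction"] = model0.explained_fraction.tolist()
    report["dropped_pcs"] = list(cfg.drop_pcs)

    # 4. replicate averaging (QCs out by default for the final model) -------
    if not cfg.include_qc_final:
        rec_table = _subset(rec_table, ~rec_table.sample_meta["qc"].astype(bool).to_numpy())
    avg = _stage("average")(average_replicates)(rec_table)
    report["stages"].append("average_replicates")

    # 5. final PCA, ellipses, loadings --------------------------------------
    Xf = avg.intensities.to_numpy(dtype=float)
    if cfg.refit_autoscale:
        from .preprocess import autoscale

        Xf, _, _ = autoscale(Xf)
    else:
        Xf = Xf - Xf.mean(axis=0)  # recenter only; scale left as reconstructed
    A_final = min(cfg.n_pcs, Xf.shape[0] - 1, Xf.shape[1])
    model = _stage("pca_final")(fit_pca)(Xf, A_final)
    classes = avg.sample_meta["class"].to_numpy()
    scores2d = model.scores[:, :2]
    counts = pd.Series(classes).value_counts()
    ellipses = {}
    if (counts >= 4).all():
        ellipses = _stage("ellipses")(group_ellipses)(scores2d, classes, cfg.ellipse_confidence)
    class_means = pd.DataFrame(Xf, columns=avg.intensities.columns).groupby(classes).mean()
    selection = _stage("loadings")(select_loadings)(
        model, avg.intensities.columns, cfg.loading_threshold, class_means
    )
    report["stages"].append("pca_final")
    report["final_explained_fraction"] = model.explained_fraction.tolist()
    report["explained_pc1_pct"] = float(model.explained_fraction[0] * 100)
    report["explained_pc2_pct"] = float(model.explained_fraction[1] * 100) if A_final > 1 else None
    report["n_selected_loadings"] = len(selection.feature_ids)

    scores_df = pd.DataFrame(
        model.scores, index=avg.intensities.index,
        columns=[f"PC{a+1}" for a in range(A_final)],
    )
    scores_df.insert(0, "class", classes)
    scores_df.to_csv(out / "pca_scores.csv")
    pd.DataFrame(
        model.loadings, index=avg.intensities.columns,
        columns=[f"PC{a+1}" for a in range(A_final)],
    ).to_csv(out / "pca_loadings.csv")
    artifact("pca_scores", out / "pca_scores.csv")
    artifact("pca_loadings", out / "pca_loadings.csv")
    (out / "ellipses.json").write_text(
        json.dumps(
            {
                g: {
                    "center": e.center.tolist(),
                    "semi_axes": e.semi_axes.tolist(),
                    "angle": e.angle,
                    "confidence": e.confidence,
                }
                for g, e in ellipses.items()
            },
            indent=1,
        )
    )
    artifact("ellipses", out / "ellipses.json")
    selection.loadings.assign(
        quadrant=[selection.quadrants[f] for f in selection.feature_ids],
        associated_class=[selection.associated_class.get(f, "") for f in selection.feature_ids],
    ).to_csv(out / "selected_loadings.csv")
    artifact("selected_loadings", out / "selected_loadings.csv")

    # 6. PLS-DA rDCV + permutation ------------------------------------------
    y = classes
    res = _stage("rdcv")(rdcv)(
        Xf,
        y,
        outer=min(cfg.outer, len(y)),
        inner=cfg.inner,
        repeats=cfg.repeats,
        max_A=cfg.max_A,
        seed=cfg.seed,
        vip_threshold=cfg.vip_threshold,
    )
    report["stages"].append("rdcv")
    report["rdcv"] = {
        "accuracy_mean_pct": res.accuracy_mean,
        "accuracy_sd_pct": res.accuracy_sd,
        "sensitivity_mean_pct": res.sensitivity_mean,
        "sensitivity_sd_pct": res.sensitivity_sd,
        "specificity_mean_pct": res.specificity_mean,
        "specificity_sd_pct": res.specificity_sd,
        "chosen_A_distribution": {str(k): v for k, v in res.chosen_A_distribution.items()},
    }
    metrics = pd.DataFrame(
        {
            "sensitivity_mean": res.sensitivity_mean,
            "sensitivity_sd": res.sensitivity_sd,
            "specificity_mean": res.specificity_mean,
            "specificity_sd": res.specificity_sd,
        }
    )
    metrics.to_csv(out / "rdcv_metrics.csv")
    res.misclassification_matrix.to_csv(out / "misclassification_matrix.csv")
    vip_table = pd.DataFrame(
        {"vip_frequency": res.vip_frequency}, index=avg.intensities.columns
    ).sort_values("vip_frequency", ascending=False)
    vip_table.to_csv(out / "vip_frequency.csv")
    artifact("rdcv_metrics", out / "rdcv_metrics.csv")
    artifact("misclassification_matrix", out / "misclassification_matrix.csv")
    artifact("vip_frequency", out / "vip_frequency.csv")

    if cfg.n_permutations > 0:
        perm = _stage("permutation")(permutation_test)(
            Xf,
            y,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            outer=min(cfg.outer, len(y)),
            inner=cfg.inner,
            max_A=cfg.max_A,
        )
        report["stages"].append("permutation")
        report["permutation"] = {
            "observed_accuracy_pct": perm.observed_metric,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
        }
        pd.DataFrame({"null_accuracy_pct": perm.null_metrics}).to_csv(
            out / "permutation_null.csv", index=False
        )
        artifact("permutation_null", out / "permutation_null.csv")

    # 7. VIP -> pathway over-representation ----------------------------------
    selected = vip_table.index[vip_table["vip_frequency"] >= cfg.vip_frequency_cutoff]
    hmdb = []
    if "hmdb_id" in avg.feature_meta.columns:
        hmdb = [
            h
            for h in avg.feature_meta.loc[
                avg.feature_meta.index.intersection(selected), "hmdb_id"
            ].tolist()
            if isinstance(h, str) and h
        ]
    report["n_vip_selected_features"] = int(len(selected))
    report["n_vip_selected_hmdb"] = len(hmdb)
    library = _load_library(cfg)
    mapped = [h for h in hmdb if h in library.universe]
    if mapped:
        ora = _stage("enrich")(enrich)(mapped, library, alpha=cfg.alpha)
        frame = results_frame(ora)
        frame.to_csv(out / "ora_results.csv", index=False)
        artifact("ora_results", out / "ora_results.csv")
        report["stages"].append("enrich")
        report["ora"] = frame[["pathway_id", "name", "k", "K", "p_value", "significant"]].to_dict(
            orient="records"
        )
    else:
        report["ora"] = []
        log.info("no VIP-selected features map to the pathway universe; ORA skipped")

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    artifact("report", out / "report.json")
    return report


def _subset(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    return FeatureTable._unchecked(
        table.intensities.loc[mask], table.sample_meta.loc[mask], table.feature_meta
    )
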