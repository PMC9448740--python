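"""End-to-end orchestration: (simulate | ingest) → preprocess → GBR-NMF →
per-task sparse LDA → validation → report.

The factorization is computed once per run and its score table is shared by
every classification task (the point of the design: one spectral acquisition
predicts several clinical factors).  One global seed expands into per-stage
seeds by hashing the stage name, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .clinical import ClinicalTable, derive_labels
from .containers import BasisLibrary, SpectrumSet
from .errors import ParameterError
from .hca import bin_scores, cluster, mean_scores_by_biopsy
from .nmf import fit_gbr_nmf, score_table
from .preprocess import PreprocessConfig, preprocess_pipeline
from .sparse_lda import fit_sparse_lda, predict, project
from .synthetic import CohortDesign, make_basis_library, simulate_cohort
from .validation import SplitPlan, confusion, make_split, overall_accuracy

TASKS = ("gleason", "capra", "ki67", "psa_median")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    design: CohortDesign | None = None
    spectra_path: str | None = None
    basis_path: str | None = None
    clinical_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tasks: tuple[str, ...] = ("gleason", "capra", "ki67")
    nmf_iters: int = 500
    nmf_tol: float = 1e-8
    lda_k: int = 8
    lda_ridge: float = 1e-4
    test_fraction: float = 0.25
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_design = self.design is not None
        has_paths = self.spectra_path is not None
        if has_design == has_paths:
            raise ParameterError(
                "exactly one of a simulation design or input paths must be given"
            )
        if not self.tasks:
            raise ParameterError("at least one task is required")
        bad = [t for t in self.tasks if t not in TASKS]
        if bad:
            raise ParameterError(f"unknown tasks {bad}; choose from {TASKS}")


@dataclass
class TaskResult:
    task: str
    classes: list[str]
    selected: list[str]
    confusion: pd.DataFrame
    accuracy_pct: float
    accuracy_pct_rounded: int
    ld_coordinates: pd.DataFrame


@dataclass
class RunReport:
    tasks: dict[str, TaskResult]
    preprocess_report: object
    nmf_objective: list[float]
    hca_newick: str | None
    hca_bins: pd.DataFrame | None
    provenance: dict


def _load_inputs(config: RunConfig):
    if config.design is not None:
        from .synthetic import default_axis

        lib = make_basis_library(
            axis=default_axis(config.design.axis_step),
            seed=stage_seed(config.seed, "library"),
        )
        spectra, _truth, clin = simulate_cohort(config.design, lib)
        return spectra, lib, clin
    spectra = rio.read_spectrum_set(config.spectra_path)
    lib = rio.read_basis_library(config.basis_path, target_axis=spectra.axis)
    clin = rio.read_clinical_table(config.clinical_path)
    return spectra, lib, clin


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and (optionally) write a plain-text report."""
    spectra, lib, clin = _load_inputs(config)
    clin.check_covers(spectra.meta["biopsy_id"])

    processed, prep_report = preprocess_pipeline(spectra, config.preprocess)
    model = fit_gbr_nmf(
        processed,
        lib,
        n_iter=config.nmf_iters,
        tol=config.nmf_tol,
        seed=stage_seed(config.seed, "nmf"),
    )
    scores = score_table(model, processed.meta)
    labels_by_biopsy = derive_labels(clin)

    results: dict[str, TaskResult] = {}
    hca_newick = None
    hca_bins = None
    for task in config.tasks:
        y = np.array(
            [labels_by_biopsy[b][task] for b in processed.meta["biopsy_id"]]
        )
        keep = y != "NA"
        task_scores = scores.loc[keep].reset_index(drop=True)
        y = y[keep]
        plan = SplitPlan(
            kind="random_75_25",
            seed=stage_seed(config.seed, f"split:{task}"),
            test_fraction=config.test_fraction,
        )
        train, test = make_split(task_scores, plan)
        lda = fit_sparse_lda(
            task_scores.iloc[train],
            y[train],
            k=config.lda_k,
            ridge=config.lda_ridge,
            seed=stage_seed(config.seed, f"lda:{task}"),
        )
        pred = predict(lda, task_scores.iloc[test])
        cm = confusion(y[test], pred, lda.classes)
        acc, acc_round = overall_accuracy(cm)
        ld = project(lda, task_scores)
        ld_frame = pd.DataFrame(
            ld, columns=[f"LD{i + 1}" for i in range(ld.shape[1])]
        )
        ld_frame.insert(0, "biopsy_id", task_scores["biopsy_id"].to_numpy())
        ld_frame.insert(1, "label", y)
        results[task] = TaskResult(
            task=task,
            classes=lda.classes,
            selected=lda.selected,
            confusion=cm.to_frame(),
            accuracy_pct=acc,
            accuracy_pct_rounded=acc_round,
            ld_coordinates=ld_frame,
        )
        if task == "ki67":
            means = mean_scores_by_biopsy(task_scores, lda.selected)
            hca_newick = cluster(means).to_newick()
            hca_bins = bin_scores(means)

    provenance = {
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ["library", "nmf"]
            + [f"split:{t}" for t in config.tasks]
            + [f"lda:{t}" for t in config.tasks]
        },
        "tasks": list(config.tasks),
        "nmf_iters": config.nmf_iters,
        "lda_k": config.lda_k,
    }
    report = RunReport(
        tasks=results,
        preprocess_report=prep_report,
        nmf_objective=model.objective_trace,
        hca_newick=hca_newick,
        hca_bins=hca_bins,
        provenance=provenance,
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> Path:
    """Write the report as diff-able TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for task, res in report.tasks.items():
        res.confusion.to_csv(out / f"{task}_confusion.tsv", sep="\t")
        res.ld_coordinates.to_csv(out / f"{task}_ld.tsv", sep="\t", index=False)
        (out / f"{task}_summary.json").write_text(
            json.dumps(
                {
                    "classes": res.classes,
                    "selected": res.selected,
                    "accuracy_pct": res.accuracy_pct,
                    "accuracy_pct_rounded": res.accuracy_pct_rounded,
                },
                indent=2,
            )
        )
    if report.hca_newick is not None:
        (out / "hca_dendrogram.nwk").write_text(report.hca_newick + "\n")
    if report.hca_bins is not None:
        report.hca_bins.to_csv(out / "hca_bins.tsv", sep="\t")
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2))
    report.preprocess_report.to_frame().to_csv(
        out / "per_biopsy_counts.tsv", sep="\t", index=False
    )
    return out
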