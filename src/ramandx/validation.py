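"""Train/test machinery and accuracy reporting.

Two validation schemes are provided: a spectrum-level random 75/25 split
(train and test may contain spectra from the same biopsy) repeated with
different seeds, and leave-one-biopsy-out evaluation in which every spectrum
of one biopsy forms the test set.  Results are reported as confusion matrices
(rows = observed, columns = predicted), overall percent accuracy, per-biopsy
percent accuracy and threshold counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows observed classes, columns predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class SplitPlan:
    """Specification of a validation split."""

    kind: str = "random_75_25"       # or "leave_one_biopsy_out"
    seed: int = 0
    test_fraction: float = 0.25
    held_out_biopsy: str | None = None


def make_split(meta: pd.DataFrame, plan: SplitPlan) -> tuple[np.ndarray, np.ndarray]:
    """Return disjoint (train_indices, test_indices) covering all spectra."""
    n = len(meta)
    if plan.kind == "random_75_25":
        rng = np.random.default_rng(plan.seed)
        perm = rng.permutation(n)
        n_test = int(np.floor(plan.test_fraction * n))
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        return train, test
    if plan.kind == "leave_one_biopsy_out":
        if plan.held_out_biopsy is None:
            raise ValidationError("leave_one_biopsy_out requires held_out_biopsy")
        mask = (meta["biopsy_id"] == plan.held_out_biopsy).to_numpy()
        if not mask.any():
            raise ValidationError(
                f"biopsy {plan.held_out_biopsy!r} not present in the metadata"
            )
        idx = np.arange(n)
        return idx[~mask], idx[mask]
    raise ValidationError(f"unknown split kind {plan.kind!r}")


def confusion(observed, predicted, classes: list[str]) -> ConfusionMatrix:
    observed = np.asarray(observed).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if observed.size != predicted.size:
        raise ValidationError("observed and predicted lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for o, p in zip(observed, predicted):
        if o not in index or p not in index:
            bad = o if o not in index else p
            raise ValidationError(f"label {bad!r} outside classes {classes}")
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(list(classes), counts)


def overall_accuracy(cm: ConfusionMatrix) -> tuple[float, int]:
    """Percent accuracy: (unrounded, nearest-integer) trace/total × 100."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    pct = 100.0 * np.trace(cm.counts) / cm.total
    return float(pct), int(round(pct))


def repeat_random_eval(
    pipeline,
    meta: pd.DataFrame,
    labels,
    repeats: int = 3,
    seeds: list[int] | None = None,
    test_fraction: float = 0.25,
) -> dict:
    """Repeat split→fit→predict; report per-repeat accuracy, mean and SD.

    ``pipeline(train_idx, test_idx)`` must return (observed, predicted) label
    arrays for the test indices.
    """
    if repeats < 2:
        raise ValidationError("repeats must be >= 2")
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValidationError("need one seed per repeat")
    labels = np.asarray(labels).astype(str)
    classes = sorted(set(labels))
    accs = []
    for seed in seeds:
        plan = SplitPlan(kind="random_75_25", seed=seed, test_fraction=test_fraction)
        train, test = make_split(meta, plan)
        obs, pred = pipeline(train, test)
        cm = confusion(obs, pred, classes)
        accs.append(overall_accuracy(cm)[0])
    accs = np.asarray(accs)
    return {
        "accuracies": accs.tolist(),
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)),
        "seeds": list(seeds),
    }


def per_biopsy_accuracy(pipeline, meta: pd.DataFrame, labels) -> pd.DataFrame:
    """Leave-one-biopsy-out accuracy table (biopsy_id, pct_correct, n).

    For each biopsy the pipeline is retrained with that biopsy excluded and
    its spectra scored; accuracy is the percentage assigned the biopsy's true
    group.
    """
    labels = np.asarray(labels).astype(str)
    biopsies = list(pd.unique(meta["biopsy_id"]))
    if len(biopsies) < 2:
        raise ValidationError("leave-one-biopsy-out needs at least 2 biopsies")
    rows = []
    for b in biopsies:
        plan = SplitPlan(kind="leave_one_biopsy_out", held_out_biopsy=b)
        train, test = make_split(meta, plan)
        obs, pred = pipeline(train, test)
        obs = np.asarray(obs).astype(str)
        pred = np.asarray(pred).astype(str)
        acc = 100.0 * float(np.mean(obs == pred))
        rows.append({"biopsy_id": b, "pct_correct": acc, "n_spectra": len(test)})
    return pd.DataFrame(rows)


def threshold_count(accuracies, threshold_pct: float) -> int:
    """Count biopsies whose accuracy meets or exceeds the threshold (closed)."""
    accs = np.asarray(list(accuracies), dtype=float)
    return int(np.sum(accs >= threshold_pct))
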