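"""Model/Results front end over the cross-validated experiment.

``MCScreeningModel`` is constructed from a cohort (or a cohort spec)
plus the experimental choices — preprocessing arm, architecture,
number of folds, training options.  ``fit()`` runs the full
preprocess → train → score loop and returns ``MCScreeningResults``
holding the per-fold AUC estimates, their spread, threshold metrics
and the fold-averaged ROC, with a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from dbtmc.data import AugmentSpec
from dbtmc.preprocess import PreprocessSpec
from dbtmc.simulate import CaseRecord, CohortSpec, generate_cohort
from dbtmc.train_eval import (
    ExperimentResult,
    TrainSpec,
    average_roc,
    compare_auc_ttest,
    density_stratified_eval,
    run_experiment,
)


class MCScreeningModel:
    """Whole-slice MC-presence classifier, fitted by k-fold CV.

    Parameters
    ----------
    cases:
        The cohort (list of :class:`~dbtmc.simulate.CaseRecord`).
    arm:
        Preprocessing arm specification; ``arm.target_size`` is also the
        network input size.
    architecture:
        ``cnn_a`` (default) or one of the references
        (``alexnet``/``googlenet``/``resnet18``/``squeezenet``).
    """

    def __init__(
        self,
        cases: list[CaseRecord],
        arm: PreprocessSpec | None = None,
        architecture: str = "cnn_a",
        k: int = 3,
        train_spec: TrainSpec | None = None,
        augment_spec: AugmentSpec | None = AugmentSpec(),
    ):
        self.cases = cases
        self.arm = arm or PreprocessSpec()
        self.architecture = architecture
        self.k = k
        self.train_spec = train_spec or TrainSpec()
        self.augment_spec = augment_spec

    @classmethod
    def from_cohort_spec(cls, cohort_spec: CohortSpec, **kwargs) -> "MCScreeningModel":
        """Generate the synthetic cohort described by ``cohort_spec``."""
        return cls(generate_cohort(cohort_spec), **kwargs)

    def fit(
        self, seed: int = 0, label_permutation_seed: int | None = None,
        keep_models: bool = False,
    ) -> "MCScreeningResults":
        result = run_experiment(
            self.cases,
            self.arm,
            self.architecture,
            self.k,
            self.train_spec,
            self.augment_spec,
            seed=seed,
            label_permutation_seed=label_permutation_seed,
            keep_models=keep_models,
        )
        return MCScreeningResults(self, result)


class MCScreeningResults:
    """Fitted-experiment results: per-fold AUCs and diagnostics."""

    def __init__(self, model: MCScreeningModel, experiment: ExperimentResult):
        self.model = model
        self.experiment = experiment

    @property
    def aucs(self) -> np.ndarray:
        """Per-fold test AUC estimates."""
        return self.experiment.aucs

    @property
    def auc_mean(self) -> float:
        return self.experiment.auc_mean

    @property
    def auc_sd(self) -> float:
        """Sample SD of the fold AUCs."""
        return self.experiment.auc_sd

    def mean_roc(self, n_grid: int = 101):
        """Vertically averaged ROC over folds (FPR grid, mean TPR)."""
        return self.experiment.mean_roc(n_grid)

    def compare(self, other: "MCScreeningResults") -> float:
        """Two-tailed p-value of the fold-AUC difference vs. another fit."""
        return compare_auc_ttest(self.aucs, other.aucs)

    def density_stratified(self) -> dict[str, float | None]:
        """Pooled per-density test AUC over all folds (None if undefined)."""
        scores, labels, densities = [], [], []
        for f in self.experiment.folds:
            scores.append(f.result.scores)
            labels.append(f.result.labels)
            densities.append(f.test_table.density.to_numpy())
        per = density_stratified_eval(
            np.concatenate(scores), np.concatenate(labels), np.concatenate(densities)
        )
        return {k: (v.auc if v is not None else None) for k, v in per.items()}

    def summary(self) -> str:
        e = self.experiment
        lines = [
            "MC screening classification results",
            "=" * 51,
            f"architecture: {e.architecture:<12s} preprocessing arm: {e.arm}",
            f"folds (patient-level, stratified): {e.k}",
            "-" * 51,
        ]
        for f in e.folds:
            r = f.result
            lines.append(
                f"fold {f.fold}:  AUC {100 * r.auc:6.2f}%   "
                f"sens {r.sensitivity:.3f}  spec {r.specificity:.3f}  acc {r.accuracy:.3f}"
            )
        lines += [
            "-" * 51,
            f"AUC (mean ± sample SD over folds): {e.summary_cell()} %",
            "=" * 51,
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None, label: str | None = None):
        """Plot the fold-averaged ROC curve (matplotlib Axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        grid, tpr = self.mean_roc()
        e = self.experiment
        ax.plot(grid, tpr, label=label or f"{e.architecture} / {e.arm} "
                f"(AUC {100 * e.auc_mean:.2f}%)")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax
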