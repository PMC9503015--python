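"""Training protocol and the evaluation stack.

Training follows the study protocol: stochastic gradient descent with
momentum 0.9 minimizing cross-entropy with an L2 penalty, mini-batches
of 32, per-epoch reshuffling, and left-right-flip / ±20° rotation
augmentation on the training side only.  Full-scale defaults are
lr 1e-3 over at most 200 epochs; the desk preset shrinks the epoch
budget (and raises the learning rate accordingly) for CPU-scale runs.

Evaluation: per-slice positive-class probabilities, ROC/AUC (trapezoid
over the ROC, equal to pairwise concordance with ties counted half),
threshold metrics, vertical ROC averaging across folds, a two-sample
t-test on per-fold AUCs, and density-stratified testing of one trained
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from dbtmc import models, nn
from dbtmc.data import AugmentSpec, assign_folds, augment, build_slice_table
from dbtmc.preprocess import PreprocessSpec, apply_preprocessing, resize_to, suppress_background
from dbtmc.simulate import DENSITY_NAMES, PRESENT, CaseRecord


@dataclass(frozen=True)
class TrainSpec:
    """Optimization options (full-scale defaults)."""

    optimizer: str = "sgdm"
    momentum: float = 0.9
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    l2_weight: float = 5e-3
    loss: str = "cross_entropy"
    seed: int = 0

    @classmethod
    def desk(cls, max_epochs: int = 10, learning_rate: float = 2e-3,
             batch_size: int = 16, seed: int = 0):
        """CPU desk-scale preset: small epoch budget, lr and batch scaled
        so SGDM still takes enough steps on a ~60-case cohort."""
        return cls(max_epochs=max_epochs, learning_rate=learning_rate,
                   batch_size=batch_size, seed=seed)


def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    """Stack unit-float slices into a zero-centered float32 NCHW batch.

    Mimics the storage chain: 8-bit quantization, then per-image
    zero-centering at model-input time.
    """
    out = np.empty((len(images), 1, *images[0].shape), dtype=np.float32)
    for i, im in enumerate(images):
        q = np.round(np.clip(im, 0, 1) * 255) / 255.0
        out[i, 0] = q - q.mean()
    return out


def train_classifier(
    model: nn.Module,
    images: list[np.ndarray],
    labels: np.ndarray,
    spec: TrainSpec,
    augment_spec: AugmentSpec | None = None,
) -> tuple[nn.Module, list[float]]:
    """Train in place; returns the model and the per-epoch loss history.

    Deterministic given ``spec.seed``: the same seed drives epoch
    shuffles and augmentation draws.  Raises on a single-class set.
    """
    labels = np.asarray(labels, dtype=int)
    if len(images) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("training needs a nonempty set with both classes present")
    rng = np.random.default_rng(spec.seed)
    opt = nn.SGD(
        model.parameters(),
        lr=spec.learning_rate,
        momentum=spec.momentum,
        weight_decay=spec.l2_weight,
    )
    model.set_training(True)
    history: list[float] = []
    n = len(images)
    for _ in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            batch_imgs = []
            for i in idx:
                im = images[i]
                if augment_spec is not None:
                    im = augment(im, augment_spec, int(rng.integers(2**31 - 1)))
                batch_imgs.append(im)
            x = nn.Tensor(_as_batch(batch_imgs))
            logits = model(x)
            loss = nn.cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    model.set_training(False)
    return model, history


def predict_scores(
    model: nn.Module, images: list[np.ndarray], batch_size: int = 32
) -> np.ndarray:
    """Positive-class probabilities, deterministic (evaluation mode)."""
    model.set_training(False)
    scores = []
    for start in range(0, len(images), batch_size):
        x = nn.Tensor(_as_batch(images[start : start + batch_size]))
        scores.append(nn.softmax_probs(model(x).data)[:, 1])
    return np.concatenate(scores)


# ---------------------------------------------------------------------------
# metrics

def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """All ROC points from (0,0) to (1,1), FPR nondecreasing."""
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr


def auc(scores, labels) -> float:
    """Area under the ROC curve (positive class = presentMCs).

    Trapezoidal area, which equals the probability that a random
    positive outscores a random negative with ties counted half.
    Undefined (raises) when a class is absent.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def metrics_at_threshold(scores, labels, threshold: float = 0.5):
    """(sensitivity, specificity, accuracy) at a score threshold.

    A slice is called positive when its score is >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels)
    return sens, spec, acc


@dataclass
class EvalResult:
    """Per-slice scores with ROC, AUC and threshold metrics."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float = 0.5


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalResult:
    fpr, tpr = roc_points(scores, labels)
    sens, spec, acc = metrics_at_threshold(scores, labels, threshold)
    return EvalResult(
        np.asarray(scores, dtype=float), np.asarray(labels, dtype=int),
        fpr, tpr, auc(scores, labels), sens, spec, acc, threshold,
    )


def average_roc(
    curves: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical averaging: TPR interpolated on a common FPR grid."""
    if not curves:
        raise ValueError("need at least one ROC curve")
    grid = np.linspace(0.0, 1.0, n_grid)
    mean_tpr = np.mean([np.interp(grid, fpr, tpr) for fpr, tpr in curves], axis=0)
    return grid, mean_tpr


def compare_auc_ttest(auc_a, auc_b) -> float:
    """Two-tailed two-sample t-test p-value on per-fold AUCs.

    Pooled-variance (equal-variance) t with n_a + n_b - 2 degrees of
    freedom; symmetric in its arguments.  Two zero-variance groups give
    p = 1 when their means agree, p = 0 otherwise.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two AUC values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def density_stratified_eval(
    scores, labels, densities, threshold: float = 0.5
) -> dict[str, EvalResult | None]:
    """Per-density evaluation of one model's test scores.

    The model is trained on all densities mixed; here its test scores
    are split by density class.  A density subset with one class has an
    undefined AUC and is reported as None.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    densities = np.asarray(densities)
    out: dict[str, EvalResult | None] = {}
    for name in DENSITY_NAMES:
        sel = densities == name
        if sel.any() and len(np.unique(labels[sel])) == 2:
            out[name] = evaluate_scores(scores[sel], labels[sel], threshold)
        else:
            out[name] = None
    return out


# ---------------------------------------------------------------------------
# the cross-validated experiment

@dataclass
class FoldResult:
    fold: int
    result: EvalResult
    loss_history: list[float]
    test_table: pd.DataFrame
    model: nn.Module | None = None


@dataclass
class ExperimentResult:
    """Per-fold evaluations plus the mean ± SD AUC summary cell."""

    arm: str
    architecture: str
    k: int
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def aucs(self) -> np.ndarray:
        return np.array([f.result.auc for f in self.folds])

    @property
    def auc_mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.folds) > 1 else 0.0

    def summary_cell(self) -> str:
        """AUC as 'mean ± SD' in percent, one row cell of the results table."""
        return f"{100 * self.auc_mean:.2f} ± {100 * self.auc_sd:.2f}"

    def mean_roc(self, n_grid: int = 101) -> tuple[np.ndarray, np.ndarray]:
        return average_roc([(f.result.fpr, f.result.tpr) for f in self.folds], n_grid)


def preprocess_cases(
    cases: list[CaseRecord],
    arm: PreprocessSpec,
    table: pd.DataFrame | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Arm output, resized to the network input, for every selected slice.

    Each slice's breast mask is computed from its own original image and
    reused for the arm's output (mask provenance: the original image,
    never an intensity-transformed one).
    """
    if table is None:
        table = build_slice_table(cases)
    by_id = {c.patient_id: c for c in cases}
    processed: dict[tuple[str, int], np.ndarray] = {}
    for row in table.itertuples():
        case = by_id[row.patient_id]
        img = case.slices[row.slice_index - 1]
        _, mask, _ = suppress_background(img)
        out = apply_preprocessing(img, arm, mask=mask)
        processed[(row.patient_id, row.slice_index)] = resize_to(out, arm.target_size)
    return processed


def run_experiment(
    cases: list[CaseRecord],
    arm: PreprocessSpec,
    architecture: str = "cnn_a",
    k: int = 3,
    train_spec: TrainSpec | None = None,
    augment_spec: AugmentSpec | None = AugmentSpec(),
    seed: int = 0,
    label_permutation_seed: int | None = None,
    keep_models: bool = False,
) -> ExperimentResult:
    """Preprocess, k-fold train and evaluate one (arm, architecture) cell.

    Folds are patient-level and stratified by (density, label).  With
    ``label_permutation_seed`` the per-patient labels are randomly
    permuted before training and scoring — a chance-level control.
    """
    train_spec = train_spec or TrainSpec()
    table = build_slice_table(cases)
    processed = preprocess_cases(cases, arm, table)

    label_by_patient = {c.patient_id: int(c.label == PRESENT) for c in cases}
    if label_permutation_seed is not None:
        pids = sorted(label_by_patient)
        values = np.array([label_by_patient[p] for p in pids])
        perm = np.random.default_rng(label_permutation_seed).permutation(len(values))
        label_by_patient = {p: int(values[j]) for p, j in zip(pids, perm)}
        table = table.assign(y=[label_by_patient[p] for p in table.patient_id])

    ss = np.random.SeedSequence(seed).spawn(2 * k + 1)
    strata = {c.patient_id: (c.density.name, c.label) for c in cases}
    folds = assign_folds(
        [c.patient_id for c in cases], k, int(ss[0].generate_state(1)[0]), strata
    )

    result = ExperimentResult(arm.method, architecture, k)
    for fold in range(k):
        train_pids = set(folds.train_patients(fold))
        train_tab = table[table.patient_id.isin(train_pids)]
        test_tab = table[~table.patient_id.isin(train_pids)]
        train_imgs = [processed[(r.patient_id, r.slice_index)] for r in train_tab.itertuples()]
        test_imgs = [processed[(r.patient_id, r.slice_index)] for r in test_tab.itertuples()]

        model_seed = int(ss[2 * fold + 1].generate_state(1)[0])
        train_seed = int(ss[2 * fold + 2].generate_state(1)[0])
        model = models.build(architecture, arm.target_size, 2, seed=model_seed)
        fold_spec = replace(train_spec, seed=train_seed)
        model, history = train_classifier(
            model, train_imgs, train_tab.y.to_numpy(), fold_spec, augment_spec
        )
        scores = predict_scores(model, test_imgs, train_spec.batch_size)
        fold_eval = evaluate_scores(scores, test_tab.y.to_numpy())
        result.folds.append(
            FoldResult(fold, fold_eval, history, test_tab.reset_index(drop=True),
                       model if keep_models else None)
        )
    return result
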