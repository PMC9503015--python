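"""Slice selection, patient-level cross-validation and augmentation.

Absent (negative) cases contribute five slices proportionally spaced
between the first and last slice of the volume; positive cases
contribute the slices holding cluster centers (deduplicated, since two
clusters can share a slice).  Cross-validation splits are made at the
patient level — no patient ever contributes slices to both the train
and the test side of a fold — and are stratified by (density, label)
so small cohorts keep both classes in every fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from dbtmc.exceptions import SelectionError
from dbtmc.simulate import ABSENT, PRESENT, CaseRecord


def select_absent_slices(n_slices: int, n_select: int = 5) -> list[int]:
    """Proportionally spaced 1-based slice indices for an absent case.

    The spacing is ``s = ceil((n_slices - 1) / (n_select - 1))`` starting
    from slice 1, with the final index clamped to the last slice; e.g.
    62 slices -> [1, 17, 33, 49, 62] and 38 slices -> [1, 11, 21, 31, 38].
    """
    if n_slices < n_select:
        raise SelectionError(f"cannot select {n_select} slices from {n_slices}")
    step = math.ceil((n_slices - 1) / (n_select - 1))
    idx = [min(1 + i * step, n_slices) for i in range(n_select - 1)]
    return idx + [n_slices]


def select_present_slices(case: CaseRecord) -> list[int]:
    """Deduplicated 1-based indices of slices holding cluster centers."""
    if case.label != PRESENT:
        raise SelectionError("slice selection by cluster center needs a presentMCs case")
    return sorted({z for z, _, _ in case.clusters})


def selected_slices(case: CaseRecord) -> list[int]:
    """The slice indices this case contributes to training/testing."""
    if case.label == ABSENT:
        return select_absent_slices(len(case.slices))
    return select_present_slices(case)


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold map for k-fold cross-validation."""

    k: int
    mapping: dict[str, int]

    def test_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.mapping.items() if f == fold]

    def train_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.mapping.items() if f != fold]


def assign_folds(
    patient_ids: list[str],
    k: int = 3,
    seed: int = 0,
    strata: dict[str, object] | None = None,
) -> FoldAssignment:
    """Random patient-level partition into k folds.

    With ``strata`` (e.g. patient -> (density, label)) the shuffle and
    round-robin assignment run within each stratum, so per-stratum fold
    sizes differ by at most one.  Deterministic per seed.
    """
    if len(patient_ids) < k:
        raise SelectionError(f"need at least k={k} patients, got {len(patient_ids)}")
    if len(set(patient_ids)) != len(patient_ids):
        raise SelectionError("patient ids must be unique")
    rng = np.random.default_rng(seed)
    groups: dict[object, list[str]] = {}
    for pid in patient_ids:
        groups.setdefault(strata[pid] if strata else None, []).append(pid)

    mapping: dict[str, int] = {}
    load = np.zeros(k, dtype=int)
    for key in sorted(groups, key=repr):
        members = list(groups[key])
        rng.shuffle(members)
        order = np.argsort(load, kind="stable")  # fill lightest folds first
        for i, pid in enumerate(members):
            fold = int(order[i % k])
            mapping[pid] = fold
            load[fold] += 1
    return FoldAssignment(k, mapping)


@dataclass(frozen=True)
class AugmentSpec:
    """Training-time augmentation: LR reflection and small rotations."""

    reflect_lr: bool = True
    rotation_range_deg: float = 20.0
    seed: int = 0


def augment(image: np.ndarray, spec: AugmentSpec, draw_seed: int) -> np.ndarray:
    """One random draw: optional left-right flip (p=0.5), then rotation
    uniform in +-rotation_range_deg (bilinear, background fill 0).

    With reflection off and zero rotation range this is the identity.
    """
    rng = np.random.default_rng(draw_seed)
    out = np.asarray(image, dtype=float)
    if spec.reflect_lr and rng.random() < 0.5:
        out = out[:, ::-1]
    if spec.rotation_range_deg > 0:
        angle = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    return np.ascontiguousarray(out)


def build_slice_table(cases: list[CaseRecord]) -> pd.DataFrame:
    """Selected-slice manifest: one row per training/testing slice.

    Columns: patient_id, density, label, slice_index (1-based), y
    (1 for presentMCs).
    """
    rows = []
    for case in cases:
        for z in selected_slices(case):
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "density": case.density.name,
                    "label": case.label,
                    "slice_index": z,
                    "y": int(case.label == PRESENT),
                }
            )
    return pd.DataFrame(rows)


def slice_arrays(
    cases: list[CaseRecord], table: pd.DataFrame
) -> list[np.ndarray]:
    """Materialize the images behind the rows of a slice table."""
    by_id = {c.patient_id: c for c in cases}
    return [
        by_id[row.patient_id].slices[row.slice_index - 1]
        for row in table.itertuples()
    ]
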