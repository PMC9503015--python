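"""Synthetic VICTRE-like DBT cohorts with known ground truth.

Real reconstructed tomosynthesis volumes are approximated by independent
2-D slices: a compressed-breast outline touching the chest wall, filled
with density-dependent power-law anatomical texture, plus low-amplitude
signal contamination outside the breast (as seen in reconstructed data
before background suppression).  Positive cases carry four
microcalcification clusters of five small bright calcifications each,
with every cluster center recorded as ground truth.

Four breast-density classes are modelled (fatty, scattered,
heterogeneous, dense), with full-scale per-volume slice counts
62/57/47/38 and population prevalence 10/40/40/10 percent.  All
randomness in a cohort flows from the single seed of its
:class:`CohortSpec`, so regeneration is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from dbtmc.exceptions import PlacementError, SizeError

ABSENT = "absent"
PRESENT = "presentMCs"

DENSITY_NAMES = ("fatty", "scattered", "heterogeneous", "dense")

#: population prevalence of the four density classes
DEFAULT_PROPORTIONS = (0.10, 0.40, 0.40, 0.10)

#: full-scale slice counts per reconstructed volume, fatty -> dense
FULL_SCALE_SLICES = {"fatty": 62, "scattered": 57, "heterogeneous": 47, "dense": 38}

# anatomical texture parameters per class: power-spectrum exponent beta
# (|F|^2 ~ f^-beta), mean glandular intensity and texture amplitude all
# increase from fatty to dense breasts.
_TEXTURE = {
    "fatty": {"beta": 2.2, "glandular": 0.30, "amplitude": 0.05},
    "scattered": {"beta": 2.5, "glandular": 0.38, "amplitude": 0.08},
    "heterogeneous": {"beta": 2.8, "glandular": 0.46, "amplitude": 0.11},
    "dense": {"beta": 3.1, "glandular": 0.54, "amplitude": 0.14},
}

# breast outline extent (fraction of grid) shrinks with density, mirroring
# the smaller reconstructed grids of denser breasts.
_OUTLINE = {
    "fatty": (0.95, 0.80),
    "scattered": (0.88, 0.72),
    "heterogeneous": (0.80, 0.64),
    "dense": (0.72, 0.56),
}


@dataclass(frozen=True)
class DensityClass:
    """One breast-density class and its slice/texture parameters."""

    name: str
    n_slices: int
    spectral_exponent: float
    glandular_fraction: float
    texture_amplitude: float

    def __post_init__(self) -> None:
        if self.name not in DENSITY_NAMES:
            raise ValueError(f"unknown density class {self.name!r}")
        if self.n_slices < 5:
            raise ValueError("n_slices must be >= 5 (slice selection needs 5)")

    @classmethod
    def standard(cls, name: str, slice_factor: float = 1.0) -> "DensityClass":
        """The named class at full scale, or with slice counts scaled down.

        ``slice_factor=1`` keeps the full-scale counts 62/57/47/38;
        smaller factors shrink the volume (never below the 5 slices that
        slice selection requires).
        """
        t = _TEXTURE[name]
        n = max(5, round(FULL_SCALE_SLICES[name] * slice_factor))
        return cls(name, n, t["beta"], t["glandular"], t["amplitude"])


@dataclass(frozen=True)
class MCClusterSpec:
    """Geometry and contrast of one microcalcification cluster.

    Five calcified lesions per cluster by default; the three diameters
    cycle over the lesions, standing in for the 195/179/171 um
    calcifications at the current pixel scale.
    """

    n_calcifications: int = 5
    calcification_diameter_px: tuple[int, ...] = (3, 3, 2)
    contrast: float = 0.40
    spread_px: int = 8

    def __post_init__(self) -> None:
        if self.n_calcifications < 1:
            raise ValueError("n_calcifications must be >= 1")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if any(d < 1 for d in self.calcification_diameter_px):
            raise ValueError("calcification diameters must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of a synthetic cohort."""

    n_cases: int
    density_proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    positive_fraction: float = 0.5
    seed: int = 0
    grid_size: int = 128
    slice_factor: float = 1.0
    cluster: MCClusterSpec = field(default_factory=MCClusterSpec)

    def __post_init__(self) -> None:
        if abs(sum(self.density_proportions) - 1.0) > 1e-9:
            raise ValueError("density proportions must sum to 1")
        if self.n_cases < 4:
            raise ValueError("need n_cases >= 4 to honor all four densities")


@dataclass
class CaseRecord:
    """One virtual patient: slices, label and cluster ground truth.

    ``clusters`` holds ``(slice_index, row, col)`` cluster centers with
    1-based slice indices; it is empty iff ``label == "absent"``.
    ``mask`` is the ground-truth breast mask (synthetic data only).
    """

    patient_id: str
    density: DensityClass
    label: str
    slices: list[np.ndarray]
    clusters: list[tuple[int, int, int]]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in (ABSENT, PRESENT):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == ABSENT) != (len(self.clusters) == 0):
            raise ValueError("clusters must be empty iff label is absent")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("all slices of a case must share one grid shape")


def generate_breast_mask(grid_size: int, density: DensityClass, seed: int) -> np.ndarray:
    """Binary CC-view breast outline touching the chest-wall (left) edge.

    The region is a mildly perturbed semi-ellipse, star-shaped about a
    point on the left edge, hence a single connected, hole-free
    component.  Deterministic for a fixed seed.
    """
    if grid_size < 32:
        raise SizeError(f"grid_size {grid_size} too small for a breast outline (need >= 32)")
    rng = np.random.default_rng(seed)
    ax_frac, ay_frac = _OUTLINE[density.name]
    a = grid_size * ax_frac * rng.uniform(0.92, 1.0)
    b = grid_size * 0.5 * ay_frac * rng.uniform(0.92, 1.0)
    cy = grid_size / 2 + rng.uniform(-0.05, 0.05) * grid_size

    rows = np.arange(grid_size)[:, None]
    cols = np.arange(grid_size)[None, :]
    rho = np.sqrt((cols / a) ** 2 + ((rows - cy) / b) ** 2)
    # smooth angular perturbation of the outline radius
    theta = np.arctan2(rows - cy, cols + 1e-9)
    p1, p2, ph1, ph2 = rng.uniform(0, 2 * np.pi, 4)
    wobble = 0.04 * np.sin(2 * theta + ph1) + 0.03 * np.sin(3 * theta + ph2)
    mask = rho <= 1.0 + wobble
    mask[:, 0] |= np.abs(rows[:, 0] - cy) <= b  # guarantee chest-wall contact
    return mask.astype(bool)


def _power_law_noise(shape: tuple[int, int], beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance field with power spectrum ~ f^-beta."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.sqrt(fx**2 + fy**2)
    f[0, 0] = 1.0
    filt = f ** (-beta / 2.0)
    filt[0, 0] = 0.0
    field_ = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    field_ -= field_.mean()
    return field_ / field_.std()


def generate_anatomical_background(
    mask: np.ndarray, density: DensityClass, seed: int
) -> np.ndarray:
    """One slice of anatomical texture plus out-of-breast contamination.

    Inside the mask: glandular mean plus power-law texture, both growing
    with density (so dense slices have larger in-mask variance), with a
    smooth intensity fade over the outer few pixels of the breast — the
    thinning compressed edge.  Outside the mask: strictly positive
    low-amplitude contamination (uniform noise plus a smooth structured
    component), emulating the residual signal of reconstructed data
    before background suppression.
    """
    rng = np.random.default_rng(seed)
    shape = mask.shape
    texture = _power_law_noise(shape, density.spectral_exponent, rng)
    inside = density.glandular_fraction + density.texture_amplitude * texture
    # compressed-breast edge: intensity fades toward the skin line
    depth = ndimage.distance_transform_edt(mask)
    fade = np.clip(0.30 + 0.70 * depth / 6.0, 0.0, 1.0)
    inside = inside * fade

    contamination = rng.uniform(0.002, 0.015, shape)
    structured = _power_law_noise(shape, 2.0, rng)
    contamination += 0.005 * np.abs(structured)

    img = np.where(mask, inside, contamination)
    return np.clip(img, 0.0, 1.0)


def insert_mc_cluster(
    image: np.ndarray,
    mask: np.ndarray,
    spec: MCClusterSpec,
    center: tuple[int, int],
    seed: int,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Add one cluster of bright calcification disks around ``center``.

    Every lesion center lies within ``spec.spread_px`` of the cluster
    center and inside the breast mask; disks are additive with a soft
    (antialiased) edge and the result is clipped to [0, 1].  Returns the
    modified image and the lesion centers.
    """
    r0, c0 = int(center[0]), int(center[1])
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]) or not mask[r0, c0]:
        raise PlacementError(f"cluster center {center} outside the breast mask")
    rng = np.random.default_rng(seed)
    rows = np.arange(image.shape[0])[:, None]
    cols = np.arange(image.shape[1])[None, :]

    centers: list[tuple[int, int]] = []
    dots = np.zeros_like(image, dtype=float)
    diams = spec.calcification_diameter_px
    for i in range(spec.n_calcifications):
        for _ in range(64):
            ang = rng.uniform(0, 2 * np.pi)
            rad = spec.spread_px * math.sqrt(rng.uniform())
            rr = int(round(r0 + rad * math.sin(ang)))
            cc = int(round(c0 + rad * math.cos(ang)))
            if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
                break
        else:  # fall back to the cluster center, always valid
            rr, cc = r0, c0
        centers.append((rr, cc))
        radius = diams[i % len(diams)] / 2.0
        dist = np.sqrt((rows - rr) ** 2 + (cols - cc) ** 2)
        dots += spec.contrast * np.clip(radius + 0.5 - dist, 0.0, 1.0)

    out = np.clip(image + np.minimum(dots, spec.contrast), 0.0, 1.0)
    return out, centers


def generate_case(
    patient_id: str,
    density: DensityClass,
    label: str,
    cluster_spec: MCClusterSpec,
    grid_size: int,
    seed: int,
) -> CaseRecord:
    """One virtual patient: ``density.n_slices`` independent slices.

    Positive cases receive exactly four clusters; their (1-based) slice
    indices are drawn with replacement, so two clusters may share a
    slice, as happens in the reference data.
    """
    ss = np.random.SeedSequence(seed)
    mask_seed, slice_seed, place_seed = (int(s.generate_state(1)[0]) for s in ss.spawn(3))
    mask = generate_breast_mask(grid_size, density, mask_seed)

    slice_ss = np.random.SeedSequence(slice_seed).spawn(density.n_slices)
    slices = [
        generate_anatomical_background(mask, density, int(s.generate_state(1)[0]))
        for s in slice_ss
    ]

    clusters: list[tuple[int, int, int]] = []
    if label == PRESENT:
        rng = np.random.default_rng(place_seed)
        # keep cluster centers a margin inside the breast
        margin = cluster_spec.spread_px + 2
        fg = np.argwhere(mask)
        interior = fg[
            (fg[:, 0] >= margin)
            & (fg[:, 0] < grid_size - margin)
            & (fg[:, 1] < grid_size - margin)
        ]
        candidates = interior if len(interior) else fg
        place_ss = np.random.SeedSequence(place_seed).spawn(4)
        for i in range(4):
            z = int(rng.integers(1, density.n_slices + 1))
            r, c = candidates[rng.integers(len(candidates))]
            new_img, _ = insert_mc_cluster(
                slices[z - 1],
                mask,
                cluster_spec,
                (int(r), int(c)),
                int(place_ss[i].generate_state(1)[0]),
            )
            slices[z - 1] = new_img
            clusters.append((z, int(r), int(c)))

    return CaseRecord(patient_id, density, label, slices, clusters, mask=mask)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total``, proportional to ``fractions``."""
    quotas = np.asarray(fractions, dtype=float) * total
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts


def generate_cohort(spec: CohortSpec) -> list[CaseRecord]:
    """Generate the full cohort described by ``spec``.

    Density counts follow largest-remainder rounding of the proportions;
    positives are spread over densities the same way, so the label
    balance stays within one case of ``positive_fraction * n_cases``.
    """
    counts = _largest_remainder(np.array(spec.density_proportions), spec.n_cases)
    n_pos_total = int(round(spec.positive_fraction * spec.n_cases))
    pos_counts = _largest_remainder(
        counts / max(counts.sum(), 1), n_pos_total
    )
    pos_counts = np.minimum(pos_counts, counts)

    assignments: list[tuple[DensityClass, str]] = []
    for name, n_d, n_p in zip(DENSITY_NAMES, counts, pos_counts):
        density = DensityClass.standard(name, spec.slice_factor)
        labels = [PRESENT] * int(n_p) + [ABSENT] * int(n_d - n_p)
        assignments.extend((density, lab) for lab in labels)

    case_ss = np.random.SeedSequence(spec.seed).spawn(len(assignments))
    cases = []
    for i, ((density, label), child) in enumerate(zip(assignments, case_ss)):
        cases.append(
            generate_case(
                f"P{i:04d}",
                density,
                label,
                spec.cluster,
                spec.grid_size,
                int(child.generate_state(1)[0]),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# cohort I/O: 8-bit grayscale TIFF slices + a manifest table

def write_cohort(cases: list[CaseRecord], out_dir: str | Path) -> pd.DataFrame:
    """Write per-slice 8-bit TIFFs and the cohort manifest CSV.

    The manifest has one row per slice: patient_id, density, label,
    slice_index (1-based), file, and the ground-truth cluster centers on
    that slice as a JSON list of [row, col] pairs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for z, img in enumerate(case.slices, start=1):
            fname = f"{case.patient_id}_s{z:03d}.tif"
            tifffile.imwrite(
                out_dir / fname, np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
            )
            centers = [[r, c] for (zz, r, c) in case.clusters if zz == z]
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "density": case.density.name,
                    "label": case.label,
                    "slice_index": z,
                    "file": fname,
                    "cluster_centers": json.dumps(centers),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_slice(path: str | Path) -> np.ndarray:
    """Read one 8-bit grayscale TIFF slice into a unit-float image."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale slice, got shape {arr.shape}")
    return arr.astype(float) / 255.0
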