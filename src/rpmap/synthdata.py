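"""Synthetic cohorts with known ground truth, and calibration/power studies.

No public deposit of co-registered glioma mask cohorts exists, so validation
runs on simulated data: each patient receives a spatially coherent tumor blob
(a jittered, rough-surfaced ellipsoid) and a residual mask drawn from a known
per-voxel ground-truth resection-probability field p*(v).  Two residual
models are provided:

``bernoulli``
    each tumor voxel is independently retained as residue with probability
    1 - p*(v); the empirical RPM then converges to p* at the binomial rate.

``coherent``
    a patient-specific smooth uniform field u(v) (Gaussian copula: smoothed
    white noise mapped through the normal CDF) thresholds the same marginal
    rule, residue = tumor & {u < 1 - p*}, producing spatially contiguous
    residues concentrated where p* is low while keeping the per-voxel
    marginal retention probability exactly 1 - p*(v).

The module also hosts the end-to-end recovery experiment (planted
probability-difference region) and the Monte-Carlo minimal-detectable-
difference analysis for the single-voxel two-sample design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import isotonic_regression
from scipy.special import ndtr

from .volumes_io import PatientCase, ValidationError, VoxelGrid
from .voxelstats import FdrConfig, VoxelComparison, compare_cohorts, two_sided_p_grid

__all__ = [
    "SyntheticTruth",
    "PowerSpec",
    "MddResult",
    "uniform_truth",
    "gradient_truth",
    "simulate_cohort",
    "recovery_experiment",
    "minimal_detectable_difference",
]

RESIDUAL_MODELS = ("bernoulli", "coherent")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated population.

    Tumor shape parameters are in voxel units on ``grid``: blob centres are
    drawn around ``mean_center`` with isotropic SD ``center_jitter``, radii
    around ``mean_radius`` with SD ``radius_sd``, and the blob surface is
    perturbed by a smooth random field scaled by ``roughness`` (relative
    radial distortion).  ``residual_coherence`` is the smoothing SD (voxels)
    of the copula field used by the coherent residual model.
    """

    grid: VoxelGrid
    prob_field: np.ndarray
    mean_center: tuple[float, float, float] | None = None
    center_jitter: float = 3.0
    mean_radius: float = 10.0
    radius_sd: float = 2.0
    roughness: float = 0.3
    residual_model: str = "bernoulli"
    residual_coherence: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.prob_field, dtype=np.float64)
        if p.shape != self.grid.shape:
            raise ValidationError("prob_field must have the grid shape")
        if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
            raise ValidationError("prob_field values must lie in [0, 1]")
        object.__setattr__(self, "prob_field", p)
        if self.mean_radius <= 0:
            raise ValidationError("mean_radius must be positive")
        if self.residual_model not in RESIDUAL_MODELS:
            raise ValidationError(
                f"residual_model must be one of {RESIDUAL_MODELS}, got {self.residual_model!r}"
            )


def uniform_truth(
    p: float = 0.7,
    shape: Sequence[int] = (48, 48, 48),
    **kwargs,
) -> SyntheticTruth:
    """Constant ground-truth resection probability on a default grid."""
    grid = VoxelGrid.default(shape)
    return SyntheticTruth(grid=grid, prob_field=np.full(grid.shape, float(p)), **kwargs)


def gradient_truth(
    low: float = 0.2,
    high: float = 0.9,
    shape: Sequence[int] = (48, 48, 48),
    axis: int = 2,
    **kwargs,
) -> SyntheticTruth:
    """Smooth axial gradient in resection probability (deep tissue is less
    often resectable than superficial tissue, emulated along one axis)."""
    grid = VoxelGrid.default(shape)
    n = grid.shape[axis]
    ramp = low + (high - low) * np.arange(n) / max(n - 1, 1)
    shape_ones = [1, 1, 1]
    shape_ones[axis] = n
    return SyntheticTruth(
        grid=grid, prob_field=np.broadcast_to(ramp.reshape(shape_ones), grid.shape).copy(), **kwargs
    )


def _default_center(truth: SyntheticTruth, side: str) -> np.ndarray:
    if truth.mean_center is not None:
        return np.asarray(truth.mean_center, dtype=float)
    center = (np.asarray(truth.grid.shape, dtype=float) - 1) / 2.0
    ax = truth.grid.midline_axis
    offset = truth.grid.shape[ax] / 4.0
    # world coordinate grows with index for the default affine; left = negative
    center[ax] += -offset if side == "left" else offset
    return center


def _tumor_blob(truth: SyntheticTruth, rng: np.random.Generator, side: str) -> np.ndarray:
    shape = truth.grid.shape
    center = _default_center(truth, side) + rng.normal(0.0, truth.center_jitter, size=3)
    radius = max(2.0, rng.normal(truth.mean_radius, truth.radius_sd))
    axis_scale = rng.uniform(0.8, 1.2, size=3)

    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0, mode="nearest")
    sd = noise.std()
    if sd > 0:
        noise /= sd

    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    dist2 = sum(
        ((g - c) / (radius * s)) ** 2 for g, c, s in zip(grids, center, axis_scale)
    )
    blob = np.sqrt(dist2) <= 1.0 + truth.roughness * noise
    if not blob.any():
        seedpoint = tuple(int(np.clip(round(c), 0, s - 1)) for c, s in zip(center, shape))
        blob[seedpoint] = True
        return blob
    labels, n_comp = ndimage.label(blob)
    if n_comp > 1:
        sizes = ndimage.sum_labels(blob, labels, index=np.arange(1, n_comp + 1))
        blob = labels == (1 + int(np.argmax(sizes)))
    return blob


def _residual(truth: SyntheticTruth, tumor: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # retention probability as residue is 1 - p*; u ~ U[0,1) marginally in
    # both models, spatially smooth in the coherent one
    if truth.residual_model == "bernoulli":
        u = rng.random(truth.grid.shape)
    else:
        g = ndimage.gaussian_filter(
            rng.standard_normal(truth.grid.shape), sigma=truth.residual_coherence, mode="nearest"
        )
        sd = g.std()
        u = ndtr(g / sd) if sd > 0 else np.full(truth.grid.shape, 0.5)
    return tumor & (u < 1.0 - truth.prob_field)


def simulate_cohort(
    truth: SyntheticTruth,
    n: int,
    cohort_label: str,
    side: str = "left",
    seed: int | None = None,
) -> list[PatientCase]:
    """Simulate ``n`` patient cases from the ground truth.

    Every generated case satisfies the full input invariants (non-empty
    binary tumor mask, residue a subset of tumor, on-grid); the same seed
    yields a bit-identical cohort.
    """
    if n <= 0:
        raise ValidationError(f"cohort size must be positive, got {n}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cases = []
    for i in range(n):
        tumor = _tumor_blob(truth, rng, side)
        residual = _residual(truth, tumor, rng)
        cases.append(
            PatientCase(
                id=f"{cohort_label}{i:03d}",
                cohort=cohort_label,
                side=side,
                tumor=tumor,
                residual=residual,
                grid=truth.grid,
            )
        )
    return cases


def centered_region(truth: SyntheticTruth, size: int = 10, side: str = "left") -> np.ndarray:
    """Cube of edge ``size`` voxels centred on the mean tumor centre for
    ``side`` — a convenient planted-effect region well covered by tumors."""
    center = np.round(_default_center(truth, side)).astype(int)
    mask = np.zeros(truth.grid.shape, dtype=bool)
    slices = tuple(
        slice(max(c - size // 2, 0), min(c - size // 2 + size, s))
        for c, s in zip(center, truth.grid.shape)
    )
    mask[slices] = True
    return mask


def _region_mask(grid: VoxelGrid, effect_region) -> np.ndarray:
    if isinstance(effect_region, np.ndarray) and effect_region.dtype == bool:
        if effect_region.shape != grid.shape:
            raise ValidationError("effect_region mask must have the grid shape")
        return effect_region
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(effect_region)] = True
    if not mask.any():
        raise ValidationError("effect_region is empty")
    return mask


def recovery_experiment(
    truth: SyntheticTruth,
    n_a: int,
    n_b: int,
    effect_region,
    delta: float,
    m: int = 200,
    seed: int = 0,
    cfg: FdrConfig = FdrConfig(),
    side: str = "left",
    dilate_voxels: int = 2,
) -> dict:
    """Planted-effect experiment exercising the full statistical pipeline.

    Cohort A is drawn from ``truth``; cohort B from the same truth with p*
    lowered by ``delta`` on ``effect_region`` (a boolean mask or a tuple of
    slices).  Sensitivity is measured on planted voxels that are testable;
    specificity on testable voxels outside a ``dilate_voxels``-voxel dilation
    of the planted region (the blur zone at the region's edge is excluded
    from both).  ``delta = 0`` is the null-calibration case.
    """
    region = _region_mask(truth.grid, effect_region)
    p_b = truth.prob_field - delta * region
    if p_b.min() < 0 or p_b.max() > 1:
        raise ValidationError(
            f"delta={delta} pushes the ground-truth probability outside [0, 1]"
        )
    truth_b = replace(truth, prob_field=p_b)

    rng = np.random.default_rng(seed)
    seed_a, seed_b, seed_perm = (int(s) for s in rng.integers(0, 2**31, size=3))
    cases_a = simulate_cohort(truth, n_a, "A", side=side, seed=seed_a)
    cases_b = simulate_cohort(truth_b, n_b, "B", side=side, seed=seed_b)
    result = compare_cohorts(cases_a, cases_b, m=m, seed=seed_perm, cfg=cfg)

    testable = result.testable_mask
    differential = result.differential
    planted = region & testable
    dilated = ndimage.binary_dilation(region, iterations=dilate_voxels) if dilate_voxels else region
    outside = testable & ~dilated

    n_planted = int(planted.sum())
    n_outside = int(outside.sum())
    tp = int((differential & planted).sum())
    fp = int((differential & outside).sum())
    report = {
        "delta": float(delta),
        "n_a": n_a,
        "n_b": n_b,
        "m": m,
        "seed": seed,
        "fdr_threshold": cfg.fdr_threshold,
        "testable_voxels": int(testable.sum()),
        "differential_voxels": int(differential.sum()),
        "differential_fraction": float(differential.sum() / max(int(testable.sum()), 1)),
        "planted_testable_voxels": n_planted,
        "outside_testable_voxels": n_outside,
        "true_positives": tp,
        "false_positives_outside_dilated": fp,
        "sensitivity": tp / n_planted if n_planted else float("nan"),
        "specificity": 1.0 - fp / n_outside if n_outside else float("nan"),
    }
    return report


@dataclass(frozen=True)
class PowerSpec:
    """Design of the single-voxel minimal-detectable-difference analysis.

    The two cohort proportions are placed symmetrically about 0.5
    (p1 = 0.5 - d/2, p2 = 0.5 + d/2), the maximal-variance baseline, and the
    two-sided Fisher exact test is simulated at level ``alpha``.
    """

    n_per_cohort: int = 30
    alpha: float = 0.10
    target_power: float = 0.8
    baseline: str = "symmetric"
    reps: int = 5000
    seed: int = 0
    max_difference: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.target_power < 1.0:
            raise ValidationError(f"target_power must be in (0, 1), got {self.target_power}")
        if self.n_per_cohort < 1 or self.reps < 1:
            raise ValidationError("n_per_cohort and reps must be positive")
        if self.baseline != "symmetric":
            raise ValidationError(f"unknown baseline rule {self.baseline!r}")


@dataclass
class MddResult:
    """Minimal detectable difference plus the full Monte-Carlo power curve."""

    mdd: float
    curve: pd.DataFrame
    spec: PowerSpec


def minimal_detectable_difference(spec: PowerSpec) -> MddResult:
    """Monte-Carlo power analysis of the voxel-level two-sample design.

    For each difference d on a 0.01 grid, ``reps`` binomial cohort pairs are
    drawn and tested with the two-sided Fisher exact test (rejection at
    p <= alpha); the MDD is the smallest d whose estimated power reaches the
    target.  The returned curve carries the raw estimates and an isotonic
    (monotone non-decreasing) smoothing of them.
    """
    n = spec.n_per_cohort
    reject = two_sided_p_grid(n, n) <= spec.alpha
    rng = np.random.default_rng(spec.seed)
    ds = np.round(np.arange(0.0, spec.max_difference + 1e-9, 0.01), 2)
    powers = np.empty(len(ds))
    for i, d in enumerate(ds):
        a = rng.binomial(n, 0.5 - d / 2.0, size=spec.reps)
        c = rng.binomial(n, 0.5 + d / 2.0, size=spec.reps)
        powers[i] = reject[a, c].mean()
    iso = isotonic_regression(powers).x
    curve = pd.DataFrame({"d": ds, "power": powers, "power_isotonic": iso})
    reached = np.flatnonzero(powers >= spec.target_power)
    if len(reached) == 0:
        raise ValidationError(
            f"target power {spec.target_power} not attained for any d <= {spec.max_difference}"
        )
    return MddResult(mdd=float(ds[reached[0]]), curve=curve, spec=spec)
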