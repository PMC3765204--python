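"""Cohort-level maps and conventional per-patient resection summaries.

For one cohort and hemisphere, summing the binary tumor masks voxel-wise
gives the tumor localization map T(v) and summing the residual masks gives
the residual localization map R(v).  The resection probability map (RPM) is

    P(v) = (T(v) - R(v)) / T(v)        wherever T(v) >= 1,

i.e. the fraction of patients with glioma at v whose tissue at v was
resected; P is undefined (NaN) where no patient had tumor.  Pooling cohorts
sums T and R before recomputing P; the voxels with T >= 1 and P = 0 -- never
resected in any patient -- form the "minimal common brain".

The module also provides the conventional, location-blind way of reporting
resection results (per-patient volumes, extent of resection, thresholded
counts and Fisher tests on them) that RPMs are designed to replace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .volumes_io import PatientCase, ValidationError, VoxelGrid

__all__ = [
    "CohortMaps",
    "build_cohort_maps",
    "minimal_common_brain",
    "summarize_cases",
    "cohort_summary",
    "conventional_compare",
]


@dataclass
class CohortMaps:
    """Per-voxel tumor count, residual count and resection probability."""

    tumor_count: np.ndarray
    residual_count: np.ndarray
    n_cases: int
    hemisphere: str
    grid: VoxelGrid
    cohort: str | None = None

    def __post_init__(self) -> None:
        t, r = self.tumor_count, self.residual_count
        if t.shape != self.grid.shape or r.shape != self.grid.shape:
            raise ValidationError("count maps must have the grid shape")
        if (r > t).any() or (t > self.n_cases).any() or t.min() < 0 or r.min() < 0:
            raise ValidationError("count maps violate 0 <= R <= T <= n_cases")

    @property
    def rpm(self) -> np.ndarray:
        """Resection probability P(v); NaN where T(v) = 0."""
        t = self.tumor_count.astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (t - self.residual_count) / t
        p[self.tumor_count == 0] = np.nan
        return p

    @property
    def informative_mask(self) -> np.ndarray:
        return self.tumor_count >= 1

    @property
    def informative_voxel_count(self) -> int:
        return int(np.count_nonzero(self.informative_mask))

    @property
    def minimal_common_mask(self) -> np.ndarray:
        """Voxels with glioma in at least one patient and residue in all of
        them (P = 0): never resected."""
        return self.informative_mask & (self.residual_count == self.tumor_count)


def build_cohort_maps(cases: Sequence[PatientCase], hemisphere: str) -> CohortMaps:
    """Voxel-wise summation of tumor and residual masks for one cohort-side."""
    if not cases:
        raise ValidationError("cannot build cohort maps from an empty case list")
    grid = cases[0].grid
    sides = {c.side for c in cases}
    if sides != {hemisphere}:
        raise ValidationError(f"cases have sides {sorted(sides)}, expected only {hemisphere!r}")
    for c in cases:
        if c.grid is not grid and not grid.matches(c.grid.shape, c.grid.affine):
            raise ValidationError(f"case {c.id} is on a different grid")
    t = np.zeros(grid.shape, dtype=np.int32)
    r = np.zeros(grid.shape, dtype=np.int32)
    for c in cases:
        t += c.tumor
        r += c.residual
    cohorts = {c.cohort for c in cases}
    return CohortMaps(
        tumor_count=t,
        residual_count=r,
        n_cases=len(cases),
        hemisphere=hemisphere,
        grid=grid,
        cohort=cohorts.pop() if len(cohorts) == 1 else None,
    )


def minimal_common_brain(maps_list: Sequence[CohortMaps]) -> CohortMaps:
    """Pool cohort maps (same grid and hemisphere) by summing T and R.

    The pooled map's ``minimal_common_mask`` is the minimal common brain of
    all contributing cohorts: once a voxel is resected in any patient it can
    never re-enter the set.
    """
    if not maps_list:
        raise ValidationError("nothing to pool")
    first = maps_list[0]
    for m in maps_list[1:]:
        if m.hemisphere != first.hemisphere:
            raise ValidationError(
                f"hemisphere mismatch in pooling: {m.hemisphere!r} vs {first.hemisphere!r}"
            )
        if not first.grid.matches(m.grid.shape, m.grid.affine):
            raise ValidationError("grid mismatch in pooling")
    return CohortMaps(
        tumor_count=sum(m.tumor_count for m in maps_list),
        residual_count=sum(m.residual_count for m in maps_list),
        n_cases=sum(m.n_cases for m in maps_list),
        hemisphere=first.hemisphere,
        grid=first.grid,
        cohort=None,
    )


def summarize_cases(cases: Sequence[PatientCase]) -> pd.DataFrame:
    """Conventional per-patient summary: volumes in mL and extent of resection.

    EOR is the percentage of the (postoperative compound) tumor volume that
    was resected: 100 * (1 - residual/tumor).
    """
    rows = []
    for c in cases:
        vv = c.grid.voxel_volume_ml
        tumor_ml = c.tumor_voxels * vv
        residual_ml = c.residual_voxels * vv
        rows.append(
            {
                "id": c.id,
                "cohort": c.cohort,
                "side": c.side,
                "tumor_volume_ml": tumor_ml,
                "residual_volume_ml": residual_ml,
                "eor_percent": 100.0 * (1.0 - residual_ml / tumor_ml),
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(
    summary: pd.DataFrame,
    eor_threshold: float = 90.0,
    residual_threshold_ml: float = 10.0,
) -> dict:
    """Cohort-level medians and thresholded counts from a per-patient summary."""
    return {
        "n": int(len(summary)),
        "median_eor_percent": float(summary["eor_percent"].median()),
        "median_residual_ml": float(summary["residual_volume_ml"].median()),
        "n_eor_over_threshold": int((summary["eor_percent"] > eor_threshold).sum()),
        "n_residual_under_threshold": int(
            (summary["residual_volume_ml"] < residual_threshold_ml).sum()
        ),
        "eor_threshold": eor_threshold,
        "residual_threshold_ml": residual_threshold_ml,
    }


def conventional_compare(
    summ_a: pd.DataFrame,
    summ_b: pd.DataFrame,
    eor_threshold: float = 90.0,
    residual_threshold_ml: float = 10.0,
) -> dict:
    """Location-blind cohort comparison: medians plus two-sided Fisher exact
    tests on EOR-over-threshold and residual-under-threshold counts."""
    from .voxelstats import fisher_two_sided

    if summ_a.empty or summ_b.empty:
        raise ValidationError("both cohort summaries must be non-empty")
    a = cohort_summary(summ_a, eor_threshold, residual_threshold_ml)
    b = cohort_summary(summ_b, eor_threshold, residual_threshold_ml)
    p_eor = fisher_two_sided(
        (
            a["n_eor_over_threshold"],
            a["n"] - a["n_eor_over_threshold"],
            b["n_eor_over_threshold"],
            b["n"] - b["n_eor_over_threshold"],
        )
    )
    p_res = fisher_two_sided(
        (
            a["n_residual_under_threshold"],
            a["n"] - a["n_residual_under_threshold"],
            b["n_residual_under_threshold"],
            b["n"] - b["n_residual_under_threshold"],
        )
    )
    return {
        "cohort_a": a,
        "cohort_b": b,
        "p_eor_over_threshold": float(p_eor),
        "p_residual_under_threshold": float(p_res),
    }
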