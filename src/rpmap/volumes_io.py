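"""Reading, validation and writing of binary mask volumes and cohort manifests.

Every patient contributes a pair of binary 3D masks already registered to a
common template grid (nominally the 1 mm MNI152 space): the *tumor* mask (the
compound of resection cavity and residual glioma on postoperative imaging) and
the *residual* mask (residual glioma only).  A cohort manifest is a delimited
text table listing, per patient, an identifier, a cohort label, the tumor
lateralization, and the two mask file paths.

All volumes attached to one analysis must live on a single :class:`VoxelGrid`;
masks are held in memory as boolean numpy arrays and exchanged on disk as
NIfTI-1 volumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeometryError",
    "ConfigurationError",
    "VoxelGrid",
    "PatientCase",
    "CohortManifest",
    "load_manifest",
    "load_case",
    "load_cases",
    "write_map",
    "read_map",
    "binarize",
    "COHORT_LABELS",
    "SIDE_LABELS",
]

#: Allowed cohort labels in a manifest.
COHORT_LABELS = ("A", "B")
#: Allowed tumor lateralization labels.
SIDE_LABELS = ("left", "right")
#: Required manifest columns, in canonical order.
MANIFEST_COLUMNS = ("id", "cohort", "side", "tumor", "residual")

#: Absolute tolerance on affine entries when deciding two grids are the same
#: (NIfTI headers store the affine in float32).
AFFINE_ATOL = 1e-4
#: Threshold applied when binarizing mask values in [0, 1] (majority rule for
#: masks that went through interpolating resampling).
BINARIZE_THRESHOLD = 0.5


class ValidationError(ValueError):
    """Input data violates an invariant (bad labels, non-subset residue, ...)."""


class GeometryError(ValidationError):
    """A volume does not live on the expected voxel grid."""


class ConfigurationError(ValueError):
    """A manifest or configuration file is structurally wrong."""


@dataclass(frozen=True, eq=False)
class VoxelGrid:
    """Shared voxel grid: array shape plus voxel-to-world affine.

    The midline (``midline_axis`` world axis at world coordinate
    ``midline_world``) separates the hemispheres; with the MNI152 convention
    the x axis (index 0) at x=0 does so, negative x being the left hemisphere.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    midline_axis: int = 0
    midline_world: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "affine", aff)
        if np.any(self.voxel_size_mm <= 0):
            raise GeometryError(f"non-positive voxel size {self.voxel_size_mm}")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Edge lengths of one voxel in mm, per axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mm^3 == 1e-3 mL)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "VoxelGrid":
        return cls(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))

    @classmethod
    def default(cls, shape: Sequence[int] = (48, 48, 48), voxel_mm: float = 1.0) -> "VoxelGrid":
        """Isotropic grid centred on the origin (midline at world x = 0)."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_mm] * 3 + [1.0])
        affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    def matches(self, shape: Sequence[int], affine: np.ndarray) -> bool:
        return tuple(shape) == self.shape and np.allclose(
            np.asarray(affine, float), self.affine, atol=AFFINE_ATOL, rtol=0.0
        )

    def check_compatible(self, shape: Sequence[int], affine: np.ndarray, context: str = "volume") -> None:
        if not self.matches(shape, affine):
            raise GeometryError(
                f"{context} is not on the analysis grid: shape {tuple(shape)} vs "
                f"{self.shape}; affine\n{np.asarray(affine)}\nvs grid affine\n{self.affine}"
            )

    def world_coordinate(self) -> np.ndarray:
        """World coordinate along ``midline_axis`` of every voxel centre."""
        idx = np.indices(self.shape, dtype=float)
        ax = self.midline_axis
        coord = (
            self.affine[ax, 0] * idx[0]
            + self.affine[ax, 1] * idx[1]
            + self.affine[ax, 2] * idx[2]
            + self.affine[ax, 3]
        )
        return coord

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean mask of voxels in the given hemisphere (midline excluded)."""
        if side not in SIDE_LABELS:
            raise ValidationError(f"side must be one of {SIDE_LABELS}, got {side!r}")
        coord = self.world_coordinate()
        return coord < self.midline_world if side == "left" else coord > self.midline_world


def binarize(data: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Binarize mask values in [0, 1] at ``threshold``.

    Values outside [0, 1] or non-finite values are rejected rather than
    coerced: they usually indicate registration or export artifacts.
    """
    data = np.asarray(data)
    if not np.isfinite(data).all():
        raise ValidationError("mask contains non-finite values")
    if data.min() < 0 or data.max() > 1:
        raise ValidationError(
            f"mask values outside [0, 1] (min {data.min():g}, max {data.max():g}); refusing to coerce"
        )
    return data > threshold


@dataclass
class PatientCase:
    """One subject: tumor/residual mask pair plus cohort and side labels.

    The tumor mask is the postoperative compound of cavity and residue, so the
    residual mask must be a voxel-wise subset of it.
    """

    id: str
    cohort: str
    side: str
    tumor: np.ndarray
    residual: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.residual = np.asarray(self.residual, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.side not in SIDE_LABELS:
            raise ValidationError(f"case {self.id}: side must be one of {SIDE_LABELS}, got {self.side!r}")
        for name, mask in (("tumor", self.tumor), ("residual", self.residual)):
            if mask.shape != self.grid.shape:
                raise GeometryError(
                    f"case {self.id}: {name} mask shape {mask.shape} != grid shape {self.grid.shape}"
                )
        if not self.tumor.any():
            raise ValidationError(f"case {self.id}: tumor mask is empty")
        outside = int(np.count_nonzero(self.residual & ~self.tumor))
        if outside:
            raise ValidationError(
                f"case {self.id}: residual mask is not a subset of the tumor mask "
                f"({outside} residual voxel(s) outside the tumor)"
            )

    @property
    def tumor_voxels(self) -> int:
        return int(np.count_nonzero(self.tumor))

    @property
    def residual_voxels(self) -> int:
        return int(np.count_nonzero(self.residual))


@dataclass
class CohortManifest:
    """Validated table of cases: columns id, cohort, side, tumor, residual."""

    frame: pd.DataFrame
    root: Path = field(default_factory=Path)

    @property
    def n_cases(self) -> int:
        return len(self.frame)

    def counts(self) -> pd.Series:
        """Number of cases per cohort x side."""
        return self.frame.groupby(["cohort", "side"]).size()

    def cohort_counts(self) -> dict[str, int]:
        return self.frame.groupby("cohort").size().to_dict()

    def rows(self) -> Iterable[pd.Series]:
        return (row for _, row in self.frame.iterrows())

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.root / p


def load_manifest(
    path: str | os.PathLike,
    allowed_cohorts: Sequence[str] = COHORT_LABELS,
    check_paths: bool = True,
) -> CohortManifest:
    """Load and validate a cohort manifest (CSV or TSV with a header row).

    Relative mask paths are interpreted relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"manifest not found: {path}")
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    frame.columns = [str(c).strip() for c in frame.columns]
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"manifest {path} is missing required column(s): {', '.join(missing)}")
    frame = frame[list(MANIFEST_COLUMNS)].apply(lambda s: s.str.strip())

    dup = frame["id"][frame["id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate case id(s) in manifest: {', '.join(dup)}")
    bad_cohort = sorted(set(frame["cohort"]) - set(allowed_cohorts))
    if bad_cohort:
        raise ValidationError(
            f"cohort label(s) {bad_cohort} not in allowed labels {tuple(allowed_cohorts)}"
        )
    bad_side = sorted(set(frame["side"]) - set(SIDE_LABELS))
    if bad_side:
        raise ValidationError(f"side label(s) {bad_side} not in allowed labels {SIDE_LABELS}")

    manifest = CohortManifest(frame=frame.reset_index(drop=True), root=path.parent)
    if check_paths:
        for row in manifest.rows():
            for col in ("tumor", "residual"):
                p = manifest.resolve(row[col])
                if not p.exists():
                    raise ConfigurationError(f"case {row['id']}: {col} mask not found at {p}")
    return manifest


def load_case(row, grid: VoxelGrid, root: Path | str = ".") -> PatientCase:
    """Load one manifest row into a validated :class:`PatientCase`.

    Masks are binarized at 0.5 (so probability-valued masks produced by
    interpolating warps are thresholded by majority) and checked against the
    shared grid and the residue-within-tumor invariant.
    """
    root = Path(root)

    def _read(col: str) -> np.ndarray:
        p = Path(row[col])
        img = nib.load(p if p.is_absolute() else root / p)
        grid.check_compatible(img.shape[:3], img.affine, context=f"case {row['id']} {col} mask")
        return binarize(np.asarray(img.dataobj, dtype=np.float64))

    return PatientCase(
        id=str(row["id"]),
        cohort=str(row["cohort"]),
        side=str(row["side"]),
        tumor=_read("tumor"),
        residual=_read("residual"),
        grid=grid,
    )


def load_cases(manifest: CohortManifest, grid: VoxelGrid | None = None) -> tuple[list[PatientCase], VoxelGrid]:
    """Load all cases of a manifest; the grid is taken from the first volume
    when not supplied."""
    rows = list(manifest.rows())
    if not rows:
        raise ValidationError("manifest has no cases")
    if grid is None:
        first = nib.load(manifest.resolve(rows[0]["tumor"]))
        grid = VoxelGrid.from_image(first)
    cases = [load_case(row, grid, root=manifest.root) for row in rows]
    return cases, grid


def write_map(volume: np.ndarray, grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a real-valued (or boolean) volume as NIfTI on the grid's affine.

    NaN marks voxels where a quantity is undefined (e.g. resection probability
    outside informative voxels) and round-trips unchanged.
    """
    volume = np.asarray(volume)
    if volume.shape != grid.shape:
        raise GeometryError(f"volume shape {volume.shape} != grid shape {grid.shape}")
    img = nib.Nifti1Image(volume.astype(np.float32), grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))


def read_map(path: str | os.PathLike, grid: VoxelGrid | None = None) -> np.ndarray:
    img = nib.load(os.fspath(path))
    if grid is not None:
        grid.check_compatible(img.shape[:3], img.affine, context=str(path))
    return np.asarray(img.dataobj, dtype=np.float32)
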