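"""Volume / phenotype I/O and analysis-mask construction.

Subject gray-matter maps live on one shared voxel grid (NIfTI-1 with a
common affine); the phenotype is a TSV keyed by ``subject_id``.  The
analysis mask reproduces the absolute-threshold masking convention of
VBM group analyses: a voxel enters the analysis only if its tissue
value exceeds the threshold, by default in *every* subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidDesignError

GROUP_TDC = "TDC"
GROUP_ASD = "ASD"
#: Pipeline-wide label encoding: TDC -> -1, ASD -> +1 (ASD is the
#: positive class for sensitivity/specificity throughout).
GROUP_CODES = {GROUP_TDC: -1, GROUP_ASD: +1}

PHENOTYPE_REQUIRED = ("subject_id", "site", "group", "age", "sex", "tiv")


@dataclass
class VolumeGrid:
    """A single subject's scalar volume with its voxel->world affine."""

    values: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidDesignError("VolumeGrid expects a 3D array")
        if self.affine.shape != (4, 4):
            raise InvalidDesignError("affine must be 4x4")
        if not np.isfinite(self.values).all():
            raise InvalidDesignError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise InvalidDesignError("affine is not invertible")


@dataclass
class Cohort:
    """Aligned per-subject volumes plus the phenotype table.

    ``volumes`` is stacked (n_subjects, X, Y, Z) in phenotype row order;
    all subjects share one grid and affine.
    """

    phenotype: pd.DataFrame
    volumes: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.volumes.ndim != 4:
            raise InvalidDesignError("volumes must be (n_subjects, X, Y, Z)")
        if len(self.phenotype) != self.volumes.shape[0]:
            raise InvalidDesignError(
                f"{len(self.phenotype)} phenotype rows but "
                f"{self.volumes.shape[0]} volumes"
            )
        validate_phenotype(self.phenotype)

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def labels(self) -> np.ndarray:
        """Class labels in cohort order, TDC -> -1, ASD -> +1."""
        return self.phenotype["group"].map(GROUP_CODES).to_numpy(dtype=np.int64)

    def subset(self, row_mask: np.ndarray) -> "Cohort":
        row_mask = np.asarray(row_mask)
        return Cohort(
            phenotype=self.phenotype.loc[row_mask].reset_index(drop=True),
            volumes=self.volumes[row_mask],
            affine=self.affine.copy(),
        )


@dataclass
class BrainMask:
    """Boolean analysis mask on the cohort grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise InvalidDesignError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    def linear_indices(self) -> np.ndarray:
        return np.flatnonzero(self.include.ravel())


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path, subject_id: str | None = None) -> VolumeGrid:
    """Read a 3D NIfTI-1 volume; raises :class:`FormatError` on failure."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float64)
        affine = np.asarray(img.affine, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    if values.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {values.shape}")
    return VolumeGrid(values=values, affine=affine,
                      subject_id=subject_id or path.name.split(".")[0])


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def write_mask(mask: BrainMask, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.include.astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Phenotype table


def _normalize_group(value: str) -> str:
    v = str(value).strip().upper()
    if v in ("TDC", "NC", "TD", "CONTROL"):
        return GROUP_TDC
    if v == "ASD":
        return GROUP_ASD
    raise FormatError(f"unknown group label {value!r} (expected TDC or ASD)")


def validate_phenotype(table: pd.DataFrame) -> None:
    missing = [c for c in PHENOTYPE_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns: {missing}")
    dup = table["subject_id"][table["subject_id"].duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate subject_id values: {sorted(set(dup))}")
    bad = set(table["group"]) - set(GROUP_CODES)
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a TSV phenotype table, normalizing group labels.

    Row order is preserved.  Group values are case/whitespace folded
    ("asd " -> "ASD"); duplicate subject ids are an error.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "site": str})
    except Exception as exc:
        raise FormatError(f"could not read phenotype TSV {path}: {exc}") from exc
    if "group" in table.columns:
        table["group"] = table["group"].map(_normalize_group)
    validate_phenotype(table)
    return table


def write_phenotype(table: pd.DataFrame, path: str | Path,
                    round_scores: bool = False) -> None:
    """Write the phenotype TSV.

    ``round_scores=True`` rounds score columns (non-required numeric
    columns) to integers on output only — in-memory values stay float so
    correlations are computed pre-rounding.
    """
    validate_phenotype(table)
    out = table.copy()
    if round_scores:
        for col in out.columns:
            if col not in PHENOTYPE_REQUIRED and pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round().astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def read_cohort(volume_dir: str | Path, phenotype_path: str | Path) -> Cohort:
    """Assemble a Cohort from ``<volume_dir>/<subject_id>.nii.gz`` files."""
    volume_dir = Path(volume_dir)
    table = read_phenotype(phenotype_path)
    grids = []
    for sid in table["subject_id"]:
        p = volume_dir / f"{sid}.nii.gz"
        if not p.exists():
            p = volume_dir / f"{sid}.nii"
        grids.append(read_volume(p, subject_id=sid))
    affine = grids[0].affine
    for g in grids[1:]:
        if g.values.shape != grids[0].values.shape or not np.allclose(g.affine, affine):
            raise FormatError(f"subject {g.subject_id} is not on the shared grid")
    return Cohort(phenotype=table,
                  volumes=np.stack([g.values for g in grids]),
                  affine=affine)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 round_scores: bool = False) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_phenotype(cohort.phenotype, out_dir / "phenotype.tsv",
                    round_scores=round_scores)
    for i, sid in enumerate(cohort.phenotype["subject_id"]):
        write_volume(VolumeGrid(cohort.volumes[i], cohort.affine, str(sid)),
                     out_dir / f"{sid}.nii.gz")


# ---------------------------------------------------------------------------
# Analysis mask


def build_group_mask(cohort: Cohort, abs_threshold: float = 0.1,
                     rule: str = "all") -> BrainMask:
    """Absolute-threshold analysis mask.

    ``rule="all"`` (default) includes a voxel iff its value exceeds
    ``abs_threshold`` in every subject — the convention of SPM-style
    absolute masking, which avoids edge effects at tissue boundaries.
    ``rule="mean"`` thresholds the cohort mean image instead.
    """
    if cohort.n_subjects == 0:
        raise InvalidDesignError("cannot build a mask from an empty cohort")
    if rule == "all":
        include = (cohort.volumes > abs_threshold).all(axis=0)
    elif rule == "mean":
        include = cohort.volumes.mean(axis=0) > abs_threshold
    else:
        raise ValueError(f"unknown mask rule {rule!r} (use 'all' or 'mean')")
    return BrainMask(include=include)
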