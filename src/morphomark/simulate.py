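"""Synthetic multi-site cohort generator.

Emulates the *outputs* of a VBM preprocessing chain — modulated,
smoothed gray-matter probability maps on a common grid — rather than
the chain itself.  Each subject volume is

    template + site shift + covariate effects + smoothed subject noise

with the case group's mean reduced inside designated atlas regions by
``effect_size_d`` noise standard deviations, so the per-voxel
standardized group difference (Cohen's d) is controlled at the
generative level.  Severity scores are generated conditionally on
regional volume to hit a target correlation.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import as_float_tuple3, as_int_tuple3
from .exceptions import FormatError, InvalidDesignError
from .volio import Cohort, GROUP_ASD, GROUP_TDC

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Table-style default site sizes (TDC, ASD): one larger "training" site
#: and two smaller transfer sites, mirroring a multi-site pediatric study.
DEFAULT_SITES: Mapping[str, tuple[int, int]] = {
    "GU": (55, 51),
    "OHSU": (56, 37),
    "UCLA": (16, 16),
}


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a synthetic cohort.

    effect_size_d is the standardized mean *reduction* in the ASD group
    inside ``effect_regions`` (Cohen's d units relative to the per-voxel
    noise SD).  covariate_slopes give the per-voxel change per unit of
    age (years) and TIV (mm^3); they are deliberately small relative to
    noise so they act as nuisance structure, not the dominant signal.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_per_group_per_site: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SITES))
    effect_regions: tuple[int, ...] = ()
    effect_size_d: float = 0.0
    covariate_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.002, "tiv": 1.0e-8})
    smoothing_fwhm_mm: float = 6.0
    noise_sd: float = 0.04
    site_shift_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        gs = as_int_tuple3(self.grid_shape, "grid_shape")
        object.__setattr__(self, "grid_shape", gs)
        vs = as_float_tuple3(self.voxel_size_mm, "voxel_size_mm")
        object.__setattr__(self, "voxel_size_mm", vs)
        if any(d < 8 for d in gs):
            raise InvalidDesignError("grid dimensions must each be >= 8")
        if any(v <= 0 for v in vs):
            raise InvalidDesignError("voxel sizes must be positive")
        if not self.n_per_group_per_site:
            raise InvalidDesignError("at least one site required")
        for site, (n_tdc, n_asd) in self.n_per_group_per_site.items():
            if n_tdc < 0 or n_asd < 0:
                raise InvalidDesignError(f"negative n at site {site}")
        total = sum(a + b for a, b in self.n_per_group_per_site.values())
        if total < 1:
            raise InvalidDesignError("empty design: no subjects at any site")
        if not np.isfinite(self.effect_size_d):
            raise InvalidDesignError("effect_size_d must be finite")
        if self.smoothing_fwhm_mm < 0:
            raise InvalidDesignError("smoothing_fwhm_mm must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be positive")
        if self.site_shift_sd < 0:
            raise InvalidDesignError("site_shift_sd must be >= 0")
        object.__setattr__(self, "effect_regions",
                           tuple(int(r) for r in self.effect_regions))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation (0 = background)."""

    labels: np.ndarray
    region_names: dict[int, str]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = set(np.unique(self.labels).tolist()) - {0}
        unnamed = present - set(self.region_names)
        if unnamed:
            raise InvalidDesignError(f"labels without a name: {sorted(unnamed)}")

    @property
    def label_values(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})

    def region_voxels(self, label: int) -> np.ndarray:
        """Linear voxel indices of one region."""
        return np.flatnonzero(self.labels.ravel() == label)


# ---------------------------------------------------------------------------
# Smoothing


def smooth_volume(grid: np.ndarray, fwhm_mm: float,
                  voxel_size_mm: Sequence[float]) -> np.ndarray:
    """Separable Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)).

    FWHM is in millimetres and converted per-axis to voxel units.
    Mirrored boundary handling: total mass is conserved up to the
    (symmetric) boundary reflection.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    grid = np.asarray(grid, dtype=np.float64)
    if fwhm_mm == 0:
        return grid.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    return ndimage.gaussian_filter(grid, sigma=sigma_vox, mode="mirror")


def _ellipsoid_support(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """In-brain ellipsoid envelope: semi-axes at 45% of each dimension."""
    axes = [np.arange(n, dtype=np.float64) - (n - 1) / 2.0 for n in grid_shape]
    semi = [0.45 * n for n in grid_shape]
    i = (axes[0] / semi[0])[:, None, None] ** 2
    j = (axes[1] / semi[1])[None, :, None] ** 2
    k = (axes[2] / semi[2])[None, None, :] ** 2
    return (i + j + k) <= 1.0


# ---------------------------------------------------------------------------
# Atlas


def make_atlas(grid_shape: Sequence[int], n_regions: int, seed: int,
               voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0)) -> AtlasParcellation:
    """Partition an ellipsoidal in-brain support into contiguous regions.

    Voronoi region growing: ``n_regions`` seed voxels are drawn from the
    support and every support voxel is assigned to its nearest seed
    (ties -> lowest label).  Cells of a Voronoi partition restricted to
    a convex support are connected, which gives contiguous toy regions
    standing in for an anatomical parcellation.
    """
    gs = as_int_tuple3(grid_shape, "grid_shape")
    if n_regions < 1:
        raise InvalidDesignError("n_regions must be >= 1")
    support = _ellipsoid_support(gs)
    coords = np.argwhere(support)
    if n_regions > len(coords):
        raise InvalidDesignError(
            f"n_regions={n_regions} exceeds in-support voxel count {len(coords)}")
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    seeds = coords[seed_idx].astype(np.float64)
    # squared distance from every support voxel to every seed
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1  # argmin ties -> lowest label
    labels = np.zeros(gs, dtype=np.int32)
    labels[tuple(coords.T)] = assignment
    names = {lab: f"region_{lab:02d}" for lab in range(1, n_regions + 1)}
    return AtlasParcellation(labels=labels, region_names=names,
                             voxel_size_mm=as_float_tuple3(voxel_size_mm, "voxel_size_mm"))


def write_atlas(atlas: AtlasParcellation, nifti_path: str | Path,
                labels_path: str | Path) -> None:
    aff = np.diag(list(atlas.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), aff), str(nifti_path))
    pd.DataFrame(
        {"label": list(atlas.region_names), "name": list(atlas.region_names.values())}
    ).to_csv(labels_path, sep="\t", index=False)


def read_atlas(nifti_path: str | Path, labels_path: str | Path) -> AtlasParcellation:
    try:
        img = nib.load(str(nifti_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        table = pd.read_csv(labels_path, sep="\t")
        names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
    except Exception as exc:
        raise FormatError(f"could not read atlas {nifti_path}: {exc}") from exc
    vox = tuple(float(v) for v in img.header.get_zooms()[:3])
    return AtlasParcellation(labels=labels, region_names=names, voxel_size_mm=vox)


# ---------------------------------------------------------------------------
# Cohort simulation


def _smoothed_unit_noise(rng: np.random.Generator, shape, fwhm_mm, voxel_size_mm):
    """Smoothed white noise renormalized to unit pointwise SD (interior).

    Smoothing shrinks pointwise variance by the kernel's sum of squares;
    dividing by that factor keeps the per-voxel SD at 1 so effect sizes
    stated in noise-SD units stay exact.
    """
    raw = rng.standard_normal(shape)
    if fwhm_mm == 0:
        return raw
    smoothed = smooth_volume(raw, fwhm_mm, voxel_size_mm)
    impulse = np.zeros(shape)
    impulse[tuple(n // 2 for n in shape)] = 1.0
    kernel = smooth_volume(impulse, fwhm_mm, voxel_size_mm)
    factor = float(np.sqrt((kernel ** 2).sum()))
    return smoothed / factor


def simulate_cohort(design: CohortDesign, atlas: AtlasParcellation) -> Cohort:
    """Generate a multi-site cohort of smoothed GM-like volumes.

    Returns a :class:`~morphomark.volio.Cohort` whose phenotype has
    columns subject_id, site, group, age, sex, tiv.  ASD volumes are
    reduced by ``effect_size_d * noise_sd`` inside the effect regions.
    """
    gs = design.grid_shape
    if atlas.labels.shape != gs:
        raise InvalidDesignError(
            f"atlas grid {atlas.labels.shape} does not match design grid {gs}")
    missing = set(design.effect_regions) - set(atlas.label_values)
    if missing:
        raise InvalidDesignError(f"effect_regions not in atlas: {sorted(missing)}")

    rng = np.random.default_rng(design.seed)
    envelope = (atlas.labels > 0).astype(np.float64)

    # Template: smooth random field on top of a constant GM level,
    # restricted to the brain envelope.  Mimics the spatial
    # autocorrelation of smoothed GM maps without real anatomy.
    template_field = _smoothed_unit_noise(
        rng, gs, max(design.smoothing_fwhm_mm, 4.0), design.voxel_size_mm)
    template = (0.55 + 0.08 * template_field) * envelope
    template = np.clip(template, 0.15 * envelope, None)

    effect_mask = np.isin(atlas.labels, design.effect_regions)
    effect_shift = design.effect_size_d * design.noise_sd

    rows = []
    volumes = []
    age_center, tiv_center, tiv_sd = 11.0, 1.45e6, 1.2e5
    slope_age = float(design.covariate_slopes.get("age", 0.0))
    slope_tiv = float(design.covariate_slopes.get("tiv", 0.0))

    for site, (n_tdc, n_asd) in design.n_per_group_per_site.items():
        site_shift = rng.normal(0.0, design.site_shift_sd) if design.site_shift_sd > 0 else 0.0
        for group, n in ((GROUP_TDC, n_tdc), (GROUP_ASD, n_asd)):
            for i in range(n):
                age = rng.uniform(7.0, 15.0)
                sex = int(rng.random() < 0.8)  # 1 = male; ASD cohorts skew male
                tiv = rng.normal(tiv_center, tiv_sd)
                noise = design.noise_sd * _smoothed_unit_noise(
                    rng, gs, design.smoothing_fwhm_mm, design.voxel_size_mm)
                vol = template + (site_shift
                                  + slope_age * (age - age_center)
                                  + slope_tiv * (tiv - tiv_center)) * envelope
                vol = vol + noise * envelope
                if group == GROUP_ASD and effect_shift != 0.0:
                    vol = vol - effect_shift * effect_mask
                np.clip(vol, 0.0, None, out=vol)
                rows.append({
                    "subject_id": f"{site}_{group}_{i:03d}",
                    "site": site, "group": group,
                    "age": round(age, 3), "sex": sex, "tiv": round(tiv, 1),
                })
                volumes.append(vol)

    if not rows:
        raise InvalidDesignError("design produced no subjects")
    return Cohort(phenotype=pd.DataFrame(rows),
                  volumes=np.stack(volumes),
                  affine=design.affine())


def simulate_scores(cohort: Cohort, region_label: int, atlas: AtlasParcellation,
                    target_r: float, score_name: str, seed: int) -> Cohort:
    """Attach a severity score column correlated with regional volume.

    Scores are generated for ASD subjects only (severity instruments are
    administered to patients); TDC rows get NaN.  The score is a linear
    map of the standardized regional summed volume plus Gaussian
    conditional noise, so the population correlation equals
    ``target_r``; |target_r| = 1 degenerates to the exact linear map.
    Stored as float; rounding to integer scales happens only on output.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError(f"target_r must be in [-1, 1], got {target_r}")
    if region_label not in atlas.label_values:
        raise InvalidDesignError(f"region label {region_label} not in atlas")
    region_idx = atlas.region_voxels(region_label)
    asd = (cohort.phenotype["group"] == GROUP_ASD).to_numpy()
    if asd.sum() < 2:
        raise InvalidDesignError("need at least two ASD subjects to attach scores")

    flat = cohort.volumes.reshape(cohort.n_subjects, -1)
    vol = flat[:, region_idx].sum(axis=1)[asd]
    z = (vol - vol.mean()) / vol.std(ddof=0)
    rng = np.random.default_rng(seed)
    if abs(target_r) == 1.0:
        score_z = np.sign(target_r) * z
    else:
        noise = rng.standard_normal(z.shape)
        score_z = target_r * z + np.sqrt(1.0 - target_r ** 2) * noise
    # ADOS-communication-like scale: mean 10, SD 3 (kept float here)
    scores = 10.0 + 3.0 * score_z

    pheno = cohort.phenotype.copy()
    col = np.full(cohort.n_subjects, np.nan)
    col[asd] = scores
    pheno[score_name] = col
    return Cohort(phenotype=pheno, volumes=cohort.volumes, affine=cohort.affine)
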