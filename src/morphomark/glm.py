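"""Voxelwise group GLM, cluster-extent thresholding, atlas labelling.

The group comparison is an ordinary least-squares fit per voxel of

    value ~ intercept + group + covariates

with the t statistic for the group contrast and two-sided p from the t
distribution on n - p degrees of freedom.  With no covariates this is
algebraically the pooled-variance two-sample t test.  Thresholded maps
are reduced to connected supra-threshold components with an extent
(minimum cluster size) filter, the standard cluster-forming rule of
voxel-based morphometry reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._utils import connectivity_structure
from .exceptions import DesignMatrixError, InvalidDesignError
from .simulate import AtlasParcellation
from .volio import BrainMask, Cohort

#: Contrast direction tags.
TDC_GT_ASD = "TDC>ASD"
ASD_GT_TDC = "ASD>TDC"


@dataclass
class GroupDiffMap:
    """Voxelwise t/p maps for the group contrast (zero outside mask)."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    contrast: str
    mask: BrainMask

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise DesignMatrixError(f"non-positive degrees of freedom: {self.df}")


@dataclass
class Cluster:
    voxels: np.ndarray          # (size, 3) voxel ijk coordinates
    size: int
    peak_ijk: tuple[int, int, int]
    peak_stat: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    connectivity: int
    grid_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.clusters)

    def total_voxels(self) -> int:
        return sum(c.size for c in self.clusters)

    def binary(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = True
        return out


# ---------------------------------------------------------------------------
# GLM


def _design_matrix(cohort: Cohort, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", "group"] + list(covariates)
    cols = [np.ones(cohort.n_subjects), (cohort.labels() == 1).astype(np.float64)]
    for cov in covariates:
        if cov not in cohort.phenotype.columns:
            raise DesignMatrixError(f"covariate column {cov!r} not in phenotype")
        cols.append(cohort.phenotype[cov].to_numpy(dtype=np.float64))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify an offending column for the error message
        for j in range(X.shape[1] - 1, 0, -1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X):
                raise DesignMatrixError(
                    f"design matrix rank deficient: column {names[j]!r} is "
                    "collinear with the others")
        raise DesignMatrixError("design matrix rank deficient")
    return X, names


def fit_voxelwise_glm(cohort: Cohort, covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                      mask: BrainMask | None = None,
                      contrast: str = TDC_GT_ASD) -> GroupDiffMap:
    """Per-voxel OLS fit with the group t contrast.

    ``contrast`` fixes the sign convention: ``TDC>ASD`` yields positive
    t where controls have larger values.  p is two-sided.
    """
    if contrast not in (TDC_GT_ASD, ASD_GT_TDC):
        raise ValueError(f"unknown contrast {contrast!r}")
    if mask is None:
        mask = BrainMask(np.ones(cohort.grid_shape, dtype=bool))
    X, _names = _design_matrix(cohort, covariates)
    m, p = X.shape
    df = m - p
    if df <= 0:
        raise DesignMatrixError(f"not enough subjects: n={m}, design columns={p}")

    idx = mask.linear_indices()
    Y = cohort.volumes.reshape(m, -1)[:, idx]

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df

    c = np.zeros(p)
    c[1] = -1.0 if contrast == TDC_GT_ASD else 1.0  # group column codes ASD=1
    denom = np.sqrt(np.maximum(sigma2 * float(c @ XtX_inv @ c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (c @ beta) / denom, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    t_grid = np.zeros(cohort.grid_shape)
    p_grid = np.ones(cohort.grid_shape)
    t_grid.ravel()[idx] = t
    p_grid.ravel()[idx] = pvals
    return GroupDiffMap(t_values=t_grid, p_values=p_grid, df=df,
                        contrast=contrast, mask=mask)


# ---------------------------------------------------------------------------
# Cluster extraction (shared with the searchlight accuracy map)


def extract_clusters(binary: np.ndarray, stat: np.ndarray, extent: int,
                     connectivity: int = 26) -> ClusterSet:
    """Connected components of ``binary``, dropping those below ``extent``.

    Clusters are sorted by size descending (ties: lowest minimum linear
    index first).  The peak is the voxel of maximum |stat| within the
    cluster, ties broken by lowest linear index.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    structure = connectivity_structure(connectivity)
    labelled, n_comp = ndimage.label(binary, structure=structure)
    clusters: list[Cluster] = []
    for lab in range(1, n_comp + 1):
        coords = np.argwhere(labelled == lab)
        if len(coords) < extent:
            continue
        lin = np.ravel_multi_index(coords.T, binary.shape)
        vals = np.abs(stat[tuple(coords.T)])
        order = np.lexsort((lin, -vals))  # max |stat|, then lowest index
        peak = tuple(int(v) for v in coords[order[0]])
        clusters.append(Cluster(voxels=coords, size=len(coords),
                                peak_ijk=peak,
                                peak_stat=float(stat[peak])))
    clusters.sort(key=lambda c: (-c.size,
                                 int(np.ravel_multi_index(c.voxels.T, binary.shape).min())))
    return ClusterSet(clusters=clusters, connectivity=connectivity,
                      grid_shape=tuple(binary.shape))


def threshold_stat_map(diff_map: GroupDiffMap, p_crit: float = 0.001,
                       extent: int = 50, connectivity: int = 26) -> ClusterSet:
    """Supra-threshold clusters: p < p_crit in the tagged direction,
    connected components, extent filter."""
    if not 0.0 < p_crit < 1.0:
        raise ValueError("p_crit must be in (0, 1)")
    supra = (diff_map.p_values < p_crit) & (diff_map.t_values > 0) & diff_map.mask.include
    return extract_clusters(supra, diff_map.t_values, extent, connectivity)


def label_clusters_with_atlas(clusters: ClusterSet, atlas: AtlasParcellation,
                              affine: np.ndarray) -> pd.DataFrame:
    """Cluster table: one row per (cluster, overlapping region).

    Columns: cluster_id, region, overlap_voxels, cluster_size,
    peak_x/y/z_mm (world coordinates of the peak voxel), peak_stat.
    """
    if atlas.labels.shape != clusters.grid_shape:
        raise InvalidDesignError(
            f"atlas grid {atlas.labels.shape} != cluster grid {clusters.grid_shape}")
    affine = np.asarray(affine, dtype=np.float64)
    rows = []
    for cid, cl in enumerate(clusters.clusters, start=1):
        labs = atlas.labels[tuple(cl.voxels.T)]
        peak_mm = affine @ np.array([*cl.peak_ijk, 1.0])
        values, counts = np.unique(labs[labs > 0], return_counts=True)
        order = np.argsort(-counts)
        for lab, cnt in zip(values[order], counts[order]):
            rows.append({
                "cluster_id": cid,
                "region": atlas.region_names[int(lab)],
                "overlap_voxels": int(cnt),
                "cluster_size": cl.size,
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_stat": cl.peak_stat,
            })
    return pd.DataFrame(rows, columns=["cluster_id", "region", "overlap_voxels",
                                       "cluster_size", "peak_x_mm", "peak_y_mm",
                                       "peak_z_mm", "peak_stat"])
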