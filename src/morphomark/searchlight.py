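"""Searchlight decoding: local PCA + linear SVM accuracy mapping.

A spherical window is slid over every in-mask voxel.  At each center a
subjects x sphere-voxels matrix is classified (TDC vs ASD) under
repeated stratified 5-fold cross-validation of a PCA -> linear-SVM
pipeline; the mean held-out accuracy becomes that voxel's value in a 3D
accuracy map.  Voxels whose local neighbourhood decodes group membership
well mark candidate structural alteration; thresholding the map (70%
accuracy, 50-voxel extent by default) yields candidate clusters, which
an atlas partitions into candidate regions.

PCA retains the minimal number of components whose cumulative variance
fraction reaches the threshold (80% by default).  The SVM minimizes the
L2-regularized squared-hinge objective

    0.5 w'w + C * sum_i max(1 - y_i w'f_i, 0)^2

with no intercept; a point is predicted positive iff w'x > 0 (exact
ties go to the negative class).  Test data are always centered with the
training mean and projected onto training components — no leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed
from .exceptions import DegenerateTrainingError, InvalidDesignError
from .glm import ClusterSet, extract_clusters
from .simulate import AtlasParcellation
from .volio import BrainMask, Cohort


# ---------------------------------------------------------------------------
# Sphere geometry

def sphere_offsets(radius_vox: float) -> np.ndarray:
    """All integer offsets with squared norm <= radius^2, lexicographic.

    Includes (0,0,0); symmetric under negation by construction.
    """
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_vox + 1e-9))
    rng = np.arange(-r, r + 1)
    grid = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    keep = (grid ** 2).sum(axis=1) <= radius_vox ** 2 + 1e-9
    offsets = grid[keep]
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0]))
    return offsets[order]


@dataclass
class SphereSpec:
    """Spherical searchlight window in voxel units."""

    radius_vox: float = 3.0
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = sphere_offsets(self.radius_vox)


@dataclass
class SphereMatrix:
    X: np.ndarray               # (m subjects, n in-mask sphere voxels)
    center: tuple[int, int, int]
    y: np.ndarray               # labels in {-1, +1}, cohort order
    columns: np.ndarray         # linear voxel index of each column


def extract_sphere_matrix(cohort: Cohort, center, spec: SphereSpec,
                          mask: BrainMask) -> SphereMatrix:
    """Data matrix of one searchlight sphere (mask-clipped columns)."""
    center = tuple(int(c) for c in center)
    if not mask.include[center]:
        raise InvalidDesignError(f"center {center} is outside the mask")
    shape = np.array(cohort.grid_shape)
    coords = np.asarray(center) + spec.offsets
    in_grid = ((coords >= 0) & (coords < shape)).all(axis=1)
    coords = coords[in_grid]
    in_mask = mask.include[tuple(coords.T)]
    coords = coords[in_mask]
    lin = np.ravel_multi_index(coords.T, cohort.grid_shape)
    X = cohort.volumes.reshape(cohort.n_subjects, -1)[:, lin]
    return SphereMatrix(X=X, center=center, y=cohort.labels(), columns=lin)


# ---------------------------------------------------------------------------
# PCA with minimal-k variance retention

@dataclass
class PcaModel:
    components: np.ndarray       # (n, k) orthonormal columns
    eigenvalues: np.ndarray      # descending, full spectrum
    variance_fractions: np.ndarray
    k: int
    train_mean: np.ndarray
    degenerate: bool = False


def pca_fit_transform(X_train: np.ndarray, X_test: np.ndarray,
                      variance_frac: float = 0.8):
    """Fit PCA on training data; project train and test.

    k is the smallest count of leading components whose cumulative
    variance fraction reaches ``variance_frac``.  The test set is
    centered with the *training* mean.  A zero-variance training matrix
    degenerates to k = 1 on an arbitrary component with a warning flag.
    """
    if not 0.0 < variance_frac <= 1.0:
        raise ValueError("variance_frac must be in (0, 1]")
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    m, n = X_train.shape
    if m < 2:
        raise DegenerateTrainingError("PCA needs at least two training rows")
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (m - 1)
    total = eigenvalues.sum()
    if total <= 1e-300:
        components = np.zeros((n, 1))
        components[0, 0] = 1.0
        model = PcaModel(components=components, eigenvalues=eigenvalues,
                         variance_fractions=np.zeros_like(eigenvalues),
                         k=1, train_mean=mean, degenerate=True)
        return Xc @ components, (X_test - mean) @ components, model
    fractions = eigenvalues / total
    cumulative = np.cumsum(fractions)
    # absolute slack absorbs SVD round-off on exact-tie spectra
    k = int(np.argmax(cumulative >= variance_frac - 1e-9)) + 1
    components = Vt[:k].T
    model = PcaModel(components=components, eigenvalues=eigenvalues,
                     variance_fractions=fractions, k=k, train_mean=mean)
    return Xc @ components, (X_test - mean) @ components, model


# ---------------------------------------------------------------------------
# Linear SVM (L2-regularized squared hinge, no intercept)

@dataclass
class LinearSvmModel:
    w: np.ndarray
    C: float


def squared_hinge_objective(w: np.ndarray, F: np.ndarray, y: np.ndarray,
                            C: float) -> float:
    """0.5 w'w + C sum_i max(1 - y_i w'f_i, 0)^2."""
    margins = np.maximum(1.0 - y * (F @ w), 0.0)
    return 0.5 * float(w @ w) + C * float((margins ** 2).sum())


def svm_fit(F: np.ndarray, y: np.ndarray, C: float = 1.0,
            tol: float = 1e-10, max_iter: int = 200) -> LinearSvmModel:
    """Newton minimization of the squared-hinge objective.

    The objective is piecewise quadratic, convex and differentiable;
    Newton steps on the active set with backtracking converge in a
    handful of iterations for the small feature counts PCA leaves.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    F = np.asarray(F, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    m, k = F.shape
    w = np.zeros(k)
    obj = squared_hinge_objective(w, F, y, C)
    scale = max(1.0, C * m)
    for _ in range(max_iter):
        margins = 1.0 - y * (F @ w)
        active = margins > 0
        grad = w - 2.0 * C * (F[active].T @ (y[active] * margins[active]))
        if np.linalg.norm(grad) <= tol * scale:
            break
        Fa = F[active]
        H = np.eye(k) + 2.0 * C * (Fa.T @ Fa)
        step = np.linalg.solve(H, grad)
        # backtracking line search (the full Newton step is almost always taken)
        t = 1.0
        new_w, new_obj = w, obj
        for _ls in range(40):
            cand = w - t * step
            cand_obj = squared_hinge_objective(cand, F, y, C)
            if cand_obj < obj:
                new_w, new_obj = cand, cand_obj
                break
            t *= 0.5
        if new_obj >= obj:  # no descent possible: at the optimum
            break
        w, obj = new_w, new_obj
    return LinearSvmModel(w=w, C=C)


def svm_predict(model: LinearSvmModel, F: np.ndarray) -> np.ndarray:
    """+1 iff w'x > 0, else -1 (exact ties -> -1)."""
    return np.where(np.asarray(F) @ model.w > 0, 1, -1).astype(np.int64)


def svm_decision(model: LinearSvmModel, F: np.ndarray) -> np.ndarray:
    return np.asarray(F) @ model.w


# ---------------------------------------------------------------------------
# Accuracy map

@dataclass
class AccuracyMap:
    accuracy: np.ndarray         # 3D, 0 outside mask
    mask: BrainMask
    n_repeats: int
    n_folds: int
    seed: int
    fold_accuracies: np.ndarray | None = None  # (n_mask_voxels, repeats*folds)
    fold_assignments: list | None = None       # per repeat: list of (train, test)


def _stratified_folds(y: np.ndarray, n_folds: int, n_repeats: int, seed: int):
    """Fold index pairs shared across voxels: repeats x folds."""
    per_repeat = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=derive_seed(seed, "fold", rep))
        per_repeat.append([(tr.copy(), te.copy())
                           for tr, te in skf.split(np.zeros(len(y)), y)])
    return per_repeat


def searchlight_accuracy_map(cohort: Cohort, mask: BrainMask,
                             spec: SphereSpec | None = None,
                             n_folds: int = 5, n_repeats: int = 5,
                             variance_frac: float = 0.8, C: float = 1.0,
                             seed: int = 0,
                             keep_fold_details: bool = True) -> AccuracyMap:
    """Repeated stratified k-fold searchlight decoding over the mask.

    Fold assignments are drawn once per repeat and shared by every
    voxel, making the map a paired comparison across space.  PCA and the
    SVM see training folds only.  Deterministic given ``seed``.
    """
    if spec is None:
        spec = SphereSpec()
    y = cohort.labels()
    for cls in (-1, 1):
        if (y == cls).sum() < n_folds:
            raise DegenerateTrainingError(
                f"class {cls} has fewer than n_folds={n_folds} subjects")

    folds = _stratified_folds(y, n_folds, n_repeats, seed)
    flat_folds = [ft for rep in folds for ft in rep]
    n_eval = len(flat_folds)

    centers = np.argwhere(mask.include)
    lin_centers = np.ravel_multi_index(centers.T, cohort.grid_shape)
    flat = cohort.volumes.reshape(cohort.n_subjects, -1)

    # Precompute each center's in-mask sphere columns.
    shape = np.array(cohort.grid_shape)
    neighbor_cols: list[np.ndarray] = []
    for c in centers:
        coords = c + spec.offsets
        ok = ((coords >= 0) & (coords < shape)).all(axis=1)
        coords = coords[ok]
        coords = coords[mask.include[tuple(coords.T)]]
        neighbor_cols.append(np.ravel_multi_index(coords.T, cohort.grid_shape))

    acc_per_fold = np.zeros((len(centers), n_eval))
    for vi, cols in enumerate(neighbor_cols):
        X = flat[:, cols]
        for fi, (tr, te) in enumerate(flat_folds):
            F_tr, F_te, _ = pca_fit_transform(X[tr], X[te], variance_frac)
            model = svm_fit(F_tr, y[tr], C=C)
            pred = svm_predict(model, F_te)
            acc_per_fold[vi, fi] = float((pred == y[te]).mean())

    mean_acc = acc_per_fold.mean(axis=1)
    grid = np.zeros(cohort.grid_shape)
    grid.ravel()[lin_centers] = mean_acc
    return AccuracyMap(accuracy=grid, mask=mask, n_repeats=n_repeats,
                       n_folds=n_folds, seed=seed,
                       fold_accuracies=acc_per_fold if keep_fold_details else None,
                       fold_assignments=folds if keep_fold_details else None)


def threshold_accuracy_map(amap: AccuracyMap, acc_threshold: float = 0.70,
                           min_cluster: int = 50,
                           connectivity: int = 26) -> ClusterSet:
    """Clusters of voxels decoding at or above ``acc_threshold``."""
    if not 0.0 < acc_threshold < 1.0:
        raise ValueError("acc_threshold must be in (0, 1)")
    supra = (amap.accuracy >= acc_threshold) & amap.mask.include
    return extract_clusters(supra, amap.accuracy, min_cluster, connectivity)


# ---------------------------------------------------------------------------
# Cluster -> region features

@dataclass
class RegionFeatureSet:
    """Atlas-partitioned candidate-cluster voxels: region -> linear indices."""

    regions: dict[str, np.ndarray]
    grid_shape: tuple[int, int, int]

    def to_json(self, path: str | Path) -> None:
        payload = {"grid_shape": list(self.grid_shape),
                   "regions": {k: np.asarray(v).tolist()
                               for k, v in self.regions.items()}}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionFeatureSet":
        payload = json.loads(Path(path).read_text())
        return cls(regions={k: np.asarray(v, dtype=np.int64)
                            for k, v in payload["regions"].items()},
                   grid_shape=tuple(payload["grid_shape"]))


def clusters_to_region_features(clusters: ClusterSet, atlas: AtlasParcellation,
                                min_overlap: int = 1) -> RegionFeatureSet:
    """Partition candidate clusters by atlas region.

    For each region: the union over clusters of (cluster ∩ region)
    voxels; regions contributing fewer than ``min_overlap`` voxels are
    dropped.
    """
    if atlas.labels.shape != clusters.grid_shape:
        raise InvalidDesignError("atlas grid does not match cluster grid")
    cluster_mask = clusters.binary()
    regions: dict[str, np.ndarray] = {}
    for lab in atlas.label_values:
        overlap = cluster_mask & (atlas.labels == lab)
        idx = np.flatnonzero(overlap.ravel())
        if len(idx) >= min_overlap:
            regions[atlas.region_names[lab]] = idx
    return RegionFeatureSet(regions=regions, grid_shape=clusters.grid_shape)
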