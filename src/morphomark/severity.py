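"""Brain-behavior correlation of regional volume with severity scores.

Regional volume follows the modulated-map convention: intensities
integrate to tissue volume, so the regional volume of a subject is the
sum of in-region intensities times the voxel volume in mm^3.  The
association with a clinical severity score (e.g. ADOS-G communication)
is a Pearson correlation with a two-sided p from the t transform on
n - 2 degrees of freedom; subjects lacking a score are dropped
pairwise.  Severity instruments are administered to patients, so in
practice the correlation runs within the ASD group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidDesignError, ZeroVarianceError
from .volio import Cohort, GROUP_ASD


@dataclass
class CorrelationResult:
    region: str
    score_name: str
    r: float
    p: float
    n: int
    sig_05: bool
    sig_01: bool


def regional_volume(cohort: Cohort, region_voxels: np.ndarray,
                    statistic: str = "sum") -> np.ndarray:
    """Per-subject regional volume in mm^3 (``statistic="mean"`` gives the
    mean intensity instead, without the voxel-volume scaling)."""
    region_voxels = np.asarray(region_voxels)
    if region_voxels.size == 0:
        raise InvalidDesignError("empty region")
    values = cohort.volumes.reshape(cohort.n_subjects, -1)[:, region_voxels]
    if statistic == "sum":
        return values.sum(axis=1) * cohort.voxel_volume_mm3
    if statistic == "mean":
        return values.mean(axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")


def correlate_severity(values: np.ndarray, scores: np.ndarray,
                       region: str = "", score_name: str = "") -> CorrelationResult:
    """Pearson r between regional volume and a severity score.

    NaN score entries are dropped pairwise; needs n >= 3 complete pairs
    and nonzero variance on both sides.
    """
    values = np.asarray(values, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if values.shape != scores.shape:
        raise InvalidDesignError("values and scores must be paired")
    keep = np.isfinite(values) & np.isfinite(scores)
    values, scores = values[keep], scores[keep]
    n = len(values)
    if n < 3:
        raise InvalidDesignError(f"need at least 3 complete pairs, got {n}")
    if values.std(ddof=0) == 0 or scores.std(ddof=0) == 0:
        raise ZeroVarianceError("correlation undefined on a constant vector")
    res = stats.pearsonr(values, scores)  # two-sided t-transform p, df = n-2
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(region=region, score_name=score_name, r=r, p=p,
                             n=n, sig_05=p < 0.05, sig_01=p < 0.01)


def correlate_region_scores(cohort: Cohort, region_voxels: np.ndarray,
                            score_name: str, region: str = "",
                            asd_only: bool = True) -> CorrelationResult:
    """Convenience wrapper: regional volume vs a phenotype score column."""
    if score_name not in cohort.phenotype.columns:
        raise InvalidDesignError(f"no score column {score_name!r} in phenotype")
    vols = regional_volume(cohort, region_voxels)
    scores = cohort.phenotype[score_name].to_numpy(dtype=np.float64)
    if asd_only:
        asd = (cohort.phenotype["group"] == GROUP_ASD).to_numpy()
        vols, scores = vols[asd], scores[asd]
    return correlate_severity(vols, scores, region=region, score_name=score_name)
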