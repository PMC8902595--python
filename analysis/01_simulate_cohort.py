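"""Simulate the study cohort: two imaging sites, a ~80-voxel region with
reduced gray-matter volume in the ASD group (d = 1.5), and severity
scores anticorrelated (target r = -0.4) with that region's volume.

Writes NIfTI volumes, the toy atlas and the phenotype TSV under
results/analysis/data/.
"""

from pathlib import Path

import morphomark as mm
from morphomark._utils import derive_seed

SEED = 1
OUT = Path("results/analysis")
EFFECT_LABEL = 12  # an 81-voxel region of the 12-region toy parcellation


def main() -> None:
    atlas = mm.make_atlas((16, 16, 16), 12, seed=0)
    design = mm.CohortDesign(
        n_per_group_per_site={"GU": (30, 30), "OHSU": (15, 15)},
        effect_regions=(EFFECT_LABEL,), effect_size_d=1.5,
        site_shift_sd=0.01, seed=derive_seed(SEED, "cohort"))
    cohort = mm.simulate_cohort(design, atlas)
    cohort = mm.simulate_scores(cohort, EFFECT_LABEL, atlas, -0.4,
                                "ados_comm", seed=derive_seed(SEED, "scores"))

    data_dir = OUT / "data"
    mm.volio.write_cohort(cohort, data_dir, round_scores=True)
    mm.simulate.write_atlas(atlas, data_dir / "atlas.nii.gz",
                            data_dir / "atlas_labels.tsv")

    n_asd = (cohort.phenotype["group"] == "ASD").sum()
    print(f"simulated {cohort.n_subjects} subjects ({n_asd} ASD) on a "
          f"{design.grid_shape} grid; effect region "
          f"{atlas.region_names[EFFECT_LABEL]} "
          f"({len(atlas.region_voxels(EFFECT_LABEL))} voxels), d = 1.5")
    print(f"wrote volumes, atlas and phenotype to {data_dir}/")


if __name__ == "__main__":
    main()
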