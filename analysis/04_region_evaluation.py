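"""Virtual-lesion evaluation of the candidate regions (feature-level
assessment).

Each candidate region is classified on its own with the three model
families (PCA+Ridge, PCA+SVM, Bagging): nested 5-fold CV with
randomized hyperparameter search on the training site, a 200-draw
label-permutation test, transfer to the held-out site, and the final
stability ruling (|SEN - SPE| <= 20 points and p < 0.05 on every
evaluation setting).
"""

from pathlib import Path

import pandas as pd

import morphomark as mm
from morphomark._utils import derive_seed
from morphomark.searchlight import RegionFeatureSet
from morphomark.volio import read_cohort

SEED = 1
OUT = Path("results/analysis")
FAMILIES = ("pca_ridge", "pca_svm", "bagging")


def main() -> None:
    data = OUT / "data"
    cohort = read_cohort(data, data / "phenotype.tsv")
    regions = RegionFeatureSet.from_json(OUT / "regions.json")
    gu = cohort.subset((cohort.phenotype["site"] == "GU").to_numpy())
    ohsu = cohort.subset((cohort.phenotype["site"] == "OHSU").to_numpy())
    space = mm.SearchSpace()

    rows, evals, perms = [], [], []
    for region in sorted(regions.regions):
        X, y = mm.extract_region_features(gu, regions, region)
        for family in FAMILIES:
            nested = mm.nested_cv_evaluate(
                X, y, family, space, outer_folds=5, n_repeats=5, budget=10,
                seed=derive_seed(SEED, "nested", region, family), region=region)
            perm = mm.permutation_test(
                X, y, family, nested.chosen_configs[0], n_perm=200,
                seed=derive_seed(SEED, "perm", region, family), region=region)
            transfer = mm.multisite_evaluate(
                gu, [ohsu], regions, region, family, space, budget=10,
                seed=derive_seed(SEED, "ms", region, family))
            evals += [nested, transfer]
            perms.append(perm)
            rows.append({"region": region, "family": family,
                         "acc": round(nested.acc, 1), "sen": round(nested.sen, 1),
                         "spe": round(nested.spe, 1), "auc": round(nested.auc, 3),
                         "transfer_acc": round(transfer.acc, 1),
                         "p_perm": perm.p})

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "evaluation.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    decisions = mm.select_biomarkers(evals, perms, gap_threshold=20.0, alpha=0.05)
    selected = [d.region for d in decisions if d.included]
    pd.DataFrame([vars(d) for d in decisions]).to_csv(
        OUT / "biomarker_decisions.tsv", sep="\t", index=False)
    print(f"\nselected biomarkers (balanced and significant): {selected}")


if __name__ == "__main__":
    main()
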