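"""Severity correlation of the selected biomarker regions (biology-level
assessment): Pearson r between each region's summed gray-matter volume
(mm^3) and the severity score, within the ASD group.
"""

from pathlib import Path

import pandas as pd

import morphomark as mm
from morphomark.searchlight import RegionFeatureSet
from morphomark.volio import read_cohort

OUT = Path("results/analysis")


def main() -> None:
    data = OUT / "data"
    cohort = read_cohort(data, data / "phenotype.tsv")
    regions = RegionFeatureSet.from_json(OUT / "regions.json")
    decisions = pd.read_csv(OUT / "biomarker_decisions.tsv", sep="\t")
    selected = decisions.loc[decisions["included"], "region"].tolist() \
        or sorted(regions.regions)

    rows = []
    for region in selected:
        res = mm.correlate_region_scores(cohort, regions.regions[region],
                                         "ados_comm", region=region)
        rows.append(vars(res))
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    for row in rows:
        verdict = ("significant negative" if row["r"] < 0 and row["sig_05"]
                   else "not significant")
        print(f"{row['region']}: r = {row['r']:.3f}, p = {row['p']:.4f} "
              f"(n = {row['n']}) -> {verdict}")


if __name__ == "__main__":
    main()
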