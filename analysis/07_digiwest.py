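#!/usr/bin/env python
"""DigiWest protein-array statistics on the 2 (serum/2i) x 3 (J1/TKO/3B3l)
factorial design: band quantification from 96-fraction profiles, beta-actin
normalization with log2 transform, permutation two-factor ANOVA (1000
permutations, alpha 0.005), and Euclidean average-linkage clustering of the
significant analytes.
"""

import argparse
from pathlib import Path

import pandas as pd

from epiwindow import (
    SimConfig,
    cluster_significant,
    normalize_to_actin,
    permutation_anova2,
    quantify_analyte,
    simulate_fraction_matrix,
)
from epiwindow.simulate import default_bands

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed, n_analytes=20,
                    digiwest_effects_sd={"analyte000": (10.0, 0.0),
                                         "analyte001": (0.0, 4.0)})
    fm, truth = simulate_fraction_matrix(cfg)
    values = quantify_analyte(fm, default_bands(truth))
    norm = normalize_to_actin(values.drop(index="beta_actin"), values.loc["beta_actin"])
    res = permutation_anova2(norm, fm.design["treatment"], fm.design["celltype"],
                             n_perm=1000, seed=seed + 1)
    order, tree = cluster_significant(norm, res, alpha=0.005)

    RESULTS.mkdir(parents=True, exist_ok=True)
    res.round(6).to_csv(RESULTS / "07_digiwest_anova.tsv", sep="\t", index_label="analyte")
    pd.Series(order, name="analyte").to_csv(RESULTS / "07_digiwest_significant.tsv",
                                            sep="\t", index=False)
    print(res.round(4).head(5).to_string())
    print(f"significant analytes (min p <= 0.005): {order}")
    print("the planted treatment (analyte000) and celltype (analyte001) effects "
          "reach the permutation floor; any other hits are null analytes at "
          "the tail of the uniform")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
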