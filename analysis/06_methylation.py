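#!/usr/bin/env python
"""Locus-level and global methylation quantification: percent methylation of
bisulfite clone matrices for a high- (serum-like) and low- (2i-like)
methylation condition with a two-tailed Mann-Whitney U comparison of
per-clone levels, plus global percent 5mC from HPLC peak areas via the
extinction-coefficient formula.
"""

import argparse
from pathlib import Path

import pandas as pd

from epiwindow import HplcAreas, SimConfig, compare_conditions, hplc_percent_5mc, simulate_clone_matrix

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed + 40, n_clones=24, n_cpgs=20,
                    clone_p_meth={"serum": 0.8, "2i": 0.2})
    res = compare_conditions(simulate_clone_matrix(cfg, "serum"),
                             simulate_clone_matrix(cfg, "2i"))

    hplc_rows = [
        ("serum-like", 88600.0, 3600.0),
        ("2i-like", 88600.0, 1800.0),  # half the 5mdCMP peak area
    ]
    hplc = pd.DataFrame(
        [(n, a, b, round(hplc_percent_5mc(HplcAreas(a, b)), 4)) for n, a, b in hplc_rows],
        columns=["sample", "a_dcmp", "a_5mdcmp", "percent_5mc"],
    )

    RESULTS.mkdir(parents=True, exist_ok=True)
    report = pd.DataFrame({
        "quantity": ["percent_serum", "percent_2i", "mwu_U", "mwu_p"],
        "value": [round(res["percent_a"], 2), round(res["percent_b"], 2),
                  res["U"], float(f"{res['p']:.3g}")],
    })
    report.to_csv(RESULTS / "06_bisulfite.tsv", sep="\t", index=False)
    hplc.to_csv(RESULTS / "06_hplc.tsv", sep="\t", index=False)
    print(report.to_string(index=False))
    print(hplc.to_string(index=False))
    print("per-clone methylation levels differ strongly between conditions; "
          "halving the 5mdCMP peak area halves the molar percent 5mC")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
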