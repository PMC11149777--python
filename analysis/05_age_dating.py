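#!/usr/bin/env python
"""Synteny-based age dating on a planted fixture, plus the homology-
detection-failure null expectation.

Runs RBH → block chaining → oldest-presence branch assignment on a 100-gene
fixture with known ages and reports the recovery rate; then evaluates how many
apparent young genes the HDF null model predicts for a slow-mutating genome
over a short timescale. Writes results/age_assignments.tsv.
"""

from pathlib import Path

import pandas as pd

from denovostruct.age_dating import age_genes, hdf_null_expectation
from denovostruct.synthetic_data import gen_synteny_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run() -> None:
    fix = gen_synteny_fixture(n_genes=100, seed=1)
    ages = age_genes(fix.focal_order, fix.outgroups, fix.genes)
    rows = [
        (g, fix.planted[g], ages[g].branch, ",".join(ages[g].support))
        for g in fix.genes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "planted_branch", "assigned", "support"])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "age_assignments.tsv", sep="\t", index=False)
    rate = (df.planted_branch == df.assigned).mean()
    print(f"branch recovery: {100 * rate:.1f}% of {len(df)} planted genes")

    # source clade: 85 putative HDF genes over 20 My at 1.7e-7 subst/site/gen;
    # focal clade: 6.5e-9 subst/site/gen over 2.4 My
    expected = hdf_null_expectation(85, 1.7e-7, 6.5e-9, 20, 2.4)
    print(
        "homology-detection-failure null: expected "
        f"{expected:.3f} spurious young genes in the focal clade "
        "(linear rate x time scaling)"
    )


if __name__ == "__main__":
    run()
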