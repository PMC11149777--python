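#!/usr/bin/env python
"""Secondary-structure element proportions versus gene age.

One SS cohort under the planted coil/helix/strand laws; per-protein P_i from
the STRIDE strings; branch medians; linear fits per element. Writes
results/ss_trends.tsv.
"""

from pathlib import Path

import pandas as pd

from denovostruct.descriptors import ss_proportions
from denovostruct.io_formats import BranchTable
from denovostruct.synthetic_data import gen_ss_cohort, get_preset
from denovostruct.trends import branch_medians, fit_linear_trend

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run() -> None:
    spec = get_preset("denovo-ss", seed=1)
    records, _ = gen_ss_cohort(spec)
    table = BranchTable(
        branches=sorted(spec.branch_times.items(), key=lambda kv: int(kv[0][2:]))
    )
    by_class = {c: {} for c in ("coil", "helix", "g310", "strand")}
    for rec in records:
        props = ss_proportions(rec.ss_string).as_dict()
        for c in by_class:
            by_class[c].setdefault(rec.branch, []).append(props[c])
    rows = []
    for c, values in by_class.items():
        fit = fit_linear_trend(branch_medians(values, table))
        rows.append((c, fit.slope, fit.intercept, fit.p_value, fit.adj_r2))
        direction = "decreases" if fit.slope < 0 else "increases"
        print(
            f"P_{c}: {direction} at {abs(fit.slope) * 100:.1f}% per protein "
            f"per My (p = {fit.p_value:.3g}, adj R^2 = {fit.adj_r2:.3f})"
        )
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        rows, columns=["element", "slope", "intercept", "p_value", "adj_r2"]
    ).to_csv(RESULTS / "ss_trends.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'ss_trends.tsv'}")


if __name__ == "__main__":
    run()
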