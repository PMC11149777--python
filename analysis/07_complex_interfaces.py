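#!/usr/bin/env python
"""Interface contacts and binding thermodynamics on toy complexes.

Round-trips a planted two-chain complex through PDB, enumerates residue
contacts at the 5.5 Å heavy-atom cutoff, reports raw and length-normalized RR
statistics, the ΔG↔Kd conversion around the −10 kcal/mol high-affinity
cutoff, and a docking-partner screen with planted passers. Writes
results/complex_stats.tsv.
"""

import tempfile
from pathlib import Path

import pandas as pd

from denovostruct.complex_interface import (
    delta_g_from_kd,
    interface_contacts,
    kd_from_delta_g,
    partner_filter,
    rr_statistics,
)
from denovostruct.io_formats import read_pdb_complex, write_pdb_complex
from denovostruct.synthetic_data import gen_toy_complex

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run() -> None:
    rows = []
    for k in (3, 7, 12):
        model, planted = gen_toy_complex(20, 15, k, seed=k)
        with tempfile.NamedTemporaryFile(suffix=".pdb") as tf:
            write_pdb_complex(model, tf.name)
            model = read_pdb_complex(tf.name)
        contacts = interface_contacts(model)
        raw, ratio = rr_statistics(contacts)
        exact = sorted(contacts.pair_set()) == planted
        rows.append((k, raw, ratio, exact))
        print(
            f"planted k={k}: {raw} contacts recovered "
            f"(nonredundant ratio {ratio:.3f}, exact match: {exact})"
        )

    dg = delta_g_from_kd(1e-8)
    print(f"Kd 1e-8 M  -> ΔG = {dg:.2f} kcal/mol (rounds to the -10 cutoff)")
    print(f"ΔG -13.3   -> Kd = {kd_from_delta_g(-13.3):.2e} M (high affinity)")

    candidates = pd.DataFrame(
        {
            "id": [f"g{i}" for i in range(6)],
            "isd_ratio": [0.01, 0.02, 0.30, 0.01, 0.04, 0.02],
            "coexpr_r": [0.95, 0.85, 0.92, 0.60, 0.90, 0.99],
            "length": [250, 480, 300, 300, 150, 210],
            "branch": ["br7", "br9", "br6", "br8", "br6", "br2"],
        }
    )
    passed, fails = partner_filter(candidates)
    print(f"partner screen: {len(passed)}/{len(candidates)} pass; failures {fails}")

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        rows, columns=["planted_k", "raw_count", "nonredundant_ratio", "exact_match"]
    ).to_csv(RESULTS / "complex_stats.tsv", sep="\t", index=False)


if __name__ == "__main__":
    run()
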