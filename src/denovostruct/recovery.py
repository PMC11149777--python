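"""Rate-recovery harness: simulate cohorts under a planted median-trend law,
run them through the real descriptor + trend pipeline, and summarize the
recovered slopes over many seeds.

This is how slope claims are checked when the underlying observational data
are not shipped: the generator plants the fitted law, and the pipeline must
get it back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List

import numpy as np

from .descriptors import ss_proportions, track_fraction
from .io_formats import BranchTable
from .synthetic_data import (
    COHORT_PRESETS,
    SS_PRESETS,
    CohortSpec,
    SSCohortSpec,
    gen_disorder_cohort,
    gen_ss_cohort,
    gen_value_cohort,
)
from .trends import TrendFit, branch_medians, fit_linear_trend


@dataclass
class RecoveryResult:
    preset: str
    metric: str
    true_slope: float
    slopes: List[float]

    @property
    def mean_slope(self) -> float:
        return float(np.mean(self.slopes))

    @property
    def mean_abs_slope(self) -> float:
        return float(np.abs(np.mean(self.slopes)))

    @property
    def n_seeds(self) -> int:
        return len(self.slopes)

    def relative_error(self) -> float:
        return abs(self.mean_slope - self.true_slope) / abs(self.true_slope)


def _branch_table_for(branch_times: Dict[str, float]) -> BranchTable:
    return BranchTable(branches=sorted(branch_times.items(), key=lambda kv: int(kv[0][2:])))


def _seed_for(base_seed: int, i: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), i]).generate_state(1)[0] % (2**31))


def _fit_cohort(values_by_branch: Dict[str, List[float]], table: BranchTable) -> TrendFit:
    return fit_linear_trend(branch_medians(values_by_branch, table))


def recover_track_slope(
    preset: str, n_seeds: int = 50, base_seed: int = 0
) -> RecoveryResult:
    """Disorder/MoRF-style cohorts: track_fraction per protein, branch medians,
    OLS slope; repeated over seeds."""
    spec0: CohortSpec = COHORT_PRESETS[preset]
    table = _branch_table_for(dict(spec0.branch_times))
    track_kind = "morf" if "morf" in preset else "disorder"
    slopes = []
    for i in range(n_seeds):
        spec = replace(spec0, seed=_seed_for(base_seed, i))
        records, _ = gen_disorder_cohort(spec, track_kind=track_kind)
        by_branch: Dict[str, List[float]] = {}
        for rec in records:
            track = rec.disorder_track if track_kind == "disorder" else rec.morf_track
            by_branch.setdefault(rec.branch, []).append(track_fraction(track))
        slopes.append(_fit_cohort(by_branch, table).slope)
    return RecoveryResult(preset, f"{track_kind}_fraction", spec0.slope, slopes)


def recover_value_slope(
    preset: str, n_seeds: int = 50, base_seed: int = 0
) -> RecoveryResult:
    """Scalar descriptor cohorts (hydrophobicity-style)."""
    spec0: CohortSpec = COHORT_PRESETS[preset]
    table = _branch_table_for(dict(spec0.branch_times))
    slopes = []
    for i in range(n_seeds):
        spec = replace(spec0, seed=_seed_for(base_seed, i))
        truth = gen_value_cohort(spec)
        by_branch = {
            b: grp["planted_value"].tolist() for b, grp in truth.groupby("branch")
        }
        slopes.append(_fit_cohort(by_branch, table).slope)
    return RecoveryResult(preset, "value", spec0.slope, slopes)


def recover_ss_slopes(
    preset: str = "denovo-ss", n_seeds: int = 50, base_seed: int = 0
) -> Dict[str, RecoveryResult]:
    """SS cohorts: P_coil / P_helix / P_strand per protein from the STRIDE
    string, branch medians, OLS slopes — all three classes from one cohort."""
    spec0: SSCohortSpec = SS_PRESETS[preset]
    table = _branch_table_for(dict(spec0.branch_times))
    per_class: Dict[str, List[float]] = {"coil": [], "helix": [], "strand": []}
    for i in range(n_seeds):
        spec = replace(spec0, seed=_seed_for(base_seed, i))
        records, _ = gen_ss_cohort(spec)
        by_branch: Dict[str, Dict[str, List[float]]] = {
            c: {} for c in per_class
        }
        for rec in records:
            props = ss_proportions(rec.ss_string).as_dict()
            for c in per_class:
                by_branch[c].setdefault(rec.branch, []).append(props[c])
        for c in per_class:
            per_class[c].append(_fit_cohort(by_branch[c], table).slope)
    return {
        c: RecoveryResult(preset, f"p_{c}", spec0.laws[c][1], per_class[c])
        for c in per_class
    }
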