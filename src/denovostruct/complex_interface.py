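"""Two-chain complex interface statistics and binding thermodynamics.

Residue–residue (RR) contacts are heavy-atom pairs across chains within a
distance cutoff (5.5 Å by default, the PRODIGY interface convention). Binding
affinity converts between Gibbs free energy and the dissociation constant via
ΔG = R·T·ln(Kd), and docking partners are screened by the four published
criteria (low disorder, high coexpression, 200–500 aa, old branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io_formats import ComplexModel

R_KCAL = 1.987e-3  # gas constant, kcal/(mol·K)

#: Default temperature for the ΔG↔Kd identity. 273.15 K is the one choice that
#: makes the published −10 kcal/mol ↔ 1e-8 M cutoff pairing exact (298.15 K
#: gives −10.9); both are configurable and recorded in outputs.
DEFAULT_TEMPERATURE_K = 273.15


@dataclass
class ContactSet:
    """Interface contacts: (residue index in A, residue index in B, min atom
    distance in Å), plus both chain lengths."""

    pairs: List[Tuple[int, int, float]]
    len_a: int
    len_b: int

    @property
    def raw_count(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set:
        return {(a, b) for a, b, _ in self.pairs}


@dataclass
class AffinityRecord:
    delta_g: float  # kcal/mol
    kd: float  # molar
    temperature: float  # K
    high_affinity: bool

    def __post_init__(self) -> None:
        expected = R_KCAL * self.temperature * math.log(self.kd)
        if abs(expected - self.delta_g) > 1e-6:
            raise ValueError(
                f"inconsistent record: ΔG={self.delta_g} but R·T·ln(Kd)={expected}"
            )


def interface_contacts(model: ComplexModel, cutoff: float = 5.5) -> ContactSet:
    """Enumerate RR contacts: a residue pair is in contact iff any heavy-atom
    pair across the two chains is within ``cutoff`` Å (inclusive). Each pair
    appears once, with its minimum atom distance."""
    chain_a, chain_b = model.chains
    if not chain_a or not chain_b:
        raise ValueError("both chains must have at least one residue")
    coords_a = np.vstack([r.atoms for r in chain_a])
    coords_b = np.vstack([r.atoms for r in chain_b])
    idx_a = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(chain_a)]
    )
    idx_b = np.concatenate(
        [np.full(len(r.atoms), j) for j, r in enumerate(chain_b)]
    )
    dists = cdist(coords_a, coords_b)
    pairs: Dict[Tuple[int, int], float] = {}
    hit_i, hit_j = np.nonzero(dists <= cutoff)
    for ai, bj in zip(hit_i, hit_j):
        key = (chain_a[int(idx_a[ai])].index, chain_b[int(idx_b[bj])].index)
        d = float(dists[ai, bj])
        if key not in pairs or d < pairs[key]:
            pairs[key] = d
    pair_list = sorted((a, b, d) for (a, b), d in pairs.items())
    return ContactSet(pairs=pair_list, len_a=len(chain_a), len_b=len(chain_b))


def rr_statistics(contacts: ContactSet) -> Tuple[int, float]:
    """(raw RR pair count, nonredundant ratio).

    The nonredundant ratio is distinct residue pairs over the total complex
    length (len_a + len_b); an alternative reading — distinct interface
    residues over total length — is available via
    :func:`interface_residue_ratio`.
    """
    total = contacts.len_a + contacts.len_b
    if total == 0:
        raise ValueError("empty complex")
    return contacts.raw_count, len(contacts.pair_set()) / total


def interface_residue_ratio(contacts: ContactSet) -> float:
    """Distinct interface residues (either chain) over total complex length."""
    res = {(0, a) for a, _, _ in contacts.pairs} | {(1, b) for _, b, _ in contacts.pairs}
    return len(res) / (contacts.len_a + contacts.len_b)


def delta_g_from_kd(kd: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """ΔG = R·T·ln(Kd), kcal/mol."""
    if kd <= 0:
        raise ValueError("Kd must be > 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return R_KCAL * T * math.log(kd)


def kd_from_delta_g(delta_g: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Kd = exp(ΔG / (R·T)), molar."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(delta_g / (R_KCAL * T))


def classify_affinity(delta_g: float, cutoff: float = -10.0) -> bool:
    """High affinity iff ΔG ≤ cutoff (−10 kcal/mol ↔ Kd 1e-8 M by default)."""
    if not math.isfinite(delta_g):
        raise ValueError("ΔG must be finite")
    return delta_g <= cutoff


def affinity_record(
    kd: float, T: float = DEFAULT_TEMPERATURE_K, cutoff: float = -10.0
) -> AffinityRecord:
    dg = delta_g_from_kd(kd, T)
    return AffinityRecord(
        delta_g=dg, kd=kd, temperature=T, high_affinity=classify_affinity(dg, cutoff)
    )


PARTNER_CRITERIA = {
    "isd_ratio": "isd_ratio < 0.05",
    "coexpr_r": "coexpr_r > 0.8",
    "length": "200 <= length <= 500",
    "branch": "branch in br6..br9",
}


def partner_filter(
    candidates: pd.DataFrame,
    max_isd: float = 0.05,
    min_r: float = 0.8,
    length_range: Tuple[int, int] = (200, 500),
    old_branches: Sequence[str] = ("br6", "br7", "br8", "br9"),
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Docking-partner screen.

    A candidate passes iff isd_ratio < 5%, coexpression r > 0.8, sequence
    length within 200–500 aa, and branch among the old branches (br6–br9).
    Returns the surviving rows and a per-criterion failure count.
    """
    required = ["isd_ratio", "coexpr_r", "length", "branch"]
    for col in required:
        if col not in candidates.columns:
            raise KeyError(f"candidate table missing field {col!r}")
        missing = candidates[candidates[col].isna()]
        if len(missing):
            gene = missing.iloc[0].get("id", missing.index[0])
            raise ValueError(f"gene {gene!r} missing field {col!r}")
    lo, hi = length_range
    fails = {
        "isd_ratio": int((~(candidates["isd_ratio"] < max_isd)).sum()),
        "coexpr_r": int((~(candidates["coexpr_r"] > min_r)).sum()),
        "length": int((~candidates["length"].between(lo, hi)).sum()),
        "branch": int((~candidates["branch"].isin(old_branches)).sum()),
    }
    mask = (
        (candidates["isd_ratio"] < max_isd)
        & (candidates["coexpr_r"] > min_r)
        & candidates["length"].between(lo, hi)
        & candidates["branch"].isin(old_branches)
    )
    return candidates[mask].copy(), fails


def contacts_to_frame(contacts: ContactSet) -> pd.DataFrame:
    return pd.DataFrame(contacts.pairs, columns=["res_a", "res_b", "min_dist"])
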