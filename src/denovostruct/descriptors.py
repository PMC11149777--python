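"""Per-protein structural and physicochemical descriptors.

Covers intrinsic structural disorder (ISD ratio and the full-ISD class),
secondary-structure element proportions from STRIDE strings, amino-acid
composition, molecular weight, Henderson–Hasselbalch net charge and
isoelectric point, hydrophobicity (Kyte–Doolittle mean by default), MoRF
fractions, pLDDT folding-confidence classes, and TM-score fold-similarity
classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io_formats import AA20, ProteinRecord, STRIDE_ALPHABET

# STRIDE letter -> secondary-structure class. Turns count as coil: unstructured
# medians in the 40–47% range only arise when T is unstructured. A different
# partition can be passed to ss_proportions.
DEFAULT_SS_PARTITION: Dict[str, str] = {
    "H": "helix",
    "I": "helix",
    "G": "g310",
    "E": "strand",
    "B": "bridge",
    "T": "coil",
    "C": "coil",
}

SS_CLASSES = ("coil", "helix", "g310", "strand", "bridge")

# EMBOSS pKa set. ipc2 (used for the published pI values) does not publish its
# fitted constants as a plain table, so the classic EMBOSS values are the
# default; the set in force is recorded in every descriptor row.
EMBOSS_PKA: Dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")

HYDROPHOBICITY_SCALES: Dict[str, Mapping[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
}


@dataclass
class SSProportions:
    """Length proportions P_i = l_i / l_total of secondary-structure classes."""

    p_coil: float
    p_helix: float
    p_310helix: float
    p_strand: float
    p_bridge: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "coil": self.p_coil,
            "helix": self.p_helix,
            "g310": self.p_310helix,
            "strand": self.p_strand,
            "bridge": self.p_bridge,
        }

    def __post_init__(self) -> None:
        total = sum(self.as_dict().values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"SS proportions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# Disorder / MoRF
# ---------------------------------------------------------------------------


def binarize_disorder(probabilities: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Per-residue disorder probability -> binary disorder call (>= threshold)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("disorder probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def track_fraction(binary_track: Sequence[float]) -> float:
    """Fraction of flagged residues out of the full protein length.

    Used for both the ISD ratio and MoRF fractions.
    """
    t = np.asarray(binary_track, dtype=float)
    if t.size == 0:
        raise ValueError("empty track")
    return float(np.count_nonzero(t) / t.size)


def classify_full_isd(isd_ratio: float) -> bool:
    """Fully disordered protein: 100% of residues in disordered state (exact)."""
    if not 0.0 <= isd_ratio <= 1.0:
        raise ValueError(f"ISD ratio {isd_ratio} outside [0, 1]")
    return isd_ratio == 1.0


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------


def ss_proportions(
    ss_string: str, partition: Mapping[str, str] = DEFAULT_SS_PARTITION
) -> SSProportions:
    """Class proportions P_i = cumulative letter count / total length."""
    if not ss_string:
        raise ValueError("empty secondary-structure string")
    counts: Counter = Counter()
    for letter in ss_string:
        if letter not in partition:
            raise KeyError(f"letter {letter!r} absent from SS partition")
        counts[partition[letter]] += 1
    n = len(ss_string)
    by_class = {c: counts.get(c, 0) / n for c in SS_CLASSES}
    return SSProportions(
        p_coil=by_class["coil"],
        p_helix=by_class["helix"],
        p_310helix=by_class["g310"],
        p_strand=by_class["strand"],
        p_bridge=by_class["bridge"],
    )


# ---------------------------------------------------------------------------
# Composition / physicochemistry
# ---------------------------------------------------------------------------


def aa_composition(sequence: str) -> Dict[str, float]:
    """20 amino-acid fractions summing to 1; 'X' is excluded from both the
    numerator and the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(c for c in sequence if c != "X")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence has no unmasked residues")
    bad = set(counts) - set(AA20)
    if bad:
        raise ValueError(f"invalid residues {bad} in sequence")
    return {aa: counts.get(aa, 0) / n for aa in AA20}


def molecular_weight(sequence: str) -> float:
    """Average molecular weight (Da): residue masses + one water. 'X' masked
    residues are excluded."""
    seq = sequence.replace("X", "")
    if not seq:
        raise ValueError("empty sequence")
    return float(_bio_molecular_weight(seq, seq_type="protein"))


def net_charge(
    sequence: str, pH: float, pka_set: Mapping[str, float] = EMBOSS_PKA
) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Ionizable groups: the two termini plus side chains of D, E, C, Y, H, K, R.
    Basic groups contribute +1/(1+10^(pH−pKa)); acidic groups −1/(1+10^(pKa−pH)).
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    counts = Counter(c for c in sequence if c != "X")
    charge = 1.0 / (1.0 + 10 ** (pH - pka_set["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka_set["Cterm"] - pH))
    for aa in _BASIC:
        if aa in pka_set:
            charge += counts.get(aa, 0) / (1.0 + 10 ** (pH - pka_set[aa]))
    for aa in _ACIDIC:
        if aa in pka_set:
            charge -= counts.get(aa, 0) / (1.0 + 10 ** (pka_set[aa] - pH))
    return float(charge)


def isoelectric_point(
    sequence: str, pka_set: Mapping[str, float] = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Net charge is monotonically non-increasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(sequence, lo, pka_set)
    c_hi = net_charge(sequence, hi, pka_set)
    if not (c_lo > 0 > c_hi):
        raise ValueError("net charge does not change sign on [0, 14]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c_mid = net_charge(sequence, mid, pka_set)
        if abs(c_mid) < tol:
            return mid
        if c_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobicity_score(
    sequence: str, scale: str | Mapping[str, float] = "kyte-doolittle"
) -> float:
    """Mean per-residue hydrophobicity under the chosen scale."""
    table = HYDROPHOBICITY_SCALES[scale] if isinstance(scale, str) else scale
    seq = sequence.replace("X", "")
    if not seq:
        raise ValueError("empty sequence")
    try:
        return float(np.mean([table[c] for c in seq]))
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} missing from hydrophobicity scale")


# ---------------------------------------------------------------------------
# Folding confidence / fold similarity
# ---------------------------------------------------------------------------


def folding_confidence(
    plddt_track: Sequence[float],
    hi: float = 0.9,
    mid: float = 0.7,
    min_len: int = 11,
) -> str:
    """pLDDT folding-confidence class.

    'high' if some contiguous run of >= min_len residues each has pLDDT >= hi;
    else 'medium' for such a run at >= mid; else 'low'. "Over ten amino acids"
    is read as a run of at least 11 residues, each individually over threshold.
    """
    track = np.asarray(plddt_track, dtype=float)
    if track.size == 0:
        raise ValueError("empty pLDDT track")
    if np.any(track < 0) or np.any(track > 1):
        raise ValueError("pLDDT values must lie in [0, 1]")

    def has_run(threshold: float) -> bool:
        run = 0
        for v in track:
            run = run + 1 if v >= threshold else 0
            if run >= min_len:
                return True
        return False

    if has_run(hi):
        return "high"
    if has_run(mid):
        return "medium"
    return "low"


def fold_similarity_class(tm_scores: Sequence[float]) -> str:
    """Median pairwise TM score -> 'similar' (> 0.5), 'random' (< 0.17),
    else 'intermediate'."""
    scores = np.asarray(tm_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty TM-score list")
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("TM scores must lie in [0, 1]")
    med = float(np.median(scores))
    if med > 0.5:
        return "similar"
    if med < 0.17:
        return "random"
    return "intermediate"


# ---------------------------------------------------------------------------
# Cohort descriptor table
# ---------------------------------------------------------------------------


def describe_protein(
    record: ProteinRecord,
    disorder_threshold: float = 0.5,
    partition: Mapping[str, str] = DEFAULT_SS_PARTITION,
    scale: str = "kyte-doolittle",
    pka_name: str = "emboss",
) -> Dict[str, object]:
    """One descriptor row for a protein; absent tracks yield NaN metrics.

    Provenance (scale, pKa set, thresholds) travels with every row.
    """
    row: Dict[str, object] = {
        "id": record.id,
        "gene_class": record.gene_class,
        "branch": record.branch,
        "length": len(record.sequence),
    }
    if record.disorder_track is not None:
        binary = record.disorder_track
        if np.any((binary != 0) & (binary != 1)):
            binary = binarize_disorder(record.disorder_track, disorder_threshold)
        row["isd_ratio"] = track_fraction(binary)
        row["is_full_isd"] = classify_full_isd(row["isd_ratio"])
    else:
        row["isd_ratio"] = np.nan
        row["is_full_isd"] = pd.NA
    if record.ss_string is not None:
        ss = ss_proportions(record.ss_string, partition)
        row.update({f"p_{k}": v for k, v in ss.as_dict().items()})
    else:
        row.update({f"p_{k}": np.nan for k in SS_CLASSES})
    comp = aa_composition(record.sequence)
    row.update({f"frac_{aa}": comp[aa] for aa in AA20})
    row["mol_weight"] = molecular_weight(record.sequence)
    row["pI"] = isoelectric_point(record.sequence)
    row["net_charge_pH7"] = net_charge(record.sequence, 7.0)
    row["hydrophobicity"] = hydrophobicity_score(record.sequence, scale)
    if record.morf_track is not None:
        row["morf_fraction"] = track_fraction(record.morf_track)
    else:
        row["morf_fraction"] = np.nan
    if record.plddt_track is not None:
        row["folding_class"] = folding_confidence(record.plddt_track)
    else:
        row["folding_class"] = pd.NA
    row["hydro_scale"] = scale
    row["pka_set"] = pka_name
    row["disorder_threshold"] = disorder_threshold
    return row


def describe_cohort(records: Sequence[ProteinRecord], **kwargs) -> pd.DataFrame:
    """Descriptor table: one row per protein, provenance columns included."""
    return pd.DataFrame([describe_protein(r, **kwargs) for r in records])
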