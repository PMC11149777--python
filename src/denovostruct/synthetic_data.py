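"""Synthetic cohorts with planted, known ground truth.

Every input the pipeline consumes can be generated here: disorder/MoRF binary
tracks following a linear median-versus-time law, STRIDE strings drawn
multinomially at branch-specific element proportions, sequences with planted
per-amino-acid composition trends, bounded scalar descriptor cohorts
(hydrophobicity-style), toy two-chain complexes with an exact planted contact
set, synteny fixtures with planted origination branches, and expression
matrices with planted coexpression partners.

Noise model: per-protein spread is applied on the logit scale and mapped back
through the logistic, which keeps the *median* of every branch exactly on the
planted law (symmetric zero-median noise commutes with the monotone logistic),
so median-trend fitting recovers the planted slope without small-sample bias.
Generation is a pure function of (spec, seed); truths are returned alongside
and can be written as sidecar TSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .age_dating import GeneOrder, SimilarityHit
from .io_formats import AA20, ComplexModel, ProteinRecord, Residue

# Branch-time anchors used by the shipped presets: br4 (0.94), br5 (1.0) and
# br6 (2.41) Mya are published anchors; br1–br3 are placeholders on the same
# ladder. All overridable per spec.
PRESET_BRANCH_TIMES: Dict[str, float] = {
    "br1": 0.1,
    "br2": 0.3,
    "br3": 0.5,
    "br4": 0.94,
    "br5": 1.0,
    "br6": 2.41,
}


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    """A linear median-versus-time law for one bounded per-protein metric.

    metric law: value(t) = intercept + slope · t, required to stay inside
    (0, 1) at every branch time; sigma is the per-protein logit-scale spread.
    """

    branch_times: Mapping[str, float]
    n_per_branch: int
    intercept: float
    slope: float
    sigma: float = 0.5
    seed: int = 0
    gene_class: str = "denovo"
    length_range: Tuple[int, int] = (100, 300)

    def law(self, t: float) -> float:
        return self.intercept + self.slope * t

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_per_branch < 1:
            raise ValueError("n_per_branch must be >= 1")
        for b, t in self.branch_times.items():
            if t < 0:
                raise ValueError(f"{b}: negative branch time")
            v = self.law(t)
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"law value {v:.4g} at branch {b} (t={t}) outside (0, 1)"
                )


def _planted_fractions(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-protein planted metric values under the law + logit noise."""
    rows = []
    for branch, t in spec.branch_times.items():
        law = spec.law(t)
        if spec.sigma > 0:
            noise = rng.normal(0.0, spec.sigma, size=spec.n_per_branch)
            vals = _expit(_logit(law) + noise)
        else:
            vals = np.full(spec.n_per_branch, law)
        for i, v in enumerate(vals):
            rows.append((f"{spec.gene_class}_{branch}_{i}", branch, t, float(v)))
    return pd.DataFrame(rows, columns=["id", "branch", "time_mya", "planted_value"])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list(AA20))[rng.integers(0, 20, size=length)])


def gen_disorder_cohort(
    spec: CohortSpec,
    n_full_isd: int = 0,
    track_kind: str = "disorder",
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Binary disorder (or MoRF) tracks whose per-protein fraction of ones is
    the planted value rounded to the protein length.

    ``n_full_isd`` proteins (taken from the start of the cohort) are planted as
    fully disordered (all-ones tracks); the truth table marks them, so
    bookkeeping never re-derives ground truth from the generated data.
    """
    spec.validate()
    if track_kind not in ("disorder", "morf"):
        raise ValueError("track_kind must be 'disorder' or 'morf'")
    rng = np.random.default_rng(spec.seed)
    truth = _planted_fractions(spec, rng)
    if n_full_isd > len(truth):
        raise ValueError("n_full_isd exceeds cohort size")
    truth["planted_full_isd"] = False
    truth.loc[: n_full_isd - 1, "planted_full_isd"] = True

    records: List[ProteinRecord] = []
    realized = []
    lo, hi = spec.length_range
    for row in truth.itertuples():
        length = int(rng.integers(lo, hi + 1))
        if row.planted_full_isd:
            k = length
        else:
            k = int(round(row.planted_value * length))
        track = np.zeros(length)
        track[:k] = 1.0
        rng.shuffle(track)
        seq = _random_sequence(rng, length)
        kwargs = {"disorder_track": track} if track_kind == "disorder" else {
            "morf_track": track
        }
        records.append(
            ProteinRecord(
                id=row.id,
                gene_class=spec.gene_class,
                branch=row.branch,
                sequence=seq,
                **kwargs,
            )
        )
        realized.append(k / length)
    truth["realized_fraction"] = realized
    return records, truth


def gen_value_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Scalar bounded descriptor cohort (e.g. normalized hydrophobicity):
    per-protein values around the branch law, logit-scale noise. Returns the
    truth table whose ``planted_value`` column IS the observable metric."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    return _planted_fractions(spec, rng)


@dataclass(frozen=True)
class SSCohortSpec:
    """Per-class linear laws for secondary-structure element proportions.

    Laws are given for coil, helix, 3_10 helix, and strand; the isolated-bridge
    class takes the residual so the five-class partition sums to 1 at every
    branch time.
    """

    branch_times: Mapping[str, float]
    n_per_branch: int
    length: int
    laws: Mapping[str, Tuple[float, float]]  # class -> (intercept, slope)
    seed: int = 0
    gene_class: str = "denovo"

    def class_probs(self, t: float) -> Dict[str, float]:
        probs = {c: i + s * t for c, (i, s) in self.laws.items()}
        rest = 1.0 - sum(probs.values())
        probs["bridge"] = probs.get("bridge", 0.0) + rest
        if any(p < 0 for p in probs.values()) or probs["bridge"] < 0:
            raise ValueError(f"class proportions negative at t={t}: {probs}")
        return probs


# Which STRIDE letters realize each class in generated strings. Coil is split
# between C and T to exercise the turns-are-coil partition rule.
_CLASS_LETTERS = {
    "coil": (("C", 0.7), ("T", 0.3)),
    "helix": (("H", 1.0),),
    "g310": (("G", 1.0),),
    "strand": (("E", 1.0),),
    "bridge": (("B", 1.0),),
}


def gen_ss_cohort(spec: SSCohortSpec) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """STRIDE strings multinomially drawn at each branch's target class
    proportions; ss_proportions recovers the targets within sampling error."""
    rng = np.random.default_rng(spec.seed)
    records: List[ProteinRecord] = []
    rows = []
    for branch, t in spec.branch_times.items():
        probs = spec.class_probs(t)
        letters: List[str] = []
        letter_p: List[float] = []
        for cls, parts in _CLASS_LETTERS.items():
            for letter, w in parts:
                letters.append(letter)
                letter_p.append(probs.get(cls, 0.0) * w)
        letter_arr = np.asarray(letters)
        p_arr = np.asarray(letter_p)
        p_arr = p_arr / p_arr.sum()
        for i in range(spec.n_per_branch):
            counts = rng.multinomial(spec.length, p_arr)
            s = np.repeat(letter_arr, counts)
            rng.shuffle(s)
            ss = "".join(s)
            pid = f"{spec.gene_class}_{branch}_{i}"
            records.append(
                ProteinRecord(
                    id=pid,
                    gene_class=spec.gene_class,
                    branch=branch,
                    sequence=_random_sequence(rng, spec.length),
                    ss_string=ss,
                )
            )
            rows.append((pid, branch, t, *[probs[c] for c in
                         ("coil", "helix", "g310", "strand", "bridge")]))
    truth = pd.DataFrame(
        rows,
        columns=["id", "branch", "time_mya", "target_coil", "target_helix",
                 "target_g310", "target_strand", "target_bridge"],
    )
    return records, truth


# Background amino-acid frequencies (UniProt-like averages, renormalized).
BASE_AA_FREQ: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Planted composition trends (fraction per My): disorder-promoting G and A
#: decline with age while order-promoting/hydrophobic Y, F, L and charged K
#: rise — the qualitative structure the per-aa age correlation should detect.
DEFAULT_AA_TRENDS: Dict[str, float] = {
    "G": -0.010, "A": -0.008, "Y": 0.004, "F": 0.004, "K": 0.005, "L": 0.005,
}


@dataclass(frozen=True)
class SequenceCohortSpec:
    branch_times: Mapping[str, float]
    n_per_branch: int
    length: int = 300
    aa_trends: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_TRENDS))
    seed: int = 0
    gene_class: str = "denovo"

    def composition(self, t: float) -> np.ndarray:
        comp = np.array([BASE_AA_FREQ[a] for a in AA20])
        for aa, slope in self.aa_trends.items():
            comp[AA20.index(aa)] += slope * t
        if np.any(comp < 0):
            raise ValueError(f"negative composition at t={t}")
        return comp / comp.sum()


def gen_sequence_cohort(
    spec: SequenceCohortSpec,
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Sequences drawn i.i.d. from branch-specific compositions with planted
    per-amino-acid trends."""
    rng = np.random.default_rng(spec.seed)
    aa_arr = np.asarray(list(AA20))
    records: List[ProteinRecord] = []
    rows = []
    for branch, t in spec.branch_times.items():
        comp = spec.composition(t)
        for i in range(spec.n_per_branch):
            seq = "".join(aa_arr[rng.choice(20, size=spec.length, p=comp)])
            pid = f"{spec.gene_class}_{branch}_{i}"
            records.append(
                ProteinRecord(
                    id=pid, gene_class=spec.gene_class, branch=branch, sequence=seq
                )
            )
            rows.append((pid, branch, t, *comp))
    truth = pd.DataFrame(
        rows, columns=["id", "branch", "time_mya", *[f"target_{a}" for a in AA20]]
    )
    return records, truth


def gen_toy_complex(
    len_a: int,
    len_b: int,
    k_contacts: int,
    cutoff: float = 5.5,
    seed: int = 0,
) -> Tuple[ComplexModel, List[Tuple[int, int]]]:
    """Two single-heavy-atom chains with exactly ``k_contacts`` planted residue
    pairs within the cutoff; every other cross-chain pair sits beyond
    cutoff + 1 Å. Returns (model, sorted planted pair list of residue indices).

    The geometry uses one contact per participating residue, so
    k_contacts ≤ min(len_a, len_b) is required; larger k is geometrically
    infeasible under the margin guarantee and raises.
    """
    if k_contacts < 0:
        raise ValueError("k_contacts must be >= 0")
    if k_contacts > min(len_a, len_b):
        raise ValueError(
            f"k_contacts={k_contacts} infeasible for chains {len_a}+{len_b} "
            "under the margin guarantee (needs k <= min(len_a, len_b))"
        )
    rng = np.random.default_rng(seed)
    spacing = max(2.0 * (cutoff + 1.0), 13.0)
    aa_arr = np.asarray(list(AA20))

    chain_a = [
        Residue(
            index=i + 1,
            aa=str(aa_arr[rng.integers(0, 20)]),
            atoms=np.array([[i * spacing, 0.0, 0.0]]),
            plddt=float(rng.uniform(0.2, 0.98)),
        )
        for i in range(len_a)
    ]
    picked_a = sorted(rng.choice(len_a, size=k_contacts, replace=False))
    picked_b = sorted(rng.choice(len_b, size=k_contacts, replace=False))
    contact_of_b = dict(zip(picked_b, picked_a))
    chain_b = []
    for j in range(len_b):
        if j in contact_of_b:
            i = contact_of_b[j]
            d = float(rng.uniform(0.6 * cutoff, 0.95 * cutoff))
            pos = [i * spacing, 0.0, d]
        else:
            pos = [j * spacing, 1000.0, 0.0]
        chain_b.append(
            Residue(
                index=j + 1,
                aa=str(aa_arr[rng.integers(0, 20)]),
                atoms=np.array([pos]),
                plddt=float(rng.uniform(0.2, 0.98)),
            )
        )
    model = ComplexModel(chain_ids=("A", "B"), chains=(chain_a, chain_b))
    planted = sorted((i + 1, j + 1) for j, i in contact_of_b.items())
    return model, planted


@dataclass
class SyntenyFixture:
    """Planted-genome fixture for the age-dating pipeline."""

    focal_order: GeneOrder
    outgroups: Dict[str, Tuple[List[SimilarityHit], List[SimilarityHit], GeneOrder]]
    planted: Dict[str, str]  # focal gene -> true branch
    genes: List[str]  # dated genes (the planted ones)


def gen_synteny_fixture(
    n_genes: int = 100,
    planted: Optional[Mapping[str, str]] = None,
    seed: int = 0,
    branches: Sequence[str] = ("br1", "br2", "br3", "br4", "br5", "br6", "br7", "br8", "br9"),
) -> SyntenyFixture:
    """Focal genome plus eight outgroup genomes with planted gene ages.

    A gene planted at branch b is present — inside a conserved neighborhood of
    old backbone genes — in the outgroups that diverged after its origin
    (br2..b) and absent from the deeper outgroups, so oldest-presence-wins
    dating recovers b; br1 genes are focal-specific.
    """
    rng = np.random.default_rng(seed)
    if planted is None:
        choices = list(branches)
        planted = {
            f"gene{i:04d}": choices[rng.integers(0, len(choices))]
            for i in range(n_genes)
        }
    planted = dict(planted)
    genes = sorted(planted)

    # Focal chromosome: backbone (old, always-present) genes interleaved with
    # the planted genes so that dropping any subset of planted genes leaves
    # anchor gaps well under the chaining limit.
    focal_genes: List[str] = []
    for i, g in enumerate(genes):
        focal_genes.append(f"bb{i:04d}")
        focal_genes.append(g)
    focal_genes.append(f"bb{len(genes):04d}")
    backbone = [g for g in focal_genes if g.startswith("bb")]
    focal_order = GeneOrder.from_list(focal_genes)

    def branch_rank(b: str) -> int:
        return int(b[2:])

    outgroups: Dict[str, Tuple[List[SimilarityHit], List[SimilarityHit], GeneOrder]] = {}
    for og in branches:
        if og == "br1":
            continue
        og_rank = branch_rank(og)
        present = [
            g
            for g in focal_genes
            if g.startswith("bb") or branch_rank(planted[g]) >= og_rank
        ]
        og_genes = [f"{g}@{og}" for g in present]
        order_o = GeneOrder.from_list(og_genes)
        hits_fo: List[SimilarityHit] = []
        hits_of: List[SimilarityHit] = []
        for g in present:
            score = float(90.0 + rng.uniform(0, 10))
            hits_fo.append((g, f"{g}@{og}", score))
            hits_of.append((f"{g}@{og}", g, score))
            # low-score decoy hit to a random backbone gene
            decoy = backbone[rng.integers(0, len(backbone))]
            if decoy != g:
                hits_fo.append((g, f"{decoy}@{og}", float(30.0 + rng.uniform(0, 10))))
        outgroups[og] = (hits_fo, hits_of, order_o)
    return SyntenyFixture(
        focal_order=focal_order, outgroups=outgroups, planted=planted, genes=genes
    )


def gen_expression_matrix(
    n_genes: int = 100,
    n_samples: int = 50,
    n_partners: int = 5,
    r_target: float = 0.95,
    seed: int = 0,
    target_id: str = "denovo_target",
) -> Tuple[pd.DataFrame, List[str]]:
    """TPM-like matrix with planted coexpression partners of one target gene.

    Partner rows are the target row plus Gaussian noise scaled so the expected
    Pearson correlation is ≈ r_target; all other genes are independent.
    Returns (genes × samples DataFrame, planted partner ids).
    """
    if not 0.0 < r_target <= 1.0:
        raise ValueError("r_target must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mean, sd = 50.0, 20.0
    target = np.clip(rng.normal(mean, sd, size=n_samples), 0.0, None)
    rows = {target_id: target}
    partners = [f"partner_{i}" for i in range(n_partners)]
    if r_target == 1.0:
        noise_sd = 0.0
    else:
        noise_sd = sd * math.sqrt(1.0 / r_target**2 - 1.0)
    for pid in partners:
        rows[pid] = np.clip(
            target + rng.normal(0.0, noise_sd, size=n_samples), 0.0, None
        )
    for i in range(n_genes):
        rows[f"gene_{i:04d}"] = np.clip(
            rng.normal(mean, sd, size=n_samples), 0.0, None
        )
    df = pd.DataFrame(rows).T
    df.columns = [f"sample_{j:02d}" for j in range(n_samples)]
    return df, partners


# ---------------------------------------------------------------------------
# Presets: the study conditions for rate-recovery simulations
# ---------------------------------------------------------------------------

#: Disorder-style cohort presets. Intercept/slope pairs are the fitted
#: median-trend laws being emulated; sigma is the per-protein logit spread.
COHORT_PRESETS: Dict[str, CohortSpec] = {
    # ISD fraction of de novo proteins: ~0.97 at origin, −0.14/My decay.
    "denovo-isd": CohortSpec(
        branch_times=PRESET_BRANCH_TIMES,
        n_per_branch=200,
        intercept=0.97,
        slope=-0.14,
        sigma=0.5,
        gene_class="denovo",
    ),
    # ISD fraction of gene duplicates: −0.099/My; intercept 0.55 places the
    # br6 (2.41 My) median at the duplicates' published overall median 0.31.
    "duplicate-isd": CohortSpec(
        branch_times=PRESET_BRANCH_TIMES,
        n_per_branch=200,
        intercept=0.55,
        slope=-0.099,
        sigma=0.5,
        gene_class="duplicate",
    ),
    # MoRF fraction of de novo proteins over br2–br6: +0.023/My growth.
    "denovo-morf": CohortSpec(
        branch_times={b: t for b, t in PRESET_BRANCH_TIMES.items() if b != "br1"},
        n_per_branch=200,
        intercept=0.05,
        slope=0.023,
        sigma=0.5,
        gene_class="denovo",
    ),
    # Normalized hydrophobicity of de novo proteins: +0.048/My growth.
    "denovo-hydro": CohortSpec(
        branch_times=PRESET_BRANCH_TIMES,
        n_per_branch=200,
        intercept=0.35,
        slope=0.048,
        sigma=0.4,
        gene_class="denovo",
    ),
    # Full-ISD bookkeeping cohort: 181 de novo proteins, 68 fully disordered.
    "denovo-full-isd": CohortSpec(
        branch_times={"br1": 0.1},
        n_per_branch=181,
        intercept=0.88,
        slope=0.0,
        sigma=0.8,
        gene_class="denovo",
    ),
}

N_FULL_ISD_PRESET = {"denovo-full-isd": 68}

#: Secondary-structure cohort preset: coil decays at 0.084/My while helix and
#: strand grow at 0.041 and 0.065/My; the 3_10 helix stays flat near its
#: observed ~2.8% and the isolated bridge absorbs the residual.
SS_PRESETS: Dict[str, SSCohortSpec] = {
    "denovo-ss": SSCohortSpec(
        branch_times=PRESET_BRANCH_TIMES,
        n_per_branch=200,
        length=300,
        laws={
            "coil": (0.47, -0.084),
            "helix": (0.23, 0.041),
            "strand": (0.13, 0.065),
            "g310": (0.028, 0.0),
        },
        gene_class="denovo",
    ),
}

SEQUENCE_PRESETS: Dict[str, SequenceCohortSpec] = {
    "denovo-aa": SequenceCohortSpec(
        branch_times=PRESET_BRANCH_TIMES, n_per_branch=200, length=300
    ),
}


def get_preset(name: str, seed: int = 0):
    """Look up any preset by name with the given seed."""
    if name in COHORT_PRESETS:
        return replace(COHORT_PRESETS[name], seed=seed)
    if name in SS_PRESETS:
        return replace(SS_PRESETS[name], seed=seed)
    if name in SEQUENCE_PRESETS:
        return replace(SEQUENCE_PRESETS[name], seed=seed)
    raise KeyError(f"unknown preset {name!r}")


def truth_to_tsv(truth: pd.DataFrame, path) -> None:
    """Write a generator truth table as a sidecar TSV."""
    truth.to_csv(path, sep="\t", index=False)
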