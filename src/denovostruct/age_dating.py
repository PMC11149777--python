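"""Synteny-based gene age dating.

Duplicated genes are dated by (i) reciprocal best hits (RBH) between the focal
proteome and each outgroup proteome, (ii) chaining RBH anchors into synteny
blocks with a bounded gene-rank gap, and (iii) assigning the gene to the branch
of the most distant outgroup in which it sits inside a conserved block
("oldest presence wins"); a gene absent from every outgroup is focal-specific
(br1). A homology-detection-failure null expectation is provided for the
"how many apparent young genes could be artifacts" sanity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .io_formats import BRANCH_IDS

SimilarityHit = Tuple[str, str, float]  # (query_id, subject_id, score)


@dataclass
class GeneOrder:
    """Gene coordinates along chromosomes for one genome: id -> (chromosome, rank).

    Ranks are 1-based within a chromosome; ids are unique within a genome.
    """

    positions: Dict[str, Tuple[str, int]]

    @classmethod
    def from_list(cls, genes: Sequence[str], chromosome: str = "chr1") -> "GeneOrder":
        return cls({g: (chromosome, i + 1) for i, g in enumerate(genes)})

    @classmethod
    def from_tsv(cls, path) -> "GeneOrder":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        return cls(
            {r.gene_id: (r.chromosome, int(r.rank)) for r in df.itertuples()}
        )

    def to_tsv(self, path) -> None:
        rows = [(g, c, r) for g, (c, r) in self.positions.items()]
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "rank"]).to_csv(
            path, sep="\t", index=False
        )

    def __contains__(self, gene: str) -> bool:
        return gene in self.positions


@dataclass
class SyntenyBlock:
    """A maximal chain of RBH anchors with bounded rank gaps on both genomes."""

    chrom_a: str
    chrom_b: str
    anchors: List[Tuple[str, str]]  # (a_gene, b_gene) in chain order

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> Tuple[int, int] | None:
        return None  # filled by build_synteny_blocks via ranks; kept simple here


@dataclass
class AgeAssignment:
    gene_id: str
    branch: str
    support: List[str]  # outgroup branches with conserved synteny


def _best_hits(hits: Iterable[SimilarityHit]) -> Dict[str, str]:
    """Unique top-scoring subject per query; queries with a tied top score are
    dropped (conservative)."""
    best: Dict[str, Tuple[str, float, bool]] = {}  # query -> (subject, score, tied)
    for q, s, sc in hits:
        sc = float(sc)
        if q not in best or sc > best[q][1]:
            best[q] = (s, sc, False)
        elif sc == best[q][1] and s != best[q][0]:
            best[q] = (best[q][0], sc, True)
    return {q: s for q, (s, _, tied) in best.items() if not tied}


def reciprocal_best_hits(
    hits_ab: Iterable[SimilarityHit], hits_ba: Iterable[SimilarityHit]
) -> List[Tuple[str, str]]:
    """Mutual unique-top-score pairs between two proteomes.

    (a, b) is returned iff b is a's unique best subject in A→B and a is b's
    unique best subject in B→A. Swapping the inputs transposes the pairs.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    pairs.sort()
    return pairs


def build_synteny_blocks(
    rbh_pairs: Sequence[Tuple[str, str]],
    order_a: GeneOrder,
    order_b: GeneOrder,
    max_gap: int = 5,
) -> List[SyntenyBlock]:
    """Chain RBH anchors into maximal synteny blocks.

    Two anchors join the same block when they lie on the same chromosome pair
    and at most ``max_gap`` genes intervene between them on BOTH genomes
    (rank difference − 1 ≤ max_gap).
    """
    for a, b in rbh_pairs:
        if a not in order_a:
            raise KeyError(f"gene {a!r} not in genome A order")
        if b not in order_b:
            raise KeyError(f"gene {b!r} not in genome B order")
    by_chrom: Dict[Tuple[str, str], List[Tuple[int, int, str, str]]] = {}
    for a, b in rbh_pairs:
        ca, ra = order_a.positions[a]
        cb, rb = order_b.positions[b]
        by_chrom.setdefault((ca, cb), []).append((ra, rb, a, b))
    blocks: List[SyntenyBlock] = []
    for (ca, cb), anchors in sorted(by_chrom.items()):
        anchors.sort()
        current: List[Tuple[int, int, str, str]] = []
        for anc in anchors:
            if current:
                ra_prev, rb_prev = current[-1][0], current[-1][1]
                gap_a = anc[0] - ra_prev - 1
                gap_b = abs(anc[1] - rb_prev) - 1
                if gap_a <= max_gap and gap_b <= max_gap:
                    current.append(anc)
                    continue
                blocks.append(
                    SyntenyBlock(ca, cb, [(x[2], x[3]) for x in current])
                )
                current = []
            current.append(anc)
        if current:
            blocks.append(SyntenyBlock(ca, cb, [(x[2], x[3]) for x in current]))
    return blocks


def genes_in_conserved_blocks(
    blocks: Sequence[SyntenyBlock], min_anchors: int = 2
) -> Set[str]:
    """Focal-genome genes that are anchors of a block with >= min_anchors
    anchors — the working definition of 'conserved synteny presence'."""
    present: Set[str] = set()
    for blk in blocks:
        if blk.n_anchors >= min_anchors:
            present.update(a for a, _ in blk.anchors)
    return present


def assign_branch(
    gene_id: str,
    synteny_presence: Mapping[str, bool],
    branch_ladder: Sequence[str] = BRANCH_IDS[1:],
) -> AgeAssignment:
    """Assign the origination branch from per-outgroup synteny presence.

    ``branch_ladder`` lists outgroup branches from nearest (br2) to farthest
    (br9). The gene gets the OLDEST branch with syntenic presence (gene loss in
    intermediate lineages is tolerated); absent everywhere → br1.
    """
    for og in synteny_presence:
        if og not in branch_ladder:
            raise KeyError(f"unknown outgroup branch {og!r}")
    support = [og for og in branch_ladder if synteny_presence.get(og, False)]
    branch = support[-1] if support else "br1"
    return AgeAssignment(gene_id=gene_id, branch=branch, support=support)


def age_genes(
    focal_order: GeneOrder,
    outgroups: Mapping[str, Tuple[Iterable[SimilarityHit], Iterable[SimilarityHit], GeneOrder]],
    genes: Sequence[str],
    max_gap: int = 5,
    min_anchors: int = 2,
) -> Dict[str, AgeAssignment]:
    """Full two-step dating: RBH → synteny blocks → oldest-presence branch.

    ``outgroups`` maps outgroup branch id (br2..br9) to
    (hits focal→outgroup, hits outgroup→focal, outgroup gene order).
    """
    ladder = [b for b in BRANCH_IDS[1:] if b in outgroups]
    presence_by_gene: Dict[str, Dict[str, bool]] = {g: {} for g in genes}
    for og in ladder:
        hits_fo, hits_of, order_o = outgroups[og]
        pairs = reciprocal_best_hits(hits_fo, hits_of)
        blocks = build_synteny_blocks(pairs, focal_order, order_o, max_gap=max_gap)
        conserved = genes_in_conserved_blocks(blocks, min_anchors=min_anchors)
        for g in genes:
            presence_by_gene[g][og] = g in conserved
    return {
        g: assign_branch(g, presence_by_gene[g], branch_ladder=ladder) for g in genes
    }


def hdf_null_expectation(
    n_source: float,
    mu_source: float,
    mu_focal: float,
    t_source: float,
    t_focal: float,
) -> float:
    """Expected number of spurious 'young genes' under the homology-detection-
    failure null, scaled linearly from a source clade to the focal clade by
    substitution rate (per site per generation) and elapsed time (My):

        n_source × (mu_focal / mu_source) × (t_focal / t_source)

    This is one defensible linear reading of the published scaling; all four
    factors are exposed so alternative rate/time unit conversions can be
    configured.
    """
    for name, v in (
        ("n_source", n_source),
        ("mu_source", mu_source),
        ("mu_focal", mu_focal),
        ("t_source", t_source),
        ("t_focal", t_focal),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return n_source * (mu_focal / mu_source) * (t_focal / t_source)
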