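"""Domain types and readers/writers for every external format the pipeline touches.

All downstream modules consume only the types defined here: :class:`ProteinRecord`
(sequence plus optional per-residue tracks), :class:`BranchTable` (the br1..br9
phylostratigraphic ladder with divergence times in Mya), and :class:`ComplexModel`
(a two-chain heavy-atom model with per-residue pLDDT).

Conventions
-----------
* pLDDT is stored internally on [0, 1]; the division by 100 happens exactly once,
  at PDB ingestion (B-factor column carries pLDDT on the 0–100 scale).
* Track positions are 1-based in files and 0-based in memory.
* STRIDE's lowercase 'b' (isolated bridge) is normalized to 'B' at read time.
* Residue alphabet checking is strict by default; ``lenient=True`` masks unknown
  residues as 'X' (excluded from composition denominators downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)
STRIDE_ALPHABET = frozenset("HGIEBTC")

BRANCH_IDS = tuple(f"br{i}" for i in range(1, 10))


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BranchTable:
    """Ordered phylogenetic branches with divergence times (Mya).

    br1 is the focal (youngest) branch; times must increase strictly with
    branch index.
    """

    branches: List[Tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [b for b, _ in self.branches]
        times = [t for _, t in self.branches]
        for b in ids:
            if b not in BRANCH_IDS:
                raise ValueError(f"unknown branch id {b!r}")
        if ids != sorted(ids, key=lambda b: int(b[2:])):
            raise ValueError("branches must be ordered br1..br9")
        if any(t < 0 for t in times):
            raise ValueError("divergence times must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("divergence times must increase strictly with branch index")

    @property
    def ids(self) -> List[str]:
        return [b for b, _ in self.branches]

    def time_of(self, branch: str) -> float:
        for b, t in self.branches:
            if b == branch:
                return t
        raise KeyError(branch)

    def __contains__(self, branch: str) -> bool:
        return any(b == branch for b, _ in self.branches)

    @classmethod
    def default(cls) -> "BranchTable":
        """Shipped Oryza ladder.

        br4 (0.94), br5 (1.0), br6 (2.41) and the ~15 My tree depth are the
        published anchors; br1–br3 and br7–br8 are interpolated placeholders
        that real analyses should override with timetree values.
        """
        return cls(
            branches=[
                ("br1", 0.1),
                ("br2", 0.3),
                ("br3", 0.5),
                ("br4", 0.94),
                ("br5", 1.0),
                ("br6", 2.41),
                ("br7", 5.0),
                ("br8", 9.0),
                ("br9", 15.0),
            ]
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BranchTable":
        df = pd.read_csv(path, sep="\t")
        if not {"branch", "time_mya"} <= set(df.columns):
            raise FormatError(f"{path}: branch table needs columns branch, time_mya")
        return cls(branches=[(str(r.branch), float(r.time_mya)) for r in df.itertuples()])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.branches, columns=["branch", "time_mya"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ProteinRecord:
    """One protein with its optional per-residue signal tracks."""

    id: str
    gene_class: str  # "denovo" | "duplicate"
    branch: str  # br1..br9
    sequence: str
    disorder_track: Optional[np.ndarray] = None  # real in [0,1] or binary
    morf_track: Optional[np.ndarray] = None  # binary
    plddt_track: Optional[np.ndarray] = None  # real in [0,1]
    ss_string: Optional[str] = None  # STRIDE alphabet

    def __post_init__(self) -> None:
        if self.gene_class not in ("denovo", "duplicate"):
            raise ValueError(f"{self.id}: gene_class must be 'denovo' or 'duplicate'")
        if self.branch not in BRANCH_IDS:
            raise ValueError(f"{self.id}: unknown branch {self.branch!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        n = len(self.sequence)
        for name in ("disorder_track", "morf_track", "plddt_track"):
            track = getattr(self, name)
            if track is not None:
                track = np.asarray(track, dtype=float)
                if track.shape != (n,):
                    raise ValueError(
                        f"{self.id}: {name} length {track.shape} != sequence length {n}"
                    )
                setattr(self, name, track)
        if self.ss_string is not None:
            if len(self.ss_string) != n:
                raise ValueError(f"{self.id}: ss_string length != sequence length")
            bad = set(self.ss_string) - STRIDE_ALPHABET
            if bad:
                raise ValueError(f"{self.id}: ss_string letters outside STRIDE alphabet: {bad}")


@dataclass
class Residue:
    """One residue of a complex chain: heavy-atom coordinates + pLDDT in [0,1]."""

    index: int
    aa: str  # one-letter code
    atoms: np.ndarray  # (n_atoms, 3), Å
    plddt: float

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2 or self.atoms.shape[1] != 3 or self.atoms.shape[0] < 1:
            raise ValueError(f"residue {self.index}: needs >= 1 atom with 3D coordinates")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError(f"residue {self.index}: non-finite coordinates")


@dataclass
class ComplexModel:
    """A two-chain complex model."""

    chain_ids: Tuple[str, str]
    chains: Tuple[List[Residue], List[Residue]]

    def __post_init__(self) -> None:
        if len(self.chain_ids) != 2 or len(self.chains) != 2:
            raise ValueError("ComplexModel requires exactly 2 chains")

    @property
    def lengths(self) -> Tuple[int, int]:
        return (len(self.chains[0]), len(self.chains[1]))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, lenient: bool = False) -> List[Tuple[str, str]]:
    """Read a protein FASTA into ``[(id, sequence), ...]`` in file order.

    Strict mode (default) rejects residues outside the 20-letter alphabet plus
    'X'; ``lenient=True`` masks them as 'X' instead.
    """
    records: List[Tuple[str, str]] = []
    allowed = AA20_SET | {"X"}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = [c for c in seq if c not in allowed]
        if bad:
            if lenient:
                seq = "".join(c if c in allowed else "X" for c in seq)
            else:
                raise FormatError(
                    f"{path}: record {rec.id!r} has invalid residue {bad[0]!r}"
                )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Per-residue track TSV (id, position, value); positions 1-based, contiguous
# ---------------------------------------------------------------------------


def read_track_tsv(path: str | Path, probability: bool = True) -> Dict[str, np.ndarray]:
    """Read per-residue tracks keyed by protein id.

    Positions must be 1-based and contiguous per id; for probability tracks,
    values outside [0, 1] are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "position", "value"} <= set(df.columns):
        raise FormatError(f"{path}: track TSV needs columns id, position, value")
    tracks: Dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy(dtype=int)
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            missing = sorted(set(expected) - set(pos))
            raise FormatError(
                f"{path}: id {pid!r} positions not contiguous"
                + (f"; position {missing[0]} missing" if missing else "")
            )
        vals = grp["value"].to_numpy(dtype=float)
        if probability and (np.any(vals < 0) or np.any(vals > 1)):
            raise FormatError(f"{path}: id {pid!r} has value outside [0, 1]")
        tracks[str(pid)] = vals
    return tracks


def write_track_tsv(tracks: Dict[str, Sequence[float]], path: str | Path) -> None:
    rows = [
        (pid, i + 1, float(v))
        for pid, vals in tracks.items()
        for i, v in enumerate(vals)
    ]
    pd.DataFrame(rows, columns=["id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# STRIDE detailed output (ASG lines)
# ---------------------------------------------------------------------------


def read_stride(path: str | Path) -> str:
    """Concatenate the one-letter secondary-structure codes of a STRIDE file.

    Parses ``ASG`` lines in residue order. The lowercase 'b' bridge code is
    normalized to 'B'; anything outside {H,G,I,E,B,T,C} is an error.
    """
    codes: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("ASG"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: short ASG line")
            code = fields[5]
            if code == "b":
                code = "B"
            if code not in STRIDE_ALPHABET:
                raise FormatError(
                    f"{path}:{lineno}: unknown secondary-structure code {code!r}"
                )
            codes.append(code)
    return "".join(codes)


def read_stride_files(paths: Dict[str, str | Path]) -> Dict[str, str]:
    """Map protein id -> ss_string for a set of per-protein STRIDE files."""
    return {pid: read_stride(p) for pid, p in paths.items()}


# ---------------------------------------------------------------------------
# PDB two-chain complex models (pLDDT in the B-factor column, 0–100 scale)
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_pdb_complex(path: str | Path) -> ComplexModel:
    """Read a two-chain PDB model; hydrogens are excluded and per-residue
    pLDDT is the B-factor of the residue's first atom divided by 100."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models in PDB file")
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 2:
        raise FormatError(f"{path}: expected exactly 2 chains, found {len(chains)}")
    out_chains: List[List[Residue]] = []
    for ch in chains:
        residues: List[Residue] = []
        for res in ch:
            atoms = [
                [a.pos.x, a.pos.y, a.pos.z]
                for a in res
                if a.element.name not in ("H", "D")
            ]
            if not atoms:
                continue
            first = next(a for a in res if a.element.name not in ("H", "D"))
            if not all(math.isfinite(v) for row in atoms for v in row):
                raise FormatError(f"{path}: non-finite coordinates in {res.name}")
            residues.append(
                Residue(
                    index=res.seqid.num,
                    aa=_THREE_TO_ONE.get(res.name, "X"),
                    atoms=np.asarray(atoms, dtype=float),
                    plddt=first.b_iso / 100.0,
                )
            )
        residues.sort(key=lambda r: r.index)
        if not residues:
            raise FormatError(f"{path}: chain {ch.name} has no heavy atoms")
        out_chains.append(residues)
    return ComplexModel(
        chain_ids=(chains[0].name, chains[1].name),
        chains=(out_chains[0], out_chains[1]),
    )


def write_pdb_complex(model: ComplexModel, path: str | Path) -> None:
    """Write a :class:`ComplexModel` as PDB ATOM records (pLDDT × 100 in the
    B-factor column, single CB-style atom naming for synthetic models)."""
    st = gemmi.Structure()
    st.name = "complex"
    md = gemmi.Model("1")
    for cid, residues in zip(model.chain_ids, model.chains):
        ch = gemmi.Chain(cid)
        for res in residues:
            r = gemmi.Residue()
            r.name = _ONE_TO_THREE.get(res.aa, "GLY")
            r.seqid = gemmi.SeqId(res.index, " ")
            for k, (x, y, z) in enumerate(np.atleast_2d(res.atoms)):
                a = gemmi.Atom()
                a.name = "CB" if k == 0 else f"C{k}"
                a.element = gemmi.Element("C")
                a.pos = gemmi.Position(float(x), float(y), float(z))
                a.b_iso = res.plddt * 100.0
                a.occ = 1.0
                r.add_atom(a)
            ch.add_residue(r)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Expression matrix (genes × samples, TPM)
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes × samples TPM matrix; first column is the gene id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: expression matrix has missing cells")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
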