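"""Shared domain types and file IO.

Sequences travel as :class:`SequenceRecord`, predicted structures as
:class:`StructureModel` (per-residue confidence read from the PDB B-factor
column, the convention structure-prediction models use for pLDDT), and metric
values as :class:`ScoreTable` rows.  FASTA/A3M parsing is delegated to
Biopython; PDB parsing uses :class:`Bio.PDB.PDBParser`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class Source(str, Enum):
    """Provenance of a sequence within a study split."""

    NATURAL_TRAIN = "natural_train"
    NATURAL_TEST = "natural_test"
    GENERATED = "generated"


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence with provenance.

    ``X`` (unknown residue) is tolerated but flagged through
    :attr:`nonstandard`; violations are recorded, never dropped.
    """

    id: str
    sequence: str
    source: Source = Source.GENERATED
    model_label: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def nonstandard(self) -> frozenset[str]:
        """Letters outside the 20-letter alphabet (e.g. ``X``)."""
        return frozenset(self.sequence) - _STANDARD_SET

    @property
    def has_x(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    bfactor: float


@dataclass
class StructureModel:
    """A single-model protein structure as a flat atom list.

    Coordinates are in Angstrom.  The B-factor column is interpreted as a
    per-residue prediction confidence in [0, 100] when it comes from a
    structure-prediction model.
    """

    atoms: list[Atom]
    name: str = ""

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_seq, res_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.res_seq)
            if key not in seen:
                seen[key] = a.res_name
                order.append((a.chain, a.res_seq, a.res_name))
        return order

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence derived from residue names."""
        letters = []
        for ch, _, res_name in self.residues():
            if chain is not None and ch != chain:
                continue
            letters.append(protein_letters_3to1.get(res_name.upper(), "X"))
        return "".join(letters)

    def residue_confidence(self, policy: str = "mean") -> list[float]:
        """Per-residue confidence from atom B-factors.

        policy="mean" averages a residue's atom B-factors (robust to PDB
        dialects); policy="first" takes the first atom's value.
        """
        if policy not in {"mean", "first"}:
            raise ValueError(f"unknown confidence policy {policy!r}")
        values: list[float] = []
        for ch, rs, _ in self.residues():
            bfs = [a.bfactor for a in self.atoms if a.chain == ch and a.res_seq == rs]
            values.append(bfs[0] if policy == "first" else sum(bfs) / len(bfs))
        return values

    def __len__(self) -> int:
        return len(self.residues())


class ScoreTable:
    """Per-sequence metric values with explicit orientation flags.

    Backed by a pandas DataFrame (rows = sequence ids, columns = metrics);
    ``orientation[metric]`` is True when higher values are better.  Missing
    values stay as NaN and are never filled implicitly.
    """

    def __init__(self, frame: pd.DataFrame | None = None,
                 orientation: dict[str, bool] | None = None) -> None:
        self.frame = frame if frame is not None else pd.DataFrame()
        self.orientation = dict(orientation or {})

    def set(self, seq_id: str, metric: str, value: float,
            higher_is_better: bool = True) -> None:
        prev = self.orientation.setdefault(metric, higher_is_better)
        if prev != higher_is_better:
            raise ValueError(f"conflicting orientation for metric {metric!r}")
        self.frame.loc[seq_id, metric] = value

    def get(self, seq_id: str, metric: str) -> float:
        return float(self.frame.loc[seq_id, metric])

    def column(self, metric: str) -> pd.Series:
        return self.frame[metric]

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "id"
        with open(path, "w") as fh:
            for metric, hib in self.orientation.items():
                fh.write(f"# orientation\t{metric}\t{'higher' if hib else 'lower'}\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        orientation: dict[str, bool] = {}
        header_lines = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("# orientation\t"):
                    _, metric, direction = line.rstrip("\n").split("\t")
                    orientation[metric] = direction == "higher"
                    header_lines += 1
                else:
                    break
        frame = pd.read_csv(path, sep="\t", skiprows=header_lines, index_col="id")
        return cls(frame, orientation)


# ---------------------------------------------------------------------------
# FASTA / A3M

def read_fasta(path: str | Path, source: Source = Source.GENERATED) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Whitespace inside sequences is stripped and ``*`` stop-codon terminators
    removed (logged).  Records containing letters outside the 20-letter
    alphabet are kept and flagged, never dropped.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if "*" in seq:
            logger.warning("record %s: removing %d '*' terminator(s)",
                           rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        sr = SequenceRecord(id=rec.id, sequence=seq, source=source,
                            description=rec.description[len(rec.id):].strip())
        if sr.nonstandard:
            logger.warning("record %s: non-standard letters %s",
                           rec.id, sorted(sr.nonstandard))
        records.append(sr)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_msa(path: str | Path, fmt: str = "fasta") -> list[SequenceRecord]:
    """Read an aligned FASTA or A3M file.

    A3M lowercase letters mark insertions relative to the query columns; they
    are *removed* so that every returned row has equal length over the shared
    column set.  Gaps are kept as ``-``.
    """
    rows: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if fmt == "a3m":
            seq = "".join(c for c in seq if not c.islower())
        seq = seq.replace(".", "-").upper()
        rows.append(SequenceRecord(id=rec.id, sequence=seq))
    if not rows:
        raise ValueError(f"no alignment rows found in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    return rows


# ---------------------------------------------------------------------------
# PDB structures

def read_structure(path: str | Path, name: str | None = None) -> StructureModel:
    """Parse a PDB coordinate file into a StructureModel.

    Only ATOM records of the first model are kept (HETATM ignored); a
    multi-model file produces a warning.  Residue numbering must be strictly
    increasing within each chain.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or Path(path).stem, str(path))
    models = list(structure)
    if len(models) > 1:
        logger.warning("%s: %d models present, using the first", path, len(models))
    atoms: list[Atom] = []
    for chain in models[0]:
        prev = None
        for residue in chain:
            hetflag, res_seq, _ = residue.id
            if hetflag.strip():  # HETATM / water
                continue
            if prev is not None and res_seq <= prev:
                raise ValueError(
                    f"{path}: residue numbering not strictly increasing in chain "
                    f"{chain.id} ({prev} -> {res_seq})")
            prev = res_seq
            for atom in residue:
                atoms.append(Atom(
                    chain=chain.id, res_seq=res_seq, res_name=residue.resname,
                    atom_name=atom.get_name(),
                    element=(atom.element or "").strip().upper(),
                    x=float(atom.coord[0]), y=float(atom.coord[1]),
                    z=float(atom.coord[2]),
                    bfactor=float(atom.get_bfactor()),
                ))
    if not atoms:
        raise ValueError(f"no ATOM records in {path}")
    return StructureModel(atoms=atoms, name=name or Path(path).stem)


_PDB_ATOM = ("{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}"
             "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}"
             "{bfac:>6.2f}          {element:>2}\n")


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a minimal fixed-column PDB file."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
            fh.write(_PDB_ATOM.format(
                record="ATOM", serial=i, name=name, altloc=" ",
                resname=a.res_name, chain=a.chain, resseq=a.res_seq, icode=" ",
                x=a.x, y=a.y, z=a.z, occ=1.0, bfac=a.bfactor, element=a.element))
        fh.write("END\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
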