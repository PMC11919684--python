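"""Pairwise global alignment against a training set and derived metrics.

Candidates are compared with their closest training-set sequence by optimal
global alignment under an affine gap model (substitution matrix BLOSUM62 by
default, gap open 10, gap extend 2; a gap of length L costs open + L x
extend, so a single-residue gap costs 12, the FASTA-package convention).
Identity is 1 minus the normalized Hamming distance of the gapped alignment:
gap columns count as mismatches and the denominator is the full alignment
length, terminal gaps included.

The actual dynamic programming is Biopython's ``PairwiseAligner``; this
module owns metric definitions, tie-breaking and the closest-hit search.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import STANDARD_AA, SequenceRecord

#: Affine gap penalties used for all training-set comparisons.
GAP_OPEN = 10
GAP_EXTEND = 2


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A named residue substitution matrix plus the gap model."""

    name: str
    matrix: "substitution_matrices.Array"
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls("BLOSUM62", substitution_matrices.load("BLOSUM62"))

    @classmethod
    def from_ncbi_file(cls, path: str | Path, name: str | None = None) -> "SubstitutionMatrix":
        """Load a matrix in NCBI text format (e.g. a PFASUM15 file)."""
        mat = substitution_matrices.read(str(path))
        return cls(name or Path(path).stem, mat)


@lru_cache(maxsize=8)
def _aligner(name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    if name == "BLOSUM62":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    # length-L gap costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _get_aligner(matrix: SubstitutionMatrix) -> Align.PairwiseAligner:
    if matrix.name == "BLOSUM62":
        return _aligner("BLOSUM62", matrix.gap_open, matrix.gap_extend)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix.matrix
    aligner.mode = "global"
    aligner.open_gap_score = -(matrix.gap_open + matrix.gap_extend)
    aligner.extend_gap_score = -matrix.gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_query: str
    gapped_reference: str
    raw_score: float

    def __post_init__(self) -> None:
        if len(self.gapped_query) != len(self.gapped_reference):
            raise ValueError("gapped strings differ in length")

    def columns(self) -> list[str]:
        """Per-column classification: match / mismatch / gap."""
        out = []
        for q, r in zip(self.gapped_query, self.gapped_reference):
            if q == "-" or r == "-":
                out.append("gap")
            elif q == r:
                out.append("match")
            else:
                out.append("mismatch")
        return out

    def identity(self, include_terminal_gaps: bool = True) -> float:
        """1 - normalized Hamming distance over the gapped alignment.

        Gap columns count as non-matching.  With
        ``include_terminal_gaps=False``, leading/trailing gap columns are
        dropped from the denominator.
        """
        cols = self.columns()
        if not include_terminal_gaps:
            lo, hi = 0, len(cols)
            while lo < hi and cols[lo] == "gap":
                lo += 1
            while hi > lo and cols[hi - 1] == "gap":
                hi -= 1
            cols = cols[lo:hi]
        if not cols:
            return 0.0
        return cols.count("match") / len(cols)


@dataclass(frozen=True)
class ClosestHit:
    reference_id: str
    alignment: PairwiseAlignment
    identity: float


def _validate(seq: str, label: str) -> None:
    bad = set(seq) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"{label} contains non-standard letters {sorted(bad)}")


def global_align(query: str, reference: str,
                 matrix: SubstitutionMatrix | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under the affine gap model.

    Among co-optimal alignments the first in Biopython's deterministic
    traceback order is returned, so repeated calls give identical output.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    _validate(query, "query")
    _validate(reference, "reference")
    aligner = _get_aligner(matrix)
    alignment = aligner.align(query, reference)[0]
    gapped_q, gapped_r = str(alignment[0]), str(alignment[1])
    return PairwiseAlignment(gapped_query=gapped_q, gapped_reference=gapped_r,
                             raw_score=float(alignment.score))


def alignment_score(query: str, reference: str,
                    matrix: SubstitutionMatrix | None = None) -> float:
    """Optimal global alignment score only (no traceback; faster)."""
    matrix = matrix or SubstitutionMatrix.blosum62()
    return float(_get_aligner(matrix).score(query, reference))


def closest_training(query: str, training_set: Sequence[SequenceRecord],
                     matrix: SubstitutionMatrix | None = None) -> ClosestHit:
    """The training sequence maximizing the global alignment score.

    Score ties break to the lexicographically smaller reference id.
    """
    if not training_set:
        raise ValueError("training set is empty")
    matrix = matrix or SubstitutionMatrix.blosum62()
    best_id, best_score = None, -np.inf
    for rec in training_set:
        s = alignment_score(query, rec.sequence, matrix)
        if s > best_score or (s == best_score and (best_id is None or rec.id < best_id)):
            best_id, best_score = rec.id, s
    best_seq = next(r.sequence for r in training_set if r.id == best_id)
    aln = global_align(query, best_seq, matrix)
    return ClosestHit(reference_id=best_id, alignment=aln, identity=aln.identity())


def mutant_position_mean(alignment: PairwiseAlignment,
                         matrix: SubstitutionMatrix | None = None) -> float | None:
    """Mean substitution score over mismatched, gap-free columns.

    Returns None when the alignment has no such column (identical pair, or
    every mismatch sits opposite a gap).
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    scores = [matrix.score(q, r)
              for q, r in zip(alignment.gapped_query, alignment.gapped_reference)
              if q != "-" and r != "-" and q != r]
    if not scores:
        return None
    return float(np.mean(scores))


def topk_mean_homology(query: str, training_set: Sequence[SequenceRecord],
                       k: int = 30, backend: str = "internal",
                       matrix: SubstitutionMatrix | None = None) -> float:
    """Mean of the k best per-reference homology scores for a query.

    backend="internal" scores every training sequence by global alignment raw
    score; backend="phmmer" uses pyhmmer's phmmer search bit scores.  With
    fewer than k references the mean of all available scores is returned
    (logged).  The two backends' scores are on different scales and must not
    be mixed in one table.
    """
    if not training_set:
        raise ValueError("training set is empty")
    if backend == "internal":
        scores = sorted((alignment_score(query, r.sequence, matrix)
                         for r in training_set), reverse=True)
    elif backend == "phmmer":
        scores = sorted(_phmmer_scores(query, training_set), reverse=True)
    else:
        raise ValueError(
            f"unknown backend {backend!r}; use 'internal' (global-alignment "
            "raw scores) or 'phmmer'")
    if len(scores) < k:
        import logging
        logging.getLogger(__name__).warning(
            "only %d references (< k=%d); averaging all", len(scores), k)
    return float(np.mean(scores[:k]))


def _phmmer_scores(query: str, training_set: Sequence[SequenceRecord]) -> list[float]:
    try:
        import pyhmmer
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "phmmer backend requested but pyhmmer is unavailable; "
            "use backend='internal'") from exc
    alphabet = pyhmmer.easel.Alphabet.amino()
    q = pyhmmer.easel.TextSequence(name=b"query", sequence=query).digitize(alphabet)
    targets = [pyhmmer.easel.TextSequence(name=r.id.encode(), sequence=r.sequence)
               .digitize(alphabet) for r in training_set]
    hits = next(iter(pyhmmer.hmmer.phmmer([q], targets)))
    return [float(h.score) for h in hits]


def identity_to_training(query: str, training_set: Sequence[SequenceRecord],
                         matrix: SubstitutionMatrix | None = None) -> float:
    """Identity of a query to its closest training sequence."""
    return closest_training(query, training_set, matrix).identity
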