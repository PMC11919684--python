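"""Scorer-agnostic average log-likelihood metrics and sequence generation.

A *likelihood scorer* answers one question: given a sequence (optionally with
MSA context) and a set of masked positions, what is the log-probability of
the observed residue at each requested position?  Real masked language models
(single-sequence or MSA-transformer style) and inverse-folding models attach
through this contract; :class:`PssmScorer` is a deterministic, context-free
stand-in built from an MSA so the whole stack runs and is testable with no
model weights.

Scoring schedules: unmasked scoring is a single pass over all positions.
Masked scoring with interval *m* uses *m* passes; pass *j* masks positions
congruent to *j* modulo *m*, so every position is masked exactly once across
passes and the pooled mean covers the whole sequence.  The MSA-context score
aligns the query with its nearest training sequences and applies a masked
schedule (default: 31 context sequences, interval 6).

Generation by iterative masking re-samples masked positions from the
scorer's distribution until every position has been redrawn once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .align_metrics import SubstitutionMatrix, alignment_score, global_align
from .io import STANDARD_AA, SequenceRecord, Source

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@runtime_checkable
class LikelihoodScorer(Protocol):
    """Contract every likelihood scorer implements."""

    def log_probs(self, sequence: str, masked: Sequence[int],
                  context: Sequence[str] | None = None) -> dict[int, float]:
        """Log-probability of the observed residue at each masked position."""
        ...


class SamplingScorer(LikelihoodScorer, Protocol):
    def sample(self, sequence: str, masked: Sequence[int], rng: np.random.Generator,
               temperature: float = 1.0,
               context: Sequence[str] | None = None) -> dict[int, str]:
        """Draw replacement residues at the masked positions."""
        ...


@dataclass(frozen=True)
class MaskSchedule:
    """Masking interval m => m passes; pass j masks positions j, j+m, ..."""

    interval: int

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be >= 1")

    @property
    def passes(self) -> int:
        return self.interval

    def mask_sets(self, length: int) -> list[list[int]]:
        return [list(range(j, length, self.interval)) for j in range(self.interval)]


class PssmScorer:
    """Context-free mock scorer: a position probability matrix from an MSA.

    Column probabilities use pseudocount alpha: p(aa | i) =
    (count + alpha) / (n_rows + 20 * alpha).  Columns are indexed by the
    first (query) row's residue positions; gap rows at a column are not
    counted.  Being context-free, its answers cannot depend on the mask set
    — a property the test-suite leans on.
    """

    def __init__(self, msa_rows: Sequence[str], alpha: float = 1.0) -> None:
        if not msa_rows:
            raise ValueError("empty MSA")
        lengths = {len(r) for r in msa_rows}
        if len(lengths) != 1:
            raise ValueError("ragged MSA")
        anchor = msa_rows[0]
        keep = [i for i, c in enumerate(anchor) if c != "-"]
        counts = np.zeros((len(keep), 20))
        for row in msa_rows:
            for out_i, col in enumerate(keep):
                aa = row[col]
                if aa in AA_INDEX:
                    counts[out_i, AA_INDEX[aa]] += 1
        self.probs = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + 20 * alpha)
        self.length = len(keep)

    def log_probs(self, sequence: str, masked: Sequence[int],
                  context: Sequence[str] | None = None) -> dict[int, float]:
        if len(sequence) != self.length:
            raise ValueError(
                f"scorer built for length {self.length}, got {len(sequence)}")
        out = {}
        for i in masked:
            aa = sequence[i]
            if aa not in AA_INDEX:
                raise ValueError(f"non-standard residue {aa!r} at position {i}")
            out[i] = float(np.log(self.probs[i, AA_INDEX[aa]]))
        return out

    def sample(self, sequence: str, masked: Sequence[int], rng: np.random.Generator,
               temperature: float = 1.0,
               context: Sequence[str] | None = None) -> dict[int, str]:
        out = {}
        for i in masked:
            p = self.probs[i]
            if temperature <= 0:  # zero-temperature limit: argmax
                out[i] = STANDARD_AA[int(np.argmax(p))]
                continue
            w = p ** (1.0 / temperature)
            w = w / w.sum()
            out[i] = STANDARD_AA[int(rng.choice(20, p=w))]
        return out


class UniformScorer:
    """Uniform 1/20 per residue; handy null scorer."""

    def log_probs(self, sequence, masked, context=None):
        return {i: float(np.log(1 / 20)) for i in masked}

    def sample(self, sequence, masked, rng, temperature=1.0, context=None):
        return {i: STANDARD_AA[int(rng.integers(20))] for i in masked}


def average_log_prob(scorer: LikelihoodScorer, sequence: str,
                     schedule: MaskSchedule | None = None,
                     context: Sequence[str] | None = None) -> float:
    """Mean log-probability of the observed residues.

    Unmasked mode (schedule=None) queries all positions in one pass.  With a
    schedule of interval m, the score is pooled over m passes, each masking
    every m-th position, then averaged over all positions.
    """
    n = len(sequence)
    if schedule is None:
        lp = scorer.log_probs(sequence, list(range(n)), context=context)
        return float(np.mean([lp[i] for i in range(n)]))
    pooled: dict[int, float] = {}
    for j, mask_set in enumerate(schedule.mask_sets(n)):
        if not mask_set:
            continue
        try:
            pooled.update(scorer.log_probs(sequence, mask_set, context=context))
        except Exception as exc:
            raise RuntimeError(f"scorer failed on pass {j}") from exc
    return float(np.mean([pooled[i] for i in range(n)]))


def _nearest_neighbors(query: str, training_set: Sequence[SequenceRecord],
                       n: int, matrix: SubstitutionMatrix | None = None,
                       backend: str = "internal") -> list[SequenceRecord]:
    if backend == "phmmer":
        from .align_metrics import _phmmer_scores
        scored = list(zip(_phmmer_scores(query, training_set), training_set))
    else:
        scored = [(alignment_score(query, r.sequence, matrix), r)
                  for r in training_set]
    scored.sort(key=lambda t: (-t[0], t[1].id))
    return [r for _, r in scored[:n]]


def star_align(query: str, others: Sequence[str],
               matrix: SubstitutionMatrix | None = None) -> list[str]:
    """Query-anchored multiple alignment.

    Each sequence is globally aligned to the query; insertions relative to
    the query are dropped, so every output row has exactly one column per
    query position (row 0 is the query itself).  Sufficient for scoring the
    query row; not a general-purpose MSA.
    """
    rows = [query]
    for other in others:
        aln = global_align(other, query, matrix)
        row = "".join(q for q, r in zip(aln.gapped_query, aln.gapped_reference)
                      if r != "-")
        rows.append(row)
    return rows


def msa_context_score(scorer: LikelihoodScorer, query: str,
                      training_set: Sequence[SequenceRecord],
                      n_context: int = 31, interval: int = 6,
                      matrix: SubstitutionMatrix | None = None,
                      aligner=None, backend: str = "internal") -> float:
    """Masked average log-probability of a query in MSA context.

    Builds an alignment of the query plus its ``n_context`` nearest training
    sequences (external aligner adapter, or the internal query-anchored star
    alignment), then scores the query row with an interval-``interval``
    masked schedule.
    """
    if not training_set:
        raise ValueError("training set is empty")
    neighbors = _nearest_neighbors(query, training_set, n_context, matrix, backend)
    if aligner is not None:
        rows = aligner(query, [r.sequence for r in neighbors])
    else:
        rows = star_align(query, [r.sequence for r in neighbors], matrix)
    return average_log_prob(scorer, query, MaskSchedule(interval), context=rows[1:])


def iterative_mask_sample(scorer: SamplingScorer, seed_msa: Sequence[str],
                          mode: str = "whole_msa", temperature: float = 1.0,
                          rng_seed: int = 0, interval: int = 6,
                          target_row: int = 0,
                          training_set: Sequence[SequenceRecord] | None = None,
                          n_context: int = 31,
                          matrix: SubstitutionMatrix | None = None,
                          ) -> list[SequenceRecord]:
    """Generate sequences by iterative masking and re-sampling.

    mode="whole_msa": every row of the seed alignment is re-sampled.
    mode="single_sequence_neighbors": only ``target_row`` is re-sampled, and
    after each sweep its context is rebuilt from the training sequences most
    similar to the current state of the row (requires ``training_set``).

    Positions of each target row are visited in a seeded random order, every
    m-th of them masked per pass; one full sweep re-draws every position
    exactly once, after which generation stops.  Fixed ``rng_seed`` gives
    identical output.
    """
    if not hasattr(scorer, "sample"):
        raise TypeError("scorer does not support sampling")
    if mode not in {"whole_msa", "single_sequence_neighbors"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single_sequence_neighbors" and training_set is None:
        raise ValueError("single_sequence_neighbors mode requires a training set")
    rng = np.random.default_rng(rng_seed)
    rows = [r.replace("-", "") for r in seed_msa]
    targets = range(len(rows)) if mode == "whole_msa" else [target_row]
    out: list[SequenceRecord] = []
    for t in targets:
        seq = list(rows[t])
        order = rng.permutation(len(seq))
        for j in range(interval):
            mask_set = sorted(int(p) for p in order[j::interval])
            if not mask_set:
                continue
            if mode == "single_sequence_neighbors":
                neighbors = _nearest_neighbors("".join(seq), training_set,
                                               n_context, matrix)
                context = star_align("".join(seq),
                                     [r.sequence for r in neighbors], matrix)[1:]
            else:
                context = [rows[i] for i in range(len(rows)) if i != t]
            draws = scorer.sample("".join(seq), mask_set, rng,
                                  temperature=temperature, context=context)
            for pos, aa in draws.items():
                seq[pos] = aa
        out.append(SequenceRecord(
            id=f"gen_{mode}_{t}_seed{rng_seed}", sequence="".join(seq),
            source=Source.GENERATED,
            model_label=f"iterative_mask[{mode},T={temperature},seed={rng_seed}]"))
    return out
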