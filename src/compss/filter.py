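"""The end-to-end COMPSS selection procedure.

The third-round selection filter, stage by stage:

1. *Sequence stage* — a candidate passes when (i) its identity to the
   closest training sequence lies inside the allowed band (default
   [0.50, 0.80], both endpoints inclusive: the exclusion rule is "less than
   50% or greater than 80%"), (ii) its language-model score reaches the
   cutoff calibrated as the top 10th percentile of natural test-sequence
   scores, and (iii) it passes the sequence quality checks (start
   methionine, no long repeats, no predicted transmembrane domain).
   Every violated criterion is reported, not just the first.
2. *Structure stage* — a seeded random sample of 200 passing sequences is
   ranked by a structure-conditioned (inverse-folding) score; from the top
   40, 18 are randomly selected for experimental characterization.
3. *Controls* — each selected sequence is paired with a seeded random draw
   from the filter-failing pool whose identity-to-training is within 0.01 of
   its own, without replacement; unmatched selections are reported.

All draws come from one named seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .io import SequenceRecord
from .seq_metrics import QualityPolicy, quality_check
from .stats_eval import percentile_threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    identity_band: tuple[float, float] = (0.50, 0.80)
    lm_percentile: float = 10.0
    n_prefilter_sample: int = 200
    top_n_structure: int = 40
    n_final: int = 18
    control_identity_tolerance: float = 0.01
    seed: int = 0
    quality: QualityPolicy = field(default_factory=QualityPolicy)

    def __post_init__(self) -> None:
        if not (self.n_final <= self.top_n_structure <= self.n_prefilter_sample):
            raise ValueError("need n_final <= top_n_structure <= n_prefilter_sample")


@dataclass
class CandidateReport:
    id: str
    stage_reached: str  # "sequence", "structure", "selected", or "failed"
    criteria: dict
    reasons: list
    scores: dict


@dataclass
class FilterReport:
    policy: FilterPolicy
    cutoff: float
    candidates: dict
    passing: list
    selected: list
    controls: dict  # selected id -> control id or None
    stage_counts: dict

    def to_manifest(self) -> dict:
        return {
            "policy": {**asdict(self.policy),
                       "quality": {k: v for k, v in
                                   asdict(self.policy.quality).items()
                                   if k != "tm_predictor"}},
            "cutoff": self.cutoff,
            "stage_counts": self.stage_counts,
            "selected": self.selected,
            "controls": self.controls,
        }


def calibrate(natural_scores: Sequence[float], policy: FilterPolicy) -> float:
    """Language-model score cutoff from natural calibration sequences."""
    if len(natural_scores) == 0:
        raise ValueError("empty calibration set")
    if len(natural_scores) < 5:
        raise ValueError("need >= 5 natural calibration scores")
    if len(natural_scores) < 20:
        logger.warning("only %d calibration scores; cutoff will be noisy",
                       len(natural_scores))
    return percentile_threshold(natural_scores, policy.lm_percentile, "top")


def sequence_stage(candidates: Sequence[SequenceRecord],
                   identities: Mapping[str, float],
                   lm_scores: Mapping[str, float],
                   cutoff: float,
                   policy: FilterPolicy) -> tuple[list[str], list[str], dict]:
    """Partition candidates by the sequence-level criteria.

    Returns (passing ids, failing ids, per-candidate reports).  A candidate
    missing either score raises, naming the metric.
    """
    lo, hi = policy.identity_band
    passing, failing, reports = [], [], {}
    for rec in candidates:
        for name, table in (("identity", identities), ("lm_score", lm_scores)):
            if rec.id not in table:
                raise KeyError(f"candidate {rec.id!r} has no {name} score")
        ident = identities[rec.id]
        lm = lm_scores[rec.id]
        qc = quality_check(rec.sequence, policy.quality)
        reasons = list(qc.reasons)
        in_band = lo <= ident <= hi
        if not in_band:
            reasons.append("identity_below_band" if ident < lo
                           else "identity_above_band")
        lm_ok = lm >= cutoff
        if not lm_ok:
            reasons.append("lm_below_cutoff")
        ok = in_band and lm_ok and qc.passed()
        reports[rec.id] = CandidateReport(
            id=rec.id, stage_reached="sequence" if ok else "failed",
            criteria={"identity_in_band": in_band, "lm_above_cutoff": lm_ok,
                      "quality": qc.passed()},
            reasons=reasons,
            scores={"identity": ident, "lm_score": lm})
        (passing if ok else failing).append(rec.id)
    return passing, failing, reports


def structure_stage(passing: Sequence[str],
                    structure_scores: Mapping[str, float],
                    policy: FilterPolicy,
                    rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Sample, rank by structure score, and draw the final selection.

    Returns (sampled ids, selected ids).  Sampled candidates without a
    structure score are dropped and back-filled from rank ``top_n_structure
    + 1`` onward (logged); ranking is by score descending with id
    tie-breaks.
    """
    passing = list(passing)
    if len(passing) < policy.n_final:
        raise ValueError(
            f"only {len(passing)} passing candidates < n_final={policy.n_final}")
    if len(passing) > policy.n_prefilter_sample:
        idx = rng.choice(len(passing), size=policy.n_prefilter_sample,
                         replace=False)
        sampled = [passing[i] for i in sorted(idx)]
    else:
        if len(passing) < policy.n_prefilter_sample:
            logger.warning("only %d passing candidates; sampling all",
                           len(passing))
        sampled = passing

    scored = [s for s in sampled if s in structure_scores
              and not np.isnan(structure_scores[s])]
    dropped = set(sampled) - set(scored)
    if dropped:
        logger.warning("%d sampled candidates lack structure scores; "
                       "back-filling from lower ranks", len(dropped))
    ranked = sorted(scored, key=lambda s: (-structure_scores[s], s))
    top = ranked[:policy.top_n_structure]
    if len(top) < policy.n_final:
        raise ValueError("not enough structure-scored candidates to select from")
    pick = rng.choice(len(top), size=min(policy.n_final, len(top)), replace=False)
    selected = [top[i] for i in sorted(pick)]
    return sampled, selected


def match_controls(selected: Sequence[str],
                   failing_pool: Sequence[str],
                   identities: Mapping[str, float],
                   policy: FilterPolicy,
                   rng: np.random.Generator) -> dict[str, str | None]:
    """Pair each selection with an identity-matched filter-failing control.

    Controls are drawn without replacement among pool members whose
    identity-to-training differs from the selection's by at most the
    tolerance; a selection with no in-tolerance candidate is reported as
    unmatched (None), never silently dropped.
    """
    available = list(failing_pool)
    pairing: dict[str, str | None] = {}
    for sel in selected:
        target = identities[sel]
        eligible = [c for c in available
                    if abs(identities[c] - target)
                    <= policy.control_identity_tolerance + 1e-12]
        if not eligible:
            logger.warning("no in-tolerance control for %s", sel)
            pairing[sel] = None
            continue
        choice = eligible[int(rng.integers(len(eligible)))]
        pairing[sel] = choice
        available.remove(choice)
    return pairing


def run_filter(candidates: Sequence[SequenceRecord],
               identities: Mapping[str, float],
               lm_scores: Mapping[str, float],
               structure_scores: Mapping[str, float],
               natural_scores: Sequence[float],
               policy: FilterPolicy | None = None) -> FilterReport:
    """Run the full pipeline for one model-family stratum."""
    policy = policy or FilterPolicy()
    rng = np.random.default_rng(policy.seed)
    cutoff = calibrate(natural_scores, policy)
    passing, failing, reports = sequence_stage(
        candidates, identities, lm_scores, cutoff, policy)
    sampled, selected = structure_stage(passing, structure_scores, policy, rng)
    for s in sampled:
        reports[s].stage_reached = "structure"
    for s in selected:
        reports[s].stage_reached = "selected"
        reports[s].scores["structure_score"] = structure_scores.get(s)
    controls = match_controls(selected, failing, identities, policy, rng)
    stage_counts = {
        "input": len(candidates), "sequence_pass": len(passing),
        "structure_sampled": len(sampled), "selected": len(selected),
        "controls_matched": sum(v is not None for v in controls.values()),
    }
    return FilterReport(policy=policy, cutoff=cutoff, candidates=reports,
                        passing=passing, selected=selected, controls=controls,
                        stage_counts=stage_counts)
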