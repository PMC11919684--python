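"""Seeded synthetic data: families, defects, structures, scorers, plates.

Everything downstream is testable offline with data generated here.  A
*family* is built from a random consensus: training and test sequences are
light mutants of it, candidates are mutants of random training sequences
with a controlled mutation load so their identity to the closest training
sequence lands in a target band.  Candidates optionally carry injected
defects mirroring the failure modes the sequence quality checks screen for
(missing start methionine, homopolymer runs, dimer runs, charge shifts,
out-of-band identity), recorded in a ground-truth manifest.

Mock metric scores and a planted activity label are coupled through the
manifest: defect-free in-band candidates receive systematically higher mock
language-model and structure scores and a higher activity probability, so
qualitative claims about the filter (quality checks help; the composite
filter enriches active sequences) become assertable properties at desk
scale.  None of this emulates real mutational epistasis, phylogenetic
structure, or model-specific artifacts; passing tests show the machinery is
correct, not that any particular generative model is good.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Atom, SequenceRecord, Source, StructureModel, STANDARD_AA
from .assay import PlateSeries, NADH_EPSILON, PLATE_PATH_CM
from .seq_metrics import QualityPolicy, quality_check

DEFECTS = ("no_start_methionine", "homopolymer_run", "dimer_run", "charge_shift",
           "identity_out_of_band")


@dataclass(frozen=True)
class FamilySpec:
    length: int = 80
    n_train: int = 20
    n_test: int = 10
    n_candidates: int = 60
    #: target candidate-to-closest-training identity band
    identity_band: tuple[float, float] = (0.60, 0.75)
    #: fraction of candidates receiving one injected defect
    defect_fraction: float = 0.5
    #: activity probabilities: clean in-band high-score vs anything else
    p_active_good: float = 0.85
    p_active_bad: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.identity_band
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"infeasible identity band {self.identity_band}")


@dataclass
class Family:
    train: list
    test: list
    candidates: list
    #: candidate id -> list of injected defect labels (empty = clean)
    defects: dict
    #: candidate id -> planted activity label (0/1)
    activity: dict
    #: candidate id -> mock scores
    lm_scores: dict
    structure_scores: dict
    consensus: str


def _random_seq(rng: np.random.Generator, length: int,
                start_met: bool = True) -> str:
    letters = [STANDARD_AA[int(i)] for i in rng.integers(0, 20, size=length)]
    if start_met:
        letters[0] = "M"
    return "".join(letters)


def _mutate(rng: np.random.Generator, seq: str, n_mut: int,
            protect_start: bool = True) -> str:
    s = list(seq)
    lo = 1 if protect_start else 0
    positions = rng.choice(np.arange(lo, len(s)), size=min(n_mut, len(s) - lo),
                           replace=False)
    for p in positions:
        choices = [a for a in STANDARD_AA if a != s[p]]
        s[p] = choices[int(rng.integers(19))]
    return "".join(s)


def _clean_mutant(rng: np.random.Generator, base: str, n_mut: int,
                  policy: QualityPolicy, max_tries: int = 50) -> str:
    """A mutant that passes the quality checks (rejection sampling)."""
    for _ in range(max_tries):
        cand = _mutate(rng, base, n_mut)
        if quality_check(cand, policy).passed():
            return cand
    raise RuntimeError("could not produce a defect-free mutant")


def _inject(rng: np.random.Generator, seq: str, defect: str) -> str:
    s = list(seq)
    if defect == "no_start_methionine":
        s[0] = "K"
    elif defect == "homopolymer_run":
        p = int(rng.integers(1, len(s) - 4))
        aa = STANDARD_AA[int(rng.integers(20))]
        s[p:p + 4] = [aa] * 4  # run of 4 > limit 3
    elif defect == "dimer_run":
        p = int(rng.integers(1, len(s) - 6))
        a, b = "L", "A"
        s[p:p + 6] = [a, b, a, b, a, b]  # span 6 > limit 4
    elif defect == "charge_shift":
        # re-draw until the lysine substitutions create no repeat defect
        for _ in range(50):
            trial = list(s)
            idx = rng.choice(np.arange(1, len(trial)), size=min(10, len(trial) - 1),
                             replace=False)
            for p in idx:
                trial[p] = "K"
            if quality_check("".join(trial), QualityPolicy()).passed():
                s = trial
                break
        else:
            raise RuntimeError("could not inject charge shift cleanly")
    else:
        raise ValueError(f"unknown defect {defect!r}")
    return "".join(s)


def make_family(spec: FamilySpec | None = None) -> Family:
    """Generate a synthetic family with ground-truth labels; seeded."""
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    policy = QualityPolicy()
    consensus = _random_seq(rng, spec.length)
    while not quality_check(consensus, policy).passed():
        consensus = _random_seq(rng, spec.length)

    # natural sequences: ~95% identity to the consensus
    n_nat_mut = max(1, round(0.05 * spec.length))
    train = [SequenceRecord(id=f"train_{i:03d}",
                            sequence=_clean_mutant(rng, consensus, n_nat_mut, policy),
                            source=Source.NATURAL_TRAIN)
             for i in range(spec.n_train)]
    test = [SequenceRecord(id=f"test_{i:03d}",
                           sequence=_clean_mutant(rng, consensus, n_nat_mut, policy),
                           source=Source.NATURAL_TEST)
            for i in range(spec.n_test)]

    lo, hi = spec.identity_band
    candidates, defects, activity = [], {}, {}
    lm_scores, structure_scores = {}, {}
    n_defective = round(spec.defect_fraction * spec.n_candidates)
    for i in range(spec.n_candidates):
        base = train[int(rng.integers(spec.n_train))].sequence
        target_ident = float(rng.uniform(lo, hi))
        n_mut = round((1.0 - target_ident) * spec.length)
        cand_defects: list[str] = []
        if i < n_defective:
            defect = DEFECTS[int(rng.integers(len(DEFECTS)))]
            cand_defects.append(defect)
        if "identity_out_of_band" in cand_defects:
            n_mut = round((1.0 - max(0.05, lo - 0.25)) * spec.length)
        seq = _clean_mutant(rng, base, n_mut, policy)
        for defect in cand_defects:
            if defect != "identity_out_of_band":
                seq = _inject(rng, seq, defect)
        cid = f"cand_{i:03d}"
        rec = SequenceRecord(id=cid, sequence=seq, source=Source.GENERATED,
                             model_label="fixture")
        candidates.append(rec)
        defects[cid] = cand_defects

        # coupled mock scores: clean in-band candidates score higher
        good = not cand_defects
        lm_scores[cid] = float((-1.8 if good else -2.6) + rng.normal(0, 0.15))
        structure_scores[cid] = float((-0.9 if good else -1.5)
                                      + rng.normal(0, 0.12))
        high_score = lm_scores[cid] > -2.2
        p = spec.p_active_good if (good and high_score) else spec.p_active_bad
        activity[cid] = int(rng.uniform() < p)

    return Family(train=train, test=test, candidates=candidates,
                  defects=defects, activity=activity, lm_scores=lm_scores,
                  structure_scores=structure_scores, consensus=consensus)


def natural_lm_scores(family: Family, seed: int | None = None) -> list[float]:
    """Mock language-model scores for the natural test split (calibration).

    Centered below the clean-candidate mock distribution so that the
    top-decile natural cutoff is passable by good candidates — the regime
    the selection filter is designed for (threshold-passing generated
    sequences exist).
    """
    spec_seed = seed if seed is not None else 1 + hash(family.consensus) % 10000
    rng = np.random.default_rng(spec_seed)
    return [float(-2.1 + rng.normal(0, 0.12)) for _ in family.test]


# ---------------------------------------------------------------------------
# Toy structures

# idealized alpha-helix: 100 degrees turn and 1.5 A rise per residue
_HELIX_TURN = math.radians(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3

_GLY = "G"


def make_structure(sequence: str, geometry: str = "ideal_helix",
                   confidence_profile=None, name: str = "fixture",
                   chain: str = "A") -> StructureModel:
    """Toy structure: backbone + CB on idealized helical geometry.

    B-factors come from ``confidence_profile`` (a scalar, a sequence of
    per-residue values, or None for 90.0 everywhere).  Geometry is plausible
    enough for surface-area sanity checks, nothing more.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    if geometry != "ideal_helix":
        raise ValueError(f"unknown geometry {geometry!r}")
    if confidence_profile is None:
        conf = [90.0] * len(sequence)
    elif np.isscalar(confidence_profile):
        conf = [float(confidence_profile)] * len(sequence)
    else:
        conf = [float(c) for c in confidence_profile]
        if len(conf) != len(sequence):
            raise ValueError("confidence profile length mismatch")

    three = {aa: name3 for name3, aa in _AA3.items()}
    atoms: list[Atom] = []
    for i, aa in enumerate(sequence):
        theta = i * _HELIX_TURN
        z = i * _HELIX_RISE
        ca = np.array([_HELIX_RADIUS * math.cos(theta),
                       _HELIX_RADIUS * math.sin(theta), z])
        outward = np.array([math.cos(theta), math.sin(theta), 0.0])
        res_name = three.get(aa, "ALA")
        b = conf[i]
        rs = i + 1
        offsets = [
            ("N", "N", ca + np.array([-0.8, 0.6, -0.8])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([0.9, -0.4, 0.9])),
            ("O", "O", ca + np.array([1.1, -1.3, 1.3])),
        ]
        if aa != _GLY:
            offsets.append(("CB", "C", ca + 1.5 * outward))
        for atom_name, element, pos in offsets:
            atoms.append(Atom(chain=chain, res_seq=rs, res_name=res_name,
                              atom_name=atom_name, element=element,
                              x=float(pos[0]), y=float(pos[1]),
                              z=float(pos[2]), bfactor=b))
    return StructureModel(atoms=atoms, name=name)


_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# Synthetic assay plates

def make_plate(truth_table: dict, mode: str = "mdh", noise_sd: float = 0.01,
               seed: int = 0, n_replicates: int = 3,
               times_s: tuple[float, ...] | None = None) -> dict:
    """Synthetic kinetic plate readings for each enzyme in ``truth_table``.

    truth_table maps enzyme id -> true activity level in [0, 1] (1 = wild
    type).  MDH mode: absorbance decays exponentially from the ~1.5 mM NADH
    start at a rate proportional to activity.  SOD mode: formazan absorbance
    grows linearly at a rate scaled down by the enzyme's inhibition.
    Returns {"samples": {id: [PlateSeries x replicates]}, "negative_control":
    [...], and for SOD also "no_sod"/"no_xo"/"blank" controls}.
    """
    rng = np.random.default_rng(seed)
    if times_s is None:
        times_s = tuple(float(t) for t in range(0, 901, 30)) if mode == "mdh" \
            else tuple(float(t) for t in range(0, 1801, 60))
    t = np.asarray(times_s)

    def noisy(values: np.ndarray) -> tuple[float, ...]:
        return tuple(float(v) for v in
                     np.maximum(0.0, values + rng.normal(0, noise_sd, len(values))))

    out: dict = {"samples": {}, "negative_control": []}
    if mode == "mdh":
        a0 = 1.5 * PLATE_PATH_CM * NADH_EPSILON  # ~2.71 A at 1.5 mM NADH
        for rep in range(n_replicates):
            out["negative_control"].append(PlateSeries(
                well=f"neg_{rep}", role="negative_control", replicate=rep,
                times_s=times_s, absorbance=noisy(np.full(len(t), a0))))
        for eid, level in truth_table.items():
            k = 0.004 * level  # s^-1 at wild-type level 1
            curve = a0 * np.exp(-k * t)
            out["samples"][eid] = [PlateSeries(
                well=f"{eid}_{rep}", role="sample", replicate=rep,
                times_s=times_s, absorbance=noisy(curve))
                for rep in range(n_replicates)]
    elif mode == "sod":
        rate = 0.0004  # formazan A450 growth per second, uninhibited
        blank = 0.05
        for rep in range(n_replicates):
            out["negative_control"].append(PlateSeries(
                well=f"neg_{rep}", role="negative_control", replicate=rep,
                times_s=times_s, absorbance=noisy(blank + rate * t)))
        out["no_sod"] = [PlateSeries(
            well=f"nosod_{rep}", role="no_sod", replicate=rep,
            times_s=times_s, absorbance=noisy(blank + rate * t))
            for rep in range(n_replicates)]
        out["blank"] = [PlateSeries(
            well=f"blank_{rep}", role="blank", replicate=rep,
            times_s=times_s, absorbance=noisy(np.full(len(t), blank)))
            for rep in range(n_replicates)]
        for eid, level in truth_table.items():
            inhibition = 0.9 * level
            curve = blank + rate * (1.0 - inhibition) * t
            series = [PlateSeries(
                well=f"{eid}_{rep}", role="sample", replicate=rep,
                times_s=times_s, absorbance=noisy(curve))
                for rep in range(n_replicates)]
            no_xo = PlateSeries(
                well=f"{eid}_noxo", role="no_xo", replicate=0,
                times_s=times_s, absorbance=noisy(np.full(len(t), blank)))
            out["samples"][eid] = series
            out.setdefault("no_xo", {})[eid] = no_xo
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
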