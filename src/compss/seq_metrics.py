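"""Alignment-free single-sequence metrics and sequence quality checks.

The repeat score for unit length *k* is ``-1 x units`` where *units* is the
maximal number of contiguous exact tandem copies of any k-mer anywhere in the
sequence.  AAAAAA therefore scores -6 at k=1 (six copies of ``A``), -3 at k=2
(three copies of ``AA``), -2 at k=3 and -1 at k=4; LALALALA scores -1, -4, -1
and -2 for k=1..4.  Long repeats are a hallmark failure mode of sequences
sampled from masked language models, which is why the quality check caps the
tandem span of 1-mers (at 3 residues) and 2-mers (at 4 residues).

Net charge counts K+R as positive and D+E as negative; histidine is excluded
(its protonation near physiological pH is ambiguous and the charge definition
used throughout deliberately ignores it).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RepeatScore:
    """Tandem-repeat score for unit length ``k`` (1-4)."""

    k: int
    units: int
    #: -1 x units; more negative = longer repeat = worse.
    score: int

    def __post_init__(self) -> None:
        if self.score != -self.units:
            raise ValueError("score must equal -units")


@dataclass(frozen=True)
class ChargeProfile:
    net_charge: int
    abs_net_charge: int
    charged_fraction: float


@dataclass(frozen=True)
class QualityPolicy:
    """Limits for the sequence quality checks.

    ``max_1mer_run`` / ``max_2mer_span`` are maximal allowed spans in
    residues; a run strictly longer fails.  ``extra_kmer_limits`` maps k to a
    maximal span for users who also want 3-/4-mer caps.  ``tm_predictor`` is
    an optional adapter: a callable mapping a sequence to a per-residue
    topology string in which 'M' marks predicted transmembrane residues.
    """

    require_start_met: bool = True
    max_1mer_run: int = 3
    max_2mer_span: int = 4
    extra_kmer_limits: dict[int, int] = field(default_factory=dict)
    tm_predictor: object | None = None


@dataclass(frozen=True)
class QualityCheckResult:
    starts_with_m: bool
    repeat_ok: bool
    tm_free: bool | None  # None = no predictor attached, not held against it
    identity_in_band: bool | None = None
    reasons: tuple[str, ...] = ()

    def passed(self) -> bool:
        checks = [self.starts_with_m, self.repeat_ok]
        if self.tm_free is not None:
            checks.append(self.tm_free)
        if self.identity_in_band is not None:
            checks.append(self.identity_in_band)
        return all(checks)


def tandem_units(sequence: str, k: int) -> int:
    """Maximal count of contiguous exact tandem copies of any k-mer.

    Scans every start offset; a copy counts only when complete (AAAAAA has a
    single complete 4-mer copy, not 1.5).
    """
    n = len(sequence)
    if not 1 <= k <= 4:
        raise ValueError(f"k must be in 1..4, got {k}")
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    best = 1
    i = 0
    while i + k <= n:
        units = 1
        j = i + k
        while j + k <= n and sequence[j:j + k] == sequence[i:i + k]:
            units += 1
            j += k
        best = max(best, units)
        i += 1
    return best


def kmer_repeat_score(sequence: str, k: int) -> RepeatScore:
    """Repeat score = -1 x maximal tandem copy count of any k-mer."""
    units = tandem_units(sequence, k)
    return RepeatScore(k=k, units=units, score=-units)


def max_tandem_span(sequence: str, k: int) -> int:
    """Residue span of the longest k-mer tandem run (= k x units)."""
    return k * tandem_units(sequence, k)


def charge_profile(sequence: str) -> ChargeProfile:
    """Net charge from K/R (+) and D/E (-) counts; H excluded."""
    if not sequence:
        raise ValueError("empty sequence")
    pos = sequence.count("K") + sequence.count("R")
    neg = sequence.count("D") + sequence.count("E")
    net = pos - neg
    return ChargeProfile(net_charge=net, abs_net_charge=abs(net),
                         charged_fraction=(pos + neg) / len(sequence))


def quality_check(sequence: str, policy: QualityPolicy | None = None) -> QualityCheckResult:
    """Apply the sequence quality checks.

    Fails on: missing start methionine; a single-residue run longer than
    ``max_1mer_run``; a residue-pair tandem spanning more than
    ``max_2mer_span`` residues.  When no transmembrane predictor adapter is
    attached, ``tm_free`` is None and does not count against the sequence.
    """
    policy = policy or QualityPolicy()
    reasons: list[str] = []

    starts_with_m = sequence.startswith("M")
    if policy.require_start_met and not starts_with_m:
        reasons.append("no_start_methionine")

    repeat_ok = True
    if len(sequence) >= 1 and max_tandem_span(sequence, 1) > policy.max_1mer_run:
        repeat_ok = False
        reasons.append("homopolymer_run")
    if len(sequence) >= 2 and max_tandem_span(sequence, 2) > policy.max_2mer_span:
        repeat_ok = False
        reasons.append("dimer_run")
    for k, limit in sorted(policy.extra_kmer_limits.items()):
        if len(sequence) >= k and max_tandem_span(sequence, k) > limit:
            repeat_ok = False
            reasons.append(f"{k}mer_run")

    tm_free: bool | None = None
    if policy.tm_predictor is not None:
        topology = policy.tm_predictor(sequence)
        tm_free = "M" not in topology
        if not tm_free:
            reasons.append("transmembrane_domain")

    return QualityCheckResult(
        starts_with_m=starts_with_m or not policy.require_start_met,
        repeat_ok=repeat_ok, tm_free=tm_free, reasons=tuple(reasons))
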