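import numpy as np
import pytest
from Bio.Align import substitution_matrices

from compss.align_metrics import (SubstitutionMatrix, alignment_score,
                                  closest_training, global_align,
                                  mutant_position_mean, topk_mean_homology)
from compss.io import SequenceRecord

B62 = substitution_matrices.load("BLOSUM62")
NEG = -10 ** 9


def gotoh_score(q: str, r: str, open_cost: int = 10, extend_cost: int = 2) -> float:
    """Independent affine-gap global DP (three-state Gotoh); end gaps
    penalized; a length-L gap costs open + L * extend."""
    n, m = len(q), len(r)
    first = open_cost + extend_cost
    M = np.full((n + 1, m + 1), NEG, dtype=float)
    X = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in r (consume q)
    Y = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in q (consume r)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(open_cost + extend_cost * i)
    for j in range(1, m + 1):
        Y[0, j] = -(open_cost + extend_cost * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = B62[q[i - 1], r[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - first, X[i - 1, j] - extend_cost,
                          Y[i - 1, j] - first)
            Y[i, j] = max(M[i, j - 1] - first, Y[i, j - 1] - extend_cost,
                          X[i, j - 1] - first)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def random_alignment_score(q: str, r: str, rng) -> float:
    """Score of one random (not necessarily optimal) global alignment."""
    qi, ri, score, in_gap = 0, 0, 0.0, None
    while qi < len(q) or ri < len(r):
        moves = []
        if qi < len(q) and ri < len(r):
            moves.append("d")
        if qi < len(q):
            moves.append("x")
        if ri < len(r):
            moves.append("y")
        mv = moves[int(rng.integers(len(moves)))]
        if mv == "d":
            score += B62[q[qi], r[ri]]
            qi, ri, in_gap = qi + 1, ri + 1, None
        else:
            score -= 2 if in_gap == mv else 12
            in_gap = mv
            if mv == "x":
                qi += 1
            else:
                ri += 1
    return score


class TestGlobalAlign:
    def test_identity_case(self):
        aln = global_align("MKV", "MKV")
        assert aln.gapped_query == aln.gapped_reference == "MKV"
        assert aln.raw_score == B62["M", "M"] + B62["K", "K"] + B62["V", "V"]
        assert aln.identity() == 1.0

    def test_single_mismatch_identity(self):
        aln = global_align("MKV", "MRV")
        assert aln.identity() == pytest.approx(2 / 3)

    def test_score_matches_independent_dp_oracle(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            q = "".join(rng.choice(aas, size=int(rng.integers(1, 16))))
            r = "".join(rng.choice(aas, size=int(rng.integers(1, 16))))
            assert alignment_score(q, r) == pytest.approx(gotoh_score(q, r)), (q, r)

    def test_optimal_beats_random_alignments(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            q = "".join(rng.choice(aas, size=int(rng.integers(1, 16))))
            r = "".join(rng.choice(aas, size=int(rng.integers(1, 16))))
            opt = alignment_score(q, r)
            for _ in range(10):
                assert opt >= random_alignment_score(q, r, rng) - 1e-9

    def test_symmetry(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            q = "".join(rng.choice(aas, size=12))
            r = "".join(rng.choice(aas, size=10))
            assert alignment_score(q, r) == alignment_score(r, q)

    def test_gap_columns_count_as_mismatch(self):
        aln = global_align("MKVLDAGHERST", "MKVDAGHERST")  # one deletion
        assert "-" in aln.gapped_reference
        assert aln.identity() == pytest.approx(11 / 12)

    def test_alphabet_violation_errors(self):
        with pytest.raises(ValueError):
            global_align("MKB", "MKV")

    def test_gaps_removed_recover_inputs(self, rng):
        aln = global_align("MKVLDAGWQ", "MKVDAGERST")
        assert aln.gapped_query.replace("-", "") == "MKVLDAGWQ"
        assert aln.gapped_reference.replace("-", "") == "MKVDAGERST"


class TestClosestTraining:
    def test_exact_member_found(self, clean_family):
        member = clean_family.train[2]
        hit = closest_training(member.sequence, clean_family.train)
        ref_seq = next(t.sequence for t in clean_family.train
                       if t.id == hit.reference_id)
        assert alignment_score(member.sequence, ref_seq) == \
            alignment_score(member.sequence, member.sequence)

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        train = [SequenceRecord(id="zz", sequence="MKVLD"),
                 SequenceRecord(id="aa", sequence="MKVLD")]
        assert closest_training("MKVLD", train).reference_id == "aa"

    def test_agrees_with_all_pairs_brute_force(self, clean_family):
        for rec in clean_family.candidates[:5]:
            hit = closest_training(rec.sequence, clean_family.train)
            brute = max(clean_family.train,
                        key=lambda t: (alignment_score(rec.sequence, t.sequence),
                                       t.id))
            best = alignment_score(rec.sequence, brute.sequence)
            assert alignment_score(rec.sequence,
                                   next(t.sequence for t in clean_family.train
                                        if t.id == hit.reference_id)) == best

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            closest_training("MKV", [])


class TestMutantPositionMean:
    def test_identical_pair_is_missing(self):
        aln = global_align("MKVLD", "MKVLD")
        assert mutant_position_mean(aln) is None

    def test_two_known_mismatches(self):
        from compss.align_metrics import PairwiseAlignment
        aln = PairwiseAlignment(gapped_query="MKD", gapped_reference="MRE",
                                raw_score=0)
        expected = (B62["K", "R"] + B62["D", "E"]) / 2
        assert mutant_position_mean(aln) == pytest.approx(expected)

    def test_mismatch_opposite_gap_is_missing(self):
        from compss.align_metrics import PairwiseAlignment
        aln = PairwiseAlignment(gapped_query="MKV-", gapped_reference="MKVL",
                                raw_score=0)
        assert mutant_position_mean(aln) is None

    def test_invariant_to_appending_identical_residues(self):
        a1 = global_align("MKDLE", "MRDLE")
        a2 = global_align("MKDLEWWG", "MRDLEWWG")
        assert mutant_position_mean(a1) == mutant_position_mean(a2)


class TestTopkMeanHomology:
    def test_short_set_averages_all(self, clean_family):
        train = clean_family.train[:3]
        q = clean_family.candidates[0].sequence
        expected = np.mean([alignment_score(q, t.sequence) for t in train])
        assert topk_mean_homology(q, train, k=30) == pytest.approx(expected)

    def test_equals_sort_and_average_oracle(self, clean_family):
        q = clean_family.candidates[1].sequence
        scores = sorted((alignment_score(q, t.sequence)
                         for t in clean_family.train), reverse=True)
        k = 4
        assert topk_mean_homology(q, clean_family.train, k=k) == \
            pytest.approx(np.mean(scores[:k]))

    def test_k1_equals_closest_raw_score(self, clean_family):
        q = clean_family.candidates[2].sequence
        hit = closest_training(q, clean_family.train)
        assert topk_mean_homology(q, clean_family.train, k=1) == \
            pytest.approx(hit.alignment.raw_score)

    def test_phmmer_backend_runs(self, clean_family):
        pytest.importorskip("pyhmmer")
        q = clean_family.candidates[0].sequence
        value = topk_mean_homology(q, clean_family.train, k=30,
                                   backend="phmmer")
        assert np.isfinite(value) and value > 0  # bit scores of true homologs

    def test_unknown_backend_errors(self, clean_family):
        with pytest.raises(ValueError, match="internal"):
            topk_mean_homology("MKV", clean_family.train, backend="nope")


class TestMatrixLoading:
    def test_ncbi_format_file_loads(self):
        from importlib.resources import files
        path = files("compss") / "data" / "pfasum15_synthetic.mat"
        m = SubstitutionMatrix.from_ncbi_file(str(path), name="pfasum15_synthetic")
        assert m.score("A", "A") > 0
        assert m.score("K", "R") == m.score("R", "K")
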