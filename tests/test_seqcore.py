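"""Alignment, distance and NG86 counting against independent oracles."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yewmine.seqcore import (
    DNA,
    PROTEIN,
    SENSE_CODONS,
    STANDARD_CODE,
    KsEstimate,
    PairwiseAlignment,
    Scoring,
    SeqError,
    SequenceRecord,
    align_pair,
    codon_pair_differences,
    jc69_correct,
    ng86_ks,
    p_distance,
    synonymous_sites,
)


def brute_force_global(a: str, b: str, scoring: Scoring) -> float:
    """Enumerate every global alignment recursively; return the best score."""

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, s + go(i + 1, j + 1))
        if i < len(a):
            best = max(best, -scoring.gap + go(i + 1, j))
        if j < len(b):
            best = max(best, -scoring.gap + go(i, j + 1))
        return best

    return go(0, 0)


class TestAlignPair:
    def test_ten_mers_one_mismatch(self):
        a = SequenceRecord("a", "ACGTACGTAC")
        b = SequenceRecord("b", "ACGTACGTAT")
        aln = align_pair(a, b, "global", Scoring(match=1, mismatch=0, gap=2))
        assert aln.score == 9
        assert aln.identity == pytest.approx(0.9)
        assert aln.coverage == 1.0

    def test_self_alignment_identity_and_coverage(self):
        for seq, alpha in [("ACGTTGCA", DNA), ("MKTWLVN", PROTEIN)]:
            rec = SequenceRecord("x", seq, alpha)
            for mode in ("global", "local"):
                aln = align_pair(rec, rec, mode)
                assert aln.identity == 1.0
                assert aln.coverage == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(SeqError):
            SequenceRecord("bad", "")

    def test_alphabet_mismatch(self):
        with pytest.raises(SeqError):
            align_pair(SequenceRecord("a", "ACGT"),
                       SequenceRecord("b", "MKWL", PROTEIN))

    def test_matches_exhaustive_enumeration_oracle(self):
        rnd = random.Random(42)
        scoring = Scoring(match=1.0, mismatch=-1.0, gap=2.0)
        for _ in range(40):
            a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 8)))
            b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 8)))
            aln = align_pair(SequenceRecord("a", a), SequenceRecord("b", b),
                             "global", scoring)
            assert aln.score == pytest.approx(
                brute_force_global(a, b, scoring))

    def test_matches_biopython_scores(self):
        """Dual-route check against Bio.Align.PairwiseAligner."""
        from Bio import Align

        rnd = random.Random(7)
        for mode in ("global", "local"):
            al = Align.PairwiseAligner()
            al.mode = mode
            al.match_score, al.mismatch_score = 2, -1
            al.open_gap_score = al.extend_gap_score = -2.5
            for _ in range(60):
                a = "".join(rnd.choice("ACGT")
                            for _ in range(rnd.randint(3, 40)))
                b = "".join(rnd.choice("ACGT")
                            for _ in range(rnd.randint(3, 40)))
                try:
                    mine = align_pair(SequenceRecord("a", a),
                                      SequenceRecord("b", b), mode)
                except SeqError:
                    assert mode == "local" and al.score(a, b) <= 0
                    continue
                assert mine.score == pytest.approx(al.score(a, b))

    def test_score_symmetric_under_swap(self):
        rnd = random.Random(3)
        for _ in range(20):
            a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 20)))
            b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 20)))
            ra, rb = SequenceRecord("a", a), SequenceRecord("b", b)
            assert (align_pair(ra, rb, "global").score
                    == align_pair(rb, ra, "global").score)

    def test_emitted_alignment_scores_consistently(self):
        """The reported score equals the column-sum of the emitted path."""
        rnd = random.Random(9)
        sc = Scoring()
        for _ in range(30):
            a = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(2, 50)))
            b = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(2, 50)))
            aln = align_pair(SequenceRecord("a", a), SequenceRecord("b", b),
                             "global", sc)
            total = 0.0
            for x, y in aln.columns():
                if "-" in (x, y):
                    total -= sc.gap
                elif x == y:
                    total += sc.match
                else:
                    total += sc.mismatch
            assert total == pytest.approx(aln.score)


class TestDistances:
    def test_p_distance_examples(self):
        same = align_pair(SequenceRecord("a", "ACGT" * 25),
                          SequenceRecord("b", "ACGT" * 25), "global")
        assert p_distance(same) == 0.0
        one_off = "ACGT" * 25
        mutated = "T" + one_off[1:]
        aln = align_pair(SequenceRecord("a", one_off),
                         SequenceRecord("b", mutated), "global")
        assert p_distance(aln) == pytest.approx(0.01)

    def test_random_long_sequences_approach_three_quarters(self, rng):
        """Uniform random 1000-mers: expected p-distance 0.75."""
        ps = []
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), 1000))
            b = "".join(rng.choice(list("ACGT"), 1000))
            cols = sum(x != y for x, y in zip(a, b)) / 1000
            ps.append(cols)
        # 95% band for mean of 30 binomial(1000, .75) proportions
        assert abs(np.mean(ps) - 0.75) < 3 * math.sqrt(0.75 * 0.25 / 30000)

    def test_jc69_examples(self):
        assert jc69_correct(0.0) == 0.0
        assert jc69_correct(0.01) == pytest.approx(0.0100672652, abs=1e-8)
        assert math.isnan(jc69_correct(0.75))

    @given(st.floats(min_value=0.0, max_value=0.7499))
    @settings(max_examples=200, deadline=None)
    def test_jc69_monotone_and_dominates_identity(self, p):
        d = jc69_correct(p)
        assert d >= p * (1 - 1e-12)
        eps = 1e-6
        if p + eps < 0.75:
            assert jc69_correct(p + eps) >= d

    def test_ambiguity_columns_excluded(self):
        aln = align_pair(SequenceRecord("a", "ACGTN"),
                         SequenceRecord("b", "ACGTA"), "global")
        assert aln.identity == 1.0
        assert p_distance(aln) == 0.0


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def oracle_pathways(c1: str, c2: str) -> tuple[float, float]:
    """Independent pathway enumeration: walk every order of the differing
    positions explicitly, drop paths through stops, average sd/nd."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        if any(STANDARD_CODE[c] == "*" for c in path[1:-1]):
            continue
        sd = sum(1 for x, y in zip(path, path[1:])
                 if STANDARD_CODE[x] == STANDARD_CODE[y])
        results.append((sd, len(diff) - sd))
    if not results:
        return (float("nan"), float("nan"))
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


class TestNG86:
    def test_identical_cds(self):
        rec = SequenceRecord("a", "ATGGATTTTGGA")
        est = ng86_ks(rec, rec)
        assert est.Sd == 0 and est.ks == 0.0

    def test_hand_checkable_example(self):
        """GGA->GGG is synonymous (Gly); S = (1 + 1/3 + 1/3) per sequence."""
        est = ng86_ks(SequenceRecord("a", "GGAGATTTT"),
                      SequenceRecord("b", "GGGGATTTT"))
        assert est.Sd == 1.0
        assert est.S == pytest.approx(5 / 3)
        assert est.pS == pytest.approx(0.6)

    def test_site_counts_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s = synonymous_sites(codon)
            assert 0.0 <= s <= 3.0

    def test_sense_codon_pairs_match_pathway_oracle(self):
        """All sense-codon pairs with <= 2 differences vs the enumeration
        oracle (the full 61x61 sweep runs in the acceptance suite)."""
        rnd = random.Random(0)
        sample = rnd.sample(
            [(a, b) for a in SENSE_CODONS for b in SENSE_CODONS
             if sum(x != y for x, y in zip(a, b)) <= 2], 400)
        for a, b in sample:
            sd, nd = codon_pair_differences(a, b)
            osd, ond = oracle_pathways(a, b)
            assert sd == pytest.approx(osd)
            assert nd == pytest.approx(ond)

    def test_invariants_on_moderately_diverged_pairs(self, rng):
        """Site/difference count invariants in the estimator's regime: pairs
        derived by point mutation, not saturated random codons."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            c1 = "".join(SENSE_CODONS[i]
                         for i in rng.integers(0, 61, size=n))
            codons = [c1[3 * k:3 * k + 3] for k in range(n)]
            for k in rng.choice(n, size=max(1, n // 5), replace=False):
                alts = [c for c in SENSE_CODONS
                        if sum(x != y for x, y in zip(c, codons[k])) == 1]
                if alts:
                    codons[k] = alts[int(rng.integers(0, len(alts)))]
            c2 = "".join(codons)
            est = ng86_ks(SequenceRecord("a", c1), SequenceRecord("b", c2))
            assert est.S + est.N == pytest.approx(3 * n)
            assert 0 <= est.Sd <= est.S + 1e-9
            assert 0 <= est.pS <= 1
            if not math.isnan(est.ks):
                assert est.ks >= est.pS - 1e-12

    def test_error_conditions(self):
        with pytest.raises(SeqError):
            ng86_ks(SequenceRecord("a", "ATGG"), SequenceRecord("b", "ATGG"))
        with pytest.raises(SeqError):  # internal stop
            ng86_ks(SequenceRecord("a", "TAAATG"),
                    SequenceRecord("b", "ATGATG"))
        with pytest.raises(SeqError):  # length mismatch
            ng86_ks(SequenceRecord("a", "ATGATG"), SequenceRecord("b", "ATG"))

    def test_terminal_stop_stripped(self):
        est = ng86_ks(SequenceRecord("a", "ATGTAA"),
                      SequenceRecord("b", "ATGTAA"))
        assert est.S + est.N == pytest.approx(3.0)

    def test_synonymous_only_simulation_within_band(self, rng):
        """Sequences mutated only at all-synonymous sites recover the planted
        per-synonymous-site substitution count."""
        from yewmine.synthetic_data import mutate_synonymous

        target = 0.2
        estimates = []
        for _ in range(30):
            cds = "".join(SENSE_CODONS[i]
                          for i in rng.integers(0, 61, size=200))
            copy = mutate_synonymous(cds, target, rng)
            est = ng86_ks(SequenceRecord("a", cds), SequenceRecord("b", copy))
            estimates.append(est.ks)
        assert abs(np.median(estimates) - target) < 0.02
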