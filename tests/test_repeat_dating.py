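"""Superfamily filters and K/2r insertion dating."""

import math

import numpy as np
import pytest

from yewmine.repeat_dating import (
    COPIA_RT_QUERY,
    DEFAULT_RATE,
    GYPSY_RT_QUERY,
    FilterConfig,
    InsertionAge,
    LTRElement,
    age_profile,
    classify_element,
    classify_superfamily,
    insertion_time,
    ltr_divergence,
    six_frame_domains,
)
from yewmine.seqcore import PROTEIN, SequenceRecord, align_pair
from yewmine.synthetic_data import mutate_clock

AA = "ACDEFGHIKLMNPQRSTVWY"


def mutant_at_identity(query: SequenceRecord, target: float,
                       rng: np.random.Generator) -> tuple[SequenceRecord, float]:
    """Mutate residues one at a time until measured identity against the
    query first drops to or below ``target``; returns (mutant, identity
    measured with the alignment oracle).

    Local-alignment identity is bounded below (~0.4: the alignment retreats
    to the best-matching segment) and non-monotone in mutation count, so the
    search is capped; if the target is unreachable the closest mutant seen
    is returned with its true measured identity — callers must check it.
    """
    residues = list(query.residues)
    order = rng.permutation(len(residues))
    best: tuple[float, SequenceRecord] | None = None
    for k in range(6 * len(residues)):
        mut = SequenceRecord("mutant", "".join(residues), PROTEIN)
        ident = align_pair(query, mut, "local").identity
        if ident <= target:
            return mut, ident
        if best is None or ident < best[0]:
            best = (ident, mut)
        i = int(order[k % len(order)])
        choices = [a for a in AA if a != residues[i]]
        residues[i] = choices[int(rng.integers(0, len(choices)))]
    return best[1], best[0]


class TestClassification:
    def test_printed_queries_self_classify(self):
        for query, label in [(GYPSY_RT_QUERY, "Gypsy"),
                             (COPIA_RT_QUERY, "Copia")]:
            call = classify_superfamily(query)
            assert call.label == label
            assert call.best_identity == 1.0
            assert call.best_coverage == 1.0

    def test_random_proteins_unclassified(self, rng):
        for _ in range(10):
            seq = "".join(AA[i] for i in rng.integers(0, 20, size=100))
            call = classify_superfamily(SequenceRecord("r", seq, PROTEIN))
            assert call.label == "unclassified"

    def test_identity_threshold_flip(self, rng):
        """Mutants straddling the Copia identity threshold flip the call."""
        above, ident_above = mutant_at_identity(COPIA_RT_QUERY, 0.70, rng)
        assert ident_above >= 0.60
        call = classify_superfamily(above)
        # may be Copia or unclassified if coverage slipped; identity alone
        # cannot unclassify it
        if call.best_coverage >= 0.90:
            assert call.label == "Copia"
        below, ident_below = mutant_at_identity(COPIA_RT_QUERY, 0.55, rng)
        assert ident_below < 0.60
        call = classify_superfamily(below)
        assert call.label != "Copia"

    def test_threshold_monotonicity(self, rng):
        """Raising identity thresholds never converts unclassified to
        classified (seeded trials)."""
        for seed in range(25):
            r = np.random.default_rng(seed)
            target = float(r.uniform(0.45, 0.95))
            mut, _ = mutant_at_identity(GYPSY_RT_QUERY, target, r)
            lax = classify_superfamily(mut, cfg=FilterConfig(
                identity_gypsy=0.4, identity_copia=0.4))
            strict = classify_superfamily(mut, cfg=FilterConfig(
                identity_gypsy=0.8, identity_copia=0.8))
            if lax.label == "unclassified":
                assert strict.label == "unclassified"

    def test_coverage_threshold(self):
        """A perfect-identity fragment below 0.90 query coverage fails."""
        frag = SequenceRecord("frag", GYPSY_RT_QUERY.residues[:50], PROTEIN)
        call = classify_superfamily(frag)
        assert call.best_coverage < 0.90
        assert call.label == "unclassified"

    def test_six_frame_recovers_domain(self, rng):
        from yewmine.synthetic_data import reverse_translate

        dna = reverse_translate(COPIA_RT_QUERY.residues, rng)
        elem = LTRElement(
            element_id="e", chromosome="chr1",
            ltr5=SequenceRecord("l5", "ACGT" * 10),
            ltr3=SequenceRecord("l3", "ACGT" * 10),
            internal_region=SequenceRecord("int", dna))
        call = classify_element(elem)
        assert call.label == "Copia"
        assert call.best_identity == 1.0


class TestDating:
    def test_insertion_time_examples(self):
        assert insertion_time(0.0).t_years == 0.0
        r = DEFAULT_RATE
        assert insertion_time(2 * r).t_years == pytest.approx(1.0)
        age = insertion_time(1.469146e-3)
        assert age.t_mya == pytest.approx(1.0, rel=1e-6)

    def test_linear_in_k_inverse_in_r(self):
        base = insertion_time(0.01)
        assert insertion_time(0.02).t_years == pytest.approx(
            2 * base.t_years)
        doubled_rate = FilterConfig(rate=2 * DEFAULT_RATE)
        assert insertion_time(0.01, doubled_rate).t_years == pytest.approx(
            base.t_years / 2)

    def test_undefined_k_propagates(self):
        age = insertion_time(float("nan"))
        assert not age.defined

    def test_identical_ltrs_k_zero(self):
        e = LTRElement("e", "chr1",
                       SequenceRecord("a", "ACGTTGCA" * 50),
                       SequenceRecord("b", "ACGTTGCA" * 50))
        assert ltr_divergence(e) == 0.0

    def test_single_substitution_k(self):
        seq = "ACGT" * 25
        e = LTRElement("e", "chr1", SequenceRecord("a", seq),
                       SequenceRecord("b", "T" + seq[1:]))
        assert ltr_divergence(e) == pytest.approx(0.01006727, abs=1e-7)

    def test_raw_distance_switch(self):
        seq = "ACGT" * 25
        e = LTRElement("e", "chr1", SequenceRecord("a", seq),
                       SequenceRecord("b", "T" + seq[1:]))
        raw = ltr_divergence(e, FilterConfig(jc_correction=False))
        assert raw == pytest.approx(0.01)

    def test_simulated_divergence_recovered(self, rng):
        """LTR pairs diverged under the JC clock at 0.02 total: mean K within
        the Monte-Carlo band."""
        t_years, rate = 1e6, 1e-8          # 2rt = 0.02
        ks = []
        for _ in range(40):
            anc = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
            e = LTRElement(
                "e", "chr1",
                SequenceRecord("a", mutate_clock(anc, t_years, rate, rng)),
                SequenceRecord("b", mutate_clock(anc, t_years, rate, rng)))
            ks.append(ltr_divergence(e))
        # sd of K per pair ~ sqrt(p(1-p)/n)/ (1-4p/3) ~ 0.0032
        assert abs(np.mean(ks) - 0.02) < 3 * 0.0032 / math.sqrt(40)


class TestAgeProfile:
    def test_identical_ltr_cohort_single_zero_bin(self):
        elems = [LTRElement(f"e{i}", "chr1",
                            SequenceRecord("a", "ACGTTGCA" * 30),
                            SequenceRecord("b", "ACGTTGCA" * 30))
                 for i in range(5)]
        prof = age_profile(elems)
        bins = {b for by in prof.counts.values() for b in by}
        assert bins == {0}
        assert prof.total_dated == 5

    def test_bimodal_cohorts_and_conservation(self, rng):
        elems = []
        for age_mya, n in [(8.0, 30), (24.0, 30)]:
            t = age_mya * 1e6
            for i in range(n):
                anc = "".join("ACGT"[j]
                              for j in rng.integers(0, 4, size=2000))
                elems.append(LTRElement(
                    f"e{age_mya}_{i}", "chr1",
                    SequenceRecord("a", mutate_clock(anc, t, DEFAULT_RATE,
                                                     rng)),
                    SequenceRecord("b", mutate_clock(anc, t, DEFAULT_RATE,
                                                     rng))))
        prof = age_profile(elems)
        assert prof.total_dated + prof.undateable == 60
        merged = {}
        for by in prof.counts.values():
            for b, c in by.items():
                merged[b] = merged.get(b, 0) + c
        # bimodal: most mass concentrates around the two planted ages (the
        # 24-MYA mode is wider: K noise scales ages by ~3 MYA there)
        near_8 = sum(c for b, c in merged.items() if 6 <= b <= 10)
        near_24 = sum(c for b, c in merged.items() if 18 <= b <= 30)
        between = sum(c for b, c in merged.items() if 12 <= b <= 16)
        assert near_8 >= 24 and near_24 >= 24
        assert between <= 3
        # per-cohort medians recover the planted ages
        for planted in (8.0, 24.0):
            cohort = [a.t_mya for eid, _, a in prof.ages
                      if eid.startswith(f"e{planted}_")]
            assert abs(np.median(cohort) - planted) / planted < 0.15
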