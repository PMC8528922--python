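"""Paralog families, median Ks, synteny chaining and duplicate classes."""

import itertools
import math

import numpy as np
import pytest

from conftest import toy_annotation
from yewmine.annotation import AnnotationError
from yewmine.dup_profile import (
    DISPERSED,
    PROXIMAL,
    SINGLETON,
    TANDEM,
    WGD_SEGMENTAL,
    ParalogFamily,
    classify_duplicates,
    cluster_paralog_families,
    family_median_ks,
    find_syntenic_blocks,
    ks_distribution,
)
from yewmine.seqcore import PROTEIN, KsEstimate, SequenceRecord


def ks_estimate(ks: float) -> KsEstimate:
    """A KsEstimate whose corrected ks equals the requested value."""
    ps = 0.75 * -math.expm1(-4.0 * ks / 3.0)
    return KsEstimate(S=100.0, N=200.0, Sd=100.0 * ps, Nd=0.0)


def fam(members, ks_values) -> ParalogFamily:
    f = ParalogFamily("fam_x", tuple(members))
    for i, ks in enumerate(ks_values):
        f.pair_ks[(f"p{i}", f"q{i}")] = ks_estimate(ks)
    return f


class TestFamilies:
    def test_mutually_identical_proteins_one_family(self):
        prots = [SequenceRecord(f"g{i}", "MKTWLVNAGHE" * 10, PROTEIN)
                 for i in range(4)]
        fams = cluster_paralog_families(prots)
        assert len(fams) == 1
        assert fams[0].members == ("g0", "g1", "g2", "g3")
        assert fams[0].family_id == "fam_g0"

    def test_two_unrelated_pairs_two_families(self, rng):
        a = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                    for i in rng.integers(0, 20, size=120))
        b = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                    for i in rng.integers(0, 20, size=120))
        prots = [SequenceRecord("a1", a, PROTEIN),
                 SequenceRecord("a2", a, PROTEIN),
                 SequenceRecord("b1", b, PROTEIN),
                 SequenceRecord("b2", b, PROTEIN)]
        fams = cluster_paralog_families(prots)
        assert [f.members for f in fams] == [("a1", "a2"), ("b1", "b2")]

    def test_duplicate_ids_rejected(self):
        prots = [SequenceRecord("g", "MKTW" * 10, PROTEIN)] * 2
        with pytest.raises(AnnotationError):
            cluster_paralog_families(prots)

    def test_prefilter_matches_full_scan(self, rng):
        """The k-mer prefilter must not change results for related pairs."""
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                       for i in rng.integers(0, 20, size=100))
        prots = [SequenceRecord("x", base, PROTEIN),
                 SequenceRecord("y", base[:50] + base[:50], PROTEIN),
                 SequenceRecord("z", base, PROTEIN)]
        with_filter = cluster_paralog_families(prots, prefilter_k=6)
        without = cluster_paralog_families(prots, prefilter_k=None)
        assert ([f.members for f in with_filter]
                == [f.members for f in without])

    def test_planted_families_recovered(self, small_genome):
        fams = cluster_paralog_families(small_genome.proteins)
        assert (sorted(tuple(f.members) for f in fams)
                == list(small_genome.truth.families))


class TestMedianKs:
    def test_identical_cds_family_zero(self):
        f = fam(["a", "b"], [0.0])
        assert f.median_ks == 0.0

    def test_odd_count_median(self):
        f = fam(["a", "b", "c"], [0.1, 0.2, 0.4])
        assert f.median_ks == pytest.approx(0.2, abs=1e-9)

    def test_even_count_mean_of_central(self):
        f = fam(["a", "b"], [0.1, 0.3])
        assert f.median_ks == pytest.approx(0.2, abs=1e-9)

    def test_no_defined_ks_flagged(self):
        f = ParalogFamily("fam_x", ("a", "b"))
        assert math.isnan(f.median_ks)

    def test_on_demand_computation(self):
        cds = {"a": SequenceRecord("a", "ATGGATTTTGGA"),
               "b": SequenceRecord("b", "ATGGATTTTGGA")}
        f = ParalogFamily("fam_a", ("a", "b"))
        assert family_median_ks(f, cds=cds) == 0.0

    def test_distribution_conservation(self):
        fams = [fam([f"a{i}", f"b{i}"], [0.1]) for i in range(5)]
        fams.append(ParalogFamily("fam_u", ("u", "v")))  # undefined
        hist, undefined = ks_distribution(fams, bin_width=0.05)
        assert sum(hist.values()) == 5
        assert undefined == 1
        assert max(hist, key=hist.get) == 2        # [0.10, 0.15)

    def test_empty_distribution(self):
        assert ks_distribution([]) == ({}, 0)


def oracle_longest_chain(points, max_gap):
    """Independent recursive longest monotone chain (either orientation)."""

    def best_from(i, sign):
        ra, rb = points[i]
        out = 1
        for j in range(len(points)):
            qa, qb = points[j]
            da, db = qa - ra, (qb - rb) * sign
            if 0 < da <= max_gap and 0 < db <= max_gap:
                out = max(out, 1 + best_from(j, sign))
        return out

    return max(best_from(i, s)
               for i in range(len(points)) for s in (1, -1))


class TestSynteny:
    def make(self, n_a=60, n_b=60):
        return toy_annotation({"A": n_a, "B": n_b})

    def pairs_at(self, idx_pairs):
        return [(f"A_g{i}", f"B_g{j}") for i, j in idx_pairs]

    def test_five_collinear_anchors_one_block(self):
        annot = self.make()
        pairs = self.pairs_at([(i, 10 + i) for i in range(5)])
        blocks = find_syntenic_blocks(annot, pairs)
        assert len(blocks) == 1
        assert blocks[0].anchor_count == 5
        assert blocks[0].orientation == "parallel"

    def test_four_anchors_no_block(self):
        annot = self.make()
        blocks = find_syntenic_blocks(
            annot, self.pairs_at([(i, i) for i in range(4)]))
        assert blocks == []

    def test_reversed_order_antiparallel(self):
        annot = self.make()
        pairs = self.pairs_at([(i, 30 - i) for i in range(6)])
        blocks = find_syntenic_blocks(annot, pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "antiparallel"
        assert blocks[0].anchor_count == 6

    def test_gap_boundary(self):
        annot = self.make(160, 160)
        gap = 25                       # default max_gene_gap
        ok = self.pairs_at([(i * gap, i * gap) for i in range(5)])
        assert len(find_syntenic_blocks(annot, ok, max_gene_gap=gap)) == 1
        too_far = self.pairs_at([(i * (gap + 1), i * (gap + 1))
                                 for i in range(5)])
        assert find_syntenic_blocks(annot, too_far, max_gene_gap=gap) == []

    def test_anchors_never_reused_and_monotone(self, small_genome):
        truth_pairs = [tuple(f) for f in small_genome.truth.families]
        blocks = find_syntenic_blocks(small_genome.annotation, truth_pairs)
        seen = set()
        for blk in blocks:
            sign = 1 if blk.orientation == "parallel" else -1
            ranks = [(small_genome.annotation.rank(a),
                      small_genome.annotation.rank(b))
                     for a, b in blk.anchors]
            for (ra1, rb1), (ra2, rb2) in zip(ranks, ranks[1:]):
                assert ra2 > ra1 and (rb2 - rb1) * sign > 0
            for anchor in blk.anchors:
                assert anchor not in seen
                seen.add(anchor)

    def test_matches_chain_oracle_on_random_instances(self):
        annot = self.make(100, 100)
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = int(r.integers(2, 12))
            idx = {(int(a), int(b))
                   for a, b in zip(r.integers(0, 100, n),
                                   r.integers(0, 100, n))}
            points = sorted(idx)
            blocks = find_syntenic_blocks(
                annot, self.pairs_at(points), min_anchors=2, max_gene_gap=10)
            got = max((b.anchor_count for b in blocks), default=1)
            want = oracle_longest_chain(points, max_gap=10)
            assert got == max(want, 1) or (want < 2 and not blocks)


class TestClassification:
    def test_tandem_pair(self):
        annot = toy_annotation({"A": 20})
        fams = [ParalogFamily("f", ("A_g7", "A_g8"))]
        classes = classify_duplicates(annot, fams, [])
        assert classes["A_g7"] == classes["A_g8"] == TANDEM

    def test_proximal_pair(self):
        annot = toy_annotation({"A": 20})
        fams = [ParalogFamily("f", ("A_g12", "A_g7"))]
        classes = classify_duplicates(annot, fams, [], proximal_window=10)
        assert classes["A_g7"] == classes["A_g12"] == PROXIMAL

    def test_dispersed_cross_chromosome(self):
        annot = toy_annotation({"A": 5, "B": 5})
        fams = [ParalogFamily("f", ("A_g1", "B_g3"))]
        classes = classify_duplicates(annot, fams, [])
        assert classes["A_g1"] == classes["B_g3"] == DISPERSED

    def test_window_boundary(self):
        annot = toy_annotation({"A": 30})
        fams = [ParalogFamily("f", ("A_g0", "A_g11"))]   # 10 intervening
        classes = classify_duplicates(annot, fams, [], proximal_window=10)
        assert classes["A_g0"] == PROXIMAL
        fams = [ParalogFamily("f", ("A_g0", "A_g12"))]   # 11 intervening
        classes = classify_duplicates(annot, fams, [], proximal_window=10)
        assert classes["A_g0"] == DISPERSED

    def test_partition_property(self, small_genome):
        fams = cluster_paralog_families(small_genome.proteins)
        pairs = [(f.members[i], f.members[j]) for f in fams
                 for i, j in itertools.combinations(range(len(f.members)), 2)]
        blocks = find_syntenic_blocks(small_genome.annotation, pairs)
        classes = classify_duplicates(small_genome.annotation, fams, blocks)
        assert len(classes) == len(small_genome.annotation)
        assert set(classes.values()) <= {WGD_SEGMENTAL, TANDEM, PROXIMAL,
                                         DISPERSED, SINGLETON}

    def test_planted_classes_recovered_exactly(self, small_genome):
        fams = cluster_paralog_families(small_genome.proteins)
        pairs = [(f.members[i], f.members[j]) for f in fams
                 for i, j in itertools.combinations(range(len(f.members)), 2)]
        blocks = find_syntenic_blocks(small_genome.annotation, pairs)
        classes = classify_duplicates(small_genome.annotation, fams, blocks)
        assert classes == small_genome.truth.duplicate_classes

    def test_no_planted_blocks_no_wgd_calls(self):
        from yewmine import synthetic_data as sd

        spec = sd.SyntheticGenomeSpec(
            seed=3, n_chromosomes=2, genes_per_chromosome=120,
            ltr_cohorts=(),
            duplications=sd.DuplicationPlan(tandem=4, proximal=3,
                                            dispersed=3, segmental_blocks=0),
            cluster=None)
        g = sd.generate(spec)
        fams = cluster_paralog_families(g.proteins)
        pairs = [(f.members[i], f.members[j]) for f in fams
                 for i, j in itertools.combinations(range(len(f.members)), 2)]
        blocks = find_syntenic_blocks(g.annotation, pairs)
        classes = classify_duplicates(g.annotation, fams, blocks)
        assert blocks == []
        assert WGD_SEGMENTAL not in classes.values()
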