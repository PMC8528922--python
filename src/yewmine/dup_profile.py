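"""Paralog families, median-Ks age profiling, synteny blocks and duplicate
type classification.

Whole-genome duplications (WGD) leave two signatures: a shared peak in the
distribution of synonymous divergence (Ks) between paralogs, and widespread
collinear (syntenic) blocks of duplicated genes. This module builds both
signals and classifies every duplicate gene as WGD/segmental (anchor in a
syntenic block), tandem (family partner at the adjacent gene rank), proximal
(partner within a small rank window) or dispersed (everything else); genes in
no family are singletons.

Families are single-linkage connected components over reciprocal
identity/coverage-passing alignments. To keep all-vs-all practical, pairs are
pre-screened with a shared-peptide-k-mer inverted index (k=6 by default);
pairs with no shared k-mer — far below any sensible identity threshold — skip
the exact DP alignment. Set ``prefilter_k=None`` to disable the screen.
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict
from dataclasses import dataclass, field

from yewmine.annotation import Annotation, AnnotationError
from yewmine.seqcore import (
    KsEstimate,
    SeqError,
    SequenceRecord,
    align_pair,
    ng86_ks,
)

DEFAULT_MIN_IDENTITY = 0.5
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GENE_GAP = 25
DEFAULT_PROXIMAL_WINDOW = 10

WGD_SEGMENTAL = "wgd_segmental"
TANDEM = "tandem"
PROXIMAL = "proximal"
DISPERSED = "dispersed"
SINGLETON = "singleton"
CLASS_ORDER = (WGD_SEGMENTAL, TANDEM, PROXIMAL, DISPERSED, SINGLETON)


@dataclass
class ParalogFamily:
    """A connected component of reciprocal-hit paralogs with per-pair Ks."""

    family_id: str
    members: tuple[str, ...]
    pair_ks: dict[tuple[str, str], KsEstimate] = field(default_factory=dict)

    @property
    def median_ks(self) -> float:
        """Median over per-pair defined ks values (even count: mean of the
        central two); NaN when no pair has a defined ks."""
        vals = sorted(e.ks for e in self.pair_ks.values()
                      if not math.isnan(e.ks))
        if not vals:
            return float("nan")
        return statistics.median(vals)


@dataclass(frozen=True)
class SyntenicBlock:
    """A chain of >= min_anchors collinear paralog pairs between two
    chromosome strands (antiparallel when ranks on side b descend)."""

    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]
    orientation: str              # "parallel" | "antiparallel"

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)


def _shared_kmer_pairs(proteins: list[SequenceRecord], k: int) -> set[frozenset]:
    index: dict[str, list[int]] = defaultdict(list)
    for idx, rec in enumerate(proteins):
        for i in range(len(rec.residues) - k + 1):
            index[rec.residues[i:i + k]].append(idx)
    pairs: set[frozenset] = set()
    for ids in index.values():
        uniq = sorted(set(ids))
        if len(uniq) < 2:
            continue
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pairs.add(frozenset((uniq[i], uniq[j])))
    return pairs


def paralog_pairs(proteins: list[SequenceRecord],
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  min_coverage: float = DEFAULT_MIN_COVERAGE,
                  prefilter_k: int | None = 6) -> list[tuple[str, str, float]]:
    """All unordered protein pairs passing reciprocal identity/coverage.

    A pair passes when the local alignment reaches ``min_identity`` and
    covers at least ``min_coverage`` of *both* sequences (reciprocity).
    Returns (id_a, id_b, identity) sorted lexicographically.
    """
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise AnnotationError("duplicate protein ids in paralog search")
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    n = len(proteins)
    if prefilter_k is None:
        candidates = {frozenset((i, j))
                      for i in range(n) for j in range(i + 1, n)}
    else:
        candidates = _shared_kmer_pairs(proteins, prefilter_k)
    out = []
    for pair in candidates:
        i, j = sorted(pair)
        a, b = proteins[i], proteins[j]
        try:
            aln = align_pair(a, b, mode="local")
        except SeqError:
            continue
        if aln.identity < min_identity:
            continue
        aligned_a = sum(1 for c in aln.aligned_query if c != "-")
        aligned_b = sum(1 for c in aln.aligned_subject if c != "-")
        if aligned_a / len(a) < min_coverage or aligned_b / len(b) < min_coverage:
            continue
        x, y = sorted((a.id, b.id))
        out.append((x, y, aln.identity))
    out.sort()
    return out


def cluster_paralog_families(proteins: list[SequenceRecord],
                             min_identity: float = DEFAULT_MIN_IDENTITY,
                             min_coverage: float = DEFAULT_MIN_COVERAGE,
                             prefilter_k: int | None = 6,
                             cds: dict[str, SequenceRecord] | None = None,
                             ) -> list[ParalogFamily]:
    """Single-linkage paralog families from pairwise reciprocal hits.

    Family ids are deterministic: ``fam_<lexicographically smallest member>``.
    When a CDS lookup is supplied, per-pair Ks is computed for every edge of
    each family (codon-aware via protein-guided alignment when lengths
    differ).
    """
    edges = paralog_pairs(proteins, min_identity, min_coverage, prefilter_k)
    parent: dict[str, str] = {p.id: p.id for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = defaultdict(list)
    for p in proteins:
        groups[find(p.id)].append(p.id)
    families = []
    prot_by_id = {p.id: p for p in proteins}
    for root in sorted(groups):
        members = tuple(sorted(groups[root]))
        if len(members) < 2:
            continue
        fam = ParalogFamily(family_id=f"fam_{members[0]}", members=members)
        if cds is not None:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    try:
                        fam.pair_ks[(a, b)] = pair_ks(
                            cds[a], cds[b], prot_by_id.get(a),
                            prot_by_id.get(b))
                    except (SeqError, KeyError):
                        continue
        families.append(fam)
    return families


def pair_ks(cds_a: SequenceRecord, cds_b: SequenceRecord,
            prot_a: SequenceRecord | None = None,
            prot_b: SequenceRecord | None = None) -> KsEstimate:
    """Ks for a CDS pair; unequal lengths are codon-aligned through a global
    protein alignment (gapped codon columns dropped)."""
    if len(cds_a) == len(cds_b):
        return ng86_ks(cds_a, cds_b)
    if prot_a is None or prot_b is None:
        raise SeqError(
            f"CDS lengths differ for {cds_a.id}/{cds_b.id} and no proteins "
            "were given to guide a codon alignment")
    aln = align_pair(prot_a, prot_b, mode="global")
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ca, cb in aln.columns():
        if ca != "-" and cb != "-":
            out_a.append(cds_a.residues[3 * ia:3 * ia + 3])
            out_b.append(cds_b.residues[3 * ib:3 * ib + 3])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    if not out_a:
        raise SeqError(f"no aligned codons for {cds_a.id}/{cds_b.id}")
    return ng86_ks(
        SequenceRecord(cds_a.id, "".join(out_a)),
        SequenceRecord(cds_b.id, "".join(out_b)))


def family_median_ks(family: ParalogFamily,
                     cds: dict[str, SequenceRecord] | None = None,
                     proteins: dict[str, SequenceRecord] | None = None,
                     ) -> float:
    """Median Ks of a family, computing missing per-pair estimates from a CDS
    lookup on demand."""
    if cds is not None:
        for i in range(len(family.members)):
            for j in range(i + 1, len(family.members)):
                a, b = family.members[i], family.members[j]
                if (a, b) in family.pair_ks:
                    continue
                try:
                    family.pair_ks[(a, b)] = pair_ks(
                        cds[a], cds[b],
                        proteins.get(a) if proteins else None,
                        proteins.get(b) if proteins else None)
                except (SeqError, KeyError):
                    continue
    return family.median_ks


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

def _chain_anchors(points: list[tuple[int, int, int]], sign: int,
                   max_gap: int, used: set[int]) -> list[int]:
    """Longest chain (by anchor count) of points monotone increasing in a-rank
    and increasing (sign=+1) / decreasing (sign=-1) in b-rank, consecutive
    steps <= max_gap ranks apart on both sides. Returns point indices."""
    pts = [p for p in points if p[2] not in used]
    pts.sort(key=lambda p: (p[0], sign * p[1]))
    n = len(pts)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        ra, rb, _ = pts[i]
        for j in range(i):
            qa, qb, _ = pts[j]
            da = ra - qa
            db = (rb - qb) * sign
            if da <= 0 or db <= 0:
                continue
            if da > max_gap or db > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not pts:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -pts[i][0]))
    chain = []
    while end != -1:
        chain.append(pts[end][2])
        end = prev[end]
    return list(reversed(chain))


def find_syntenic_blocks(annotation: Annotation,
                         pairs: list[tuple[str, str]],
                         min_anchors: int = DEFAULT_MIN_ANCHORS,
                         max_gene_gap: int = DEFAULT_MAX_GENE_GAP,
                         min_pair_separation: int = DEFAULT_PROXIMAL_WINDOW + 1,
                         ) -> list[SyntenicBlock]:
    """Chain paralog anchor pairs into collinear blocks.

    Greedy longest-chain-first extraction per (chromosome pair, orientation):
    the longest monotone chain with per-step gaps <= max_gene_gap is emitted,
    its anchors are excluded, and the search repeats while chains of at least
    ``min_anchors`` remain.

    Same-chromosome pairs closer than ``min_pair_separation`` intervening
    genes (the tandem/proximal band) are not anchor candidates: runs of local
    duplicates sit near the self-diagonal and would otherwise masquerade as
    collinear segments. Set it to 0 to admit every pair.
    """
    by_cpair: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for idx, (a, b) in enumerate(pairs):
        ga, gb = annotation[a], annotation[b]
        ca, cb = ga.chromosome, gb.chromosome
        ra, rb = annotation.rank(a), annotation.rank(b)
        if ca == cb and abs(ra - rb) - 1 < min_pair_separation:
            continue
        if (cb, rb, b) < (ca, ra, a):
            ca, cb, ra, rb, a, b = cb, ca, rb, ra, b, a
        by_cpair[(ca, cb)].append((ra, rb, idx))
    pair_list = list(pairs)
    blocks = []
    for (ca, cb) in sorted(by_cpair):
        points = by_cpair[(ca, cb)]
        used: set[int] = set()
        while True:
            best_chain: list[int] = []
            best_sign = 1
            for sign in (1, -1):
                chain = _chain_anchors(points, sign, max_gene_gap, used)
                if len(chain) > len(best_chain):
                    best_chain, best_sign = chain, sign
            if len(best_chain) < min_anchors:
                break
            anchors = []
            for idx in best_chain:
                a, b = pair_list[idx]
                if (annotation[b].chromosome, annotation.rank(b), b) < (
                        annotation[a].chromosome, annotation.rank(a), a):
                    a, b = b, a
                anchors.append((a, b))
            used.update(best_chain)
            blocks.append(SyntenicBlock(
                chrom_a=ca, chrom_b=cb, anchors=tuple(anchors),
                orientation="parallel" if best_sign == 1 else "antiparallel"))
    return blocks


# ---------------------------------------------------------------------------
# duplicate classification
# ---------------------------------------------------------------------------

def classify_duplicates(annotation: Annotation,
                        families: list[ParalogFamily],
                        blocks: list[SyntenicBlock],
                        proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
                        ) -> dict[str, str]:
    """One class per annotated gene; precedence
    wgd_segmental > tandem > proximal > dispersed; non-family genes are
    singletons."""
    partners: dict[str, set[str]] = defaultdict(set)
    for fam in families:
        for m in fam.members:
            partners[m] |= set(fam.members) - {m}
    anchored: set[str] = set()
    for blk in blocks:
        for a, b in blk.anchors:
            anchored.add(a)
            anchored.add(b)
    classes: dict[str, str] = {}
    for g in annotation:
        gid = g.gene_id
        if gid not in partners:
            classes[gid] = SINGLETON
            continue
        if gid in anchored:
            classes[gid] = WGD_SEGMENTAL
            continue
        rank = annotation.rank(gid)
        chrom = g.chromosome
        best = DISPERSED
        for p in partners[gid]:
            gp = annotation[p]
            if gp.chromosome != chrom:
                continue
            gap = abs(annotation.rank(p) - rank)
            if gap == 1:
                best = TANDEM
                break
            if gap - 1 <= proximal_window:
                best = PROXIMAL
        classes[gid] = best
    return classes


def ks_distribution(families: list[ParalogFamily],
                    bin_width: float = 0.05) -> tuple[dict[int, int], int]:
    """Histogram of family median Ks: (bin index -> count, undefined count).

    Bin i covers [i * bin_width, (i+1) * bin_width).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist: dict[int, int] = {}
    undefined = 0
    for fam in families:
        m = fam.median_ks
        if math.isnan(m):
            undefined += 1
            continue
        b = int(m // bin_width)
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items())), undefined
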