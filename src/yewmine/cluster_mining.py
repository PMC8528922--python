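"""Biosynthetic gene-cluster mining by the gene-distance rule.

Given a set of pathway reference proteins (the Taxol route: GGPPS, TXS, the
CYP725A taxoid hydroxylases T5aOH/T10bOH/T2aOH/T7bOH/T13aOH, and the
acyltransferases TAT, DBAT, TBT, BAPT, DBTNBT), homologs are identified in
the annotated proteome by local alignment under identity/coverage thresholds.
Hits on one chromosome whose *gene distance* — the number of annotated gene
models between them — is strictly below a cutoff (default 10) chain into a
cluster; clusters can then be partitioned into sub-clusters at their largest
internal base-pair gaps (the "artificial" sub-cluster divisions of large
clusters).

The bundled reference set is synthetic: deterministic stand-in peptides keyed
by the pathway role names, generated by :func:`synthetic_reference_proteins`.
Real reference accessions can be supplied as a role-tagged FASTA instead.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field

from yewmine.annotation import Annotation
from yewmine.seqcore import (
    PROTEIN,
    SeqError,
    SequenceRecord,
    align_pair,
)

PATHWAY_ROLES = (
    "GGPPS", "TXS", "T5aOH", "T10bOH", "T2aOH", "T7bOH", "T13aOH",
    "TAT", "DBAT", "TBT", "BAPT", "DBTNBT",
)
CYP_UNASSIGNED = "CYP725-unassigned"
#: roles encoded by CYP725A-family P450s (carry the conserved P450 domain)
CYP_ROLES = {"T5aOH", "T10bOH", "T2aOH", "T7bOH", "T13aOH"}

DEFAULT_MIN_IDENTITY = 0.6
DEFAULT_MIN_COVERAGE = 0.6
DEFAULT_MAX_DISTANCE = 10
DEFAULT_MIN_SIZE = 2

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class MiningError(ValueError):
    pass


def synthetic_reference_proteins(length: int = 180) -> dict[str, SequenceRecord]:
    """Deterministic synthetic stand-ins for the pathway reference proteins.

    One pseudo-random peptide per role (seeded by the role name, so the set
    is stable across runs and machines), plus a shared conserved "P450
    domain" segment spliced into every CYP-family role — the hook used to
    flag CYP725-like proteins that match no specific role.
    """
    domain = _synthetic_p450_domain()
    refs: dict[str, SequenceRecord] = {}
    for role in PATHWAY_ROLES:
        rng = random.Random(f"yewmine-ref-{role}")
        body = "".join(rng.choice(_AA20) for _ in range(length))
        if role in CYP_ROLES:
            mid = length // 2
            body = body[:mid] + domain.residues + body[mid:]
        refs[role] = SequenceRecord(role, body, alphabet=PROTEIN)
    return refs


def _synthetic_p450_domain(length: int = 60) -> SequenceRecord:
    """Synthetic conserved-domain reference (a PF00067-style P450 signature
    stand-in); shared verbatim by every synthetic CYP-family reference."""
    rng = random.Random("yewmine-ref-P450-domain")
    return SequenceRecord("P450_domain",
                          "".join(rng.choice(_AA20) for _ in range(length)),
                          alphabet=PROTEIN)


P450_DOMAIN = _synthetic_p450_domain()


@dataclass(frozen=True)
class PathwayGeneHit:
    gene_id: str
    role: str
    best_identity: float
    best_coverage: float
    reference_id: str


@dataclass
class GeneCluster:
    """Hits chained by the gene-distance rule on one chromosome, in rank
    order, with an optional ordered sub-cluster partition."""

    cluster_id: str
    chromosome: str
    members: tuple[str, ...]
    span: int
    sub_clusters: tuple[tuple[str, ...], ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


def identify_pathway_homologs(proteins: list[SequenceRecord],
                              references: dict[str, SequenceRecord] | None = None,
                              min_identity: float = DEFAULT_MIN_IDENTITY,
                              min_coverage: float = DEFAULT_MIN_COVERAGE,
                              domain_reference: SequenceRecord | None = None,
                              domain_min_identity: float = 0.6,
                              ) -> list[PathwayGeneHit]:
    """Assign each protein the role of its best-scoring passing reference.

    The reference is the alignment query, so coverage is reference coverage
    (BLAST-style). Proteins matching no role reference but passing the
    conserved-domain screen are reported as CYP725-unassigned.
    """
    if references is None:
        references = synthetic_reference_proteins()
    if not references:
        raise MiningError("empty reference set")
    if domain_reference is None:
        domain_reference = P450_DOMAIN
    hits = []
    for prot in proteins:
        best = None  # (score, role, identity, coverage, ref id)
        for role, ref in references.items():
            try:
                aln = align_pair(ref, prot, mode="local")
            except SeqError:
                continue
            if aln.identity >= min_identity and aln.coverage >= min_coverage:
                key = (aln.score, aln.identity)
                if best is None or key > (best[0], best[2]):
                    best = (aln.score, role, aln.identity, aln.coverage,
                            ref.id)
        if best is not None:
            _, role, ident, cov, ref_id = best
            hits.append(PathwayGeneHit(prot.id, role, ident, cov, ref_id))
            continue
        try:
            daln = align_pair(domain_reference, prot, mode="local")
        except SeqError:
            continue
        if (daln.identity >= domain_min_identity
                and daln.coverage >= min_coverage):
            hits.append(PathwayGeneHit(prot.id, CYP_UNASSIGNED,
                                       daln.identity, daln.coverage,
                                       domain_reference.id))
    return hits


def gene_distance(a: str, b: str, annotation: Annotation) -> int | None:
    """Number of annotated gene models between two genes; None across
    chromosomes (see :meth:`Annotation.gene_distance`)."""
    return annotation.gene_distance(a, b)


def mine_clusters(hits: list[PathwayGeneHit], annotation: Annotation,
                  max_distance: int = DEFAULT_MAX_DISTANCE,
                  min_size: int = DEFAULT_MIN_SIZE) -> list[GeneCluster]:
    """Chain hit genes into clusters where consecutive hits (in rank order on
    one chromosome) are strictly less than ``max_distance`` gene models
    apart; chains shorter than ``min_size`` are dropped.

    Cluster ids are deterministic: ``cluster_<chrom>_<leftmost rank>``.
    Input order of hits is irrelevant.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    seen: set[str] = set()
    for h in hits:
        if h.gene_id in seen:
            continue
        seen.add(h.gene_id)
        g = annotation[h.gene_id]
        by_chrom[g.chromosome].append((annotation.rank(h.gene_id), h.gene_id))
    clusters = []
    for chrom in sorted(by_chrom):
        ranked = sorted(by_chrom[chrom])
        chain: list[tuple[int, str]] = []
        for rank, gid in ranked + [(None, None)]:
            if chain and (rank is None
                          or rank - chain[-1][0] - 1 >= max_distance):
                if len(chain) >= min_size:
                    members = tuple(g for _, g in chain)
                    clusters.append(GeneCluster(
                        cluster_id=f"cluster_{chrom}_{chain[0][0]}",
                        chromosome=chrom, members=members,
                        span=cluster_span(members, annotation)))
                chain = []
            if rank is not None:
                chain.append((rank, gid))
    return clusters


def cluster_span(members, annotation: Annotation) -> int:
    """max(end) - min(start) over member genes (bp, 0-based half-open)."""
    genes = [annotation[m] for m in members]
    if not genes:
        raise MiningError("span of an empty cluster")
    return max(g.end for g in genes) - min(g.start for g in genes)


def partition_subclusters(cluster: GeneCluster, annotation: Annotation,
                          k: int | None = None,
                          breakpoints: list[int] | None = None,
                          ) -> GeneCluster:
    """Split a cluster into ordered sub-clusters.

    Default: cut at the (k-1) largest internal bp gaps (gap = next gene start
    minus previous gene end). ``breakpoints`` (member indices at which a new
    sub-cluster starts) override the gap heuristic.
    """
    members = list(cluster.members)
    if not members:
        raise MiningError("cannot partition an empty cluster")
    if breakpoints is not None:
        cuts = sorted(set(breakpoints))
        if any(c <= 0 or c >= len(members) for c in cuts):
            raise MiningError("breakpoints must be internal member indices")
    else:
        if k is None:
            k = 1
        if k < 1 or k > len(members):
            raise MiningError(
                f"k={k} sub-clusters impossible for {len(members)} members")
        gaps = []
        for i in range(1, len(members)):
            gap = annotation[members[i]].start - annotation[members[i - 1]].end
            gaps.append((gap, i))
        # largest gaps win; ties resolved to the leftmost cut
        gaps.sort(key=lambda t: (-t[0], t[1]))
        cuts = sorted(i for _, i in gaps[:k - 1])
    subs = []
    prev = 0
    for c in cuts + [len(members)]:
        subs.append(tuple(members[prev:c]))
        prev = c
    cluster.sub_clusters = tuple(subs)
    return cluster


def validate_cluster(cluster: GeneCluster, annotation: Annotation,
                     max_distance: int = DEFAULT_MAX_DISTANCE) -> bool:
    """Re-check a cluster's defining invariant by direct scan: consecutive
    members strictly closer than ``max_distance`` gene models, one
    chromosome, rank-ordered."""
    genes = [annotation[m] for m in cluster.members]
    if any(g.chromosome != cluster.chromosome for g in genes):
        return False
    ranks = [annotation.rank(m) for m in cluster.members]
    if ranks != sorted(ranks):
        return False
    for r1, r2 in zip(ranks, ranks[1:]):
        if r2 - r1 - 1 >= max_distance:
            return False
    if cluster.sub_clusters:
        flat = tuple(g for sub in cluster.sub_clusters for g in sub)
        if flat != cluster.members:
            return False
    return True
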