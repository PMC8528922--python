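"""Deterministic synthetic genome generator with planted ground truth.

This is the acceptance surface for the whole pipeline: a miniature genome
(default 4 chromosomes x 300 genes, ~2 Mb each) in which every analysis
target is planted by construction —

* LTR retrotransposon cohorts diverged under a Jukes-Cantor clock at rate r
  from shared ancestral repeats, so dating them back with t = K/2r has a
  known answer;
* paralog pairs in tandem / proximal / dispersed / collinear-block layouts,
  mutated synonymously to target Ks values, so family clustering, median-Ks
  profiling and duplicate-type classification have exact truth;
* one biosynthetic gene cluster (role genes plus CYP725-like genes) with
  internal gene distances < 10 and flanking gaps >= 10, laid out in three
  bp-gap-separated sub-clusters;
* a five-tissue x three-replicate FPKM matrix in which cluster genes share a
  correlated bark-high latent profile.

All randomness flows from one ``numpy.random.default_rng(seed)``; identical
spec + seed reproduce byte-identical output files. Genes are placed on the
forward strand only (transcriptional strand affects none of the statistics
computed downstream); this and other simplifications are documented in the
methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from yewmine.annotation import Annotation, GeneModel, write_gff3
from yewmine.cluster_mining import (
    CYP_UNASSIGNED,
    _synthetic_p450_domain,
    synthetic_reference_proteins,
)
from yewmine.coexpression import TISSUES
from yewmine.dup_profile import DEFAULT_MAX_GENE_GAP
from yewmine.repeat_dating import (
    COPIA_RT_QUERY,
    DEFAULT_RATE,
    GYPSY_RT_QUERY,
    LTRElement,
    YEARS_PER_MY,
)
from yewmine.seqcore import (
    DNA,
    PROTEIN,
    STANDARD_CODE,
    SENSE_CODONS,
    SequenceRecord,
    synonymous_sites,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: codons per amino acid (standard code), sorted for determinism
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(STANDARD_CODE[_codon], []).append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()
# no codon exists for the rare 'O' (Pyl) code seen in legacy printed domains;
# reverse-translate it as Leu
_CODONS_FOR_AA.setdefault("O", ["CTG"])
_CODONS_FOR_AA.setdefault("X", ["GCT"])


class GenerationError(ValueError):
    """Raised when a planted layout cannot fit the requested genome."""


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTRCohort:
    age_mya: float
    count: int
    ltr_length: int = 2000
    superfamily: str = "Gypsy"       # "Gypsy" | "Copia"


@dataclass(frozen=True)
class DuplicationPlan:
    """Counts of planted duplicate pairs per type and target Ks per cohort.

    ``segmental_blocks`` collinear blocks of ``segmental_anchors`` anchor
    pairs each are planted across two chromosomes.
    """

    tandem: int = 20
    proximal: int = 15
    dispersed: int = 15
    segmental_blocks: int = 2
    segmental_anchors: int = 6
    target_ks: dict = field(default_factory=lambda: {
        "tandem": 0.1, "proximal": 0.1, "dispersed": 0.3, "segmental": 0.1})


@dataclass(frozen=True)
class ClusterPlan:
    """Planted pathway cluster: ordered roles, the gene distance (number of
    intervening background genes) before each member after the first, and the
    member indices at which new sub-clusters start."""

    roles: tuple[str, ...] = tuple(
        [CYP_UNASSIGNED] * 12 + ["TXS", "T5aOH"]
        + ["T10bOH", "T2aOH", "T7bOH", "T13aOH"])
    internal_distances: tuple[int, ...] = (
        0, 1, 0, 2, 0, 0, 1, 0, 0, 2, 0,        # within sub-cluster I
        4,                                       # I -> II boundary
        0,                                       # within II
        5,                                       # II -> III boundary
        0, 1, 0)                                 # within III
    sub_cluster_starts: tuple[int, ...] = (12, 14)
    flank_gap: int = 12             # background genes kept hit-free each side
    boundary_spacer: int = 300_000  # bp of intergenic at sub-cluster cuts

    def __post_init__(self) -> None:
        if len(self.internal_distances) != len(self.roles) - 1:
            raise GenerationError(
                "need one internal distance per cluster member after the first")
        if any(d >= 10 for d in self.internal_distances):
            raise GenerationError("planted internal gene distances must be < 10")
        if self.flank_gap < 10:
            raise GenerationError("flank gaps must be >= 10 gene models")


@dataclass(frozen=True)
class ExpressionPlan:
    """Bark-high module profile and noise levels for the FPKM matrix."""

    replicates: int = 3
    module_profile: tuple[float, ...] = (5.0, 8.0, 12.0, 120.0, 6.0)
    module_correlation: float = 0.95
    profile_sigma: float = 0.25       # per-gene log-profile jitter (log2)
    replicate_sigma: float = 0.25     # log-normal replicate noise (natural log)
    background_log2_mean: float = 3.0
    background_log2_sigma: float = 1.5


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 300
    cds_codons: tuple[int, int] = (120, 220)        # uniform range
    exons_per_gene: tuple[int, int] = (2, 5)
    intron_length: tuple[int, int] = (80, 2_000)
    intergenic_length: tuple[int, int] = (500, 3_000)
    ltr_cohorts: tuple[LTRCohort, ...] = (
        LTRCohort(1.0, 200, 2000, "Gypsy"),
        LTRCohort(8.0, 200, 2000, "Gypsy"),
        LTRCohort(24.0, 200, 2000, "Copia"),
    )
    duplications: DuplicationPlan = field(default_factory=DuplicationPlan)
    cluster: ClusterPlan | None = field(default_factory=ClusterPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    rate: float = DEFAULT_RATE


@dataclass
class GroundTruth:
    """What was planted, keyed the way the analysis modules report."""

    ltr_ages: dict[str, tuple[float, str]]          # element -> (MYA, family)
    families: list[tuple[str, ...]]                 # planted family groups
    family_target_ks: dict[tuple[str, ...], float]
    duplicate_classes: dict[str, str]               # gene -> class
    pathway_roles: dict[str, str]                   # gene -> role
    cluster_members: tuple[str, ...]
    cluster_sub_clusters: tuple[tuple[str, ...], ...]
    cluster_chromosome: str
    cluster_span: int
    module_genes: tuple[str, ...]
    anchor_genes: tuple[str, ...]


@dataclass
class SyntheticGenome:
    """Everything :func:`generate` produces, in memory."""

    spec: SyntheticGenomeSpec
    genome: dict[str, str]
    annotation: Annotation
    proteins: list[SequenceRecord]
    cds: dict[str, SequenceRecord]
    ltr_elements: list[LTRElement]
    fpkm: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Emit the full fixture set; returns {name: path}."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def p(name):
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        write_fasta(
            (SequenceRecord(c, self.genome[c]) for c in sorted(self.genome)),
            p("genome.fa"))
        write_gff3(self.annotation, p("annotation.gff3"))
        write_fasta(self.proteins, p("proteins.fa"))
        write_fasta((self.cds[k] for k in sorted(self.cds)), p("cds.fa"))
        with open(p("ltr_elements.tsv"), "w") as fh:
            fh.write("element_id\tchrom\tltr5_start\tltr5_end\t"
                     "ltr3_start\tltr3_end\n")
            for e in self.ltr_elements:
                (s5, e5), (s3, e3) = e.coordinates[0], e.coordinates[-1]
                fh.write(f"{e.element_id}\t{e.chromosome}\t{s5}\t{e5}\t"
                         f"{s3}\t{e3}\n")
        self.fpkm.to_csv(p("expression_fpkm.tsv"), sep="\t",
                         float_format="%.6g")
        self.samples.to_csv(p("samples.tsv"), sep="\t")
        t = self.truth
        with open(p("truth_ltr_ages.tsv"), "w") as fh:
            fh.write("element_id\tage_mya\tsuperfamily\n")
            for eid in sorted(t.ltr_ages):
                age, fam = t.ltr_ages[eid]
                fh.write(f"{eid}\t{age:.6g}\t{fam}\n")
        with open(p("truth_duplicate_classes.tsv"), "w") as fh:
            fh.write("gene_id\tclass\n")
            for gid in sorted(t.duplicate_classes):
                fh.write(f"{gid}\t{t.duplicate_classes[gid]}\n")
        with open(p("truth_families.tsv"), "w") as fh:
            fh.write("family_members\ttarget_ks\n")
            for fam in sorted(t.families):
                ks = t.family_target_ks.get(fam, float("nan"))
                fh.write(",".join(fam) + f"\t{ks:.6g}\n")
        with open(p("truth_cluster.tsv"), "w") as fh:
            fh.write("gene_id\trole\tsub_cluster\n")
            sub_of = {g: i + 1 for i, sub in enumerate(t.cluster_sub_clusters)
                      for g in sub}
            for gid in t.cluster_members:
                fh.write(f"{gid}\t{t.pathway_roles[gid]}\t{sub_of[gid]}\n")
        with open(p("truth_module.tsv"), "w") as fh:
            fh.write("gene_id\trole_in_module\n")
            for gid in t.module_genes:
                kind = "anchor" if gid in t.anchor_genes else "member"
                fh.write(f"{gid}\t{kind}\n")
        return paths


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def translate(cds: str) -> str:
    return "".join(STANDARD_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """DNA coding for ``peptide`` with codons drawn uniformly per residue."""
    out = []
    for aa in peptide:
        choices = _CODONS_FOR_AA[aa]
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def mutate_clock(seq: str, t_years: float, rate: float,
                 rng: np.random.Generator) -> str:
    """Jukes-Cantor substitutions for ``t_years`` at ``rate`` per site/year.

    Each site differs from the ancestor with probability
    (3/4)(1 - exp(-4 d / 3)), d = t * r, landing uniformly on the three other
    bases — the exact JC transition kernel, so expected p-distance to the
    ancestor matches the closed form and divergence is additive on the two
    halves of an LTR pair.
    """
    if t_years < 0 or rate < 0:
        raise GenerationError("time and rate must be non-negative")
    if not seq:
        raise GenerationError("cannot mutate an empty sequence")
    d = t_years * rate
    p_change = 0.75 * -math.expm1(-4.0 * d / 3.0)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < p_change
    idx = np.nonzero(hit)[0]
    if len(idx):
        cur = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=len(idx))
        arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode("ascii")


def mutate_synonymous(cds: str, target_ks: float,
                      rng: np.random.Generator) -> str:
    """Apply synonymous substitutions so an NG86 estimate of Ks against the
    input lands at ``target_ks``.

    Only positions whose every non-stop single-base alternative is synonymous
    (mostly four-fold third positions) are touched, so the protein is
    unchanged and every planted difference counts as one synonymous
    difference. The number of substituted sites is ceil(pS_target * S) with
    pS_target the JC inverse of the target — an expected-count scheme, no
    rejection loop.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    free = []          # (codon index, position) with all-synonymous changes
    S = 0.0
    for ci, codon in enumerate(codons):
        S += synonymous_sites(codon)
        for pos in range(3):
            alts = []
            ok = True
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if STANDARD_CODE[alt] == "*":
                    continue
                if STANDARD_CODE[alt] != STANDARD_CODE[codon]:
                    ok = False
                alts.append(alt)
            if ok and alts:
                free.append((ci, pos))
    pS_target = 0.75 * -math.expm1(-4.0 * target_ks / 3.0)
    m = math.ceil(pS_target * S)
    if m > len(free):
        raise GenerationError(
            f"target Ks {target_ks} needs {m} free synonymous sites but the "
            f"CDS has only {len(free)}")
    chosen = rng.choice(len(free), size=m, replace=False)
    for k in sorted(chosen):
        ci, pos = free[k]
        codon = codons[ci]
        alts = sorted(
            codon[:pos] + b + codon[pos + 1:]
            for b in "ACGT"
            if b != codon[pos]
            and STANDARD_CODE[codon[:pos] + b + codon[pos + 1:]] != "*")
        codons[ci] = alts[rng.integers(0, len(alts))]
    return "".join(codons)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def plant_expression(gene_classes: dict[str, str],
                     plan: ExpressionPlan,
                     rng: np.random.Generator,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (genes x samples) and sample sheet.

    ``gene_classes`` maps gene id -> "module" or "background". Module genes
    share the plan's bark-high latent profile, jittered per gene in log2
    space by ``profile_sigma``; background genes draw independent log-normal
    tissue profiles. Every sample gets multiplicative log-normal replicate
    noise (sigma = ``replicate_sigma``; zero sigma means identical
    replicates).
    """
    genes = list(gene_classes)
    n_t = len(TISSUES)
    base = np.log2(np.asarray(plan.module_profile, dtype=float))
    if len(base) != n_t:
        raise GenerationError("module_profile must have one value per tissue")
    means = np.empty((len(genes), n_t))
    for gi, g in enumerate(genes):
        if gene_classes[g] == "module":
            means[gi] = base + rng.normal(0.0, plan.profile_sigma, size=n_t)
        else:
            means[gi] = rng.normal(plan.background_log2_mean,
                                   plan.background_log2_sigma, size=n_t)
    mean_fpkm = np.power(2.0, means)
    cols = []
    data = []
    for ti, tissue in enumerate(TISSUES):
        for rep in range(1, plan.replicates + 1):
            cols.append(f"{tissue}_r{rep}")
            noise = (np.exp(rng.normal(0.0, plan.replicate_sigma,
                                       size=len(genes)))
                     if plan.replicate_sigma > 0 else np.ones(len(genes)))
            data.append(mean_fpkm[:, ti] * noise)
    fpkm = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    fpkm.index.name = "gene_id"
    samples = pd.DataFrame(
        {"tissue": [c.rsplit("_r", 1)[0] for c in cols],
         "replicate": [int(c.rsplit("_r", 1)[1]) for c in cols]},
        index=pd.Index(cols, name="sample_id"))
    return fpkm, samples


def generate_expression_module(n_module: int = 50, n_background: int = 500,
                               plan: ExpressionPlan | None = None,
                               seed: int = 0):
    """Stand-alone planted co-expression instance (no genome needed):
    returns (ExpressionMatrix, module gene ids, background gene ids)."""
    from yewmine.coexpression import ExpressionMatrix

    plan = plan or ExpressionPlan()
    rng = np.random.default_rng(seed)
    classes = {f"mod{i:04d}": "module" for i in range(n_module)}
    classes.update({f"bg{i:04d}": "background" for i in range(n_background)})
    fpkm, samples = plant_expression(classes, plan, rng)
    m = ExpressionMatrix(fpkm=fpkm, samples=samples)
    return (m, [g for g, c in classes.items() if c == "module"],
            [g for g, c in classes.items() if c == "background"])


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _gene_id(chrom_i: int, idx: int) -> str:
    return f"Ty{chrom_i + 1:02d}G{idx:04d}"


def generate(spec: SyntheticGenomeSpec | None = None) -> SyntheticGenome:
    """Build the synthetic genome, annotation, sequences, LTR table,
    expression matrix and ground truth for a spec (deterministic per seed)."""
    spec = spec or SyntheticGenomeSpec()
    rng = np.random.default_rng(spec.seed)
    n_chrom = spec.n_chromosomes
    n_genes = spec.genes_per_chromosome
    if n_chrom < 1 or n_genes < 1:
        raise GenerationError("need at least one chromosome and one gene")

    # --- 1. reserve gene slots for planted features -----------------------
    # plan[c][i] = ("background",) | ("cds", dna) | ("protein", peptide, role)
    plan: list[list[tuple | None]] = [[None] * n_genes for _ in range(n_chrom)]
    spacer_before: dict[tuple[int, int], int] = {}
    truth_classes: dict[str, str] = {}
    families: list[tuple[str, ...]] = []
    family_ks: dict[tuple[str, ...], float] = {}
    cursor = [0] * n_chrom     # next free slot per chromosome

    def take(chrom_i: int, count: int, gap_after: int = 2) -> list[int]:
        """Reserve ``count`` consecutive slots, leaving a small gap after."""
        start = cursor[chrom_i]
        if start + count > n_genes:
            raise GenerationError(
                f"planted features exceed capacity of chromosome "
                f"{chrom_i + 1}: need slot {start + count}, have {n_genes}")
        cursor[chrom_i] = start + count + gap_after
        return list(range(start, start + count))

    dup = spec.duplications

    def plant_pair(slots_a: tuple[int, int], slots_b: tuple[int, int],
                   kind: str, ks: float) -> None:
        (ca, ia), (cb, ib) = slots_a, slots_b
        n_codons = int(rng.integers(*spec.cds_codons))
        src = _random_cds(rng, n_codons)
        copy = mutate_synonymous(src, ks, rng)
        plan[ca][ia] = ("cds", src)
        plan[cb][ib] = ("cds", copy)
        ga, gb = _gene_id(ca, ia), _gene_id(cb, ib)
        truth_classes[ga] = truth_classes[gb] = kind
        fam = tuple(sorted((ga, gb)))
        families.append(fam)
        family_ks[fam] = ks

    # tandem: adjacent ranks on a rotating chromosome
    for k in range(dup.tandem):
        c = k % n_chrom
        i, j = take(c, 2)
        plant_pair((c, i), (c, j), "tandem", dup.target_ks["tandem"])
    # proximal: 2-5 intervening background genes
    for k in range(dup.proximal):
        c = k % n_chrom
        gap = 2 + int(rng.integers(0, 4))
        slots = take(c, gap + 2)
        plant_pair((c, slots[0]), (c, slots[-1]), "proximal",
                   dup.target_ks["proximal"])
    # dispersed: different chromosomes
    if dup.dispersed and n_chrom < 2:
        raise GenerationError("dispersed duplicates need >= 2 chromosomes")
    for k in range(dup.dispersed):
        ca = k % n_chrom
        cb = (k + 1) % n_chrom
        ia = take(ca, 1)[0]
        # wide spacing on the partner side keeps successive dispersed pairs
        # from lining up into a spurious collinear run
        ib = take(cb, 1, gap_after=DEFAULT_MAX_GENE_GAP + 1)[0]
        plant_pair((ca, ia), (cb, ib), "dispersed", dup.target_ks["dispersed"])
    # segmental: collinear anchor runs across two chromosomes
    for b in range(dup.segmental_blocks):
        ca = b % n_chrom
        cb = (b + 2) % n_chrom if n_chrom > 2 else (b + 1) % n_chrom
        if ca == cb:
            raise GenerationError("segmental blocks need two distinct "
                                  "chromosomes")
        sa = take(ca, dup.segmental_anchors)
        sb = take(cb, dup.segmental_anchors)
        for ia, ib in zip(sa, sb):
            plant_pair((ca, ia), (cb, ib), "wgd_segmental",
                       dup.target_ks["segmental"])

    # pathway cluster
    refs = synthetic_reference_proteins()
    domain = _synthetic_p450_domain()
    pathway_roles: dict[str, str] = {}
    cluster_members: tuple[str, ...] = ()
    sub_clusters: tuple[tuple[str, ...], ...] = ()
    cluster_chrom = ""
    if spec.cluster is not None:
        cl = spec.cluster
        c = n_chrom - 1            # last chromosome hosts the cluster
        cursor[c] += cl.flank_gap  # hit-free flank before the cluster
        total = len(cl.roles) + sum(cl.internal_distances)
        slots = take(c, total, gap_after=cl.flank_gap)
        member_idx = [slots[0]]
        for d in cl.internal_distances:
            member_idx.append(member_idx[-1] + d + 1)
        members = []
        for mi, (idx, role) in enumerate(zip(member_idx, cl.roles)):
            if role == CYP_UNASSIGNED:
                body_len = 120
                half = body_len // 2
                body = "".join(
                    "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                    for _ in range(body_len))
                pep = body[:half] + domain.residues + body[half:]
            else:
                if role not in refs:
                    raise GenerationError(f"unknown pathway role {role!r}")
                pep = refs[role].residues
            plan[c][idx] = ("protein", pep, role)
            gid = _gene_id(c, idx)
            pathway_roles[gid] = role
            members.append(gid)
            if mi in cl.sub_cluster_starts:
                spacer_before[(c, idx)] = cl.boundary_spacer
        cluster_members = tuple(members)
        cluster_chrom = f"chr{c + 1}"
        starts = (0,) + tuple(cl.sub_cluster_starts) + (len(members),)
        sub_clusters = tuple(tuple(members[a:b])
                             for a, b in zip(starts, starts[1:]))

    # --- 2. materialise chromosomes --------------------------------------
    genome: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    cds_records: dict[str, SequenceRecord] = {}
    protein_records: list[SequenceRecord] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        parts: list[str] = []
        pos = 0
        for i in range(n_genes):
            gid = _gene_id(c, i)
            entry = plan[c][i]
            if entry is None:
                entry = ("cds", _random_cds(
                    rng, int(rng.integers(*spec.cds_codons))))
                plan[c][i] = entry
            if entry[0] == "protein":
                cds = reverse_translate(entry[1], rng)
            else:
                cds = entry[1]
            pep = translate(cds)
            spacer = spacer_before.get(
                (c, i), int(rng.integers(*spec.intergenic_length)))
            parts.append(_random_dna(rng, spacer))
            pos += spacer
            n_exons = min(int(rng.integers(spec.exons_per_gene[0],
                                           spec.exons_per_gene[1] + 1)),
                          len(cds) // 3)
            bounds = sorted(rng.choice(
                np.arange(1, len(cds) // 3), size=n_exons - 1,
                replace=False)) if n_exons > 1 else []
            pieces = np.split(np.arange(len(cds) // 3),
                              [int(b) for b in bounds])
            exons = []
            gstart = pos
            for k, codon_idx in enumerate(pieces):
                seg = cds[3 * codon_idx[0]: 3 * (codon_idx[-1] + 1)]
                if k > 0:
                    intron = _random_dna(
                        rng, int(rng.integers(*spec.intron_length)))
                    parts.append(intron)
                    pos += len(intron)
                exons.append((pos, pos + len(seg)))
                parts.append(seg)
                pos += len(seg)
            gene_models.append(GeneModel(
                gene_id=gid, chromosome=chrom, start=gstart, end=pos,
                strand="+", exons=tuple(exons)))
            cds_records[gid] = SequenceRecord(gid, cds)
            protein_records.append(SequenceRecord(gid, pep, alphabet=PROTEIN))
        genome[chrom] = "".join(parts)

    # --- 3. LTR elements in the chromosome tails --------------------------
    ltr_elements: list[LTRElement] = []
    ltr_truth: dict[str, tuple[float, str]] = {}
    rt_dna = {
        "Gypsy": reverse_translate(GYPSY_RT_QUERY.residues, rng),
        "Copia": reverse_translate(COPIA_RT_QUERY.residues, rng),
    }
    eid = 0
    tails: dict[str, list[str]] = {f"chr{c + 1}": [] for c in range(n_chrom)}
    for cohort in spec.ltr_cohorts:
        if cohort.superfamily not in rt_dna:
            raise GenerationError(
                f"unknown superfamily {cohort.superfamily!r}")
        t_years = cohort.age_mya * YEARS_PER_MY
        for k in range(cohort.count):
            chrom = f"chr{(eid % n_chrom) + 1}"
            ancestor = _random_dna(rng, cohort.ltr_length)
            ltr5 = mutate_clock(ancestor, t_years, spec.rate, rng)
            ltr3 = mutate_clock(ancestor, t_years, spec.rate, rng)
            internal = rt_dna[cohort.superfamily]
            name = f"LTR{eid:05d}"
            base = len(genome[chrom]) + sum(
                len(s) for s in tails[chrom]) + 200
            tails[chrom].append(_random_dna(rng, 200) + ltr5 + internal + ltr3)
            coords = (
                (base, base + len(ltr5)),
                (base + len(ltr5), base + len(ltr5) + len(internal)),
                (base + len(ltr5) + len(internal),
                 base + len(ltr5) + len(internal) + len(ltr3)),
            )
            ltr_elements.append(LTRElement(
                element_id=name, chromosome=chrom,
                ltr5=SequenceRecord(f"{name}_5", ltr5),
                ltr3=SequenceRecord(f"{name}_3", ltr3),
                internal_region=SequenceRecord(f"{name}_int", internal),
                coordinates=coords))
            ltr_truth[name] = (cohort.age_mya, cohort.superfamily)
            eid += 1
    for chrom in genome:
        genome[chrom] = genome[chrom] + "".join(tails[chrom])

    annotation = Annotation(gene_models)

    # --- 4. expression -----------------------------------------------------
    gene_classes = {g.gene_id: "background" for g in gene_models}
    for gid in cluster_members:
        gene_classes[gid] = "module"
    fpkm, samples = plant_expression(gene_classes, spec.expression, rng)

    # --- 5. ground truth ---------------------------------------------------
    for g in gene_models:
        truth_classes.setdefault(g.gene_id, "singleton")
    anchor_genes = tuple(g for g in cluster_members
                         if pathway_roles[g] != CYP_UNASSIGNED)
    span = 0
    if cluster_members:
        span = (max(annotation[g].end for g in cluster_members)
                - min(annotation[g].start for g in cluster_members))
    truth = GroundTruth(
        ltr_ages=ltr_truth,
        families=sorted(families),
        family_target_ks=family_ks,
        duplicate_classes=truth_classes,
        pathway_roles=pathway_roles,
        cluster_members=cluster_members,
        cluster_sub_clusters=sub_clusters,
        cluster_chromosome=cluster_chrom,
        cluster_span=span,
        module_genes=cluster_members,
        anchor_genes=anchor_genes,
    )
    return SyntheticGenome(
        spec=spec, genome=genome, annotation=annotation,
        proteins=protein_records, cds=cds_records,
        ltr_elements=ltr_elements, fpkm=fpkm, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# read synthetic fixtures back (pipeline input contract)
# ---------------------------------------------------------------------------

def read_ltr_table(table_path, genome: dict[str, str]) -> list[LTRElement]:
    """Build LTRElements from the element table TSV plus the genome FASTA
    (the internal region is everything between the two LTRs)."""
    df = pd.read_csv(table_path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        seq = genome[row.chrom]
        ltr5 = seq[row.ltr5_start:row.ltr5_end]
        ltr3 = seq[row.ltr3_start:row.ltr3_end]
        internal = seq[row.ltr5_end:row.ltr3_start]
        out.append(LTRElement(
            element_id=row.element_id, chromosome=row.chrom,
            ltr5=SequenceRecord(f"{row.element_id}_5", ltr5),
            ltr3=SequenceRecord(f"{row.element_id}_3", ltr3),
            internal_region=(SequenceRecord(f"{row.element_id}_int", internal)
                             if internal else None),
            coordinates=((row.ltr5_start, row.ltr5_end),
                         (row.ltr3_start, row.ltr3_end))))
    return out
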