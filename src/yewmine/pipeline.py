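"""End-to-end pipeline orchestration and interchange-file writers.

Stages (simulate -> stats -> date-ltrs -> dup-profile -> mine-clusters ->
coexpress) each read standard formats (FASTA/GFF3/TSV) from a working
directory and write TSV/BED results plus a machine-readable JSON manifest
with config echo and output checksums. Floats are rendered with 6
significant digits and rows are deterministically ordered, so a rerun with
the same config is byte-identical.

The defaults bundle every threshold the analyses are calibrated to:
identity >= 0.50 (Gypsy) / 0.60 (Copia) with coverage >= 0.90 for
superfamily calls, r = 7.34573e-10 substitutions/site/year, >= 5 anchors per
syntenic block, gene distance < 10 for clusters, and r > 0.8 / P < 0.05 for
co-expression nomination.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field, replace

import pandas as pd

from yewmine import (
    annotation as ann,
    cluster_mining as cm,
    coexpression as cx,
    dup_profile as dp,
    genome_stats as gs,
    repeat_dating as rd,
    seqcore,
    synthetic_data as sd,
)

F = "%.6g"


def fmt(x) -> str:
    if isinstance(x, float):
        return "nan" if math.isnan(x) else F % x
    return str(x)


def write_tsv(path, header: list[str], rows, comments: list[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(x) for x in row) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters with their calibrated defaults."""

    seed: int = 0
    # superfamily / dating
    identity_gypsy: float = 0.50
    identity_copia: float = 0.60
    min_coverage: float = 0.90
    rate: float = rd.DEFAULT_RATE
    jc_correction: bool = True
    # duplicate profiling
    family_min_identity: float = dp.DEFAULT_MIN_IDENTITY
    family_min_coverage: float = dp.DEFAULT_MIN_COVERAGE
    min_anchors: int = dp.DEFAULT_MIN_ANCHORS
    max_gene_gap: int = dp.DEFAULT_MAX_GENE_GAP
    proximal_window: int = dp.DEFAULT_PROXIMAL_WINDOW
    ks_bin_width: float = 0.05
    # cluster mining
    max_distance: int = cm.DEFAULT_MAX_DISTANCE
    min_cluster_size: int = cm.DEFAULT_MIN_SIZE
    hit_min_identity: float = cm.DEFAULT_MIN_IDENTITY
    hit_min_coverage: float = cm.DEFAULT_MIN_COVERAGE
    sub_clusters: int = 3
    # coexpression
    r_threshold: float = cx.DEFAULT_R_THRESHOLD
    p_threshold: float = cx.DEFAULT_P_THRESHOLD
    # stats
    window: int = gs.DEFAULT_WINDOW
    kmer_k: int = 17

    def filter_config(self) -> rd.FilterConfig:
        return rd.FilterConfig(
            identity_gypsy=self.identity_gypsy,
            identity_copia=self.identity_copia,
            min_coverage=self.min_coverage,
            rate=self.rate, jc_correction=self.jc_correction)


def _read_genome(path) -> dict[str, str]:
    return {r.id: r.residues for r in seqcore.read_fasta(str(path))}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir, cfg: RunConfig,
                   spec: sd.SyntheticGenomeSpec | None = None) -> list[str]:
    spec = spec or sd.SyntheticGenomeSpec(seed=cfg.seed, rate=cfg.rate)
    genome = sd.generate(spec)
    paths = genome.write(outdir)
    return sorted(paths.values())


def stage_stats(outdir, cfg: RunConfig, genome_path, gff_path,
                reads_path=None, repeats=None) -> list[str]:
    genome = _read_genome(genome_path)
    annotation = ann.read_gff3(gff_path)
    outputs = []

    lengths = sorted((len(s) for s in genome.values()), reverse=True)
    intron = gs.top_decile_intron_stats(annotation)
    gene_lengths = [g.length for g in annotation]
    exon_lengths = [x for g in annotation for x in g.exon_lengths]
    rows = [
        ("total_length_bp", sum(lengths)),
        ("n_sequences", len(lengths)),
        ("longest_bp", lengths[0]),
        ("n50_bp", gs.n50(lengths)),
        ("gc_fraction", _genome_gc(genome)),
        ("n_genes", len(annotation)),
        ("mean_gene_length_bp", sum(gene_lengths) / len(gene_lengths)),
        ("mean_exon_length_bp", sum(exon_lengths) / len(exon_lengths)),
        ("mean_exons_per_gene", len(exon_lengths) / len(annotation)),
        ("top_decile_intron_count", intron.count),
        ("top_decile_intron_min_bp", intron.min),
        ("top_decile_intron_max_bp", intron.max),
        ("top_decile_intron_mean_bp", intron.mean),
    ]
    if reads_path is not None:
        reads = seqcore.read_fasta(str(reads_path))
        prof = gs.kmer_genome_size(reads, k=cfg.kmer_k)
        rows += [("kmer_k", prof.k), ("kmer_peak_depth", prof.peak_depth),
                 ("kmer_genome_size_bp", prof.genome_size_estimate)]
    p = os.path.join(outdir, "stats_summary.tsv")
    write_tsv(p, ["statistic", "value"], rows)
    outputs.append(p)

    tracks = gs.windowed_tracks(genome, annotation, repeats, window=cfg.window)
    rows = []
    for kind in sorted(tracks):
        for tr in tracks[kind]:
            for s, v in zip(tr.starts, tr.values):
                rows.append((tr.chromosome, int(s),
                             int(min(s + tr.window, len(genome[tr.chromosome]))),
                             kind, float(v)))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    p = os.path.join(outdir, "window_tracks.tsv")
    write_tsv(p, ["chrom", "start", "end", "track", "value"], rows)
    outputs.append(p)
    return outputs


def _genome_gc(genome: dict[str, str]) -> float:
    gc = total = 0
    for seq in genome.values():
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        total += len(s) - s.count("N")
    return gc / total if total else 0.0


def stage_date_ltrs(outdir, cfg: RunConfig, genome_path, elements_path
                    ) -> list[str]:
    genome = _read_genome(genome_path)
    elements = sd.read_ltr_table(elements_path, genome)
    fc = cfg.filter_config()
    dated = rd.date_elements(elements, fc)
    rows = []
    for call, age in dated:
        rows.append((age.element_id, call.label, call.best_identity,
                     call.best_coverage, age.K, age.t_years, age.t_mya))
    rows.sort(key=lambda r: r[0])
    p1 = os.path.join(outdir, "ltr_ages.tsv")
    write_tsv(p1, ["element_id", "superfamily", "identity", "coverage", "K",
                   "t_years", "t_mya"], rows)
    profile = rd.age_profile(elements, fc)
    hrows = []
    for fam in sorted(profile.counts):
        for b in sorted(profile.counts[fam]):
            hrows.append((fam, b * profile.bin_mya, (b + 1) * profile.bin_mya,
                          profile.counts[fam][b]))
    p2 = os.path.join(outdir, "ltr_age_histogram.tsv")
    write_tsv(p2, ["superfamily", "bin_start_mya", "bin_end_mya", "count"],
              hrows, comments=[f"undateable\t{profile.undateable}"])
    return [p1, p2]


def stage_dup_profile(outdir, cfg: RunConfig, gff_path, proteins_path,
                      cds_path) -> list[str]:
    annotation = ann.read_gff3(gff_path)
    proteins = seqcore.read_fasta(str(proteins_path), alphabet=seqcore.PROTEIN)
    cds = {r.id: r for r in seqcore.read_fasta(str(cds_path))}
    families = dp.cluster_paralog_families(
        proteins, min_identity=cfg.family_min_identity,
        min_coverage=cfg.family_min_coverage, cds=cds)
    frows = []
    for fam in families:
        frows.append((fam.family_id, len(fam.members), ",".join(fam.members),
                      fam.median_ks))
    frows.sort(key=lambda r: r[0])
    p1 = os.path.join(outdir, "families.tsv")
    write_tsv(p1, ["family_id", "size", "members", "median_ks"], frows)

    pairs = [(fam.members[i], fam.members[j]) for fam in families
             for i in range(len(fam.members))
             for j in range(i + 1, len(fam.members))]
    blocks = dp.find_syntenic_blocks(annotation, pairs,
                                     min_anchors=cfg.min_anchors,
                                     max_gene_gap=cfg.max_gene_gap)
    brows = []
    for bi, blk in enumerate(blocks):
        for a, b in blk.anchors:
            brows.append((f"block{bi:03d}", blk.chrom_a, blk.chrom_b,
                          blk.orientation, a, b))
    p2 = os.path.join(outdir, "blocks.tsv")
    write_tsv(p2, ["block_id", "chrom_a", "chrom_b", "orientation",
                   "gene_a", "gene_b"], brows)

    classes = dp.classify_duplicates(annotation, families, blocks,
                                     proximal_window=cfg.proximal_window)
    crows = sorted(classes.items())
    p3 = os.path.join(outdir, "duplicate_classes.tsv")
    write_tsv(p3, ["gene_id", "class"], crows)

    hist, undefined = dp.ks_distribution(families, bin_width=cfg.ks_bin_width)
    hrows = [(b * cfg.ks_bin_width, (b + 1) * cfg.ks_bin_width, n)
             for b, n in hist.items()]
    p4 = os.path.join(outdir, "ks_histogram.tsv")
    write_tsv(p4, ["bin_start", "bin_end", "families"], hrows,
              comments=[f"undefined_median_families\t{undefined}"])
    return [p1, p2, p3, p4]


def stage_mine_clusters(outdir, cfg: RunConfig, gff_path, proteins_path,
                        refs_path=None) -> list[str]:
    annotation = ann.read_gff3(gff_path)
    proteins = seqcore.read_fasta(str(proteins_path), alphabet=seqcore.PROTEIN)
    references = None
    if refs_path is not None:
        references = {r.id: r for r in seqcore.read_fasta(
            str(refs_path), alphabet=seqcore.PROTEIN)}
    hits = cm.identify_pathway_homologs(
        proteins, references, min_identity=cfg.hit_min_identity,
        min_coverage=cfg.hit_min_coverage)
    hrows = sorted((h.gene_id, h.role, h.best_identity, h.best_coverage,
                    h.reference_id) for h in hits)
    p1 = os.path.join(outdir, "pathway_hits.tsv")
    write_tsv(p1, ["gene_id", "role", "identity", "coverage", "reference"],
              hrows)

    clusters = cm.mine_clusters(hits, annotation,
                                max_distance=cfg.max_distance,
                                min_size=cfg.min_cluster_size)
    role_of = {h.gene_id: h.role for h in hits}
    crows = []
    brows = []
    for cl in clusters:
        k = min(cfg.sub_clusters, cl.size)
        cm.partition_subclusters(cl, annotation, k=k)
        sub_of = {g: si + 1 for si, sub in enumerate(cl.sub_clusters)
                  for g in sub}
        for g in cl.members:
            crows.append((cl.cluster_id, cl.chromosome, cl.span, g,
                          role_of[g], sub_of[g]))
        start = min(annotation[g].start for g in cl.members)
        end = max(annotation[g].end for g in cl.members)
        brows.append((cl.chromosome, start, end, cl.cluster_id, cl.size, "+"))
    p2 = os.path.join(outdir, "clusters.tsv")
    write_tsv(p2, ["cluster_id", "chrom", "span_bp", "gene_id", "role",
                   "sub_cluster"], crows)
    p3 = os.path.join(outdir, "clusters.bed")
    with open(p3, "w") as fh:
        for row in sorted(brows):
            fh.write("\t".join(str(x) for x in row) + "\n")
    return [p1, p2, p3]


def stage_coexpress(outdir, cfg: RunConfig, matrix_path, samples_path,
                    anchors: list[str], candidates: list[str] | None = None
                    ) -> list[str]:
    m = cx.read_expression(matrix_path, samples_path)
    if candidates is None:
        candidates = [g for g in m.genes if g not in set(anchors)]
    results, nominated = cx.nominate_candidates(
        m, anchors, candidates, r_threshold=cfg.r_threshold,
        p_threshold=cfg.p_threshold)
    rows = sorted((r.candidate, r.anchor, r.r, r.p, int(r.passes),
                   r.tissue_of_max) for r in results)
    p1 = os.path.join(outdir, "coexpression_results.tsv")
    write_tsv(p1, ["candidate", "anchor", "r", "p", "passes",
                   "tissue_of_max"], rows)
    p2 = os.path.join(outdir, "nominated_genes.txt")
    with open(p2, "w") as fh:
        for g in sorted(nominated):
            fh.write(g + "\n")
    heat = cx.heatmap_matrix(m)
    p3 = os.path.join(outdir, "heatmap_log2_tissue_means.tsv")
    heat.to_csv(p3, sep="\t", float_format=F)
    return [p1, p2, p3]


def run_pipeline(outdir, cfg: RunConfig | None = None,
                 spec: sd.SyntheticGenomeSpec | None = None) -> dict:
    """simulate -> stats -> date-ltrs -> dup-profile -> mine-clusters ->
    coexpress on one output directory; returns the manifest (also written as
    ``manifest.json``)."""
    cfg = cfg or RunConfig()
    os.makedirs(outdir, exist_ok=True)
    produced: list[str] = []
    stages_run: list[str] = []

    produced += stage_simulate(outdir, cfg, spec)
    stages_run.append("simulate")
    gpath = os.path.join(outdir, "genome.fa")
    gff = os.path.join(outdir, "annotation.gff3")

    produced += stage_stats(outdir, cfg, gpath, gff)
    stages_run.append("stats")
    produced += stage_date_ltrs(outdir, cfg, gpath,
                                os.path.join(outdir, "ltr_elements.tsv"))
    stages_run.append("date-ltrs")
    produced += stage_dup_profile(outdir, cfg, gff,
                                  os.path.join(outdir, "proteins.fa"),
                                  os.path.join(outdir, "cds.fa"))
    stages_run.append("dup-profile")
    produced += stage_mine_clusters(outdir, cfg, gff,
                                    os.path.join(outdir, "proteins.fa"))
    stages_run.append("mine-clusters")

    anchors = []
    truth_module = os.path.join(outdir, "truth_module.tsv")
    if os.path.exists(truth_module):
        t = pd.read_csv(truth_module, sep="\t")
        anchors = list(t.loc[t.role_in_module == "anchor", "gene_id"])
    if anchors:
        produced += stage_coexpress(
            outdir, cfg, os.path.join(outdir, "expression_fpkm.tsv"),
            os.path.join(outdir, "samples.tsv"), anchors)
        stages_run.append("coexpress")

    from yewmine import __version__

    manifest = {
        "version": __version__,
        "stages": stages_run,
        "config": asdict(cfg),
        "outputs": {os.path.basename(p): _sha256(p)
                    for p in sorted(set(produced))},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
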