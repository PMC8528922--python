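"""Gene models, chromosome gene ranks and GFF3 input/output.

All coordinates in memory are 0-based half-open; GFF3's 1-based closed
intervals are converted exactly once, at the reader/writer boundary.

Gene *rank* — the per-chromosome index of a gene when genes are ordered by
start coordinate (ties broken by end, then id) — is the unit in which gene
distances, tandem/proximal windows and synteny chains are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene models."""


@dataclass(frozen=True)
class GeneModel:
    """A positioned gene with exon structure (0-based half-open intervals)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s >= e:
                raise AnnotationError(f"gene {self.gene_id!r}: empty exon [{s}, {e})")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon [{s}, {e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exons overlap or unsorted at [{s}, {e})")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, as 0-based half-open intervals."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.introns)


class Annotation:
    """An ordered gene set with per-chromosome ranks and gene distances."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self._genes.values():
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        self._rank: dict[str, int] = {}
        for chrom, glist in self._by_chrom.items():
            glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(glist):
                self._rank[g.gene_id] = rank

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id!r}") from None

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> Sequence[GeneModel]:
        """Genes on a chromosome in rank order."""
        return tuple(self._by_chrom.get(chromosome, ()))

    def rank(self, gene_id: str) -> int:
        self[gene_id]
        return self._rank[gene_id]

    def gene_distance(self, a: str, b: str) -> int | None:
        """Number of annotated gene models between two genes on the same
        chromosome; ``None`` (undefined) across chromosomes."""
        ga, gb = self[a], self[b]
        if ga.chromosome != gb.chromosome:
            return None
        if a == b:
            return 0
        return abs(self._rank[a] - self._rank[b]) - 1


# ---------------------------------------------------------------------------
# GFF3 I/O (conversion between 1-based closed and 0-based half-open happens
# only here)
# ---------------------------------------------------------------------------

def write_gff3(annotation: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join([
                g.chromosome, "yewmine", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs]) + "\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write("\t".join([
                g.chromosome, "yewmine", "mRNA", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"]) + "\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chromosome, "yewmine", "exon", str(s + 1), str(e),
                    ".", g.strand, ".",
                    f"ID={mrna_id}.exon{k};Parent={mrna_id}"]) + "\n")


def read_gff3(path) -> Annotation:
    """Load gene models (gene + exon features) from a GFF3 file.

    Parsing goes through gffutils; errors name the offending file.
    """
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises several parse error types
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(feat, featuretype="exon"))
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(
            gene_id=gene_id, chromosome=feat.seqid,
            start=feat.start - 1, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            exons=tuple(exons)))
    return Annotation(genes)
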