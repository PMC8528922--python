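# Methods

This note documents the models behind each analysis, the defaults and why
they are set where they are, what the synthetic-data generator does and does
not emulate, and the numerical choices that make runs bit-reproducible.

## Pairwise alignment

All homology decisions rest on exact dynamic-programming alignment with
linear gap costs (default match +2, mismatch -1, gap -2.5): global
(Needleman-Wunsch) for LTR pairs, local (Smith-Waterman) for domain and
protein homology. The score matrix is filled row by row with the horizontal
dependency resolved in closed form (a running maximum of `t[k] + g*k`), so a
2-kb x 2-kb alignment is a few thousand vector operations. Traceback ties
prefer diagonal over up over left, and the best local cell is the first in
row-major order, so alignments — not just scores — are deterministic.
Identity is matches over ungapped columns; coverage is aligned query
residues over full query length (BLAST-style, with the first argument as
query). Columns containing ambiguity codes (N for DNA; B/Z/J/X/U/O for
protein) are excluded from both the numerator and denominator of identity
and p-distance. There is no heuristic seeding: inputs are desk-scale and
the DP is exact.

## Distances and the insertion clock

Observed divergence p is corrected for multiple hits with Jukes-Cantor,
d = -(3/4) ln(1 - 4p/3); p >= 3/4 yields NaN (flagged, not raised), which
propagates to an "undateable" element rather than an error. Insertion age is
t = K/2r with r = 7.34573e-10 substitutions/site/year, the slow
conifer-calibrated rate. K is JC-corrected by default — at the 8-44 MYA ages
typical of conifer LTR cohorts, multiple hits are not negligible — but a
config switch (`jc_correction=False`) reports raw p-distance instead, since
dating conventions differ between studies. Age histograms use left-closed
1-MYA bins.

Superfamily classification aligns a candidate RT domain locally against the
two reference RT peptides (stored verbatim; the Gypsy reference carries a
legacy 'O' character, which the protein alphabet accepts and identity
counting skips as an ambiguity column). Thresholds: identity >= 0.50
(Gypsy), >= 0.60 (Copia), coverage >= 0.90 of the reference. When only the
nucleotide internal region is available, a six-frame translation with
longest-ORF selection supplies candidate domains.

## Nei-Gojobori Ks

Ks uses NG86 counting rather than a codon-model ML estimator (yn00-style
codon-frequency machinery is out of proportion at this scale; the estimator
sits behind a small interface if a replacement is wanted). Per codon
position, the synonymous fraction is computed over the non-stop single-base
alternatives and renormalised so synonymous + nonsynonymous site counts sum
to 3 per codon; sites S are averaged over the two sequences. Differences
between codons average sd/nd with equal weight over all minimal mutational
pathways, discarding pathways through stop codons (if every pathway is
blocked, all are used). pS = Sd/S receives the same -(3/4)ln(1-4pS/3)
correction. Sequences must be codon-aligned; unequal-length pairs are
threaded through a global protein alignment with gapped codon columns
dropped. A shared terminal stop is stripped; internal stops are errors.

## Families, synteny, duplicate classes

Families are connected components (union-find) over pairs passing local
alignment identity >= 0.5 with >= 0.5 coverage of *both* sequences;
single-linkage replaces Markov clustering deliberately — at this scale it is
deterministic and auditable, and the clustering function is swappable. An
inverted index of 6-mer peptides gates which pairs are aligned at all: pairs
sharing no 6-mer cannot approach the identity threshold, so the gate changes
nothing above it while collapsing the all-vs-all cost; `prefilter_k=None`
disables it. Family ids derive from the lexicographically smallest member.
The family Ks is the median over defined pair estimates (even count: mean of
the central two).

Syntenic blocks chain anchor pairs into maximal monotone runs (parallel or
antiparallel) with consecutive anchors at most 25 ranks apart on both sides
and at least 5 anchors per block, extracted greedily longest-first without
anchor reuse. Same-chromosome pairs closer than 11 intervening genes are not
anchor candidates: tandem and proximal arrays hug the self-diagonal and
would otherwise read as collinearity. Gene ranks are per-chromosome 0-based
indices ordered by start (ties: end, then id).

Duplicate classes follow the precedence WGD/segmental > tandem > proximal >
dispersed: block anchor first; else a family partner at the adjacent rank;
else a partner within 10 intervening ranks (the proximal window is not
standardised anywhere, so it is configurable); else dispersed. Genes in no
family are singletons. The precedence makes the classification a partition.

## Cluster mining

Gene distance between two genes on one chromosome is the count of annotated
gene models strictly between them; it is undefined across chromosomes.
Consecutive pathway hits join a cluster when their distance is strictly
less than 10 — the rule is read as strict "< 10", with the cutoff
configurable and the boundary covered by tests — and a cluster needs at
least 2 members (a singleton is not a cluster). Spans are bp from min start
to max end. Sub-clusters split at the (k-1) largest internal bp gaps
(ties: leftmost cut), or at caller-given breakpoints; the three-way split of
a large cluster is an explicitly artificial division, so the largest-gap
heuristic is this package's choice of formalisation. The bundled pathway
reference proteins are synthetic stand-ins generated deterministically per
role name (real reference accessions are not redistributable here); any
role-tagged FASTA can replace them, and CYP725-likeness is flagged via a
conserved-domain reference sequence carried by all CYP-family roles.

## Co-expression

Correlations run on the five tissue means (replicates averaged, then
log2(FPKM+1); pseudocount 1 maps zero to zero) — matching how tissue
profiles are displayed and compared — rather than on the fifteen raw
samples; `replicate_level=True` switches to raw vectors, which triples the
degrees of freedom but mixes replicate noise into the profile. With n = 5
the P < 0.05 two-sided cut corresponds to |r| > ~0.878 (computed from the t
quantile at run time, never hard-coded), so the stated r > 0.8 threshold is
effectively subsumed by the P threshold at this n. P-values are per-pair
with no multiple-testing correction, mirroring the screening convention the
thresholds come from; a Benjamini-Hochberg helper can be layered on the
returned results but is off by default. Zero-variance profiles yield NaN r
(flagged, never nominated).

## Genome statistics

N50 is the largest L such that sequences >= L sum to at least half the
total. Windowed tracks use 5-Mb windows by default (the genome-figure
convention); GC is over non-N bases, gene density counts gene starts,
repeat fractions merge overlapping intervals first. The long-intron
statistic pools introns genome-wide (not per gene) and takes the
ceil(0.1 n) longest. K-mer genome size counts canonical 17-mers exactly;
depths below the first local minimum of the spectrum (the sequencing-error
band) are excluded, the coverage peak is located as the rounded
depth-weighted mean of the remaining band (stabler than the raw mode, which
wobbles across the flat top of a Poisson-like spectrum and shifts the
estimate by percents per depth unit), and the estimate is total k-mers over
that peak. Heterozygous-peak modelling is out of scope.

## The synthetic-data generator

The generator emulates the *shape* of a conifer genome study at 1/5000
scale: 4 chromosomes x 300 genes (~2.2 Mb each), genes with 2-5 exons and
CDS of 120-220 codons assembled from sense codons, intergenic spacers of
0.5-3 kb. It plants:

* **LTR cohorts** — by default 200 elements each at 1, 8 and 24 MYA with
  2-kb LTRs. Both LTRs of an element are drawn from a common ancestor via
  the exact JC transition kernel for t*r expected substitutions per site
  per copy, so the pairwise expectation is 2tr and dating with t = K/2r is
  calibrated by construction. Internal regions carry a reverse-translated
  RT domain so superfamily classification has signal.
* **duplicate cohorts** — tandem (adjacent), proximal (2-5 intervening
  genes), dispersed (across chromosomes, spaced widely enough not to fake
  collinearity) and segmental blocks (6 consecutive anchor pairs across two
  chromosomes). Paralogs differ only by synonymous substitutions: the
  generator substitutes ceil(pS_target * S) sites whose every non-stop
  alternative is synonymous, so proteins stay identical (family recovery is
  exact) and the planted Ks lands at or just above target (cohorts at 0.1
  fall inside the [0.10, 0.15) bin rather than straddling the bin edge).
* **one pathway cluster** — 12 CYP725-like genes, then TXS + T5aOH, then
  the four taxoid hydroxylases, with internal gene distances < 10,
  hit-free flanks of >= 12 genes, and 300-kb intergenic spacers at the two
  sub-cluster boundaries so the largest-gap partition is unambiguous.
* **expression** — cluster genes share a bark-high latent profile
  (FPKM means 5/8/12/120/6 across root/stem/twig bark/bark/leaf), jittered
  per gene by sigma = 0.25 in log2 so pairwise module correlations stay
  >= ~0.95; background genes draw independent log-normal profiles;
  replicates multiply by log-normal noise with sigma = 0.25.

One `numpy.random.default_rng(seed)` drives everything; identical spec and
seed give byte-identical files. Genes sit on the forward strand only and
repeats do not nest or truncate; neither affects any statistic computed
here, but it means passing tests say nothing about strand-aware parsing or
nested-repeat resolution on real data. Likewise the sequence-noise-free
paralogs and pathway genes make family and role recovery exact by design:
those tests validate the chaining/classification logic, not alignment
sensitivity at realistic divergence.

## Problem sizes and runtime

The default pipeline (1,200 genes, 600 LTR elements, 550-gene expression
screen) completes in about 3 minutes on one core, dominated by the 600
2-kb global alignments; unit tests use a 2-chromosome, 400-gene variant.
These sizes were chosen so every planted cohort is large enough for its
tolerance (e.g. 200 elements per age cohort keeps the binomial noise on
the cohort median well inside 10%) while the whole suite stays interactive.
At 1 MYA and 2-kb LTRs the expected substitution count is only ~3, so
recovered medians are quantised to ~0.34-MYA steps; the 10% band holds for
the cohort median but per-element ages at that age are intrinsically
coarse.

## Known limitations

* NG86 underestimates Ks relative to codon-frequency ML (yn00) when codon
  usage is strongly biased; planted cohorts are usage-neutral, real data
  may not be.
* The k-mer peak finder assumes a unimodal coverage peak past the error
  band; heterozygous genomes produce a shoulder it will not model.
* Block chaining is greedy longest-first; pathological anchor sets can
  admit alternative equal-size tilings, though ids and output order remain
  deterministic.
* The co-expression screen inherits the n = 5 design: power is limited and
  the P threshold dominates the r threshold; replicate-level mode trades
  profile smoothing for df.
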