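import numpy as np
import pytest

from yewmine import synthetic_data as sd
from yewmine.annotation import Annotation, GeneModel


def toy_annotation(layout: dict[str, int], gene_length: int = 500,
                   spacing: int = 1000) -> Annotation:
    """Evenly spaced single-exon genes: ``layout`` maps chromosome -> count.

    Gene ids are ``<chrom>_g<rank>`` so ranks are readable in assertions.
    """
    genes = []
    for chrom, n in layout.items():
        for i in range(n):
            s = i * spacing
            genes.append(GeneModel(
                gene_id=f"{chrom}_g{i}", chromosome=chrom,
                start=s, end=s + gene_length,
                exons=((s, s + gene_length),)))
    return Annotation(genes)


SMALL_SPEC = sd.SyntheticGenomeSpec(
    seed=7,
    n_chromosomes=2,
    genes_per_chromosome=200,
    ltr_cohorts=(
        sd.LTRCohort(8.0, 20, 1000, "Gypsy"),
        sd.LTRCohort(24.0, 10, 1000, "Copia"),
    ),
    duplications=sd.DuplicationPlan(tandem=4, proximal=3, dispersed=3,
                                    segmental_blocks=1, segmental_anchors=5),
)


@pytest.fixture(scope="session")
def small_genome() -> sd.SyntheticGenome:
    """A scaled-down synthetic genome shared by unit tests."""
    return sd.generate(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-spec pipeline run shared by the acceptance tests.

    Returns (output directory, elapsed seconds, manifest).
    """
    import time

    from yewmine import pipeline as pl

    outdir = tmp_path_factory.mktemp("default_run")
    t0 = time.time()
    manifest = pl.run_pipeline(outdir, pl.RunConfig(seed=11),
                               sd.SyntheticGenomeSpec(seed=11))
    return outdir, time.time() - t0, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
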