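"""Tissue co-expression screening against known pathway anchor genes.

The input is an FPKM matrix over five tissues (root, stem, twig_bark, bark,
leaf) with biological replicates. Replicates are averaged per tissue, the
tissue means are log2(FPKM + 1)-transformed, and each candidate gene is
correlated (Pearson) with each anchor gene over the five tissue means. A
candidate is nominated when it passes r > 0.8 and two-sided P < 0.05 against
at least one anchor; with n = 5 tissues that P threshold corresponds to
|r| above the t-quantile critical value at 3 degrees of freedom (~0.878), so
the r cutoff is effectively the P cutoff's weaker sibling.

The tissue of maximal mean expression is reported with each result, so
bark-high candidates (the expression signature of taxoid-pathway genes) can
be read off directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("root", "stem", "twig_bark", "bark", "leaf")

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_P_THRESHOLD = 0.05


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM with a sample -> (tissue, replicate) map."""

    fpkm: pd.DataFrame                      # index: gene ids, columns: samples
    samples: pd.DataFrame                   # index: sample ids; tissue, replicate

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ExpressionError("FPKM values must be non-negative")
        missing = set(self.fpkm.columns) - set(self.samples.index)
        if missing:
            raise ExpressionError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.samples.loc[list(self.fpkm.columns), "tissue"]) - set(TISSUES)
        if bad:
            raise ExpressionError(f"unknown tissues: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    def tissues_present(self) -> list[str]:
        present = set(self.samples.loc[list(self.fpkm.columns), "tissue"])
        return [t for t in TISSUES if t in present]


def average_replicates(m: ExpressionMatrix,
                       require_all_tissues: bool = True) -> pd.DataFrame:
    """Arithmetic mean FPKM per (gene, tissue); columns in canonical tissue
    order."""
    present = m.tissues_present()
    if require_all_tissues and set(present) != set(TISSUES):
        missing = sorted(set(TISSUES) - set(present))
        raise ExpressionError(f"missing tissues: {missing}")
    tissue_of = m.samples.loc[list(m.fpkm.columns), "tissue"]
    means = m.fpkm.T.groupby(tissue_of.values).mean().T
    return means[[t for t in TISSUES if t in means.columns]]


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(FPKM + pseudocount); with the default pseudocount of 1, zero
    expression maps to zero."""
    if (matrix.values < 0).any():
        raise ExpressionError("negative values in expression matrix")
    return np.log2(matrix + pseudocount)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided P from the t transform
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.

    Returns (nan, nan) — a flagged undefined result, not an exception — when
    either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ExpressionError("vectors must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ExpressionError("need at least 3 points for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(xm @ ym / math.sqrt((xm @ xm) * (ym @ ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (r, float(p))


@dataclass(frozen=True)
class CoexpressionResult:
    candidate: str
    anchor: str
    r: float
    p: float
    passes: bool
    tissue_of_max: str


def nominate_candidates(m: ExpressionMatrix, anchors, candidates,
                        r_threshold: float = DEFAULT_R_THRESHOLD,
                        p_threshold: float = DEFAULT_P_THRESHOLD,
                        replicate_level: bool = False,
                        pseudocount: float = 1.0,
                        ) -> tuple[list[CoexpressionResult], list[str]]:
    """Correlate every candidate against every anchor and nominate passers.

    Correlations run on replicate-averaged, log2-transformed tissue vectors
    (n = 5) by default; ``replicate_level=True`` switches to the raw
    per-sample vectors (n = samples), trading profile smoothing for degrees
    of freedom.

    Returns (all pairwise results, nominated candidate ids). A candidate is
    nominated when it passes r > r_threshold and P < p_threshold against at
    least one anchor.
    """
    anchors = list(anchors)
    candidates = list(candidates)
    unknown = (set(anchors) | set(candidates)) - set(m.fpkm.index)
    if unknown:
        raise ExpressionError(f"unknown gene ids: {sorted(unknown)}")
    tissue_means = average_replicates(m)
    log_means = log2_transform(tissue_means, pseudocount)
    if replicate_level:
        profile = log2_transform(m.fpkm, pseudocount)
    else:
        profile = log_means
    results = []
    nominated = []
    for cand in candidates:
        passed = False
        tmax = str(tissue_means.loc[cand].idxmax())
        for anchor in anchors:
            if cand == anchor:
                continue
            r, p = pearson_with_p(profile.loc[cand].values,
                                  profile.loc[anchor].values)
            ok = (not math.isnan(r)) and r > r_threshold and p < p_threshold
            results.append(CoexpressionResult(cand, anchor, r, p, ok, tmax))
            passed = passed or ok
        if passed:
            nominated.append(cand)
    return results, nominated


def critical_r(n: int, p_threshold: float = DEFAULT_P_THRESHOLD) -> float:
    """|r| above which the two-sided P at n-2 df drops below p_threshold."""
    if n < 3:
        raise ExpressionError("need n >= 3")
    tcrit = stats.t.ppf(1.0 - p_threshold / 2.0, df=n - 2)
    return float(tcrit / math.sqrt(n - 2 + tcrit ** 2))


def heatmap_matrix(m: ExpressionMatrix, genes=None,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Heat-map-ready matrix: log2 tissue-averaged FPKM, genes x tissues."""
    out = log2_transform(average_replicates(m), pseudocount)
    if genes is not None:
        out = out.loc[list(genes)]
    return out


def read_expression(matrix_path, samples_path) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV plus a sample sheet TSV
    (sample_id, tissue, replicate)."""
    fpkm = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    sheet = pd.read_csv(samples_path, sep="\t", comment="#")
    if "sample_id" not in sheet.columns:
        raise ExpressionError(f"{samples_path}: sample sheet needs a "
                              "sample_id column")
    sheet = sheet.set_index("sample_id")
    return ExpressionMatrix(fpkm=fpkm, samples=sheet)
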