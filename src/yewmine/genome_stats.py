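"""Assembly and annotation summary statistics.

Covers the descriptive statistics a genome report leans on: N50 of contig or
scaffold lengths, 5-Mb windowed GC / gene-density / repeat-fraction tracks,
the genome-wide "10% longest introns" statistic characteristic of
large-intron conifer genomes, and k-mer-spectrum genome-size estimation
(total k-mers divided by the modal sequencing depth).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from yewmine.annotation import Annotation

DEFAULT_WINDOW = 5_000_000


class StatsError(ValueError):
    pass


def n50(lengths) -> int:
    """Largest L such that sequences of length >= L sum to at least half the
    total assembly length."""
    lens = sorted(int(x) for x in lengths)
    if not lens:
        raise StatsError("n50 of an empty length set")
    if any(x <= 0 for x in lens):
        raise StatsError("n50 requires positive lengths")
    total = sum(lens)
    acc = 0
    for x in reversed(lens):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# windowed tracks
# ---------------------------------------------------------------------------

@dataclass
class WindowTrack:
    """Per-window values tiling one chromosome; the last window may be short."""

    chromosome: str
    window: int
    starts: np.ndarray          # window start coordinates (bp)
    values: np.ndarray          # GC fraction, gene count, or repeat fraction
    kind: str = "gc"

    def __len__(self) -> int:
        return len(self.values)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def windowed_tracks(genome: dict[str, str],
                    annotation: Annotation | None = None,
                    repeats: dict[str, list[tuple[int, int]]] | None = None,
                    window: int = DEFAULT_WINDOW) -> dict[str, list[WindowTrack]]:
    """GC, gene-density and repeat-fraction tracks in fixed windows.

    GC is computed over non-N bases; gene counts assign each gene to the
    window of its start; repeat intervals are merged before coverage is
    counted so overlapping annotations are not double-counted.

    Returns ``{"gc": [...], "genes": [...], "repeats": [...]}`` with one
    WindowTrack per chromosome (sorted by name) per requested layer.
    """
    if window <= 0:
        raise StatsError("window must be positive")
    out: dict[str, list[WindowTrack]] = {"gc": []}
    if annotation is not None:
        out["genes"] = []
    if repeats is not None:
        out["repeats"] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(seq)
        nwin = max(1, math.ceil(L / window)) if L else 0
        starts = np.arange(nwin) * window
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        gc_vals = np.zeros(nwin)
        for w in range(nwin):
            lo, hi = w * window, min((w + 1) * window, L)
            denom = hi - lo - int(is_n[lo:hi].sum())
            gc_vals[w] = is_gc[lo:hi].sum() / denom if denom else 0.0
        out["gc"].append(WindowTrack(chrom, window, starts, gc_vals, "gc"))
        if annotation is not None:
            counts = np.zeros(nwin)
            for g in annotation.genes_on(chrom):
                w = min(g.start // window, nwin - 1)
                counts[w] += 1
            out["genes"].append(WindowTrack(chrom, window, starts, counts,
                                            "genes"))
        if repeats is not None:
            frac = np.zeros(nwin)
            merged = _merge_intervals(list(repeats.get(chrom, [])))
            for s, e in merged:
                s, e = max(0, s), min(L, e)
                w = s // window
                while s < e:
                    hi = min((w + 1) * window, L)
                    frac[w] += min(e, hi) - s
                    s = hi
                    w += 1
            widths = np.minimum((starts + window), L) - starts
            with np.errstate(invalid="ignore"):
                frac = np.where(widths > 0, frac / widths, 0.0)
            out["repeats"].append(WindowTrack(chrom, window, starts, frac,
                                              "repeats"))
    return out


# ---------------------------------------------------------------------------
# intron statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronDecileStats:
    count: int
    min: int
    max: int
    mean: float

    @property
    def empty(self) -> bool:
        return self.count == 0


def top_decile_intron_stats(annotation: Annotation,
                            fraction: float = 0.1) -> IntronDecileStats:
    """Pool introns genome-wide, keep the ceil(fraction * n) longest, report
    their count, min, max and mean.

    Returns a flagged-empty result when the annotation has no introns.
    """
    lengths = []
    for g in annotation:
        lengths.extend(g.intron_lengths)
    if not lengths:
        return IntronDecileStats(0, 0, 0, float("nan"))
    lengths.sort(reverse=True)
    k = math.ceil(fraction * len(lengths))
    top = lengths[:k]
    return IntronDecileStats(count=k, min=min(top), max=max(top),
                             mean=sum(top) / k)


# ---------------------------------------------------------------------------
# k-mer genome-size estimation
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerProfile:
    """Canonical k-mer depth spectrum and the genome size it implies.

    ``estimate = total k-mer occurrences / peak depth`` — the classic
    k-mer-frequency estimator; the modal depth is searched after skipping the
    low-depth error band (depths below the first local minimum).
    """

    k: int
    histogram: dict[int, int]       # depth -> number of distinct k-mers
    total_kmers: int
    peak_depth: int

    @property
    def genome_size_estimate(self) -> float:
        return self.total_kmers / self.peak_depth


def _find_peak(hist: dict[int, int]) -> int:
    """Coverage-peak depth after excluding the leading error band.

    The error band ends at the first local minimum of counts along depth
    (for a genome read exactly once there is no band and every depth is
    kept). Within the remaining band the peak is located as the rounded
    depth-weighted mean: on flat-topped (Poisson-like) spectra this is far
    more stable than the raw mode, which wobbles by a few depth units of
    multinomial noise and moves the size estimate by percents per unit.
    The raw in-band mode is the fallback if the rounded mean falls outside
    the band.
    """
    depths = sorted(hist)
    counts = [hist[d] for d in depths]
    cut = 0
    for i in range(1, len(counts)):
        if counts[i] > counts[i - 1]:
            cut = i
            break
    band = depths[cut:]
    if not band:
        band = depths
    total = sum(hist[d] for d in band)
    mean_depth = sum(d * hist[d] for d in band) / total
    peak = int(round(mean_depth))
    if not band[0] <= peak <= band[-1]:
        peak = max(band, key=lambda d: (hist[d], -d))
    return max(peak, 1)


def kmer_genome_size(reads, k: int = 17) -> KmerProfile:
    """Estimate genome size from a read set by exact canonical k-mer counting.

    ``reads`` is an iterable of DNA strings (or SequenceRecord-likes with a
    ``residues`` attribute). k-mers containing non-ACGT characters are
    skipped.
    """
    if k < 2:
        raise StatsError("k must be >= 2")
    counts: Counter[str] = Counter()
    n_reads = 0
    for read in reads:
        seq = getattr(read, "residues", read).upper()
        n_reads += 1
        if k >= len(seq):
            raise StatsError(
                f"k={k} exceeds read length {len(seq)}")
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[_canonical(kmer)] += 1
    if n_reads == 0:
        raise StatsError("no reads supplied")
    hist: Counter[int] = Counter(counts.values())
    total = sum(counts.values())
    peak = _find_peak(dict(hist))
    return KmerProfile(k=k, histogram=dict(sorted(hist.items())),
                       total_kmers=total, peak_depth=peak)
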