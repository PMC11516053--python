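"""Neighborhood-score (NS) computation for expression-inferred CNAs.

Copy-number changes shift the expression of every gene they span, while
gene-specific transcriptional programs do not respect genomic contiguity.
The NS exploits this: each gene's differential-expression statistic
(paired t across tumor/normal pairs, or a z-score for one tumor against
the non-tumor reference) is smoothed along the genome by summing the
statistics of neighboring genes weighted by a triangular kernel of
genomic distance.  Dosage signal adds up coherently across a CNA; noise
does not.

The triangular kernel w(d) = max(0, 1 - d/half_width) has compact support
(default half-width 2 Mb, matching the focal-CNA size range the method
targets), gives the gene itself weight 1, and never smooths across
chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionCohort

PAIRED_T = "paired_t"
SINGLE_SAMPLE_Z = "single_sample_z"

DEFAULT_T_CLAMP = 50.0


@dataclass(frozen=True)
class KernelSpec:
    """Triangular distance kernel: w(d) = max(0, 1 - d/half_width_bp)."""

    shape: str = "triangular"
    half_width_bp: float = 2_000_000.0

    def __post_init__(self) -> None:
        if self.shape != "triangular":
            raise ValueError(f"unsupported kernel shape {self.shape!r}")
        if self.half_width_bp <= 0:
            raise ValueError("half_width_bp must be positive")

    def weight(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(0.0, 1.0 - np.abs(distance_bp) / self.half_width_bp)


@dataclass
class GeneStatTrack:
    """Per-gene differential statistic aligned with a gene annotation table."""

    genes: pd.DataFrame
    stat: np.ndarray
    mode: str
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, float)
        if len(self.stat) != len(self.genes):
            raise ValueError("stat length does not match gene count")
        if not np.isfinite(self.stat).all():
            raise ValueError("non-finite statistic; clamping failed upstream")


@dataclass
class NeighborhoodScoreTrack:
    genes: pd.DataFrame
    ns: np.ndarray
    kernel: KernelSpec
    mode: str

    def to_frame(self, stat: np.ndarray | None = None) -> pd.DataFrame:
        """TSV-ready table (gene_id, chrom, midpoint, stat, ns)."""
        df = self.genes[["gene_id", "chrom", "midpoint"]].copy()
        if stat is not None:
            df["stat"] = stat
        df["ns"] = self.ns
        return df


def _t_from_diffs(diffs: np.ndarray, t_clamp: float) -> np.ndarray:
    """Paired t per row of a (genes x pairs) difference matrix.

    sd uses the n-1 denominator.  Degenerate rows (sd == 0) map to 0 when
    the mean is also 0 and to +/- t_clamp otherwise.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    # a single pair has no spread estimate; treat as the sd=0 degenerate case
    sd = diffs.std(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean == 0)] = 0.0
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * t_clamp
    return np.clip(t, -t_clamp, t_clamp)


def paired_t_stats(
    cohort: ExpressionCohort, t_clamp: float = DEFAULT_T_CLAMP
) -> GeneStatTrack:
    """Per-gene paired t of tumor minus matched non-tumor differences."""
    if cohort.n_pairs < 2:
        raise ValueError("paired t requires at least 2 tumor/normal pairs")
    tumor, normal = cohort.paired_matrices()
    if np.isnan(tumor).any() or np.isnan(normal).any():
        raise ValueError("missing values; run preprocessing first")
    t = _t_from_diffs(tumor - normal, t_clamp)
    return GeneStatTrack(genes=cohort.genes, stat=t, mode=PAIRED_T, n_pairs=cohort.n_pairs)


def single_sample_z_stats(
    cohort: ExpressionCohort,
    tumor_sample: str,
    t_clamp: float = DEFAULT_T_CLAMP,
) -> GeneStatTrack:
    """Per-gene z of one tumor against the cohort's non-tumor reference.

    z = (x_tumor - mean_nontumor) / sd_nontumor, sample sd (n-1) over all
    non-tumor samples; zero-sd genes clamp as in paired_t_stats.
    """
    normals = cohort.non_tumor_samples
    if len(normals) < 3:
        raise ValueError("need >=3 non-tumor samples for the reference")
    if tumor_sample not in cohort.values.columns:
        raise KeyError(f"unknown sample id {tumor_sample!r}")
    ref = cohort.values[normals].to_numpy(float)
    x = cohort.values[tumor_sample].to_numpy(float)
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    zero_sd = sd == 0
    dev = x - mean
    z[zero_sd & (dev == 0)] = 0.0
    z[zero_sd & (dev != 0)] = np.sign(dev[zero_sd & (dev != 0)]) * t_clamp
    z = np.clip(z, -t_clamp, t_clamp)
    return GeneStatTrack(genes=cohort.genes, stat=z, mode=SINGLE_SAMPLE_Z)


def _ns_matrix(
    genes: pd.DataFrame, stat: np.ndarray, kernel: KernelSpec
) -> np.ndarray:
    """Sliding-window NS; accepts stat of shape (G,) or (G, R).

    For each gene the window of same-chromosome genes within the kernel
    support is located with binary search; the weighted sum is then taken
    directly over the window, which keeps floating-point behavior identical
    to the naive all-pairs computation.
    """
    stat2 = np.atleast_2d(stat.T).T  # (G, R)
    out = np.empty_like(stat2)
    chrom = genes["chrom"].to_numpy()
    mid = genes["midpoint"].to_numpy(float)
    hw = kernel.half_width_bp
    # contiguous chromosome blocks (genes are genomically sorted)
    boundaries = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1], True])
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        pos = mid[b0:b1]
        block = stat2[b0:b1]
        lo = np.searchsorted(pos, pos - hw, side="left")
        hi = np.searchsorted(pos, pos + hw, side="right")
        for i in range(len(pos)):
            w = 1.0 - np.abs(pos[lo[i]:hi[i]] - pos[i]) / hw
            np.clip(w, 0.0, None, out=w)
            out[b0 + i] = w @ block[lo[i]:hi[i]]
    return out.reshape(np.shape(stat))


def neighborhood_scores(
    stats: GeneStatTrack, kernel: KernelSpec | None = None
) -> NeighborhoodScoreTrack:
    """Smooth a per-gene statistic track into neighborhood scores."""
    kernel = kernel or KernelSpec()
    ns = _ns_matrix(stats.genes, stats.stat, kernel)
    return NeighborhoodScoreTrack(genes=stats.genes, ns=ns, kernel=kernel, mode=stats.mode)


def neighborhood_scores_batch(
    genes: pd.DataFrame, stat: np.ndarray, kernel: KernelSpec
) -> np.ndarray:
    """NS for a (genes x replicates) statistic matrix in one pass.

    Used by the permutation machinery, where many statistic tracks share
    one gene annotation.
    """
    return _ns_matrix(genes, np.asarray(stat, float), kernel)


def neighborhood_scores_naive(
    genes: pd.DataFrame, stat: np.ndarray, kernel: KernelSpec
) -> np.ndarray:
    """O(G^2) all-pairs reference for the sliding-window computation."""
    chrom = genes["chrom"].to_numpy()
    mid = genes["midpoint"].to_numpy(float)
    stat = np.asarray(stat, float)
    out = np.zeros_like(stat)
    for i in range(len(stat)):
        same = chrom == chrom[i]
        w = kernel.weight(mid[same] - mid[i])
        out[i] = float(np.dot(w, stat[same]))
    return out
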