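"""Per-sample CNA assessment at a target region and stratification rules.

A single tumor has no paired design to permute, so significance rests on
the gene-name permutation null alone: the sample's z-score track is
shuffled across genomic positions, the NS recomputed, and the empirical
FDR thresholded with the same alpha and minimum run length used for
cohorts.  A sample is "high" at a region when a qualifying aberrant run
of the region's direction overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ace_core import (
    DEFAULT_T_CLAMP,
    KernelSpec,
    neighborhood_scores,
    single_sample_z_stats,
)
from .io_formats import AMPLIFICATION, ExpressionCohort
from .significance import (
    AMP,
    DEL,
    ConsensusRegion,
    PermutationConfig,
    SegmentConfig,
    SCHEME_GENE_NAME,
    call_aberrant,
    call_segments,
    estimate_fdr,
    null_ns_gene_name,
)

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    region: ConsensusRegion
    ns_mean: float
    call: str


@dataclass(frozen=True)
class FoldChangeCall:
    sample_id: str
    gene_id: str
    fold_change: float
    call: str


def _region_gene_mask(cohort: ExpressionCohort, region: ConsensusRegion) -> np.ndarray:
    genes = cohort.genes
    return (
        (genes["chrom"] == region.chrom)
        & (genes["midpoint"] >= region.start)
        & (genes["midpoint"] <= region.end)
    ).to_numpy()


def assess_sample(
    cohort: ExpressionCohort,
    tumor_sample: str,
    region: ConsensusRegion,
    kernel: KernelSpec | None = None,
    perm_cfg: PermutationConfig | None = None,
    seg_cfg: SegmentConfig | None = None,
    t_clamp: float = DEFAULT_T_CLAMP,
) -> SampleCall:
    """Call one tumor high/low for a consensus region.

    Computes the z-score track against the cohort's non-tumor reference,
    its NS, the gene-name permutation FDR in the region's direction, and
    scans for qualifying aberrant runs overlapping the region.
    """
    kernel = kernel or KernelSpec()
    perm_cfg = perm_cfg or PermutationConfig()
    seg_cfg = seg_cfg or SegmentConfig()
    if not (cohort.genes["chrom"] == region.chrom).any():
        raise ValueError(f"region chromosome {region.chrom!r} absent from annotation")

    stats = single_sample_z_stats(cohort, tumor_sample, t_clamp=t_clamp)
    track = neighborhood_scores(stats, kernel)
    null = null_ns_gene_name(stats, kernel, perm_cfg)
    fdr = {
        (SCHEME_GENE_NAME, direction): estimate_fdr(track, null, direction)
        for direction in (AMP, DEL)
    }
    result = call_aberrant(track, fdr, seg_cfg, schemes=(SCHEME_GENE_NAME,))
    runs = call_segments(result, seg_cfg, cohort_id=tumor_sample)

    mask = _region_gene_mask(cohort, region)
    ns_mean = float(track.ns[mask].mean()) if mask.any() else float("nan")
    hit = any(
        seg.chrom == region.chrom
        and seg.direction == region.direction
        and seg.start <= region.end
        and seg.end >= region.start
        for seg in runs
    )
    return SampleCall(
        sample_id=tumor_sample,
        region=region,
        ns_mean=ns_mean,
        call=HIGH if hit else LOW,
    )


def region_mean_ns(
    cohort: ExpressionCohort,
    region: ConsensusRegion,
    kernel: KernelSpec | None = None,
    t_clamp: float = DEFAULT_T_CLAMP,
) -> dict[str, float]:
    """Region-mean single-sample NS for every tumor of the cohort.

    All tumors share the non-tumor reference, so the z tracks are computed
    in one batch; used for NS <-> array concordance.
    """
    from .ace_core import neighborhood_scores_batch

    kernel = kernel or KernelSpec()
    normals = cohort.non_tumor_samples
    if len(normals) < 3:
        raise ValueError("need >=3 non-tumor samples for the reference")
    ref = cohort.values[normals].to_numpy(float)
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    tumors = cohort.tumor_samples
    x = cohort.values[tumors].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean[:, None]) / sd[:, None]
    dev = x - mean[:, None]
    zero = sd == 0
    z[zero] = np.sign(dev[zero]) * t_clamp
    z[zero[:, None] & (dev == 0)] = 0.0
    np.clip(z, -t_clamp, t_clamp, out=z)
    ns = neighborhood_scores_batch(cohort.genes, z, kernel)
    mask = _region_gene_mask(cohort, region)
    if not mask.any():
        raise ValueError("no genes fall inside the region")
    means = ns[mask].mean(axis=0)
    return dict(zip(tumors, means.tolist()))


def fold_change_call(
    tumor_value: float,
    nontumor_value: float,
    sample_id: str = "",
    gene_id: str = "",
    threshold: float = 2.0,
) -> FoldChangeCall:
    """Tumor/non-tumor linear fold change from log2 values; high iff >= 2."""
    fc = float(2.0 ** (tumor_value - nontumor_value))
    return FoldChangeCall(
        sample_id=sample_id,
        gene_id=gene_id,
        fold_change=fc,
        call=HIGH if fc >= threshold else LOW,
    )
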