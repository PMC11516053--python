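"""Permutation significance for neighborhood scores and segment calling.

Two null schemes bracket the two ways an NS peak could arise by chance:

* sample-label permutation — per-pair tumor/non-tumor swaps (sign flips of
  the paired differences) destroy the tumor/normal contrast while keeping
  every gene's variance and the genomic autocorrelation of the track;
* gene-name permutation — statistics are shuffled across genomic positions,
  destroying genomic contiguity while keeping the marginal distribution of
  the per-gene statistics.

A gene is aberrant only when its empirical FDR clears the threshold under
BOTH schemes in the same direction, and only runs of at least ``min_run``
consecutive aberrant genes become segments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ace_core import (
    GeneStatTrack,
    KernelSpec,
    NeighborhoodScoreTrack,
    _t_from_diffs,
    DEFAULT_T_CLAMP,
    PAIRED_T,
    neighborhood_scores,
    neighborhood_scores_batch,
)
from .io_formats import AMPLIFICATION, DELETION, CnaSegmentRecord, ExpressionCohort

logger = logging.getLogger(__name__)

AMP = "amp"
DEL = "del"
NONE = "none"

SCHEME_SAMPLE_LABEL = "sample_label"
SCHEME_GENE_NAME = "gene_name"


@dataclass(frozen=True)
class PermutationConfig:
    n_sample_label: int = 1000
    n_gene_name: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample_label < 1 or self.n_gene_name < 1:
            raise ValueError("permutation counts must be >= 1")


@dataclass(frozen=True)
class SegmentConfig:
    min_run: int = 10
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class NullNsCollection:
    """Null NS values, shape (n_genes, n_replicates), plus provenance."""

    ns: np.ndarray
    scheme: str
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.ns.shape[1]


@dataclass
class SignificanceResult:
    genes: pd.DataFrame
    ns_observed: np.ndarray
    # per-scheme per-direction FDR arrays, keyed (scheme, direction)
    fdr: dict[tuple[str, str], np.ndarray]
    aberrant: np.ndarray  # per-gene flag in {amp, del, none}

    def to_frame(self) -> pd.DataFrame:
        df = self.genes[["gene_id", "chrom", "midpoint"]].copy()
        df["ns"] = self.ns_observed
        for (scheme, direction), vals in sorted(self.fdr.items()):
            df[f"fdr_{direction}_{scheme}"] = vals
        df["aberrant"] = self.aberrant
        return df


def null_ns_sample_label(
    cohort: ExpressionCohort,
    kernel: KernelSpec,
    cfg: PermutationConfig,
    t_clamp: float = DEFAULT_T_CLAMP,
) -> NullNsCollection:
    """Null NS under per-pair tumor/non-tumor label swaps.

    Each replicate independently swaps the labels of each pair with
    probability 1/2, equivalent to flipping the sign of that pair's
    difference column, then recomputes the paired t track and its NS.
    """
    tumor, normal = cohort.paired_matrices()
    diffs = tumor - normal  # (G, P)
    n_pairs = diffs.shape[1]
    rng = np.random.default_rng(cfg.seed)
    flips = rng.integers(0, 2, size=(cfg.n_sample_label, n_pairs)) * 2 - 1
    # t statistics for all replicates at once: sign flips leave sum(d^2)
    # untouched, so only the mean varies across replicates.
    n = n_pairs
    means = diffs @ (flips.T / n)  # (G, B)
    sumsq = np.einsum("gp,gp->g", diffs, diffs)
    if n > 1:
        var = np.maximum((sumsq[:, None] - n * means**2) / (n - 1), 0.0)
    else:
        var = np.zeros_like(means)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (means == 0)] = 0.0
    t[zero_sd & (means != 0)] = (
        np.sign(means[zero_sd & (means != 0)]) * t_clamp
    )
    np.clip(t, -t_clamp, t_clamp, out=t)
    ns = neighborhood_scores_batch(cohort.genes, t, kernel)
    return NullNsCollection(ns=ns, scheme=SCHEME_SAMPLE_LABEL, seed=cfg.seed)


def null_ns_gene_name(
    stats: GeneStatTrack, kernel: KernelSpec, cfg: PermutationConfig
) -> NullNsCollection:
    """Null NS with the observed statistics shuffled across gene positions."""
    rng = np.random.default_rng(cfg.seed)
    g = len(stats.stat)
    perm = np.empty((g, cfg.n_gene_name))
    for b in range(cfg.n_gene_name):
        perm[:, b] = stats.stat[rng.permutation(g)]
    ns = neighborhood_scores_batch(stats.genes, perm, kernel)
    return NullNsCollection(ns=ns, scheme=SCHEME_GENE_NAME, seed=cfg.seed)


def estimate_fdr(
    observed: NeighborhoodScoreTrack | np.ndarray,
    null: NullNsCollection,
    direction: str,
) -> np.ndarray:
    """Empirical per-gene FDR for one direction against one null scheme.

    For amplification the score is the NS itself; for deletion the negated
    NS, so "more extreme" is always "larger".  At gene i's score s_i the
    raw estimate is

        FDR_i = min(1, (mean null count >= s_i + 1/B) / max(1, obs count >= s_i))

    with B replicates; the +1/B pseudocount keeps FDRs away from zero.  The
    raw values are then monotonized so FDR never increases with score:
    each gene takes the minimum raw FDR over all genes with score <= its own
    (the usual step-up construction).
    """
    ns_obs = observed.ns if isinstance(observed, NeighborhoodScoreTrack) else observed
    ns_obs = np.asarray(ns_obs, float)
    if direction == AMP:
        s_obs, s_null = ns_obs, null.ns
    elif direction == DEL:
        s_obs, s_null = -ns_obs, -null.ns
    else:
        raise ValueError(f"direction must be {AMP!r} or {DEL!r}")

    B = null.n_replicates
    null_sorted = np.sort(s_null, axis=None)
    obs_sorted = np.sort(s_obs)
    n_null_ge = len(null_sorted) - np.searchsorted(null_sorted, s_obs, side="left")
    n_obs_ge = len(s_obs) - np.searchsorted(obs_sorted, s_obs, side="left")
    raw = np.minimum(
        1.0, (n_null_ge / B + 1.0 / B) / np.maximum(1, n_obs_ge)
    )
    # step-up: q_i = min{ raw_j : s_j <= s_i }
    order = np.argsort(s_obs, kind="stable")
    q = np.empty_like(raw)
    q[order] = np.minimum.accumulate(raw[order])
    return q


def call_aberrant(
    observed: NeighborhoodScoreTrack,
    fdr: dict[tuple[str, str], np.ndarray],
    cfg: SegmentConfig,
    schemes: tuple[str, ...] = (SCHEME_SAMPLE_LABEL, SCHEME_GENE_NAME),
) -> SignificanceResult:
    """Flag genes aberrant where FDR < alpha under every required scheme.

    Directions cannot collide: an amp call additionally requires NS > 0 and
    a del call NS < 0.
    """
    g = len(observed.ns)
    flags = np.array([NONE] * g, dtype=object)
    for direction, sign in ((AMP, 1.0), (DEL, -1.0)):
        ok = np.ones(g, bool)
        for scheme in schemes:
            ok &= fdr[(scheme, direction)] < cfg.alpha
        ok &= sign * observed.ns > 0
        flags[ok] = direction
    return SignificanceResult(
        genes=observed.genes, ns_observed=observed.ns, fdr=dict(fdr), aberrant=flags
    )


_DIRECTION_NAME = {AMP: AMPLIFICATION, DEL: DELETION}


def call_segments(
    result: SignificanceResult, cfg: SegmentConfig, cohort_id: str = "cohort"
) -> list[CnaSegmentRecord]:
    """Maximal same-direction runs of aberrant genes, kept if >= min_run.

    Segment coordinates are the first gene's annotated start and the last
    gene's annotated end.
    """
    genes = result.genes
    chrom = genes["chrom"].to_numpy()
    flags = result.aberrant
    segments: list[CnaSegmentRecord] = []
    i = 0
    g = len(flags)
    while i < g:
        if flags[i] == NONE:
            i += 1
            continue
        j = i
        while j + 1 < g and flags[j + 1] == flags[i] and chrom[j + 1] == chrom[i]:
            j += 1
        run_len = j - i + 1
        if run_len >= cfg.min_run:
            segments.append(
                CnaSegmentRecord(
                    chrom=str(chrom[i]),
                    start=int(genes["start"].iloc[i]),
                    end=int(genes["end"].iloc[j]),
                    direction=_DIRECTION_NAME[flags[i]],
                    n_genes=run_len,
                    mean_ns=float(result.ns_observed[i : j + 1].mean()),
                    cohort_id=cohort_id,
                )
            )
        i = j + 1
    return segments


def detect_cohort_cnas(
    cohort: ExpressionCohort,
    kernel: KernelSpec | None = None,
    perm_cfg: PermutationConfig | None = None,
    seg_cfg: SegmentConfig | None = None,
    cohort_id: str = "cohort",
    t_clamp: float = DEFAULT_T_CLAMP,
) -> tuple[NeighborhoodScoreTrack, SignificanceResult, list[CnaSegmentRecord]]:
    """Full cohort path: paired t -> NS -> both nulls -> FDR -> segments."""
    from .ace_core import paired_t_stats

    kernel = kernel or KernelSpec()
    perm_cfg = perm_cfg or PermutationConfig()
    seg_cfg = seg_cfg or SegmentConfig()
    stats = paired_t_stats(cohort, t_clamp=t_clamp)
    track = neighborhood_scores(stats, kernel)
    null_sl = null_ns_sample_label(cohort, kernel, perm_cfg, t_clamp=t_clamp)
    null_gn = null_ns_gene_name(
        stats,
        kernel,
        PermutationConfig(
            n_sample_label=perm_cfg.n_sample_label,
            n_gene_name=perm_cfg.n_gene_name,
            seed=perm_cfg.seed + 1,
        ),
    )
    fdr = {}
    for null in (null_sl, null_gn):
        for direction in (AMP, DEL):
            fdr[(null.scheme, direction)] = estimate_fdr(track, null, direction)
    result = call_aberrant(track, fdr, seg_cfg)
    segments = call_segments(result, seg_cfg, cohort_id=cohort_id)
    return track, result, segments


@dataclass(frozen=True)
class ConsensusRegion:
    """Minimal common interval of same-direction segments across cohorts."""

    chrom: str
    start: int
    end: int
    direction: str
    supporting_cohorts: frozenset[str]
    n_support: int

    @property
    def width_bp(self) -> int:
        return self.end - self.start + 1


def _overlap_components(
    segs: list[CnaSegmentRecord],
) -> list[list[CnaSegmentRecord]]:
    """Connected components of the interval-overlap graph (transitive)."""
    segs = sorted(segs, key=lambda s: (s.start, s.end, s.cohort_id))
    groups: list[list[CnaSegmentRecord]] = []
    current: list[CnaSegmentRecord] = []
    reach = -1
    for s in segs:
        if current and s.start > reach:
            groups.append(current)
            current = []
        current.append(s)
        reach = max(reach, s.end)
    if current:
        groups.append(current)
    return groups


def _best_intersection(
    group: list[CnaSegmentRecord],
) -> tuple[int, int, frozenset[str]] | None:
    """Pick one segment per cohort maximizing the common intersection.

    Exhaustive over the per-cohort choices (groups are small); ties broken
    by the leftmost interval.  Returns None if every combination is empty.
    """
    by_cohort: dict[str, list[CnaSegmentRecord]] = {}
    for s in group:
        by_cohort.setdefault(s.cohort_id, []).append(s)
    cohorts = sorted(by_cohort)
    best: tuple[int, int] | None = None
    for combo in itertools.product(*(by_cohort[c] for c in cohorts)):
        start = max(s.start for s in combo)
        end = min(s.end for s in combo)
        if end < start:
            continue
        if (
            best is None
            or (end - start) > (best[1] - best[0])
            or ((end - start) == (best[1] - best[0]) and start < best[0])
        ):
            best = (start, end)
    if best is None:
        return None
    return best[0], best[1], frozenset(cohorts)


def consensus_regions(
    segments_by_cohort: dict[str, list[CnaSegmentRecord]],
    min_cohorts: int | None = None,
) -> list[ConsensusRegion]:
    """Cross-cohort minimal common intervals.

    Same-chromosome, same-direction segments are grouped by transitive
    overlap; a group supported by >= min_cohorts distinct cohorts yields a
    region spanning the intersection (max start, min end) of one segment
    per supporting cohort.  min_cohorts defaults to half the cohorts,
    rounded up.
    """
    if not segments_by_cohort:
        raise ValueError("need at least one cohort")
    if min_cohorts is None:
        min_cohorts = -(-len(segments_by_cohort) // 2)

    pooled: dict[tuple[str, str], list[CnaSegmentRecord]] = {}
    for segs in segments_by_cohort.values():
        for s in segs:
            pooled.setdefault((s.chrom, s.direction), []).append(s)

    regions: list[ConsensusRegion] = []
    for (chrom, direction), segs in sorted(pooled.items()):
        for group in _overlap_components(segs):
            n_cohorts = len({s.cohort_id for s in group})
            if n_cohorts < min_cohorts:
                continue
            picked = _best_intersection(group)
            if picked is None:
                # transitive chain with empty common core: fall back to
                # pairwise-overlap components and retry each
                logger.info(
                    "empty intersection in consensus group on %s; splitting", chrom
                )
                for sub in _split_pairwise(group):
                    sub_cohorts = len({s.cohort_id for s in sub})
                    if sub_cohorts < min_cohorts:
                        continue
                    sub_picked = _best_intersection(sub)
                    if sub_picked is None:
                        continue
                    start, end, cohorts = sub_picked
                    regions.append(
                        ConsensusRegion(chrom, start, end, direction, cohorts, len(cohorts))
                    )
                continue
            start, end, cohorts = picked
            regions.append(
                ConsensusRegion(chrom, start, end, direction, cohorts, len(cohorts))
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


def _split_pairwise(group: list[CnaSegmentRecord]) -> list[list[CnaSegmentRecord]]:
    """Split a transitive group into components of mutually overlapping cores."""
    remaining = sorted(group, key=lambda s: (s.start, s.end))
    out: list[list[CnaSegmentRecord]] = []
    while remaining:
        seed = remaining.pop(0)
        comp = [seed]
        lo, hi = seed.start, seed.end
        rest = []
        for s in remaining:
            if s.start <= hi and s.end >= lo:
                comp.append(s)
                lo, hi = max(lo, s.start), min(hi, s.end)
            else:
                rest.append(s)
        remaining = rest
        out.append(comp)
    return out


def consensus_to_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "width_bp": r.width_bp,
                "direction": r.direction,
                "n_support": r.n_support,
                "supporting_cohorts": ",".join(sorted(r.supporting_cohorts)),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "width_bp", "direction",
            "n_support", "supporting_cohorts",
        ],
    )
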