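"""Expression preprocessing: presence filter, probe summarization, log2,
quantile normalization, and within-group median imputation.

The presence filter is strictly greater-than: a probe observed in exactly
90% of samples is dropped at the default threshold of 0.9.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionCohort

logger = logging.getLogger(__name__)

PROBE_META_COLUMNS = ["probe_id", "gene_id", "is_exonic"]


@dataclass(frozen=True)
class PreprocessConfig:
    min_presence_fraction: float = 0.9
    log2_offset: float = 1.0
    impute: str = "gene_median_within_group"
    quantile_joint: bool = True  # normalize tumor and non-tumor arrays together

    def __post_init__(self) -> None:
        if not 0.0 < self.min_presence_fraction < 1.0:
            raise ValueError("min_presence_fraction must be in (0, 1)")
        if self.log2_offset < 0:
            raise ValueError("log2_offset must be >= 0")
        if self.impute != "gene_median_within_group":
            raise ValueError(f"unknown imputation scheme {self.impute!r}")


@dataclass
class ProbeTable:
    """Probe-level intensities with probe->gene mapping.

    meta: DataFrame with columns probe_id, gene_id, is_exonic (probe_id unique).
    values: probes x samples DataFrame, index aligned with meta.probe_id.
    """

    meta: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta["probe_id"].duplicated().any():
            dup = self.meta["probe_id"][self.meta["probe_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate probe id {dup!r}")
        if list(self.meta["probe_id"]) != list(self.values.index):
            raise ValueError("meta and values row order disagree")


def filter_probes(probes: ProbeTable, cfg: PreprocessConfig) -> ProbeTable:
    """Keep probes whose non-missing fraction strictly exceeds the threshold."""
    if probes.values.empty:
        raise ValueError("empty probe table")
    frac = probes.values.notna().mean(axis=1)
    keep = (frac > cfg.min_presence_fraction).to_numpy()
    if not keep.any():
        raise ValueError(
            "presence filter removed every probe; review min_presence_fraction"
        )
    return ProbeTable(
        meta=probes.meta[keep].reset_index(drop=True),
        values=probes.values[keep],
    )


def summarize_probes(probes: ProbeTable) -> pd.DataFrame:
    """Per-gene arithmetic mean over exonic probes (non-exonic ignored).

    Genes whose probes are all non-exonic are dropped; the count is logged.
    Gene order follows first appearance in the probe table.
    """
    exonic = probes.meta["is_exonic"].to_numpy(bool)
    all_genes = probes.meta["gene_id"].drop_duplicates()
    meta = probes.meta[exonic]
    vals = probes.values[exonic]
    n_dropped = len(set(all_genes) - set(meta["gene_id"]))
    if n_dropped:
        logger.info("dropped %d genes with no exonic probe", n_dropped)
    grouped = vals.groupby(meta["gene_id"].to_numpy(), sort=False).mean()
    grouped.index.name = "gene_id"
    return grouped


def log2_transform(table: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """x -> log2(x + offset); linear-scale input must be non-negative."""
    arr = table.to_numpy(float)
    if np.nanmin(arr) < 0:
        raise ValueError("negative value in linear-scale expression table")
    return pd.DataFrame(
        np.log2(arr + cfg.log2_offset), index=table.index, columns=table.columns
    )


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so tied inputs stay tied in the output.  Idempotent.
    """
    if table.isna().any().any():
        raise ValueError("missing values; impute before quantile normalization")
    if table.shape[1] == 1:
        warnings.warn("single-column table: quantile normalization is a no-op")
        return table.copy()
    arr = table.to_numpy(float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # average reference values over tied input ranks
        ser = pd.Series(mapped).groupby(col).transform("mean")
        out[:, j] = ser.to_numpy()
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def impute_missing(cohort: ExpressionCohort, cfg: PreprocessConfig) -> ExpressionCohort:
    """Replace missing cells by the gene's median within the sample's group."""
    values = cohort.values
    if not values.isna().any().any():
        return cohort
    out = values.copy()
    for cols in (cohort.tumor_samples, cohort.non_tumor_samples):
        block = out[cols]
        med = block.median(axis=1)
        fully_missing = block.isna().all(axis=1)
        if fully_missing.any():
            gene = block.index[fully_missing][0]
            raise ValueError(
                f"gene {gene!r} entirely missing within one group; cannot impute"
            )
        out[cols] = block.apply(lambda c: c.fillna(med))
    return cohort.with_values(out)


def preprocess_cohort(
    cohort: ExpressionCohort,
    cfg: PreprocessConfig | None = None,
    normalize: bool = True,
) -> ExpressionCohort:
    """Impute residual missingness, then quantile-normalize (jointly, all
    samples of the cohort together)."""
    cfg = cfg or PreprocessConfig()
    cohort = impute_missing(cohort, cfg)
    if normalize:
        if cfg.quantile_joint:
            cohort = cohort.with_values(quantile_normalize(cohort.values))
        else:
            out = cohort.values.copy()
            for cols in (cohort.tumor_samples, cohort.non_tumor_samples):
                out[cols] = quantile_normalize(cohort.values[cols])
            cohort = cohort.with_values(out)
    return cohort
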