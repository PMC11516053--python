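"""Synthetic paired tumor/normal cohorts with focal CNA dosage effects.

The generator emulates the statistical structure the inference assumes:
genes scattered along chromosomes with irregular (exponential) spacing,
per-gene baseline expression shared by a tumor and its matched normal,
and focal CNA regions carried by a fraction of tumors that shift the
log2 expression of every spanned gene by ``dosage_slope * log2(copy/2)``
— the cis-dosage model.  Matched observables are emitted for validation:
a per-sample array log-ratio per region (log2(copy/2) plus noise) and a
qPCR Ct panel whose target genes are shifted by -log2(copy/2) cycles in
tumor tissue relative to the three-gene internal reference.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionCohort
from .validation_scores import QpcrPanel, REFERENCE_GENES, TARGET_GENES


@dataclass(frozen=True)
class CnaRegionSpec:
    chrom: str
    start: int
    end: int
    copy_number: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is diploid; the region would be a no-op")
        if self.end < self.start:
            raise ValueError("region end < start")

    @property
    def log2_dosage(self) -> float:
        """log2(copy/2); -inf-safe floor at copy number 0.125."""
        return float(np.log2(max(self.copy_number, 0.125) / 2.0))


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 5000
    n_chromosomes: int = 5
    gene_spacing_bp: float = 100_000.0
    n_pairs: int = 30
    baseline_mean_sd: float = 2.0
    noise_sd: float = 0.5
    cna_regions: tuple[CnaRegionSpec, ...] = ()
    dosage_slope: float = 1.0
    array_noise_sd: float = 0.2
    qpcr_ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_pairs < 1:
            raise ValueError("counts must be positive")
        for sd in (self.baseline_mean_sd, self.noise_sd, self.array_noise_sd,
                   self.qpcr_ct_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a simulated cohort."""

    regions: tuple[CnaRegionSpec, ...]
    carriers: dict[CnaRegionSpec, frozenset[str]]
    copy_number: pd.DataFrame  # regions x tumor samples (2.0 where diploid)
    array_lr: pd.DataFrame  # regions x tumor samples, noisy log2(copy/2)
    qpcr_panels: dict[str, QpcrPanel]  # tumor sample -> Ct panel

    def region_label(self, region: CnaRegionSpec) -> str:
        return f"{region.chrom}:{region.start}-{region.end}"


def _simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    rows = []
    gi = 0
    for c, n in enumerate(per_chrom, start=1):
        gaps = rng.exponential(cfg.gene_spacing_bp, size=n)
        starts = np.maximum(1, np.cumsum(gaps).astype(np.int64))
        lengths = rng.integers(1_000, 50_000, size=n)
        for s, L in zip(starts, lengths):
            rows.append((f"G{gi:05d}", f"chr{c}", int(s), int(s + L)))
            gi += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df.sort_values(["chrom", "midpoint", "gene_id"], kind="stable").reset_index(
        drop=True
    )


_BASELINE_MEAN = 8.0  # log2 microarray-scale center
_QPCR_BASE_CT = 26.0


def simulate_cohort(cfg: SimulationConfig) -> tuple[ExpressionCohort, SyntheticTruth]:
    """Draw one paired cohort plus matched array/qPCR observables."""
    rng = np.random.default_rng(cfg.seed)
    genes = _simulate_annotation(cfg, rng)
    g = len(genes)

    chrom_max = genes.groupby("chrom")["end"].max()
    for region in cfg.cna_regions:
        if region.chrom not in chrom_max.index:
            raise ValueError(f"region chromosome {region.chrom!r} not simulated")
        if region.start > chrom_max[region.chrom]:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} lies outside "
                f"the simulated coordinates (chrom ends at {chrom_max[region.chrom]})"
            )

    tumors = [f"T{k:03d}" for k in range(cfg.n_pairs)]
    normals = [f"N{k:03d}" for k in range(cfg.n_pairs)]
    pairing = dict(zip(tumors, normals))

    baseline = _BASELINE_MEAN + rng.normal(0.0, cfg.baseline_mean_sd, size=g)

    # per-region carrier draws and per-sample copy numbers
    carriers: dict[CnaRegionSpec, frozenset[str]] = {}
    copy = pd.DataFrame(2.0, index=[f"{r.chrom}:{r.start}-{r.end}" for r in cfg.cna_regions],
                        columns=tumors)
    dosage_shift = np.zeros((g, cfg.n_pairs))
    mid = genes["midpoint"].to_numpy()
    chrom_arr = genes["chrom"].to_numpy()
    for region in cfg.cna_regions:
        is_carrier = rng.random(cfg.n_pairs) < region.carrier_fraction
        carriers[region] = frozenset(np.array(tumors)[is_carrier].tolist())
        label = f"{region.chrom}:{region.start}-{region.end}"
        copy.loc[label, is_carrier] = region.copy_number
        in_region = (
            (chrom_arr == region.chrom) & (mid >= region.start) & (mid <= region.end)
        )
        dosage_shift[np.ix_(in_region, is_carrier)] += (
            cfg.dosage_slope * region.log2_dosage
        )

    normal_vals = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(g, cfg.n_pairs))
    tumor_vals = (
        baseline[:, None]
        + dosage_shift
        + rng.normal(0.0, cfg.noise_sd, size=(g, cfg.n_pairs))
    )
    values = pd.DataFrame(
        np.hstack([tumor_vals, normal_vals]),
        index=genes["gene_id"],
        columns=tumors + normals,
    )
    cohort = ExpressionCohort(genes=genes, values=values, pairing=pairing)

    # matched array log-ratios per region x tumor
    lr = pd.DataFrame(index=copy.index, columns=tumors, dtype=float)
    for label in copy.index:
        dosage = np.log2(np.maximum(copy.loc[label].to_numpy(float), 0.125) / 2.0)
        lr.loc[label] = dosage + rng.normal(0.0, cfg.array_noise_sd, size=cfg.n_pairs)

    # qPCR panels keyed to the FIRST region (the assay targets one locus);
    # diploid for every sample when no region is simulated
    panels: dict[str, QpcrPanel] = {}
    region_dosage = (
        copy.iloc[0].to_numpy(float) if len(cfg.cna_regions) else np.full(cfg.n_pairs, 2.0)
    )
    for k, sample in enumerate(tumors):
        shift = -float(np.log2(max(region_dosage[k], 0.125) / 2.0))
        noise = lambda: float(rng.normal(0.0, cfg.qpcr_ct_noise_sd))
        target_ct = {
            gname: {
                "tumor": _QPCR_BASE_CT + shift + noise(),
                "normal": _QPCR_BASE_CT + noise(),
            }
            for gname in TARGET_GENES
        }
        reference_ct = {
            gname: {
                "tumor": _QPCR_BASE_CT + noise(),
                "normal": _QPCR_BASE_CT + noise(),
            }
            for gname in REFERENCE_GENES
        }
        panels[sample] = QpcrPanel(target_ct=target_ct, reference_ct=reference_ct)

    truth = SyntheticTruth(
        regions=cfg.cna_regions,
        carriers=carriers,
        copy_number=copy,
        array_lr=lr,
        qpcr_panels=panels,
    )
    return cohort, truth


def null_cohort(cfg: SimulationConfig) -> tuple[ExpressionCohort, SyntheticTruth]:
    """A cohort with no CNA regions, for type-I-error calibration."""
    return simulate_cohort(replace(cfg, cna_regions=()))
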