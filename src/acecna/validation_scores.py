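"""Orthogonal copy-number readouts and clinical scoring formulas.

qPCR relative copy number uses the comparative-Ct (ddCt) method with a
three-gene internal reference panel: for each target gene the Ct is first
referenced to the mean Ct of the three reference genes within the same
tissue, the tumor dCt is then compared to the matched normal dCt, and
2**(-ddCt) gives the linear relative copy number.  The readout is the
arithmetic mean over the three target genes; a value strictly above 1.25
is a genomic gain.

Array calls threshold the segment-mean log2 ratio at +/-0.3 (strict);
the IHC combined score sums a 0-5 proportion category and a 0-4 intensity
category (zero-proportion slides score 0, so the attainable set is
{0, 2..9}); xenograft tumor volume is the caliper ellipsoid estimate
V = L * W^2 / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Mapping

import numpy as np
from scipy import stats as sps

TARGET_GENES = ("C8orf76", "ATAD2", "NDUFB9")
REFERENCE_GENES = ("LTBP1", "SATB1", "ANO3")

GAIN_THRESHOLD = 1.25
LR_GAIN = 0.3
LR_LOSS = -0.3

TissueCt = Mapping[str, float]  # {"tumor": Ct, "normal": Ct}


@dataclass(frozen=True)
class QpcrPanel:
    """Ct values for the 3 target and 3 reference genes, both tissues."""

    target_ct: Mapping[str, TissueCt]
    reference_ct: Mapping[str, TissueCt]

    def __post_init__(self) -> None:
        for genes, table, kind in (
            (TARGET_GENES, self.target_ct, "target"),
            (REFERENCE_GENES, self.reference_ct, "reference"),
        ):
            for g in genes:
                if g not in table:
                    raise ValueError(f"missing {kind} gene {g!r}")
                for tissue in ("tumor", "normal"):
                    ct = table[g].get(tissue)
                    if ct is None:
                        raise ValueError(f"missing {tissue} Ct for {g!r}")
                    if not ct > 0:
                        raise ValueError(f"non-positive Ct for {g!r}/{tissue}")


@dataclass(frozen=True)
class RelativeCopyNumberCall:
    rcn: float  # linear, 1.0 = same dosage as normal
    gain: bool
    per_target: Mapping[str, float]


@dataclass(frozen=True)
class ArrayLrCall:
    segment_lr_mean: float
    call: str  # gain / loss / neutral


@dataclass(frozen=True)
class IhcScore:
    proportion_score: int
    intensity_score: int
    overall: int


def relative_copy_number(panel: QpcrPanel) -> RelativeCopyNumberCall:
    """ddCt relative copy number averaged over the three target genes."""
    ref_tumor = mean(panel.reference_ct[g]["tumor"] for g in REFERENCE_GENES)
    ref_normal = mean(panel.reference_ct[g]["normal"] for g in REFERENCE_GENES)
    per_target = {}
    for g in TARGET_GENES:
        dct_tumor = panel.target_ct[g]["tumor"] - ref_tumor
        dct_normal = panel.target_ct[g]["normal"] - ref_normal
        per_target[g] = float(2.0 ** -(dct_tumor - dct_normal))
    rcn = float(mean(per_target.values()))
    return RelativeCopyNumberCall(
        rcn=rcn, gain=rcn > GAIN_THRESHOLD, per_target=per_target
    )


def array_call(segment_lr_mean: float) -> ArrayLrCall:
    """Gain / loss / neutral from a segment-mean log2 ratio (strict +/-0.3)."""
    if segment_lr_mean > LR_GAIN:
        call = "gain"
    elif segment_lr_mean < LR_LOSS:
        call = "loss"
    else:
        call = "neutral"
    return ArrayLrCall(segment_lr_mean=float(segment_lr_mean), call=call)


def ns_array_concordance(
    ns_per_sample: Mapping[str, float] | np.ndarray,
    lr_per_sample: Mapping[str, float] | np.ndarray,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between region-mean NS and array LR.

    Mapping inputs are matched on sample id; array inputs positionally.
    """
    if isinstance(ns_per_sample, Mapping):
        if not isinstance(lr_per_sample, Mapping):
            raise TypeError("both inputs must be mappings or both arrays")
        common = sorted(set(ns_per_sample) & set(lr_per_sample))
        x = np.array([ns_per_sample[s] for s in common], float)
        y = np.array([lr_per_sample[s] for s in common], float)
    else:
        x = np.asarray(ns_per_sample, float)
        y = np.asarray(lr_per_sample, float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ihc_overall(proportion_score: int, intensity_score: int) -> IhcScore:
    """Combined IHC score: 0 for negative slides, else proportion+intensity."""
    if proportion_score not in range(6):
        raise ValueError("proportion score must be an integer 0-5")
    if intensity_score not in range(5):
        raise ValueError("intensity score must be an integer 0-4")
    if proportion_score == 0:
        if intensity_score != 0:
            raise ValueError("no positive cells but non-zero intensity")
        overall = 0
    else:
        if intensity_score == 0:
            raise ValueError("positive cells but zero intensity")
        overall = proportion_score + intensity_score
    return IhcScore(proportion_score, intensity_score, overall)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: V = L * W^2 / 2."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    return 0.5 * length_mm * width_mm**2
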