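import numpy as np
import pandas as pd
import pytest

from acecna.io_formats import ExpressionCohort
from acecna.significance import ConsensusRegion
from acecna.synthetic_data import CnaRegionSpec, SimulationConfig, simulate_cohort


def make_annotation(positions, chroms=None, gene_ids=None, length=1000):
    """Annotation frame from midpoint-ish positions (start=pos, end=pos+length)."""
    n = len(positions)
    chroms = chroms or ["chr1"] * n
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": [int(p) for p in positions],
            "end": [int(p) + length for p in positions],
        }
    )
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df.sort_values(["chrom", "midpoint", "gene_id"], kind="stable").reset_index(
        drop=True
    )


def make_cohort(values, positions=None, chroms=None, n_pairs=None):
    """ExpressionCohort from a (genes x 2*pairs) array: tumors first."""
    values = np.asarray(values, float)
    g, s = values.shape
    n_pairs = n_pairs or s // 2
    positions = positions if positions is not None else np.arange(g) * 1_000_000
    genes = make_annotation(positions, chroms=chroms)
    tumors = [f"T{i}" for i in range(n_pairs)]
    normals = [f"N{i}" for i in range(n_pairs)]
    vals = pd.DataFrame(values, index=genes["gene_id"], columns=tumors + normals)
    return ExpressionCohort(
        genes=genes, values=vals, pairing=dict(zip(tumors, normals))
    )


AMP_REGION_SPEC = CnaRegionSpec(
    chrom="chr1", start=40_000_000, end=42_000_000, copy_number=4.0,
    carrier_fraction=0.5,
)
AMP_REGION = ConsensusRegion(
    chrom="chr1", start=40_000_000, end=42_000_000, direction="amplification",
    supporting_cohorts=frozenset(), n_support=0,
)


def amp_config(seed, **overrides):
    """Study-condition simulation: 30 pairs, 5000 genes, one 2 Mb gain."""
    kwargs = dict(seed=seed, cna_regions=(AMP_REGION_SPEC,))
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def amp_cohort():
    """One simulated cohort carrying the canonical amplification."""
    return simulate_cohort(amp_config(seed=1))


@pytest.fixture
def toy_files(tmp_path):
    """3-gene, 2-pair on-disk fixture for the io round trip."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene_id\tT1\tT2\tN1\tN2\n"
        "gA\t5.0\t6.0\t4.0\t4.5\n"
        "gB\t2.0\t2.5\t2.0\t2.2\n"
        "gC\t7.0\t7.5\t7.1\t6.9\n"
    )
    anno = tmp_path / "anno.bed"
    anno.write_text(
        "chr1\t100\t2100\tgA\n"
        "chr1\t5000\t9000\tgB\n"
        "chr2\t100\t1100\tgC\n"
    )
    pairs = tmp_path / "pairs.tsv"
    pairs.write_text("T1\tN1\nT2\tN2\n")
    return expr, anno, pairs
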