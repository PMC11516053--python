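import itertools

import numpy as np
import pytest

from acecna.ace_core import GeneStatTrack, KernelSpec, neighborhood_scores
from acecna.io_formats import CnaSegmentRecord
from acecna.significance import (
    AMP,
    DEL,
    NONE,
    NullNsCollection,
    PermutationConfig,
    SCHEME_GENE_NAME,
    SCHEME_SAMPLE_LABEL,
    SegmentConfig,
    SignificanceResult,
    call_aberrant,
    call_segments,
    consensus_regions,
    estimate_fdr,
    null_ns_gene_name,
    null_ns_sample_label,
)
from conftest import make_annotation, make_cohort

KERNEL = KernelSpec()


class TestSampleLabelNull:
    def test_seed_determinism(self):
        rng = np.random.default_rng(20)
        cohort = make_cohort(rng.normal(size=(40, 12)), n_pairs=6)
        cfg = PermutationConfig(n_sample_label=25, n_gene_name=25, seed=7)
        a = null_ns_sample_label(cohort, KERNEL, cfg)
        b = null_ns_sample_label(cohort, KERNEL, cfg)
        np.testing.assert_array_equal(a.ns, b.ns)

    def test_single_pair_single_gene_enumerates_sign_flips(self):
        # one pair, difference d != 0: the only replicate stats are the
        # clamped +/- t(d)
        cohort = make_cohort([[4.0, 1.0]], n_pairs=1)
        cfg = PermutationConfig(n_sample_label=64, n_gene_name=1, seed=3)
        null = null_ns_sample_label(cohort, KERNEL, cfg)
        assert set(np.unique(null.ns)) == {-50.0, 50.0}

    def test_identical_groups_make_null_match_observed_law(self):
        # tumor block identical to normal block: every difference is 0, so
        # observed and every replicate are all-zero tracks
        rng = np.random.default_rng(21)
        half = rng.normal(size=(30, 5))
        cohort = make_cohort(np.hstack([half, half]), n_pairs=5)
        cfg = PermutationConfig(n_sample_label=10, n_gene_name=1, seed=0)
        null = null_ns_sample_label(cohort, KERNEL, cfg)
        assert np.all(null.ns == 0.0)


class TestGeneNameNull:
    def test_constant_stats_are_permutation_invariant(self):
        genes = make_annotation(np.arange(20) * 500_000)
        track = GeneStatTrack(genes=genes, stat=np.full(20, 1.5), mode="paired_t")
        observed = neighborhood_scores(track, KERNEL).ns
        null = null_ns_gene_name(
            track, KERNEL, PermutationConfig(n_sample_label=1, n_gene_name=8, seed=1)
        )
        for b in range(8):
            np.testing.assert_allclose(null.ns[:, b], observed, atol=1e-9)

    def test_three_genes_visit_all_six_permutations(self):
        genes = make_annotation([1, 600_000, 1_600_000], length=0)
        stat = np.array([1.0, 2.0, 4.0])
        track = GeneStatTrack(genes=genes, stat=stat, mode="paired_t")
        null = null_ns_gene_name(
            track, KERNEL, PermutationConfig(n_sample_label=1, n_gene_name=300, seed=2)
        )
        expected = set()
        mid = genes["midpoint"].to_numpy(float)
        for perm in itertools.permutations(stat):
            s = np.array(perm)
            ns = np.array(
                [sum(KERNEL.weight(mid[j] - mid[i]) * s[j] for j in range(3))
                 for i in range(3)]
            )
            expected.add(tuple(np.round(ns, 9)))
        seen = {tuple(np.round(null.ns[:, b], 9)) for b in range(300)}
        assert seen == expected

    def test_seed_determinism(self):
        genes = make_annotation(np.arange(15) * 300_000)
        track = GeneStatTrack(
            genes=genes, stat=np.random.default_rng(5).normal(size=15), mode="paired_t"
        )
        cfg = PermutationConfig(n_sample_label=1, n_gene_name=20, seed=9)
        a = null_ns_gene_name(track, KERNEL, cfg)
        b = null_ns_gene_name(track, KERNEL, cfg)
        np.testing.assert_array_equal(a.ns, b.ns)


class TestEstimateFdr:
    def test_observed_beyond_all_null_tends_to_zero(self):
        obs = np.array([10.0, 11.0, 12.0, 13.0])
        null = NullNsCollection(
            ns=np.random.default_rng(0).uniform(0, 1, size=(4, 50)),
            scheme=SCHEME_GENE_NAME, seed=0,
        )
        fdr = estimate_fdr(obs, null, AMP)
        # every observed score beats the whole null: after monotonization all
        # genes share the floor value (pseudocount over all observed calls)
        np.testing.assert_allclose(fdr, 1.0 / (50 * 4))

    def test_exchangeable_observed_has_fdr_near_one(self):
        rng = np.random.default_rng(30)
        null = NullNsCollection(
            ns=rng.normal(size=(100, 200)), scheme=SCHEME_GENE_NAME, seed=0
        )
        medians = []
        for _ in range(20):
            obs = rng.normal(size=100)
            medians.append(np.median(estimate_fdr(obs, null, AMP)))
        assert np.mean(medians) > 0.8

    @pytest.mark.parametrize("direction", [AMP, DEL])
    def test_monotone_in_score(self, direction):
        rng = np.random.default_rng(31)
        obs = rng.normal(size=80)
        null = NullNsCollection(
            ns=rng.normal(size=(80, 60)), scheme=SCHEME_GENE_NAME, seed=0
        )
        fdr = estimate_fdr(obs, null, direction)
        s = obs if direction == AMP else -obs
        order = np.argsort(s)
        diffs = np.diff(fdr[order])
        assert (diffs <= 1e-15).all()

    def test_bounded_by_one(self):
        rng = np.random.default_rng(32)
        obs = rng.normal(size=50)
        null = NullNsCollection(
            ns=rng.normal(size=(50, 30)), scheme=SCHEME_GENE_NAME, seed=0
        )
        assert (estimate_fdr(obs, null, AMP) <= 1.0).all()


def significance_from(ns, fdr_tables, genes=None):
    genes = genes if genes is not None else make_annotation(
        np.arange(len(ns)) * 200_000
    )
    track = neighborhood_scores(
        GeneStatTrack(genes=genes, stat=np.zeros(len(ns)), mode="paired_t"), KERNEL
    )
    track.ns = np.asarray(ns, float)
    return track


class TestCallAberrant:
    def test_nothing_under_alpha_gives_all_none(self):
        track = significance_from(np.ones(5), None)
        fdr = {
            (scheme, d): np.full(5, 0.5)
            for scheme in (SCHEME_SAMPLE_LABEL, SCHEME_GENE_NAME)
            for d in (AMP, DEL)
        }
        result = call_aberrant(track, fdr, SegmentConfig())
        assert (result.aberrant == NONE).all()

    def test_hand_built_table(self):
        ns = np.array([5.0, -4.0, 3.0, -2.0])
        lo, hi = 1e-5, 0.5
        fdr = {
            (SCHEME_SAMPLE_LABEL, AMP): np.array([lo, hi, hi, hi]),
            (SCHEME_GENE_NAME, AMP): np.array([lo, hi, hi, hi]),
            (SCHEME_SAMPLE_LABEL, DEL): np.array([hi, lo, hi, lo]),
            (SCHEME_GENE_NAME, DEL): np.array([hi, lo, hi, hi]),
        }
        result = call_aberrant(significance_from(ns, None), fdr, SegmentConfig())
        # gene 0: amp under both; gene 1: del under both; gene 3: del under
        # one scheme only -> none
        assert list(result.aberrant) == [AMP, DEL, NONE, NONE]

    def test_single_scheme_significance_is_not_enough(self):
        ns = np.array([5.0])
        lo, hi = 1e-5, 0.9
        fdr = {
            (SCHEME_SAMPLE_LABEL, AMP): np.array([lo]),
            (SCHEME_GENE_NAME, AMP): np.array([hi]),
            (SCHEME_SAMPLE_LABEL, DEL): np.array([hi]),
            (SCHEME_GENE_NAME, DEL): np.array([hi]),
        }
        result = call_aberrant(significance_from(ns, None), fdr, SegmentConfig())
        assert result.aberrant[0] == NONE


def result_from_flags(flags, chroms=None):
    n = len(flags)
    genes = make_annotation(np.arange(n) * 200_000, chroms=chroms)
    return SignificanceResult(
        genes=genes,
        ns_observed=np.where(np.array(flags) == DEL, -3.0, 3.0),
        fdr={},
        aberrant=np.array(flags, dtype=object),
    )


class TestCallSegments:
    @pytest.mark.parametrize("run,expected", [(9, 0), (10, 1), (15, 1)])
    def test_min_run_boundary(self, run, expected):
        flags = [NONE] * 3 + [AMP] * run + [NONE] * 3
        segs = call_segments(result_from_flags(flags), SegmentConfig())
        assert len(segs) == expected
        if expected:
            assert segs[0].n_genes == run
            assert segs[0].direction == "amplification"

    def test_interrupted_run_is_not_a_segment(self):
        flags = [AMP] * 9 + [NONE] + [AMP] * 9
        assert call_segments(result_from_flags(flags), SegmentConfig()) == []

    def test_chromosome_boundary_breaks_runs(self):
        flags = [AMP] * 12
        chroms = ["chr1"] * 6 + ["chr2"] * 6
        assert call_segments(result_from_flags(flags, chroms), SegmentConfig()) == []

    def test_matches_brute_force_run_scan(self):
        rng = np.random.default_rng(40)
        flags = rng.choice([AMP, DEL, NONE], size=300, p=[0.35, 0.35, 0.3])
        result = result_from_flags(list(flags))
        cfg = SegmentConfig(min_run=4)
        segs = call_segments(result, cfg)
        # brute force: enumerate maximal runs
        expected = []
        i = 0
        while i < 300:
            j = i
            while j + 1 < 300 and flags[j + 1] == flags[i]:
                j += 1
            if flags[i] != NONE and j - i + 1 >= 4:
                expected.append((i, j, flags[i]))
            i = j + 1
        assert len(segs) == len(expected)
        for seg, (i, j, d) in zip(segs, expected):
            assert seg.n_genes == j - i + 1
            assert seg.start == int(result.genes["start"].iloc[i])
            assert seg.end == int(result.genes["end"].iloc[j])


def seg(chrom, start, end, cohort, direction="amplification"):
    return CnaSegmentRecord(
        chrom=chrom, start=start, end=end, direction=direction,
        n_genes=10, mean_ns=20.0, cohort_id=cohort,
    )


class TestConsensusRegions:
    def test_two_cohort_intersection(self):
        regions = consensus_regions(
            {"A": [seg("chr1", 100, 300, "A")], "B": [seg("chr1", 200, 400, "B")]},
            min_cohorts=2,
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (200, 300)
        assert regions[0].n_support == 2

    def test_insufficient_support_gives_nothing(self):
        regions = consensus_regions(
            {"A": [seg("chr1", 100, 300, "A")], "B": []}, min_cohorts=2
        )
        assert regions == []

    def test_directions_do_not_mix(self):
        regions = consensus_regions(
            {
                "A": [seg("chr1", 100, 300, "A", "amplification")],
                "B": [seg("chr1", 200, 400, "B", "deletion")],
            },
            min_cohorts=2,
        )
        assert regions == []

    def test_default_min_cohorts_is_half_rounded_up(self):
        by_cohort = {
            "A": [seg("chr1", 100, 300, "A")],
            "B": [seg("chr1", 150, 350, "B")],
            "C": [],
        }
        regions = consensus_regions(by_cohort)  # ceil(3/2) = 2
        assert len(regions) == 1 and regions[0].n_support == 2

    def test_cohort_with_multiple_segments_maximizes_intersection(self):
        by_cohort = {
            "A": [seg("chr1", 100, 120, "A"), seg("chr1", 100, 500, "A")],
            "B": [seg("chr1", 110, 400, "B")],
        }
        regions = consensus_regions(by_cohort, min_cohorts=2)
        assert (regions[0].start, regions[0].end) == (110, 400)

    def test_printed_interval_width(self):
        # the 8q24.13 minimal common interval: 124154100-126060811 spans
        # 1,906,711 bp, i.e. about 1.91 Mb
        regions = consensus_regions(
            {
                "A": [seg("chr8", 123_000_000, 126_060_811, "A")],
                "B": [seg("chr8", 124_154_100, 127_500_000, "B")],
            },
            min_cohorts=2,
        )
        assert (regions[0].start, regions[0].end) == (124_154_100, 126_060_811)
        assert regions[0].end - regions[0].start == 1_906_711
        assert regions[0].width_bp / 1e6 == pytest.approx(1.91, abs=0.005)
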