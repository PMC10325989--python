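"""Interval model, peak I/O round trips, overlap arithmetic against
brute-force oracles, and Fisher-combined replicate consensus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbgrn.intervals import (
    ConsensusConfig,
    GenomicInterval,
    ParseError,
    PeakCollection,
    ScoredPeak,
    ValidationError,
    consensus_replicates,
    fisher_combine,
    merge_union,
    overlap_pairs,
    read_peaks,
    write_peaks,
)


def random_collection(rng, n, chroms=("chr1", "chr2"), with_fold=True, **kwargs):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, 100_000))
        length = int(rng.integers(50, 500))
        peaks.append(
            ScoredPeak(
                GenomicInterval(chrom, start, start + length),
                neglog10_p=float(np.round(rng.uniform(0, 30), 4)),
                fold_enrichment=float(np.round(rng.uniform(0, 50), 4)) if with_fold else None,
                name=f"p{i}",
            )
        )
    return PeakCollection(peaks=peaks, **kwargs)


def chi2_tail_oracle(statistic: float, k: int) -> float:
    """Analytic chi-square upper-tail for 2k degrees of freedom:
    exp(-s/2) * sum_{i<k} (s/2)^i / i!  (the integral of the density,
    evaluated in closed form, independent of the implementation path)."""
    half = statistic / 2.0
    return math.exp(-half) * sum(half**i / math.factorial(i) for i in range(k))


class TestInterval:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValidationError):
            ScoredPeak(GenomicInterval("chr1", 0, 10), neglog10_p=-1.0)

    def test_overlap_length(self):
        a = GenomicInterval("chr1", 100, 200)
        assert a.overlap_length(GenomicInterval("chr1", 150, 250)) == 50
        assert a.overlap_length(GenomicInterval("chr2", 150, 250)) == 0
        assert a.overlap_length(GenomicInterval("chr1", 200, 250)) == 0


class TestPeakIO:
    @pytest.mark.parametrize("fmt", ["narrowPeak", "BED6"])
    def test_round_trip(self, rng, tmp_path, fmt):
        coll = random_collection(rng, 50, with_fold=(fmt == "narrowPeak"))
        path = tmp_path / f"peaks.{fmt}"
        write_peaks(coll, path, fmt)
        back = read_peaks(path, fmt)
        assert [p.interval for p in back] == [p.interval for p in coll]
        assert [p.neglog10_p for p in back] == [p.neglog10_p for p in coll]
        assert [p.fold_enrichment for p in back] == [p.fold_enrichment for p in coll]
        assert [p.name for p in back] == [p.name for p in coll]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert len(read_peaks(path)) == 0

    def test_narrowpeak_field_mapping(self, tmp_path):
        path = tmp_path / "one.narrowPeak"
        path.write_text("chr1\t100\t400\tpk\t0\t.\t12.5\t8.0\t-1\t150\n")
        peak = read_peaks(path)[0]
        assert peak.neglog10_p == 8.0
        assert peak.fold_enrichment == 12.5

    def test_parse_errors_name_line(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t400\tpk\t0\t.\t1\t8.0\t-1\t150\nchr1\t100\n")
        with pytest.raises(ParseError, match="line 2"):
            read_peaks(path)
        path.write_text("chr1\t400\t100\tpk\t0\t.\t1\t8.0\t-1\t150\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_peaks(path)


class TestOverlapPairs:
    def test_forced_pair_and_disjoint(self):
        a = PeakCollection([ScoredPeak(GenomicInterval("chr1", 100, 200), 1.0)])
        b = PeakCollection([ScoredPeak(GenomicInterval("chr1", 150, 250), 1.0)])
        assert overlap_pairs(a, b, 1) == [(0, 0)]
        c = PeakCollection([ScoredPeak(GenomicInterval("chr1", 300, 400), 1.0)])
        assert overlap_pairs(a, c, 1) == []

    def test_negative_min_overlap_rejected(self):
        a = PeakCollection([ScoredPeak(GenomicInterval("chr1", 0, 10), 1.0)])
        with pytest.raises(ValidationError):
            overlap_pairs(a, a, -1)

    @pytest.mark.parametrize("min_overlap", [1, 25, 100])
    def test_matches_quadratic_scan(self, rng, min_overlap):
        a = random_collection(rng, 200)
        b = random_collection(rng, 200)
        expected = sorted(
            (i, j)
            for i, pa in enumerate(a)
            for j, pb in enumerate(b)
            if pa.interval.overlap_length(pb.interval) >= min_overlap
        )
        assert overlap_pairs(a, b, min_overlap) == expected
        # symmetry under swap
        swapped = sorted((j, i) for i, j in overlap_pairs(b, a, min_overlap))
        assert swapped == expected


def sweep_merge_oracle(intervals):
    """Independent sort-and-sweep reimplementation of interval union."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


class TestMergeUnion:
    def test_identity_on_disjoint(self):
        coll = PeakCollection(
            [
                ScoredPeak(GenomicInterval("chr1", 0, 100), 1.0),
                ScoredPeak(GenomicInterval("chr1", 200, 300), 2.0),
            ]
        )
        merged = merge_union([coll])
        assert [(r.interval.start, r.interval.end) for r in merged] == [(0, 100), (200, 300)]

    def test_forced_union(self):
        coll = PeakCollection(
            [
                ScoredPeak(GenomicInterval("chr1", 0, 100), 1.0),
                ScoredPeak(GenomicInterval("chr1", 50, 150), 2.0),
            ]
        )
        merged = merge_union([coll])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 150)
        assert merged[0].neglog10_p == 2.0

    def test_matches_sweep_oracle_and_idempotent(self, rng):
        colls = [random_collection(rng, 150) for _ in range(3)]
        merged = merge_union(colls)
        got = [(r.interval.chrom, r.interval.start, r.interval.end) for r in merged]
        expected = sweep_merge_oracle([p.interval for c in colls for p in c])
        assert got == expected
        assert len(merged) <= sum(len(c) for c in colls)
        # idempotence: merging the merged set changes nothing
        as_coll = PeakCollection([ScoredPeak(r.interval, r.neglog10_p) for r in merged])
        again = merge_union([as_coll])
        assert [(r.interval.chrom, r.interval.start, r.interval.end) for r in again] == got

    def test_sources_recorded(self):
        a = PeakCollection([ScoredPeak(GenomicInterval("chr1", 0, 100), 1.0)], factor="A")
        b = PeakCollection([ScoredPeak(GenomicInterval("chr1", 50, 150), 1.0)], factor="B")
        merged = merge_union([a, b], labels=["A", "B"])
        assert merged[0].sources == frozenset({"A", "B"})


class TestFisherCombine:
    def test_single_member_is_identity(self, rng):
        for nl in rng.uniform(0.1, 50, 20):
            _, p = fisher_combine([nl])
            assert p == pytest.approx(10.0 ** (-nl), rel=1e-12)

    def test_null_pvalues_give_zero_statistic(self):
        stat, p = fisher_combine([0.0, 0.0])  # both peaks at p = 1
        assert stat == 0.0
        assert p == 1.0

    def test_against_chi_square_tail_oracle(self, rng):
        for _ in range(1000):
            nls = rng.uniform(0.5, 40, 2)
            stat, p = fisher_combine(nls)
            expected = chi2_tail_oracle(stat, k=2)
            assert abs(p - expected) / expected < 1e-9

    def test_clamps_infinite_scores(self):
        stat, p = fisher_combine([float("inf"), 8.0])
        assert math.isfinite(stat) and p > 0


def _rep(peaks, i):
    return PeakCollection(peaks=peaks, factor="PBX1", replicate=i)


class TestConsensus:
    def test_single_replicate_peak_excluded(self):
        shared = ScoredPeak(GenomicInterval("chr1", 1000, 1300), 9.0)
        only_r1 = ScoredPeak(GenomicInterval("chr1", 5000, 5300), 9.0)
        cons = consensus_replicates(
            [_rep([shared, only_r1], 1), _rep([shared], 2)], ConsensusConfig()
        )
        assert len(cons) == 1
        assert cons[0].interval.start == 1000

    def test_weak_threshold_gates_members(self):
        # 1e-8 in both replicates passes weak 1e-6 and combines below 1e-10
        strong = ScoredPeak(GenomicInterval("chr1", 1000, 1300), 8.0)
        cons = consensus_replicates([_rep([strong], 1), _rep([strong], 2)])
        assert len(cons) == 1
        expected = chi2_tail_oracle(fisher_combine([8.0, 8.0])[0], k=2)
        assert 10 ** (-cons[0].neglog10_p) == pytest.approx(expected, rel=1e-6)
        # p = 1 peaks never enter (Fisher statistic vanishes)
        null = ScoredPeak(GenomicInterval("chr1", 1000, 1300), 0.0)
        assert len(consensus_replicates([_rep([null], 1), _rep([null], 2)])) == 0

    def test_combined_threshold_decides_inclusion(self):
        # each replicate at 1e-6 passes weak, but the combination
        # (p ~ 2.0e-11) sits near the stringent cut; check both sides
        borderline = ScoredPeak(GenomicInterval("chr1", 1000, 1300), 6.0)
        stat, p = fisher_combine([6.0, 6.0])
        cons = consensus_replicates([_rep([borderline], 1), _rep([borderline], 2)])
        assert (len(cons) == 1) == (p <= 1e-10)
        tight = ConsensusConfig(stringent_p=p / 2, weak_p=1e-6)
        assert len(consensus_replicates([_rep([borderline], 1), _rep([borderline], 2)], tight)) == 0

    def test_requires_enough_collections(self):
        with pytest.raises(ValidationError):
            consensus_replicates([_rep([], 1)], ConsensusConfig(min_replicates=2))

    def test_monotone_in_stringent_threshold(self, rng):
        reps = [random_collection(rng, 120, factor="PBX1", replicate=i) for i in (1, 2)]
        sizes = []
        for stringent in (1e-14, 1e-10, 1e-7):
            cfg = ConsensusConfig(stringent_p=stringent, weak_p=1e-6)
            sizes.append(len(consensus_replicates(reps, cfg)))
        assert sizes == sorted(sizes)

    def test_output_covered_by_input_union(self, rng):
        reps = [random_collection(rng, 80, factor="PBX1", replicate=i) for i in (1, 2)]
        union = sweep_merge_oracle([p.interval for r in reps for p in r])
        cons = consensus_replicates(reps)
        for peak in cons:
            assert any(
                chrom == peak.interval.chrom and s <= peak.interval.start and peak.interval.end <= e
                for chrom, s, e in union
            )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)), min_size=1, max_size=60))
def test_merge_union_property(spans):
    coll = PeakCollection(
        [ScoredPeak(GenomicInterval("chr1", s, s + l), 1.0) for s, l in spans]
    )
    merged = merge_union([coll])
    ivs = [r.interval for r in merged]
    # non-overlapping, sorted, and covering every input base
    for left, right in zip(ivs, ivs[1:]):
        assert left.end <= right.start
    total_in = set()
    for s, l in spans:
        total_in.update(range(s, s + l))
    total_out = set()
    for iv in ivs:
        total_out.update(range(iv.start, iv.end))
    assert total_in == total_out
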