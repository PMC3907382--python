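"""CNVR merging, sharing, annotation, and summary-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cghcnv import (CNVR, GenomeSpec, chromosome_summary, cnvr_status,
                    common_in_all, compare_sets, genes_overlapping,
                    label_sharing, merge_to_cnvrs, round_half_up, size_bins,
                    status_summary)
from cghcnv.calling import CALL_COLUMNS


def calls_frame(rows):
    """rows: (sample, chrom, start, end, status)"""
    return pd.DataFrame(
        [(s, c, a, b, st_, 1.0 if st_ == "gain" else -1.0, 10)
         for s, c, a, b, st_ in rows], columns=CALL_COLUMNS)


def union_length_bp_marking(rows, genome_len=1_000_000):
    """Independent oracle: mark every covered bp on a small genome."""
    by_chrom = {}
    for _, chrom, start, end, _ in rows:
        mask = by_chrom.setdefault(chrom, np.zeros(genome_len + 2, dtype=bool))
        mask[start:end + 1] = True
    return sum(int(m.sum()) for m in by_chrom.values())


class TestMerge:
    def test_overlapping_gain_loss_becomes_both(self):
        cnvrs = merge_to_cnvrs(calls_frame([
            ("A", "chr1", 100, 200, "gain"),
            ("B", "chr1", 150, 300, "loss")]))
        assert len(cnvrs) == 1
        r = cnvrs[0]
        assert (r.start, r.end, r.status) == (100, 300, "both")
        assert r.samples == {"A", "B"}

    def test_book_ended_calls_stay_apart(self):
        cnvrs = merge_to_cnvrs(calls_frame([
            ("A", "chr1", 100, 200, "gain"),
            ("B", "chr1", 201, 300, "gain")]))
        assert len(cnvrs) == 2

    def test_single_bp_overlap_merges(self):
        cnvrs = merge_to_cnvrs(calls_frame([
            ("A", "chr1", 100, 200, "gain"),
            ("B", "chr1", 200, 300, "gain")]))
        assert len(cnvrs) == 1

    def test_union_length_matches_bp_marking_oracle(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(100):
            start = int(rng.integers(1, 900_000))
            end = start + int(rng.integers(1, 50_000))
            rows.append((f"s{i % 5}", f"chr{i % 3}", start, end,
                         "gain" if rng.random() < 0.5 else "loss"))
        cnvrs = merge_to_cnvrs(calls_frame(rows))
        assert sum(r.length for r in cnvrs) == union_length_bp_marking(rows)

    def test_merge_idempotent_and_contractive(self):
        rng = np.random.default_rng(22)
        rows = [("s%d" % (i % 4), "chr1", int(a := rng.integers(1, 500_000)),
                 int(a + rng.integers(1, 30_000)), "loss") for i in range(60)]
        calls = calls_frame(rows)
        cnvrs = merge_to_cnvrs(calls)
        assert len(cnvrs) <= len(calls)
        # re-merging the regions is a fixed point
        as_calls = pd.DataFrame(
            [("m", r.chrom, r.start, r.end, "loss", -1.0, 10) for r in cnvrs],
            columns=CALL_COLUMNS)
        again = merge_to_cnvrs(as_calls)
        assert [(r.chrom, r.start, r.end) for r in again] == \
               [(r.chrom, r.start, r.end) for r in cnvrs]

    @given(st.lists(st.tuples(st.integers(1, 10_000), st.integers(1, 500)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_union_conservation_property(self, intervals):
        rows = [("s", "c", a, a + l - 1, "gain") for a, l in intervals]
        cnvrs = merge_to_cnvrs(calls_frame(rows))
        assert sum(r.length for r in cnvrs) == \
            union_length_bp_marking(rows, genome_len=11_000)

    def test_members_overlap_their_region(self):
        cnvrs = merge_to_cnvrs(calls_frame([
            ("A", "chr1", 1, 100, "gain"), ("B", "chr1", 50, 400, "gain"),
            ("C", "chr1", 380, 500, "loss")]))
        for r in cnvrs:
            for m in r.members.itertuples():
                assert m.start <= r.end and r.start <= m.end


class TestStatusAndSharing:
    def test_cnvr_status_rules(self):
        assert cnvr_status(["gain", "gain"]) == "gain"
        assert cnvr_status(["loss"]) == "loss"
        assert cnvr_status(["gain", "loss"]) == "both"
        with pytest.raises(ValueError):
            cnvr_status([])

    def test_single_sample_all_breed_specific(self):
        out = label_sharing(calls_frame([
            ("A", "chr1", 1, 100, "gain"), ("A", "chr1", 500, 900, "loss")]))
        assert (out["sharing"] == "breed_specific").all()

    def test_identical_call_in_two_samples_shared(self):
        out = label_sharing(calls_frame([
            ("A", "chr1", 100, 200, "gain"), ("B", "chr1", 100, 200, "gain")]))
        assert (out["sharing"] == "shared").all()
        assert (out["n_shared_samples"] == 2).all()

    def test_chain_component_counts_three_samples(self):
        # A-B overlap, B-C overlap, A-C disjoint -> all shared among 3
        out = label_sharing(calls_frame([
            ("A", "chr1", 100, 200, "gain"),
            ("B", "chr1", 150, 350, "gain"),
            ("C", "chr1", 300, 500, "gain")]))
        assert (out["sharing"] == "shared").all()
        assert (out["n_shared_samples"] == 3).all()

    def test_sharing_partitions_calls(self):
        rng = np.random.default_rng(23)
        rows = [(f"s{i % 3}", "chr1", int(a := rng.integers(1, 200_000)),
                 int(a + rng.integers(1, 20_000)), "gain") for i in range(40)]
        out = label_sharing(calls_frame(rows))
        n_bs = (out["sharing"] == "breed_specific").sum()
        n_sh = (out["sharing"] == "shared").sum()
        assert n_bs + n_sh == len(rows)

    def test_common_in_all(self):
        cnvrs = merge_to_cnvrs(calls_frame(
            [(s, "chr1", 100, 200, "gain") for s in "ABCDE"]
            + [("A", "chr2", 100, 200, "loss")]))
        hit = common_in_all(cnvrs, list("ABCDE"))
        assert len(hit) == 1 and hit[0].chrom == "chr1"
        assert common_in_all(cnvrs, list("ABCDEF")) == []
        # brute-force re-check
        expected = [r for r in cnvrs if set("ABCDE") <= set(r.samples)]
        assert hit == expected


class TestCompareSets:
    def _regions(self, triples):
        return [CNVR(chrom=c, start=a, end=b, status="gain",
                     samples=frozenset()) for c, a, b in triples]

    def test_self_comparison_counts_all(self):
        a = self._regions([("1", 100, 200), ("2", 5, 50)])
        n, pairs = compare_sets(a, a)
        assert n == len(a)

    def test_disjoint_zero(self):
        a = self._regions([("1", 100, 200)])
        b = self._regions([("1", 300, 400), ("2", 100, 200)])
        assert compare_sets(a, b)[0] == 0

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(24)
        def rand(n):
            return self._regions([
                ("c%d" % rng.integers(0, 3), int(s := rng.integers(1, 100_000)),
                 int(s + rng.integers(1, 8000))) for _ in range(n)])
        a, b = rand(40), rand(40)
        n, _ = compare_sets(a, b)
        expected = sum(
            any(ra.chrom == rb.chrom and ra.start <= rb.end and rb.start <= ra.end
                for rb in b) for ra in a)
        assert n == expected


class TestGenesOverlapping:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                           "biotype"])

    def test_inside_and_boundary(self):
        cnvrs = [CNVR("1", 1000, 2000, "gain", frozenset())]
        ann = self._ann([("inside", "1", 1200, 1300, ""),
                         ("straddle", "1", 1990, 2500, ""),
                         ("past_end", "1", 2001, 2600, "")])
        lists, n = genes_overlapping(cnvrs, ann)
        assert lists == [["inside", "straddle"]]
        assert n == 2

    def test_unknown_chromosome_warns(self):
        genome = GenomeSpec((("1", 10_000),))
        cnvrs = [CNVR("1", 100, 200, "gain", frozenset())]
        ann = self._ann([("g1", "1", 100, 150, ""), ("g2", "weird", 1, 50, "")])
        with pytest.warns(UserWarning, match="weird"):
            _, n = genes_overlapping(cnvrs, ann, genome)
        assert n == 1

    def test_global_count_deduplicates(self):
        cnvrs = [CNVR("1", 100, 200, "gain", frozenset()),
                 CNVR("1", 300, 400, "loss", frozenset())]
        ann = self._ann([("g", "1", 150, 350, "")])
        lists, n = genes_overlapping(cnvrs, ann)
        assert lists == [["g"], ["g"]] and n == 1


class TestSummaries:
    def test_chr12_like_row_reproduces_published_arithmetic(self):
        """6 CNVRs totaling 2,611,353 bp on a 33,091,231 bp chromosome ->
        7.89% coverage, mean 435.23 Kb."""
        sizes = [1, 1, 1, 1, 1, 2_611_348]
        pos, regions = 1, []
        for s in sizes:
            regions.append(CNVR("12", pos, pos + s - 1, "loss", frozenset({"S"})))
            pos += s + 10_000
        genome = GenomeSpec((("12", 33_091_231),))
        table = chromosome_summary(regions, genome)
        row = table[table["chrom"] == "12"].iloc[0]
        assert row["total_cnvr_bp"] == 2_611_353
        assert row["percent_of_chrom"] == 7.89
        assert row["mean_cnvr_kb"] == 435.23

    def test_empty_chromosome_row(self):
        genome = GenomeSpec((("1", 1000), ("2", 2000)))
        table = chromosome_summary([CNVR("1", 1, 100, "gain", frozenset())],
                                   genome)
        row = table[table["chrom"] == "2"].iloc[0]
        assert row["n_cnvrs"] == 0
        assert row["percent_of_chrom"] == 0.0
        assert row["mean_cnvr_kb"] == 0.0

    def test_totals_match_direct_summation(self):
        rng = np.random.default_rng(25)
        genome = GenomeSpec((("1", 1_000_000), ("2", 2_000_000)))
        regions = []
        pos = {"1": 1, "2": 1}
        for _ in range(30):
            c = "1" if rng.random() < 0.5 else "2"
            ln = int(rng.integers(100, 5000))
            regions.append(CNVR(c, pos[c], pos[c] + ln - 1, "gain",
                                frozenset({"S"})))
            pos[c] += ln + 100
        table = chromosome_summary(regions, genome)
        total = table[table["chrom"] == "total"].iloc[0]
        assert total["total_cnvr_bp"] == sum(r.length for r in regions)
        assert total["n_cnvrs"] == 30

    def test_size_bins_boundaries_and_partition(self):
        regions = [CNVR("1", 1, 9_999, "gain", frozenset()),        # 9,999 bp
                   CNVR("1", 20_000, 69_999, "gain", frozenset()),  # 50,000 bp
                   CNVR("1", 100_000, 700_000, "loss", frozenset())]  # 600,001
        bins = size_bins(regions)
        assert bins["1-10 Kb"] == 1
        assert bins["50-100 Kb"] == 1  # 50,000 falls in the third bin
        assert bins[">500 Kb"] == 1
        assert bins.sum() == len(regions)

    def test_size_bins_partition_random(self):
        rng = np.random.default_rng(26)
        regions = [CNVR("1", 1, int(rng.integers(1_000, 800_000)), "gain",
                        frozenset()) for _ in range(40)]
        assert size_bins(regions).sum() == 40

    def test_status_summary_published_gain_mean(self):
        """109 gain CNVRs totaling 5,005,156 bp -> mean 45.92 Kb."""
        regions = []
        pos = 1
        sizes = [1] * 108 + [5_005_156 - 108]
        for s in sizes:
            regions.append(CNVR("1", pos, pos + s - 1, "gain", frozenset()))
            pos += s + 10
        table = status_summary(regions)
        gain = table[table["status"] == "gain"].iloc[0]
        assert gain["n_cnvrs"] == 109
        assert gain["mean_kb"] == 45.92
        assert gain["percent_of_total_length"] == 100.0

    def test_single_cnvr_hundred_percent(self):
        table = status_summary([CNVR("1", 1, 1000, "loss", frozenset())])
        loss = table[table["status"] == "loss"].iloc[0]
        assert loss["percent_of_total_length"] == 100.0

    def test_percents_sum_to_hundred(self):
        rng = np.random.default_rng(27)
        regions = [CNVR("1", 1, int(rng.integers(100, 90_000)),
                        ["gain", "loss", "both"][i % 3], frozenset())
                   for i in range(30)]
        table = status_summary(regions)
        assert table["percent_of_total_length"].sum() == pytest.approx(100, abs=0.02)


def test_round_half_up():
    assert round_half_up(0.605, 2) == 0.61
    assert round_half_up(0.60499, 2) == 0.60
    assert round_half_up(435.2255, 2) == 435.23
    assert round_half_up(2.5, 0) == 3.0
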