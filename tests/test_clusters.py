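"""Cluster calling, RPM, input noise filtering and the interval universe."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import sliceclip as sc
from sliceclip import clusters as cu

from conftest import random_reads


def oracle_single_linkage(reads: pd.DataFrame, window: int = 6) -> set:
    """Independent O(n^2) oracle: graph of |pi - pj| <= window links,
    connected components via scipy's csgraph."""
    out = set()
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"]):
        pos = grp["pos"].to_numpy()
        adj = np.abs(pos[:, None] - pos[None, :]) <= window
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            members = pos[labels == comp]
            out.add((chrom, strand, int(members.min()),
                     int(members.max()) + 1, len(members)))
    return out


def clusters_as_set(df: pd.DataFrame) -> set:
    return set(map(tuple, df[["chrom", "strand", "start", "end", "count"]]
                   .itertuples(index=False)))


class TestCallClusters:
    def test_linked_and_separate_groups(self):
        reads = pd.DataFrame({
            "chrom": "chr1", "strand": "+", "pos": [100, 103, 106, 120]})
        out = sc.call_clusters(reads, window=6)
        assert clusters_as_set(out) == {
            ("chr1", "+", 100, 107, 3), ("chr1", "+", 120, 121, 1)}

    def test_singleton_read(self):
        reads = pd.DataFrame({"chrom": ["chrX"], "strand": ["-"], "pos": [500]})
        out = sc.call_clusters(reads)
        assert clusters_as_set(out) == {("chrX", "-", 500, 501, 1)}

    def test_strands_never_merge(self):
        reads = pd.DataFrame({
            "chrom": "chr1", "strand": ["+", "-"], "pos": [100, 100]})
        out = sc.call_clusters(reads)
        assert len(out) == 2
        assert set(out["strand"]) == {"+", "-"}

    def test_gap_of_exactly_window_links(self):
        reads = pd.DataFrame({"chrom": "c", "strand": "+", "pos": [10, 16, 23]})
        out = sc.call_clusters(reads, window=6)
        # 10-16 links (gap 6 <= 6); 16-23 does not (gap 7)
        assert clusters_as_set(out) == {
            ("c", "+", 10, 17, 2), ("c", "+", 23, 24, 1)}

    def test_empty_input_gives_empty_output(self):
        out = sc.call_clusters(pd.DataFrame(columns=["chrom", "strand", "pos"]))
        assert len(out) == 0

    def test_invalid_strand_rejected(self):
        reads = pd.DataFrame({"chrom": ["c"], "strand": ["*"], "pos": [1]})
        with pytest.raises(ValueError, match="strand"):
            sc.call_clusters(reads)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, int(rng.integers(1, 400)))
        window = int(rng.integers(1, 12))
        out = sc.call_clusters(reads, window=window)
        assert clusters_as_set(out) == oracle_single_linkage(reads, window)
        # no read lost or double counted
        assert out["count"].sum() == len(reads)

    def test_invariant_under_read_order(self):
        rng = np.random.default_rng(3)
        reads = random_reads(rng, 300)
        shuffled = reads.sample(frac=1, random_state=1).reset_index(drop=True)
        a = sc.call_clusters(reads)
        b = sc.call_clusters(shuffled)
        pd.testing.assert_frame_equal(a, b)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(pos=st.lists(st.integers(0, 300), min_size=1, max_size=60),
           window=st.integers(1, 10))
    def test_oracle_property(self, pos, window):
        reads = pd.DataFrame({"chrom": "c", "strand": "+", "pos": pos})
        out = sc.call_clusters(reads, window=window)
        assert clusters_as_set(out) == oracle_single_linkage(reads, window)
        assert out["count"].sum() == len(pos)


class TestRpm:
    def test_definition_and_arithmetic(self):
        clus = pd.DataFrame({"chrom": "c", "strand": "+", "start": [0, 5],
                             "end": [1, 6], "count": [10, 7]})
        out = sc.compute_rpm(clus, 10**6)
        assert out["rpm"].tolist() == [10.0, 7.0]
        out = sc.compute_rpm(clus, int(3.5e6))
        assert out["rpm"].tolist() == [pytest.approx(10 / 3.5), 2.0]

    def test_zero_count_cluster(self):
        clus = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "start": [0],
                             "end": [1], "count": [0]})
        assert sc.compute_rpm(clus, 1000)["rpm"].iloc[0] == 0.0

    def test_nonpositive_total_rejected(self):
        clus = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "start": [0],
                             "end": [1], "count": [1]})
        with pytest.raises(ValueError):
            sc.compute_rpm(clus, 0)


def _one_cluster(rpm):
    return pd.DataFrame({"chrom": ["c"], "strand": ["+"], "start": [100],
                         "end": [110], "count": [1], "rpm": [float(rpm)]})


def _input_reads(n, pos=105):
    return pd.DataFrame({"chrom": "c", "strand": "+", "pos": [pos] * n})


class TestInputNoiseFilter:
    def test_rpm_exactly_five_rejected(self):
        # abundance must exceed 5 RPM strictly
        out = sc.input_noise_filter(_one_cluster(5.0), _input_reads(0), 10**6)
        assert len(out) == 0

    def test_fifteen_fold_exactly_retained(self):
        clus = _one_cluster(6.0)
        inp = _input_reads(4)  # 0.4 RPM at total 1e7
        out = sc.input_noise_filter(clus, inp, 10**7)
        assert len(out) == 1
        assert out["input_fold"].iloc[0] == pytest.approx(15.0)

    def test_equal_abundance_rejected(self):
        clus = _one_cluster(100.0)
        inp = _input_reads(100)  # 100 RPM at total 1e6
        out = sc.input_noise_filter(clus, inp, 10**6)
        assert len(out) == 0

    def test_input_counted_on_same_strand_only(self):
        clus = _one_cluster(6.0)
        minus = _input_reads(100).assign(strand="-")
        out = sc.input_noise_filter(clus, minus, 10**6)
        assert len(out) == 1  # opposite-strand input is invisible

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        reads = random_reads(rng, 400)
        clus = sc.compute_rpm(sc.call_clusters(reads), 2000)
        inp = random_reads(rng, 400)
        kept = {}
        for min_rpm, min_fold in [(5, 15), (10, 15), (5, 30), (10, 30)]:
            out = sc.input_noise_filter(clus, inp, 2000, min_rpm, min_fold)
            kept[(min_rpm, min_fold)] = clusters_as_set(out)
        assert kept[(10, 15)] <= kept[(5, 15)]
        assert kept[(5, 30)] <= kept[(5, 15)]
        assert kept[(10, 30)] <= kept[(10, 15)] <= kept[(5, 15)]


class TestUniverse:
    def test_overlapping_intervals_merge(self):
        a = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "start": [100],
                          "end": [107]})
        b = pd.DataFrame({"chrom": ["c"], "strand": ["+"], "start": [105],
                          "end": [110]})
        merged = sc.merge_intervals([a, b])
        assert merged[["start", "end"]].values.tolist() == [[100, 110]]

    def test_same_interval_opposite_strands_kept_apart(self):
        a = pd.DataFrame({"chrom": ["c", "c"], "strand": ["+", "-"],
                          "start": [100, 100], "end": [107, 107]})
        merged = sc.merge_intervals([a])
        assert len(merged) == 2

    def test_zero_fill_for_absent_library(self):
        clus = {"A": pd.DataFrame({"chrom": ["c"], "strand": ["+"],
                                   "start": [0], "end": [10]})}
        reads = {"A": pd.DataFrame({"chrom": "c", "strand": "+", "pos": [5]}),
                 "B": pd.DataFrame({"chrom": "c", "strand": "+", "pos": [50]})}
        uni = sc.build_universe(clus, reads, {"A": 100, "B": 100})
        assert uni.counts.loc[0, "A"] == 1
        assert uni.counts.loc[0, "B"] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_abundance_matches_exhaustive_recount(self, seed):
        rng = np.random.default_rng(seed)
        libs = {f"lib{i}": random_reads(rng, int(rng.integers(50, 300)))
                for i in range(3)}
        totals = {lib: len(df) for lib, df in libs.items()}
        clus = {lib: sc.call_clusters(df) for lib, df in libs.items()}
        uni = sc.build_universe(clus, libs, totals)
        # brute-force recount, read by read
        for lib, df in libs.items():
            for idx, iv in uni.intervals.iterrows():
                n = sum((r.chrom == iv["chrom"]) and (r.strand == iv["strand"])
                        and (iv["start"] <= r.pos < iv["end"])
                        for r in df.itertuples())
                assert uni.counts.loc[idx, lib] == n
        # merged intervals are pairwise disjoint per strand
        for (_, _), grp in uni.intervals.groupby(["chrom", "strand"]):
            srt = grp.sort_values("start")
            assert (srt["start"].to_numpy()[1:]
                    >= srt["end"].to_numpy()[:-1]).all()


class TestCorrelation:
    @pytest.fixture()
    def toy_universe(self):
        rng = np.random.default_rng(0)
        reads = {"A": random_reads(rng, 500)}
        reads["B"] = pd.concat([reads["A"], reads["A"]], ignore_index=True)
        clus = {"A": sc.call_clusters(reads["A"])}
        return sc.build_universe(clus, reads, {"A": 500, "B": 1000})

    def test_self_correlation_is_one(self, toy_universe):
        assert sc.correlate_libraries(toy_universe, "A", "A") == pytest.approx(1.0)

    def test_doubled_library_correlates_perfectly(self, toy_universe):
        # B holds every A read twice at the same total-scaled abundance
        r = sc.correlate_libraries(toy_universe, "A", "B")
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_too_few_intervals_error(self):
        reads = {"A": pd.DataFrame({"chrom": "c", "strand": "+", "pos": [1]})}
        clus = {"A": sc.call_clusters(reads["A"])}
        uni = sc.build_universe(clus, reads, {"A": 1})
        with pytest.raises(ValueError, match="at least 3"):
            sc.correlate_libraries(uni, "A", "A")


class TestBedRoundTrip:
    def test_reads_written_and_reread_identically(self, tmp_path):
        rng = np.random.default_rng(8)
        reads = random_reads(rng, 100)
        path = tmp_path / "lib.bed"
        cu.write_reads_bed6(reads, "lib", path)
        back = cu.read_bed6(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["chrom", "strand", "pos"], ignore_index=True),
            reads[["chrom", "strand", "pos"]]
            .sort_values(["chrom", "strand", "pos"], ignore_index=True))
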