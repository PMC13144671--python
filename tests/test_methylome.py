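import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mced import methylome as me
from .conftest import make_table


class TestFilterSites:
    def test_low_coverage_removed(self):
        t = make_table([[1, 1, 1], [5, 5, 5]], [[1, 1, 1], [5, 5, 5]])
        out = me.filter_sites(t, ["s0", "s1", "s2"], min_cov=3)
        assert out.n_sites == 1
        assert out.sites["pos0"].iloc[0] == 100

    def test_sex_chromosomes_removed(self):
        t = make_table([[10], [10]], [[10], [10]], chroms=["chrX", "chr1"])
        out = me.filter_sites(t, ["s0"], min_cov=3)
        assert list(out.sites["chrom"]) == ["chr1"]

    def test_noop_filter(self):
        t = make_table([[10, 10]] * 4, [[0, 0]] * 4)
        out = me.filter_sites(t, ["s0", "s1"], min_cov=3, blacklist=[])
        assert out.n_sites == 4

    def test_blacklist(self):
        t = make_table([[10]] * 3, [[10]] * 3)
        out = me.filter_sites(t, ["s0"], min_cov=3, blacklist=[("chr1", 90, 150)])
        assert list(out.sites["pos0"]) == [0, 200]

    def test_bad_blacklist_interval(self):
        t = make_table([[10]], [[10]])
        with pytest.raises(ValueError, match="start >= end"):
            me.filter_sites(t, ["s0"], blacklist=[("chr1", 100, 100)])

    def test_empty_healthy_errors(self):
        t = make_table([[10]], [[10]])
        with pytest.raises(ValueError, match="non-empty"):
            me.filter_sites(t, [])

    def test_all_aggregator(self):
        # mean coverage is 3 but one sample is below min_cov
        t = make_table([[4, 1]], [[1, 0]])
        assert me.filter_sites(t, ["s0", "s1"], 3, coverage_agg="mean").n_sites == 1
        assert me.filter_sites(t, ["s0", "s1"], 3, coverage_agg="all").n_sites == 0


class TestClassifyStatus:
    def _table_from_betas(self, betas, cov=10):
        betas = np.asarray(betas, dtype=float)
        C = np.rint(betas * cov).astype(int)[:, None]
        T = cov - C
        return make_table(C, T)

    def test_clear_extremes(self):
        betas = np.concatenate([[0.02, 0.95], np.linspace(0.3, 0.7, 18)])
        t = self._table_from_betas(betas)
        status = me.classify_cpg_status(t, ["s0"], pct=10)
        assert status[0] == me.STATUS_UNMETHYLATED
        assert status[1] == me.STATUS_METHYLATED
        assert (status[2:] == me.STATUS_NEUTRAL).all()

    def test_decile_without_beta_cut_is_neutral(self):
        # top decile but below 0.5: the conjunction fails -> neutral
        betas = np.concatenate([np.full(19, 0.1), [0.48]])
        t = self._table_from_betas(betas, cov=100)
        status = me.classify_cpg_status(t, ["s0"], pct=10)
        assert status[-1] == me.STATUS_NEUTRAL

    def test_identical_betas_all_neutral(self):
        t = self._table_from_betas(np.full(10, 0.7))
        status = me.classify_cpg_status(t, ["s0"], pct=10)
        assert (status == me.STATUS_NEUTRAL).all()

    def test_pct_bounds(self):
        t = self._table_from_betas([0.5, 0.5])
        with pytest.raises(ValueError):
            me.classify_cpg_status(t, ["s0"], pct=60)


class TestBuildRegions:
    def _sites(self, n, chroms=None):
        return pd.DataFrame({
            "chrom": chroms or ["chr1"] * n,
            "pos0": np.arange(n) * 100,
            "strand": "+",
        })

    def test_hand_run_length(self):
        M, U, N = me.STATUS_METHYLATED, me.STATUS_UNMETHYLATED, me.STATUS_NEUTRAL
        status = np.array([M, M, M, U, U, N, M], dtype=object)
        regions = me.build_regions(status, self._sites(7), min_cpg=2)
        assert len(regions) == 2
        assert regions[0].status == M and list(regions[0].site_idx) == [0, 1, 2]
        assert regions[1].status == U and list(regions[1].site_idx) == [3, 4]

    def test_all_neutral_empty(self):
        status = np.array([me.STATUS_NEUTRAL] * 5, dtype=object)
        assert me.build_regions(status, self._sites(5), 1) == []

    def test_chromosome_boundary_splits(self):
        M = me.STATUS_METHYLATED
        status = np.array([M, M, M, M], dtype=object)
        sites = self._sites(4, chroms=["chr1", "chr1", "chr2", "chr2"])
        regions = me.build_regions(status, sites, min_cpg=2)
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chr1", "chr2"}

    def test_unsorted_sites_error(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos0": [200, 100], "strand": "+"})
        status = np.array([me.STATUS_METHYLATED] * 2, dtype=object)
        with pytest.raises(ValueError, match="sorted"):
            me.build_regions(status, sites, 1)

    def test_partition_property(self):
        # regions are disjoint, ordered and status-homogeneous on random input
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 80))
            status = rng.choice(
                [me.STATUS_METHYLATED, me.STATUS_UNMETHYLATED, me.STATUS_NEUTRAL], n
            ).astype(object)
            chroms = np.sort(rng.choice(["chr1", "chr2"], n))
            regions = me.build_regions(status, self._sites(n, list(chroms)), min_cpg=1)
            seen = set()
            for r in regions:
                assert (status[r.site_idx] == r.status).all()
                assert not (seen & set(r.site_idx.tolist()))
                seen |= set(r.site_idx.tolist())
            non_neutral = {i for i in range(n) if status[i] != me.STATUS_NEUTRAL}
            assert seen == non_neutral


class TestAMF:
    def test_hand_example(self):
        # per-site fractions 1, 0.75, 0.5 -> mean 0.75
        t = make_table([[5], [3], [2]], [[0], [1], [2]])
        region = me.MethylRegion("r0", "chr1", 0, 201, me.STATUS_METHYLATED,
                                 np.array([0, 1, 2]))
        amf = me.compute_amf(t, [region])
        assert amf.loc["s0", "r0"] == pytest.approx(0.75)

    def test_fully_methylated_upper_bound(self):
        t = make_table([[5], [7]], [[0], [0]])
        region = me.MethylRegion("r0", "chr1", 0, 101, me.STATUS_METHYLATED,
                                 np.array([0, 1]))
        assert me.compute_amf(t, [region]).loc["s0", "r0"] == 1.0

    def test_uncovered_site_excluded(self):
        # site 1 has zero coverage: mean over covered sites only
        t = make_table([[4], [0], [1]], [[0], [0], [3]])
        region = me.MethylRegion("r0", "chr1", 0, 201, me.STATUS_METHYLATED,
                                 np.array([0, 1, 2]))
        assert me.compute_amf(t, [region]).loc["s0", "r0"] == pytest.approx((1 + 0.25) / 2)

    def test_no_covered_sites_missing(self):
        t = make_table([[0]], [[0]])
        region = me.MethylRegion("r0", "chr1", 0, 1, me.STATUS_METHYLATED, np.array([0]))
        assert np.isnan(me.compute_amf(t, [region]).loc["s0", "r0"])

    def test_empty_region_rejected_at_construction(self):
        with pytest.raises(ValueError, match="zero member"):
            me.MethylRegion("r0", "chr1", 0, 1, me.STATUS_METHYLATED, np.array([], dtype=int))


def bh_oracle(p):
    """Independent step-up oracle: q_i = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, i in enumerate(order, start=1):
        candidates = []
        for rank_j, j in enumerate(order, start=1):
            if rank_j >= rank:
                candidates.append(p[j] * m / rank_j)
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_example(self):
        q = me.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert me.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_cap_at_one(self):
        assert np.allclose(me.bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            me.bh_fdr([0.5, 1.2])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=30)
            q = me.bh_fdr(p)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_fuzz(self, p):
        assert np.allclose(me.bh_fdr(p), bh_oracle(p), atol=1e-12)


class TestSelectDMRs:
    def _amf(self, values, samples):
        return pd.DataFrame(values, index=samples,
                            columns=[f"r{i}" for i in range(np.shape(values)[1])])

    def test_identical_groups_not_selected(self):
        amf = self._amf([[0.5]] * 6, [f"s{i}" for i in range(6)])
        markers, _ = me.select_dmrs(amf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert markers.empty

    def test_toy_hyper_selected(self):
        rng = np.random.default_rng(0)
        a = 0.9 + rng.normal(0, 1e-3, 3)
        b = 0.1 + rng.normal(0, 1e-3, 3)
        amf = self._amf(np.r_[a, b][:, None], [f"s{i}" for i in range(6)])
        markers, _ = me.select_dmrs(amf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert len(markers) == 1
        assert markers["direction"].iloc[0] == "hyper"
        assert markers["q_value"].iloc[0] >= markers["p_value"].iloc[0] - 1e-15

    def test_small_group_skipped_not_failed(self):
        amf = self._amf([[0.9], [np.nan], [0.1], [0.2]], ["a1", "a2", "b1", "b2"])
        markers, skipped = me.select_dmrs(amf, ["a1", "a2"], ["b1", "b2"])
        assert skipped == ["r0"]
        assert markers.empty

    def test_overlapping_groups_error(self):
        amf = self._amf([[0.5]] * 3, ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="disjoint"):
            me.select_dmrs(amf, ["s0", "s1"], ["s1", "s2"])

    def test_null_type_one_error_rate(self):
        # Monte-Carlo: on pure-noise AMF the selected fraction stays near FDR
        rng = np.random.default_rng(42)
        n_regions, selected = 1000, 0
        for rep in range(5):
            amf = self._amf(rng.uniform(0.3, 0.7, size=(20, n_regions)),
                            [f"s{i}" for i in range(20)])
            markers, _ = me.select_dmrs(amf, [f"s{i}" for i in range(10)],
                                        [f"s{i}" for i in range(10, 20)], fdr=0.05)
            selected += len(markers)
        assert selected / (5 * n_regions) <= 0.05


class TestConcordance:
    def _markers(self, rows):
        return pd.DataFrame(rows, columns=me.MARKER_COLUMNS)

    def test_same_direction_retained(self):
        tissue = self._markers([["r1", "tumor-vs-adjacent", "hyper", 0.01, 0.02, "liver"]])
        cfdna = self._markers([["r1", "cfdna-cancer-vs-healthy", "hyper", 0.01, 0.02, "liver"]])
        out = me.concordance_filter(tissue, cfdna)
        assert list(out["region_id"]) == ["r1"]

    def test_direction_conflict_dropped(self):
        tissue = self._markers([["r1", "tumor-vs-adjacent", "hyper", 0.01, 0.02, "liver"]])
        cfdna = self._markers([["r1", "cfdna-cancer-vs-healthy", "hypo", 0.01, 0.02, "liver"]])
        assert me.concordance_filter(tissue, cfdna).empty

    def test_tissue_only_dropped(self):
        tissue = self._markers([["r1", "tumor-vs-adjacent", "hyper", 0.01, 0.02, "liver"]])
        cfdna = self._markers([["r2", "cfdna-cancer-vs-healthy", "hyper", 0.01, 0.02, "liver"]])
        assert me.concordance_filter(tissue, cfdna).empty

    def test_empty_sets_allowed(self):
        empty = self._markers([])
        assert me.concordance_filter(empty, empty).empty
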