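"""Rank-sum testing, run scanning, and gene-level DMR summaries."""

import numpy as np
import pytest
from dataclasses import replace

from mbdpipe.annotation import (GeneModel, RegionClass, assign_bins_to_regions,
                                partition_gene_regions)
from mbdpipe.coverage import BinMatrix
from mbdpipe.dmr import (BinTestTable, DmrCallParams, call_gene_dmrs,
                         dmr_mean_profile, gene_region_status, rank_sum_test,
                         scan_runs, union_across_controls)
from mbdpipe.dmr import test_region_bins as run_bin_tests
from oracles import brute_force_ranksum, brute_force_scan, random_bin_table

PARAMS = DmrCallParams()


# ---------------------------------------------------------------------------
# Rank-sum test


def test_fully_separated_triples_give_point_one():
    # 2 of the C(6,3)=20 rank splits reach the extreme U, doubled -> 0.1
    assert rank_sum_test([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)


def test_identical_samples_give_p_one():
    assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_rank_sum_is_symmetric(rng):
    for _ in range(20):
        a = rng.normal(size=rng.integers(2, 8))
        b = rng.normal(size=rng.integers(2, 8))
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))


def test_short_vectors_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([1], [2, 3])


def test_exact_branch_matches_brute_enumeration(rng):
    for _ in range(15):
        na, nb = rng.integers(2, 6, size=2)
        vals = rng.permutation(np.arange(na + nb, dtype=float) * 1.7 + 0.3)
        a, b = vals[:na], vals[na:]
        assert rank_sum_test(a, b) == pytest.approx(
            brute_force_ranksum(a, b), abs=1e-12)


def test_asymptotic_branch_matches_scipy_with_ties(rng):
    from scipy.stats import mannwhitneyu
    for _ in range(20):
        a = rng.integers(0, 5, size=12).astype(float)
        b = rng.integers(0, 5, size=11).astype(float)
        if len(set(a.tolist() + b.tolist())) == a.size + b.size:
            continue
        expected = mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
        assert rank_sum_test(a, b) == pytest.approx(expected, rel=1e-9)


def test_large_groups_use_normal_approximation():
    a = np.arange(15, dtype=float)
    b = np.arange(15, dtype=float) + 0.5
    from scipy.stats import mannwhitneyu
    expected = mannwhitneyu(a, b, alternative="two-sided",
                            method="asymptotic").pvalue
    assert rank_sum_test(a, b) == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# Per-bin testing


def test_log2fc_uses_pseudocount():
    va = np.array([[0.8, 0.8, 0.8]])
    vb = np.array([[0.2, 0.2, 0.2]])
    t = run_bin_tests(va, vb, [0], PARAMS)
    assert t.log2fc[0] == pytest.approx(np.log2(3.0))
    assert t[0].direction == "hyper"


def test_all_zero_bin_is_null():
    t = run_bin_tests(np.zeros((1, 4)), np.zeros((1, 4)), [0], PARAMS)
    assert t.p[0] == 1.0 and t[0].direction == "none"


def test_hypo_direction_from_sign_of_difference():
    va = np.array([[0.1, 0.1, 0.1]])
    vb = np.array([[0.7, 0.7, 0.7]])
    assert run_bin_tests(va, vb, [0], PARAMS)[0].direction == "hypo"


def test_single_sample_group_rejected():
    with pytest.raises(ValueError):
        run_bin_tests(np.zeros((1, 1)), np.zeros((1, 3)), [0], PARAMS)


# ---------------------------------------------------------------------------
# Run scanning


def _table(p, log2fc, mean_a, mean_b, start=0):
    p = np.asarray(p, dtype=float)
    direction = np.sign(np.asarray(mean_a, dtype=float)
                        - np.asarray(mean_b, dtype=float)).astype(np.int8)
    return BinTestTable(np.arange(start, start + p.size), p, mean_a, mean_b,
                        log2fc, direction)


def test_three_consecutive_bins_make_a_tss_dmr():
    t = _table(p=[0.2, 0.01, 0.02, 0.04, 0.3],
               log2fc=[1.5] * 5, mean_a=[0.5] * 5, mean_b=[0.1] * 5)
    (d,) = scan_runs(t, RegionClass.TSS, PARAMS)
    assert (d.n_bins, d.direction) == (3, "hyper")
    assert (d.start, d.end) == (100, 400)


def test_genic_region_needs_five_bins():
    t = _table(p=[0.01, 0.01, 0.01, 0.01],
               log2fc=[1.5] * 4, mean_a=[0.5] * 4, mean_b=[0.1] * 4)
    assert scan_runs(t, RegionClass.GENIC, PARAMS) == []
    assert len(scan_runs(t, RegionClass.TSS, PARAMS)) == 1


def test_low_rpm_run_is_dropped():
    t = _table(p=[0.01] * 3, log2fc=[1.5] * 3,
               mean_a=[0.1] * 3, mean_b=[0.01] * 3)
    assert scan_runs(t, RegionClass.TSS, PARAMS) == []


def test_hypo_run_checks_control_group_rpm():
    t = _table(p=[0.01] * 3, log2fc=[-1.5] * 3,
               mean_a=[0.01] * 3, mean_b=[0.5] * 3)
    (d,) = scan_runs(t, RegionClass.TSS, PARAMS)
    assert d.direction == "hypo" and d.mean_rpm_high == pytest.approx(0.5)


def test_direction_flip_breaks_a_run():
    t = _table(p=[0.01] * 6, log2fc=[1.5, 1.5, 1.5, -1.5, -1.5, -1.5],
               mean_a=[0.5, 0.5, 0.5, 0.1, 0.1, 0.1],
               mean_b=[0.1, 0.1, 0.1, 0.5, 0.5, 0.5])
    dmrs = scan_runs(t, RegionClass.TSS, PARAMS)
    assert [d.direction for d in dmrs] == ["hyper", "hypo"]


def test_scan_matches_brute_oracle_on_random_tables(rng):
    for _ in range(200):
        t = random_bin_table(rng)
        region = [RegionClass.TSS, RegionClass.GENIC][int(rng.integers(0, 2))]
        assert scan_runs(t, region, PARAMS) == brute_force_scan(t, region, PARAMS)


def test_relaxing_p_threshold_never_removes_dmrs(rng):
    loose = replace(PARAMS, p_threshold=0.10)
    for _ in range(50):
        t = random_bin_table(rng)
        strict_set = {(d.start, d.end, d.direction)
                      for d in scan_runs(t, RegionClass.TSS, PARAMS)}
        loose_cover = [(d.start, d.end, d.direction)
                       for d in scan_runs(t, RegionClass.TSS, loose)]
        # every strict DMR is contained in some loose DMR of the same direction
        for s, e, dr in strict_set:
            assert any(ls <= s and e <= le and dr == ld
                       for ls, le, ld in loose_cover)


def test_raising_min_run_never_adds_dmrs(rng):
    harsh = replace(PARAMS, min_run_default=5, min_run_genic=7)
    for _ in range(50):
        t = random_bin_table(rng)
        base = {(d.start, d.end) for d in scan_runs(t, RegionClass.TSS, PARAMS)}
        assert {(d.start, d.end)
                for d in scan_runs(t, RegionClass.TSS, harsh)} <= base


def test_swapping_groups_mirrors_directions(rng):
    va = rng.gamma(2.0, 1.0, size=(30, 8))
    vb = va * rng.choice([0.2, 1.0, 5.0], size=(30, 1))
    bins = np.arange(30)
    d1 = scan_runs(run_bin_tests(va, vb, bins, PARAMS), RegionClass.TSS, PARAMS)
    d2 = scan_runs(run_bin_tests(vb, va, bins, PARAMS), RegionClass.TSS, PARAMS)
    flip = {"hyper": "hypo", "hypo": "hyper"}
    assert [(d.start, d.end, flip[d.direction]) for d in d1] \
        == [(d.start, d.end, d.direction) for d in d2]


# ---------------------------------------------------------------------------
# Whole-gene calling


def _noise_free_matrix(gene, shift_bins=(), shift=4.0, baseline=1.0):
    """Constant counts everywhere except a planted multiplicative shift in
    the tumor samples of the given bins; two groups of 6 samples."""
    regions = partition_gene_regions(gene, 10_000_000)
    bins = np.sort(np.concatenate(list(assign_bins_to_regions(regions).values())))
    n_t, n_c = 6, 6
    counts = np.full((bins.size, n_t + n_c), baseline)
    # jitter control/tumor alternately so ranks are well-defined but means equal
    for j in range(n_t + n_c):
        counts[:, j] += (j % 3) * 1e-4
    idx = np.searchsorted(bins, np.asarray(list(shift_bins)))
    counts[idx, :n_t] *= shift
    samples = [f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(n_c)]
    totals = {s: 1e6 for s in samples}
    m = BinMatrix(100, samples, {gene.chrom: (bins, counts)}, totals=totals)
    return regions, m, samples[:n_t], samples[n_c:]


def test_planted_genic_shift_yields_one_genic_dmr():
    gene = GeneModel("g", "chr1", "+", 150000, 160000)
    regions = partition_gene_regions(gene, 10_000_000)
    genic_bins = np.sort(assign_bins_to_regions(regions)[RegionClass.GENIC])[10:15]
    regions, m, tum, ctl = _noise_free_matrix(gene, shift_bins=genic_bins)
    dmrs = call_gene_dmrs(regions, m, (tum, ctl), PARAMS, comparison=("L", "N"))
    assert len(dmrs) == 1
    d = dmrs[0]
    assert (d.region, d.direction, d.n_bins) == (RegionClass.GENIC, "hyper", 5)
    assert d.gene_id == "g" and d.comparison == ("L", "N")


def test_no_group_difference_means_no_dmrs():
    gene = GeneModel("g", "chr1", "+", 150000, 160000)
    regions, m, tum, ctl = _noise_free_matrix(gene)
    assert call_gene_dmrs(regions, m, (tum, ctl), PARAMS) == []


def test_empty_genic_region_is_skipped_not_fatal():
    gene = GeneModel("g", "chr1", "+", 150000, 152500)   # span 2.5 kb
    regions, m, tum, ctl = _noise_free_matrix(gene)
    tss_bins = np.sort(assign_bins_to_regions(regions)[RegionClass.TSS])[:4]
    regions, m, tum, ctl = _noise_free_matrix(gene, shift_bins=tss_bins)
    dmrs = call_gene_dmrs(regions, m, (tum, ctl), PARAMS)
    assert {d.region for d in dmrs} == {RegionClass.TSS}


# ---------------------------------------------------------------------------
# Gene-level summaries


def _mk_dmr(gene="g", region=RegionClass.TSS, direction="hyper"):
    from mbdpipe.dmr import Dmr
    return Dmr(gene_id=gene, region=region, chrom="chr1", start=0, end=300,
               n_bins=3, direction=direction, min_p=0.01, max_p=0.04,
               mean_rpm_high=0.5, run_log2fc=1.5)


def test_gene_region_status_summaries():
    assert gene_region_status([_mk_dmr()], "g", RegionClass.TSS) == "hyper"
    both = [_mk_dmr(region=RegionClass.DISTAL),
            _mk_dmr(region=RegionClass.DISTAL, direction="hypo")]
    assert gene_region_status(both, "g", RegionClass.DISTAL) == "both"
    assert gene_region_status([], "g", RegionClass.TSS) == "none"


@pytest.mark.parametrize("vs_n,vs_adj,expected", [
    ("hyper", "none", "hyper"),
    ("none", "hypo", "hypo"),
    ("hyper", "hypo", "both"),
    ("none", "none", "none"),
    ("both", "hyper", "both"),
    ("hypo", "hypo", "hypo"),
])
def test_union_across_controls(vs_n, vs_adj, expected):
    assert union_across_controls(vs_n, vs_adj) == expected


# ---------------------------------------------------------------------------
# DMR-centered profiles


def test_constant_coverage_gives_flat_profile():
    bins = np.arange(0, 60)
    counts = np.ones((60, 2))
    m = BinMatrix(100, ["a", "b"], {"chr1": (bins, counts)},
                  totals={"a": 1e6, "b": 1e6})
    d = _mk_dmr()
    d = replace(d, chrom="chr1", start=2000, end=2300)
    prof = dmr_mean_profile([d], m, {"G": ["a", "b"]}, half_window=500)
    assert prof["G"].shape == (10,)
    assert np.allclose(prof["G"], 1.0)


def test_profiles_average_across_dmrs():
    bins = np.arange(0, 100)
    counts = np.zeros((100, 1))
    counts[:50] = 2.0   # first DMR's window sees 2.0, second sees 0.0
    m = BinMatrix(100, ["a"], {"chr1": (bins, counts)}, totals={"a": 1e6})
    d1 = replace(_mk_dmr(), chrom="chr1", start=2000, end=2300)
    d2 = replace(_mk_dmr(), chrom="chr1", start=8000, end=8300)
    prof = dmr_mean_profile([d1, d2], m, {"G": ["a"]}, half_window=500)
    assert np.allclose(prof["G"], 1.0)   # (2 + 0) / 2 elementwise


def test_profile_requires_dmrs():
    m = BinMatrix(100, ["a"], {"chr1": (np.arange(3), np.ones((3, 1)))},
                  totals={"a": 1e6})
    with pytest.raises(ValueError):
        dmr_mean_profile([], m, {"G": ["a"]})
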