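"""Gene-region partitioning: coordinate conventions, uniqueness, bin assignment."""

import numpy as np
import pytest

from mbdpipe.annotation import (GeneModel, RegionClass, assign_bins_to_regions,
                                load_gene_models, partition_gene_regions,
                                read_chrom_sizes, read_region_table,
                                select_unique_transcripts, write_region_table)

CHROM_LEN = 10_000_000


# ---------------------------------------------------------------------------
# Readers


def test_bed_reader_maps_strand_aware_ends(tmp_path):
    p = tmp_path / "anno.bed"
    p.write_text("chr1\t150000\t160000\ttx1\t0\t+\n"
                 "chr1\t150000\t160000\ttx2\t0\t-\n")
    models = load_gene_models(p, "bed12")
    assert models[0].tss == 150000 and models[0].tes == 160000
    assert models[1].tss == 160000 and models[1].tes == 150000


def test_bed_reader_rejects_unknown_strand(tmp_path):
    p = tmp_path / "anno.bed"
    p.write_text("chr1\t100\t200\ttx1\t0\t.\n")
    with pytest.raises(ValueError, match="line 1.*strand"):
        load_gene_models(p, "bed12")


def test_bed_reader_names_bad_line(tmp_path):
    p = tmp_path / "anno.bed"
    p.write_text("chr1\t100\t200\ta\t0\t+\nchr1\tNOPE\t300\tb\t0\t+\n")
    with pytest.raises(ValueError, match="line 2"):
        load_gene_models(p, "bed12")


def test_refflat_reader(tmp_path):
    p = tmp_path / "genes.refflat"
    p.write_text("GENE1\tNM_1\tchr2\t-\t5000\t25000\t5000\t25000\t1\t5000,\t25000,\n")
    (m,) = load_gene_models(p)
    assert (m.gene_id, m.transcript_id, m.tss, m.tes) == ("GENE1", "NM_1", 25000, 5000)


def test_gtf_reader(tmp_path):
    p = tmp_path / "genes.gtf"
    p.write_text(
        'chr1\tsrc\ttranscript\t1001\t9000\t.\t+\t.\t'
        'gene_id "G1"; transcript_id "G1.t1";\n'
        'chr1\tsrc\texon\t1001\t9000\t.\t+\t.\t'
        'gene_id "G1"; transcript_id "G1.t1";\n')
    (m,) = load_gene_models(p)
    assert (m.chrom, m.strand, m.tss, m.tes) == ("chr1", "+", 1000, 9000)


def test_chrom_sizes_reader(tmp_path):
    p = tmp_path / "chrom.sizes"
    p.write_text("chr1\t1000000\nchr2\t500000\n")
    assert read_chrom_sizes(p) == {"chr1": 1000000, "chr2": 500000}


def test_gene_model_validates_strand_orientation():
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "+", 200, 100)
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "?", 100, 200)


# ---------------------------------------------------------------------------
# Transcript selection


def _gm(gene, tss, tes, strand="+", chrom="chr1"):
    return GeneModel(gene, chrom, strand, tss, tes)


def test_shared_tss_drops_both_genes():
    models = [_gm("a", 1000, 9000), _gm("b", 1000, 20000)]
    assert select_unique_transcripts(models) == []


def test_lone_transcript_is_retained_unchanged():
    models = [_gm("a", 1000, 9000)]
    assert select_unique_transcripts(models) == models


def test_longest_isoform_wins_within_gene():
    iso_long = _gm("a", 1000, 11000)
    iso_short = _gm("a", 2000, 6000)
    # oracle: exhaustively check the longest-span rule on the toy list
    assert max([iso_long, iso_short], key=lambda m: m.span) is iso_long
    assert select_unique_transcripts([iso_short, iso_long]) == [iso_long]


def test_cross_gene_switch_can_be_disabled():
    models = [_gm("a", 1000, 9000), _gm("b", 1000, 20000)]
    kept = select_unique_transcripts(models, cross_gene=False)
    assert {m.gene_id for m in kept} == {"a", "b"}


def test_shared_tes_also_drops():
    models = [_gm("a", 1000, 9000), _gm("b", 3000, 9000)]
    assert select_unique_transcripts(models) == []


# ---------------------------------------------------------------------------
# Region partitioning


def test_partition_plus_strand_worked_example():
    gr = partition_gene_regions(_gm("g", 150000, 160000), CHROM_LEN)
    assert gr.tss_region == (148000, 152000)
    assert gr.genic == (152000, 159000)
    assert gr.tes_region == (159000, 161000)
    assert gr.distal == (50000, 148000)


def test_partition_minus_strand_mirror():
    gr = partition_gene_regions(_gm("g", 160000, 150000, strand="-"), CHROM_LEN)
    assert gr.tss_region == (158000, 162000)
    assert gr.distal == (162000, 260000)
    assert gr.genic == (151000, 158000)
    assert gr.tes_region == (149000, 151000)


def test_short_transcript_has_empty_genic():
    gr = partition_gene_regions(_gm("g", 150000, 152500), CHROM_LEN)
    assert gr.genic[0] == gr.genic[1]


def test_distal_clipped_at_chromosome_start():
    gr = partition_gene_regions(_gm("g", 30000, 40000), CHROM_LEN)
    assert gr.distal == (0, 28000)


def _random_models(n, rng, margin=150_000):
    models = []
    for i in range(n):
        tss = int(rng.integers(margin, CHROM_LEN - margin))
        span = int(rng.integers(3_100, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            models.append(_gm(f"g{i}", tss, tss + span, strand))
        else:
            models.append(_gm(f"g{i}", tss, tss - span, strand))
    return models


def test_regions_tile_without_gap_or_overlap(rng):
    """Distal+TSS+Genic+TES tile [TSS-100kb, TES+1kb) exactly (mirrored on -)."""
    for m in _random_models(300, rng):
        gr = partition_gene_regions(m, CHROM_LEN)
        ivs = sorted(v for v in gr.intervals().values() if v[0] < v[1])
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2, "gap or overlap between adjacent regions"
        lo, hi = ivs[0][0], ivs[-1][1]
        if m.strand == "+":
            assert (lo, hi) == (m.tss - 100_000, m.tes + 1_000)
        else:
            assert (lo, hi) == (m.tes - 1_000, m.tss + 100_000)
        assert gr.tss_region[1] - gr.tss_region[0] == 4_000
        assert gr.tes_region[1] - gr.tes_region[0] == 2_000
        assert gr.distal[1] - gr.distal[0] == 98_000
        assert gr.genic[1] - gr.genic[0] == m.span - 3_000


def test_strand_flip_mirrors_partition(rng):
    """Flipping the strand (TSS and TES trade places) mirrors every interval
    about the transcript midpoint."""
    for m in _random_models(50, rng):
        if m.strand != "+":
            continue
        gr = partition_gene_regions(m, CHROM_LEN)
        flipped = GeneModel(m.gene_id, m.chrom, "-", m.tes, m.tss)
        gf = partition_gene_regions(flipped, CHROM_LEN)
        mirror = lambda iv: (m.tss + m.tes - iv[1], m.tss + m.tes - iv[0])
        assert gf.tss_region == mirror(gr.tss_region)
        assert gf.tes_region == mirror(gr.tes_region)
        assert gf.distal == mirror(gr.distal)
        if gr.genic[0] < gr.genic[1]:
            assert gf.genic == mirror(gr.genic)


# ---------------------------------------------------------------------------
# Bin assignment


def test_tss_region_has_forty_bins():
    gr = partition_gene_regions(_gm("g", 150000, 160000), CHROM_LEN)
    bins = assign_bins_to_regions(gr, 100)
    tss = bins[RegionClass.TSS]
    # oracle: brute-force enumeration of bin starts inside the interval
    expected = [b for b in range(CHROM_LEN // 100) if 148000 <= b * 100 < 152000]
    assert tss.tolist() == expected
    assert len(tss) == 40 and tss[0] == 1480 and tss[-1] == 1519


def test_partial_bins_use_bin_start_rule():
    # region [50, 250): bin 0 starts at 0 (outside), bins 1 and 2 start inside
    from mbdpipe.annotation import GeneRegions
    gr = GeneRegions("g", "chr1", "+", distal=(0, 0), tss_region=(50, 250),
                     genic=(0, 0), tes_region=(0, 0))
    bins = assign_bins_to_regions(gr, 100)
    assert bins[RegionClass.TSS].tolist() == [1, 2]


def test_empty_genic_yields_empty_bin_list():
    gr = partition_gene_regions(_gm("g", 150000, 152500), CHROM_LEN)
    assert assign_bins_to_regions(gr)[RegionClass.GENIC].size == 0


def test_region_bin_lists_are_pairwise_disjoint(rng):
    for m in _random_models(50, rng):
        gr = partition_gene_regions(m, CHROM_LEN)
        bins = assign_bins_to_regions(gr)
        all_bins = np.concatenate(list(bins.values()))
        assert len(np.unique(all_bins)) == all_bins.size


def test_minus_strand_bins_run_five_prime_to_three_prime():
    gr = partition_gene_regions(_gm("g", 160000, 150000, strand="-"), CHROM_LEN)
    tss = assign_bins_to_regions(gr)[RegionClass.TSS]
    assert tss[0] > tss[-1]


# ---------------------------------------------------------------------------
# Region table round trip


def test_region_table_round_trip(tmp_path, rng):
    models = _random_models(10, rng)
    regions = [partition_gene_regions(m, CHROM_LEN) for m in models]
    path = tmp_path / "regions.tsv"
    write_region_table(regions, path)
    assert read_region_table(path) == regions
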