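"""Coverage normalization, gene regions, region means and profiles."""

import numpy as np
import pytest

from polkin.binning import (CoverageTrack, GeneModel, RegionError,
                            Site, background_subtract,
                            cpm_normalize, empirical_region_vector,
                            gene_regions, metagene_profile,
                            metasite_profile, read_bedgraph,
                            read_genes_bed, read_genes_gff3, region_means,
                            write_genes_bed, write_genes_gff3)
from polkin.model import GeneClass


def _track(values, units="raw", chrom="chrS"):
    return CoverageTrack(data={chrom: np.asarray(values, dtype=float)},
                         units=units)


class TestCpmNormalize:
    def test_position_value_scales_by_total(self):
        v = np.zeros(100)
        v[10] = 20
        v[50] = 2e6 - 20
        cpm = cpm_normalize(_track(v))
        assert cpm.data["chrS"][10] == pytest.approx(10.0)
        assert cpm.total == pytest.approx(1e6)

    def test_uniform_track_sums_to_one_million(self):
        cpm = cpm_normalize(_track(np.full(1000, 3.0)))
        assert np.allclose(cpm.data["chrS"], 1e6 / 1000)
        assert cpm.total == pytest.approx(1e6)

    def test_double_normalization_rejected(self):
        cpm = cpm_normalize(_track(np.ones(10)))
        with pytest.raises(ValueError):
            cpm_normalize(cpm)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cpm_normalize(_track(np.zeros(10)))

    def test_scale_invariance(self):
        a = cpm_normalize(_track([1, 2, 3, 4.0]))
        b = cpm_normalize(_track([10, 20, 30, 40.0]))
        assert np.allclose(a.data["chrS"], b.data["chrS"])


class TestBackgroundSubtract:
    def test_identical_tracks_cancel(self):
        t = cpm_normalize(_track([1, 2, 3.0]), units_out="CPMn")
        delta = background_subtract(t, t)
        assert np.all(delta.data["chrS"] == 0)
        assert delta.units == "delta"

    def test_elementwise_difference_and_linearity(self):
        spec = _track([5, 5, 5.0], units="CPMn")
        ctrl = _track([2, 1, 7.0], units="CPMn")
        d1 = background_subtract(spec, ctrl)
        assert d1.data["chrS"] == pytest.approx([3, 4, -2])

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError):
            background_subtract(_track([1.0]), _track([1.0], units="CPMn"))

    def test_reference_mismatch_rejected(self):
        a = _track([1, 2.0], units="CPMn")
        b = _track([1, 2, 3.0], units="CPMn")
        with pytest.raises(ValueError):
            background_subtract(a, b)


class TestGeneRegions:
    def test_plus_strand_worked_example(self):
        gene = GeneModel("g1", "chrS", "+", tss=1000, tes=3000)
        regions = gene_regions(gene)
        assert regions["UAS"] == ("chrS", 500, 850)
        assert regions["promoter"] == ("chrS", 850, 1026)
        assert regions["transcript"] == ("chrS", 1026, 2925)
        assert regions["3'UTR"] == ("chrS", 2925, 3151)

    def test_constant_region_widths(self):
        for tss, tes, strand in [(1000, 3000, "+"), (9000, 5000, "-"),
                                 (700, 1500, "+")]:
            regions = gene_regions(GeneModel("g", "chrS", strand, tss, tes))
            widths = {n: e - s for n, (_, s, e) in regions.items()}
            assert widths["UAS"] == 350
            assert widths["promoter"] == 176
            assert widths["3'UTR"] == 226

    def test_minus_strand_mirror_is_involution(self):
        """Reflecting a minus-strand gene through the chromosome maps its
        regions onto the equivalent plus-strand gene's regions."""
        L = 10_000
        plus = GeneModel("g", "chrS", "+", tss=2000, tes=4000)
        minus = GeneModel("g", "chrS", "-", tss=L - 1 - 2000,
                          tes=L - 1 - 4000)
        rp = gene_regions(plus)
        rm = gene_regions(minus)
        for name in rp:
            _, s, e = rm[name]
            assert (L - e, L - s) == rp[name][1:]

    def test_minus_strand_uas_is_downstream_in_coordinates(self):
        regions = gene_regions(GeneModel("g", "chrS", "-", tss=5000,
                                         tes=3000))
        assert regions["UAS"][1] > regions["promoter"][1] > 3000

    def test_too_short_gene_flagged(self):
        with pytest.raises(RegionError):
            gene_regions(GeneModel("tiny", "chrS", "+", tss=1000, tes=1080))


class TestRegionMeans:
    def test_uniform_track_gives_uniform_means(self):
        gene = GeneModel("g1", "chrS", "+", tss=1000, tes=3000)
        track = _track(np.full(4000, 2.5), units="CPMn")
        means = region_means(track, gene_regions(gene))
        assert all(v == pytest.approx(2.5) for v in means.values())

    def test_promoter_only_signal(self):
        gene = GeneModel("g1", "chrS", "+", tss=1000, tes=3000)
        v = np.zeros(4000)
        v[850:1026] = 1.0  # total 176 over the 176 bp promoter
        means = region_means(_track(v, units="CPMn"),
                             gene_regions(gene))
        assert means["promoter"] == pytest.approx(1.0)
        assert means["UAS"] == 0 and means["3'UTR"] == 0

    def test_out_of_bounds_region_clipped(self, caplog):
        track = _track(np.ones(100), units="CPMn")
        means = region_means(track, {"promoter": ("chrS", 50, 300)})
        assert means["promoter"] == pytest.approx(1.0)

    def test_empirical_vector_satisfies_region_contract(self):
        gene = GeneModel("g1", "chrS", "+", tss=1000, tes=3000)
        track = _track(np.full(4000, 1.0), units="CPMn")
        vec = empirical_region_vector(track, [gene], GeneClass.STM)
        assert vec.labels == ("UAS", "promoter", "transcript", "3'UTR")
        assert np.all(vec.values >= 0)

    def test_expression_filter_drops_low_count_genes(self):
        genes = [GeneModel("hi", "chrS", "+", 1000, 3000),
                 GeneModel("lo", "chrS", "+", 6000, 8000)]
        v = np.zeros(10_000)
        v[850:1026] = 1.0
        track = _track(v, units="CPMn")
        vec = empirical_region_vector(track, genes, GeneClass.STM,
                                      gene_counts={"hi": 100, "lo": 5},
                                      min_counts=50)
        assert vec.values[1] == pytest.approx(1.0)  # only "hi" contributes


class TestMetagene:
    def _gene(self, tss, tes, strand="+"):
        return GeneModel(f"g{tss}", "chrS", strand, tss, tes)

    def test_uniform_signal_flat_profile(self):
        track = _track(np.full(6000, 3.0), units="CPMn")
        prof = metagene_profile([track], [self._gene(2000, 3500)])
        assert prof.values == pytest.approx(np.full(300, 3.0))
        assert prof.n == 1

    def test_replicates_are_averaged_per_bp(self):
        a = _track(np.full(6000, 2.0), units="CPMn")
        b = _track(np.full(6000, 4.0), units="CPMn")
        prof = metagene_profile([a, b], [self._gene(2000, 3500)])
        assert prof.values == pytest.approx(np.full(300, 3.0))

    def test_gene_length_invariance(self):
        """Same per-segment signal level, different gene lengths: binning
        normalizes length away."""
        v = np.zeros(20_000)
        g1, g2 = self._gene(2000, 3000), self._gene(10_000, 14_000)
        for g in (g1, g2):
            v[g.start - 1000:g.start] = 1.0
            v[g.start:g.end] = 5.0
            v[g.end:g.end + 1000] = 2.0
        track = _track(v, units="CPMn")
        p1 = metagene_profile([track], [g1])
        p2 = metagene_profile([track], [g2])
        assert p1.values == pytest.approx(p2.values)

    def test_minus_strand_gene_is_orientation_corrected(self):
        v = np.zeros(12_000)
        plus, minus = self._gene(3000, 5000), GeneModel(
            "m", "chrS", "-", tss=9000, tes=7000)
        # asymmetric marker: strong at the TSS-proximal tenth of the body
        v[3000:3200] = 7.0
        v[8801:9001] = 7.0
        track = _track(v, units="CPMn")
        pp = metagene_profile([track], [plus])
        pm = metagene_profile([track], [minus])
        assert pp.values == pytest.approx(pm.values)

    def test_short_gene_skipped(self):
        track = _track(np.ones(5000), units="CPMn")
        with pytest.raises(ValueError):
            metagene_profile([track], [self._gene(2000, 2050)])


class TestMetasite:
    def test_impulse_response(self):
        v = np.zeros(1000)
        v[500] = 10.0
        prof = metasite_profile(_track(v, units="CPMn"),
                                [Site("chrS", 500)])
        nonzero = np.flatnonzero(prof.values)
        assert len(nonzero) == 2          # window 10, step 5
        assert prof.values[nonzero] == pytest.approx([1.0, 1.0])

    def test_output_point_count_and_positions(self):
        prof = metasite_profile(_track(np.ones(1000), units="CPMn"),
                                [Site("chrS", 500)])
        assert len(prof.values) == 99     # (501 - 10)//5 + 1 full windows
        assert prof.positions[0] == pytest.approx(-250 + 4.5)

    def test_orientation_contract(self):
        """Minus-strand sites over mirrored signal give the same profile as
        plus-strand sites over the original."""
        rng = np.random.default_rng(0)
        v = rng.random(2001)
        plus = metasite_profile(_track(v, units="CPMn"),
                                [Site("chrS", 1000, "+")])
        minus = metasite_profile(_track(v[::-1].copy(), units="CPMn"),
                                 [Site("chrS", 1000, "-")])
        assert plus.values == pytest.approx(minus.values)

    def test_edge_sites_skipped(self):
        """A site within one flank of the contig edge contributes nothing;
        with no usable site left the profile is an error."""
        v = np.ones(1000)
        track = _track(v, units="CPMn")
        prof = metasite_profile(track, [Site("chrS", 100),
                                        Site("chrS", 500)])
        assert prof.n == 1
        with pytest.raises(ValueError):
            metasite_profile(track, [Site("chrS", 100)])


class TestAnnotationIO:
    def test_bed_round_trip(self, tmp_path):
        genes = [GeneModel("gA", "chrS", "+", 1000, 3000),
                 GeneModel("gB", "chrS", "-", 9000, 6000,
                           provenance="utr_fallback")]
        p = tmp_path / "genes.bed"
        write_genes_bed(genes, p)
        assert read_genes_bed(p) == genes

    def test_gff3_round_trip(self, tmp_path):
        genes = [GeneModel("gA", "chrS", "+", 1000, 3000),
                 GeneModel("gB", "chrS", "-", 9000, 6000)]
        p = tmp_path / "genes.gff3"
        write_genes_gff3(genes, p)
        assert read_genes_gff3(p) == genes

    def test_bedgraph_round_trip(self, tmp_path):
        v = np.zeros(500)
        v[100:200] = 4
        v[250] = 1
        track = _track(v)
        p = tmp_path / "cov.bedgraph"
        track.to_bedgraph(p)
        back = read_bedgraph(p, {"chrS": 500})
        assert np.array_equal(back.data["chrS"], v)

    def test_utr_fallback_extends_cds(self):
        g = GeneModel.from_cds("g", "chrS", "+", 1000, 2000)
        assert g.tss == 1000 - 47 and g.tes == 1999 + 118
        assert g.provenance == "utr_fallback"
        gm = GeneModel.from_cds("g", "chrS", "-", 1000, 2000)
        assert gm.tss == 1999 + 47 and gm.tes == 1000 - 118
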