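"""Six-region partition identities, feature assignment precedence, region
profiles and DMR-TSG overlap counting."""

import numpy as np
import pytest

from methintegrate import intervals as iv
from methintegrate.diffmeth import DMR
from methintegrate.io import CpGRecord, GeneModel, GenomicInterval
from methintegrate.regions import (
    REGION_NAMES,
    assign_features,
    build_partition,
    overlap_tsg,
    region_methylation_profiles,
)


def gene_at(tss, strand="+", gene_id="g", chrom="chr1"):
    if strand == "+":
        return GeneModel(gene_id, chrom, "+", tss, tss + 5000, tss + 500,
                         tss + 4500, (tss,), (tss + 5000,))
    return GeneModel(gene_id, chrom, "-", tss - 5000, tss, tss - 4500,
                     tss - 500, (tss - 5000,), (tss,))


class TestPartition:
    def test_worked_interval_example(self):
        # TSS=10000(+): P=[9000,11000); CGI=[10500,10800);
        # shores=[9500,10500) u [10800,11800)
        g = gene_at(10_000)
        cgi = [GenomicInterval("chr1", 10_500, 10_800, "cgi")]
        part = build_partition(cgi, [g])
        got = {name: part.regions[name]["chr1"].tolist() for name in REGION_NAMES}
        assert got["CGI.NP"] == []
        assert got["CGIS.NP"] == [[11_000, 11_800]]
        assert got["P.CGI"] == [[10_500, 10_800]]
        assert got["P.CGIS"] == [[9_500, 10_500], [10_800, 11_000]]
        assert got["P.NCGI"] == [[9_000, 10_500], [10_800, 11_000]]
        assert got["P.NCGIS"] == [[9_000, 9_500]]

    def test_no_cgis_promoter_only(self):
        part = build_partition([], [gene_at(5_000)])
        assert len(part.regions["CGI.NP"].get("chr1", [])) == 0
        assert part.regions["P.NCGI"]["chr1"].tolist() == [[4_000, 6_000]]
        assert part.regions["P.NCGIS"]["chr1"].tolist() == [[4_000, 6_000]]

    def test_overlapping_promoters_merged(self):
        part = build_partition([], [gene_at(5_000, gene_id="a"),
                                    gene_at(5_800, gene_id="b")])
        assert part.promoters["chr1"].tolist() == [[4_000, 6_800]]

    @pytest.mark.parametrize("seed", range(30))
    def test_base_set_identities_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        genes = [gene_at(int(t), strand=rng.choice(["+", "-"]), gene_id=f"g{i}")
                 for i, t in enumerate(rng.integers(6_000, 80_000, rng.integers(1, 8)))]
        cgis = [GenomicInterval("chr1", int(s), int(s) + int(w), f"c{i}")
                for i, (s, w) in enumerate(zip(rng.integers(0, 90_000, rng.integers(0, 10)),
                                               rng.integers(200, 2_000, 10)))]
        part = build_partition(cgis, genes)
        chrom = "chr1"
        P = part.promoters[chrom]
        CGI = part.cgis[chrom]
        S = part.shores[chrom]
        r = {n: part.regions[n][chrom] for n in REGION_NAMES}
        # V u III = promoter bases; I u III = CGI bases; II disjoint from CGI
        assert iv.union(r["P.NCGI"], r["P.CGI"]).tolist() == P.tolist()
        assert iv.union(r["CGI.NP"], r["P.CGI"]).tolist() == CGI.tolist()
        assert iv.total_length(iv.intersect(r["CGIS.NP"], CGI)) == 0
        assert iv.total_length(iv.intersect(S, CGI)) == 0

    def test_partition_invariant_to_input_order(self):
        genes = [gene_at(5_000, gene_id="a"), gene_at(20_000, gene_id="b")]
        cgis = [GenomicInterval("chr1", 4_800, 5_400, "x"),
                GenomicInterval("chr1", 19_000, 19_500, "y")]
        a = build_partition(cgis, genes)
        b = build_partition(cgis[::-1], genes[::-1])
        for name in REGION_NAMES:
            assert a.regions[name]["chr1"].tolist() == b.regions[name]["chr1"].tolist()


class TestAssignFeatures:
    def test_precedence_and_fractions(self):
        g = gene_at(10_000)
        cgis = [GenomicInterval("chr1", 10_500, 10_700, "c")]
        sites = [("chr1", 10_100),   # promoter AND exon -> promoter; in a shore
                 ("chr1", 13_000),   # exon only, open sea
                 ("chr1", 50_000),   # nothing
                 ("chr1", 10_550)]   # promoter + CGI
        df, fr = assign_features(sites, cgis, [g])
        assert df["gene_context"].tolist() == ["promoter", "exon", "intergenic", "promoter"]
        assert df["cpg_context"].tolist() == ["shore", "open sea", "open sea", "CGI"]
        assert fr["promoter"] == pytest.approx(0.5)
        assert fr["intergenic"] == pytest.approx(0.25)

    def test_every_site_single_label(self):
        rng = np.random.default_rng(5)
        g = gene_at(10_000)
        cgis = [GenomicInterval("chr1", 9_000, 9_400, "c")]
        sites = [("chr1", int(p)) for p in rng.integers(0, 30_000, 200)]
        df, fr = assign_features(sites, cgis, [g])
        assert len(df) == 200
        assert sum(fr[k] for k in ("promoter", "exon", "intron", "intergenic")) == \
            pytest.approx(1.0)
        assert sum(fr[k] for k in ("CGI", "shore", "open sea")) == pytest.approx(1.0)


class TestProfiles:
    def test_all_zero_methylome_mass_in_first_bin(self):
        g = gene_at(10_000)
        cgis = [GenomicInterval("chr1", 10_400, 10_800, "c")]
        part = build_partition(cgis, [g])
        meth = [CpGRecord("chr1", p, "+", 20, 0) for p in range(9_000, 11_000, 50)]
        prof = region_methylation_profiles(meth, part)
        for name in REGION_NAMES:
            if prof[name]["n"]:
                assert prof[name]["counts"][0] == prof[name]["n"]

    def test_histogram_conserves_counts(self):
        rng = np.random.default_rng(6)
        g = gene_at(10_000)
        cgis = [GenomicInterval("chr1", 10_400, 10_800, "c")]
        part = build_partition(cgis, [g])
        meth = [CpGRecord("chr1", int(p), "+", 20, int(rng.integers(0, 21)))
                for p in rng.integers(8_000, 13_000, 300)]
        prof = region_methylation_profiles(meth, part)
        for name in REGION_NAMES:
            assert prof[name]["counts"].sum() == prof[name]["n"]

    def test_hyper_cgi_hypo_promoter_pattern(self):
        # methylation high inside the promoter CGI, low in promoter-outside-shore
        g = gene_at(10_000)
        cgis = [GenomicInterval("chr1", 10_400, 10_800, "c")]
        part = build_partition(cgis, [g])
        rng = np.random.default_rng(7)
        meth = []
        for p in range(9_000, 11_000, 20):
            inside = 10_400 <= p < 10_800
            prop = rng.beta(20, 2) if inside else rng.beta(2, 20)
            meth.append(CpGRecord("chr1", p, "+", 50, int(round(prop * 50))))
        prof = region_methylation_profiles(meth, part)
        assert prof["P.CGI"]["quartiles"][1] >= 80
        assert prof["P.NCGIS"]["quartiles"][1] <= 20


class TestTSGOverlap:
    def make_dmr(self, start, end, direction):
        return DMR(GenomicInterval("chr1", start, end, f"dmr{start}"), 30.0,
                   1e-4, 6, direction, "significant")

    def test_promoter_and_utr_yield_two_records_one_gene(self, plus_gene):
        dmr = self.make_dmr(900, 2_100, "hyper")  # spans promoter+5'UTR+CDS
        recs, counts = overlap_tsg([dmr], ["gplus"], [plus_gene])
        assert {(r.segment) for r in recs} >= {"promoter", "5'UTR"}
        assert counts == {"hyper": 1, "hypo": 0}

    def test_non_tsg_gene_ignored(self, plus_gene):
        dmr = self.make_dmr(900, 2_100, "hyper")
        recs, counts = overlap_tsg([dmr], ["unknown"], [plus_gene])
        assert recs == [] and counts == {"hyper": 0, "hypo": 0}

    def test_per_direction_deduplicated_counts(self):
        genes = [gene_at(10_000, gene_id="A"), gene_at(30_000, gene_id="B"),
                 gene_at(50_000, gene_id="C")]
        hyper = [self.make_dmr(9_500, 10_200, "hyper"),
                 self.make_dmr(10_300, 10_600, "hyper"),
                 self.make_dmr(29_500, 30_200, "hyper")]
        hypo = [self.make_dmr(29_600, 30_100, "hypo"),
                self.make_dmr(49_500, 50_200, "hypo")]
        _, counts = overlap_tsg(hyper + hypo, ["A", "B", "C"], genes)
        assert counts == {"hyper": 2, "hypo": 2}
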