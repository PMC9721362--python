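"""Variant-effect annotation: regions, codon consequences, summaries."""

import math

import pytest

from emsomics import PipelineConfig, Variant
from emsomics import variants as va
from emsomics.models import GeneModel, revcomp


def _simple_gene(start=10_001, cds_len=3_000, strand="+", chrom="Chr01", gene_id="gA"):
    end = start + cds_len - 1
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        exons=[(start, end)], cds=[(start, end)],
    )


@pytest.fixture()
def single_gene_index():
    gene = _simple_gene()
    return gene, va.GeneIndex([gene], chroms={"Chr01"})


class TestRegions:
    def test_downstream_within_5kb_of_plus_strand_gene(self, single_gene_index):
        gene, index = single_gene_index
        v = Variant("Chr01", gene.end + 3000, "A", "G")
        eff = va.classify_region(v, index)
        assert eff.region == "downstream_5kb" and eff.gene_id == "gA"

    def test_upstream_mirror_on_minus_strand(self):
        gene = _simple_gene(strand="-")
        index = va.GeneIndex([gene])
        eff = va.classify_region(Variant("Chr01", gene.end + 3000, "A", "G"), index)
        assert eff.region == "upstream_5kb"

    def test_beyond_flank_is_intergenic(self, single_gene_index):
        gene, index = single_gene_index
        eff = va.classify_region(Variant("Chr01", gene.end + 6000, "A", "G"), index)
        assert eff.region == "intergenic" and eff.gene_id is None

    def test_flank_tie_prefers_nearest_then_lexicographic(self):
        g1 = _simple_gene(start=10_001, cds_len=300, gene_id="gB")
        g2 = _simple_gene(start=14_302, cds_len=300, gene_id="gA")
        index = va.GeneIndex([g1, g2])
        # midpoint 12301 is 2001 bp from both spans -> lexicographically smaller id
        eff = va.classify_region(Variant("Chr01", 12_301, "A", "G"), index)
        assert eff.gene_id == "gA"
        eff = va.classify_region(Variant("Chr01", 11_000, "A", "G"), index)
        assert eff.gene_id == "gB"

    def test_unknown_chromosome_raises(self, single_gene_index):
        _, index = single_gene_index
        with pytest.raises(va.UnplacedVariantError):
            va.classify_region(Variant("ChrZZ", 100, "A", "G"), index)

    def test_every_variant_gets_exactly_one_region(self, variant_data, genome_and_genes):
        genome, genes = genome_and_genes
        variants, _ = variant_data
        effects = va.annotate_all(variants, genes, genome)
        assert len(effects) == len(variants)
        from emsomics.models import REGIONS

        assert all(e.region in REGIONS for e in effects)


class TestCodingEffects:
    """Toy CDS ATG GCT TAA embedded at a known position."""

    def _toy(self):
        chrom_seq = "TTT" + "ATGGCTTAA" + "TTTT"
        gene = GeneModel(
            gene_id="toy", chrom="c", strand="+", start=4, end=12,
            exons=[(4, 12)], cds=[(4, 12)],
        )
        return {"c": chrom_seq}, gene

    def test_synonymous_third_position(self):
        genome, gene = self._toy()
        v = Variant("c", 9, "T", "C")  # GCT -> GCC, Ala=Ala
        eff = va.coding_effect(va.VariantEffect(v, "toy", "exon"), gene, genome)
        assert eff.coding_effect == "synonymous" and eff.aa_change == ""

    def test_nonsynonymous_with_aa_change(self):
        genome, gene = self._toy()
        v = Variant("c", 7, "G", "A")  # GCT -> ACT, Ala2Thr
        eff = va.coding_effect(va.VariantEffect(v, "toy", "exon"), gene, genome)
        assert eff.coding_effect == "nonsynonymous"
        assert eff.aa_change == "Ala2Thr"

    def test_stop_lost_and_start_lost(self):
        genome, gene = self._toy()
        eff = va.coding_effect(
            va.VariantEffect(Variant("c", 10, "T", "C"), "toy", "exon"), gene, genome
        )  # TAA -> CAA
        assert eff.coding_effect == "stop_lost"
        eff = va.coding_effect(
            va.VariantEffect(Variant("c", 4, "A", "G"), "toy", "exon"), gene, genome
        )  # ATG -> GTG
        assert eff.coding_effect == "start_lost"

    def test_frameshift_vs_codon_indel(self):
        genome, gene = self._toy()
        ins1 = Variant("c", 5, "T", "TA")
        eff = va.coding_effect(va.VariantEffect(ins1, "toy", "exon"), gene, genome)
        assert eff.coding_effect == "frameshift"
        ins3 = Variant("c", 5, "T", "TAAA")
        eff = va.coding_effect(va.VariantEffect(ins3, "toy", "exon"), gene, genome)
        assert eff.coding_effect == "codon_insertion"

    def test_reference_mismatch_raises(self):
        genome, gene = self._toy()
        with pytest.raises(va.ReferenceMismatchError):
            va.coding_effect(
                va.VariantEffect(Variant("c", 7, "C", "A"), "toy", "exon"), gene, genome
            )

    def test_agrees_with_whole_protein_diff_oracle(self, variant_data, genome_and_genes):
        """Per-codon annotation must reproduce the re-translation truth labels."""
        genome, genes = genome_and_genes
        variants, truth = variant_data
        effects = va.annotate_all(variants, genes, genome)
        coding = 0
        for eff, label in zip(effects, truth.variant_labels):
            got = (eff.region, eff.gene_id, eff.coding_effect, eff.aa_change)
            want = (
                label["region"],
                label["gene_id"],
                label["coding_effect"],
                label["aa_change"],
            )
            assert got == want
            if label["coding_effect"] != "none":
                coding += 1
        assert coding >= 5  # the fixture exercises real coding consequences


class TestSpliceSites:
    def _two_exon_gene(self):
        # exon1 1001..1100, intron 1101..1400, exon2 1401..1500, all CDS
        return GeneModel(
            gene_id="sp", chrom="c", strand="+", start=1001, end=1500,
            exons=[(1001, 1100), (1401, 1500)],
            cds=[(1001, 1100), (1401, 1500)],
        )

    def test_intron_convention_default(self):
        gene = self._two_exon_gene()
        index = va.GeneIndex([gene])
        donor = va.classify_region(Variant("c", 1101, "A", "G"), index)
        acceptor = va.classify_region(Variant("c", 1400, "A", "G"), index)
        assert (donor.region, donor.coding_effect) == ("splice_site", "splice_donor")
        assert (acceptor.region, acceptor.coding_effect) == ("splice_site", "splice_acceptor")
        mid = va.classify_region(Variant("c", 1250, "A", "G"), index)
        assert mid.region == "intron"

    def test_exon_convention_switch(self):
        gene = self._two_exon_gene()
        index = va.GeneIndex([gene])
        cfg = PipelineConfig(splice_site_on="exon")
        last2 = va.classify_region(Variant("c", 1100, "A", "G"), index, cfg)
        assert (last2.region, last2.coding_effect) == ("splice_site", "splice_donor")
        # under the default intron convention the same base is plain CDS
        assert va.classify_region(Variant("c", 1100, "A", "G"), index).region == "exon"


class TestTiTv:
    def test_worked_examples(self):
        mk = lambda ref, alt: Variant("c", 1, ref, alt)
        assert va.titv([mk("A", "G"), mk("C", "T"), mk("A", "T")]) == 2.0
        assert va.titv([mk("A", "C")]) == 0.0
        assert math.isinf(va.titv([mk("A", "G")]))

    def test_invariant_under_strand_complementation(self, variant_data):
        variants, _ = variant_data
        snps = [v for v in variants if v.vtype == "snp"]
        flipped = [
            Variant(v.chrom, v.pos, revcomp(v.ref), revcomp(v.alt), v.zygosity)
            for v in snps
        ]
        assert va.titv(snps) == pytest.approx(va.titv(flipped))


class TestSummaries:
    def test_indel_histogram_and_het_fraction(self):
        vs = [
            Variant("c", 10, "A", "AT", "hom"),
            Variant("c", 80, "A", "AG", "hom"),
            Variant("c", 150, "G", "GC", "hom"),
            Variant("c", 220, "ATT", "A", "hom"),
        ]
        s = va.variant_summaries(vs, [va.VariantEffect(v, None, "intergenic") for v in vs])
        assert s["indel_size_histogram"] == {-2: 1, 1: 3}
        assert s["het_fraction"] == 0.0

    def test_region_percentages_partition(self, variant_data, genome_and_genes):
        genome, genes = genome_and_genes
        variants, _ = variant_data
        effects = va.annotate_all(variants, genes, genome)
        s = va.variant_summaries(variants, effects)
        assert sum(s["region_percent"].values()) == pytest.approx(100.0, abs=1e-9)

    def test_mutated_gene_set_semantics(self):
        v = Variant("c", 1, "A", "G")
        mk = lambda gid, ce: va.VariantEffect(v, gid, "exon", ce)
        effects = [
            mk("g1", "nonsynonymous"),
            mk("g1", "nonsynonymous"),
            mk("g1", "frameshift"),
            mk("g2", "synonymous"),
            mk(None, "none"),
        ]
        assert va.mutated_gene_set(effects) == {"g1"}
        only_nonsyn = va.mutated_gene_set(effects, frozenset({"nonsynonymous"}))
        assert only_nonsyn == {"g1"}
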