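"""Effect annotation: region resolution, codon logic, partition identities
and strand invariance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from brassica_variome import simulate
from brassica_variome.annotate import (
    GeneIndex,
    annotate,
    annotate_variant,
    classify_indel_cds,
    classify_snp_cds,
    functional_counts,
    locate,
    marginal_counts,
)
from brassica_variome.models import GeneModel, ReferenceGenome, Variant, revcomp


@pytest.fixture(scope="module")
def toy_gene():
    """Hand-built plus-strand gene on a 400 bp chromosome.

    exon1 81..140, intron 141..200, exon2 201..280;
    CDS 101..140 + 201..240 (spliced: ATG, 24 middle codons... 40+40=80 bp
    is not a multiple of 3, so build 101..140 + 201..241: 81 bp = 27 codons).
    """
    rng = np.random.default_rng(1)
    seq = list("".join(rng.choice(list("ACGT"), size=400)))
    cds = "ATG" + "CTG" * 25 + "TAA"  # 81 bp, Leu body: no internal stops
    seq[100:140] = cds[:40]
    seq[200:241] = cds[40:]
    ref = ReferenceGenome({"c": "".join(seq)})
    gene = GeneModel(
        gene_id="toy", chrom="c", strand="+",
        exons=((81, 140), (201, 280)), cds_start=101, cds_end=241,
    )
    return ref, gene


class TestLocate:
    @pytest.mark.parametrize(
        "pos, region",
        [
            (145, "splice"),   # 5 bp into the intron from the donor junction
            (148, "splice"),   # 8th intronic base: still inside the window
            (149, "intron"),   # 9 bp in: outside the 8 bp window
            (196, "splice"),   # 5 bp from the acceptor junction
            (120, "CDS"),
            (90, "UTR5"),
            (250, "UTR3"),
            (50, "intergenic"),
            (350, "intergenic"),
        ],
    )
    def test_regions(self, toy_gene, pos, region):
        ref, gene = toy_gene
        index = GeneIndex([gene])
        v = Variant("c", pos, ref.base("c", pos), "A" if ref.base("c", pos) != "A" else "G")
        gene_id, got = locate(v, index, ref)
        assert got == region
        assert (gene_id is None) == (region == "intergenic")

    def test_unknown_chromosome_raises(self, toy_gene):
        ref, gene = toy_gene
        with pytest.raises(KeyError):
            locate(Variant("zz", 10, "A", "G"), GeneIndex([gene]), ref)

    def test_utr_orientation_flips_on_minus_strand(self, toy_gene):
        ref, gene = toy_gene
        flipped = GeneModel(
            gene_id="toy-", chrom="c", strand="-",
            exons=gene.exons, cds_start=gene.cds_start, cds_end=gene.cds_end,
        )
        assert flipped.region_of(90) == "UTR3"
        assert flipped.region_of(250) == "UTR5"


class TestSnpCds:
    def test_start_codon_change_is_nonsyn(self, toy_gene):
        ref, gene = toy_gene
        # ATG -> ACG (M -> T) at the second CDS base (pos 102)
        v = Variant("c", 102, ref.base("c", 102), "C")
        assert ref.base("c", 102) == "T"
        assert classify_snp_cds(v, gene, ref) == "nonSyn"

    def test_third_position_wobble_is_syn(self, toy_gene):
        ref, gene = toy_gene
        # CTG codon at CDS positions 4..6 (genomic 104..106): CTG->CTA is L->L
        v = Variant("c", 106, ref.base("c", 106), "A")
        assert ref.base("c", 106) == "G"
        assert classify_snp_cds(v, gene, ref) == "Syn"

    def test_stop_loss_counts_as_nonsyn(self, toy_gene):
        ref, gene = toy_gene
        # last codon TAA at genomic 239..241; TAA->TAC is stop->Y
        v = Variant("c", 241, ref.base("c", 241), "C")
        assert classify_snp_cds(v, gene, ref) == "nonSyn"

    def test_reference_mismatch_raises(self, toy_gene):
        ref, gene = toy_gene
        wrong = "A" if ref.base("c", 120) != "A" else "C"
        with pytest.raises(ValueError, match="reference allele mismatch"):
            classify_snp_cds(Variant("c", 120, wrong, "G"), gene, ref)

    def test_agrees_with_full_protein_retranslation(self, small_study):
        """Both strands: codon-level call equals brute-force mutant-protein
        translation for every planted coding SNP plus random CDS SNPs."""
        ref, genes, _, manifest = small_study
        index = GeneIndex(genes)
        rng = np.random.default_rng(5)
        cases = []
        for pv in manifest.variants:
            if pv.variant.vclass == "SNP" and pv.category in ("Syn", "nonSyn"):
                cases.append(pv.variant)
        for gene in genes:
            positions = rng.choice(gene.cds_genomic_positions, size=30)
            for pos in positions:
                refbase = ref.base(gene.chrom, int(pos))
                alt = rng.choice([b for b in "ACGT" if b != refbase])
                cases.append(Variant(gene.chrom, int(pos), refbase, str(alt)))
        assert len(cases) >= 200
        for v in cases:
            gene = index.gene_at(v.chrom, v.pos)
            got = classify_snp_cds(v, gene, ref)
            # oracle: rebuild and translate the whole mutated CDS
            mutated = (
                ref.chromosomes[v.chrom][: v.pos - 1]
                + v.alt
                + ref.chromosomes[v.chrom][v.pos :]
            )
            mref = ReferenceGenome({v.chrom: mutated})
            before = str(Seq(gene.cds_sequence(ref)).translate())
            after = str(Seq(gene.cds_sequence(mref)).translate())
            assert got == ("Syn" if before == after else "nonSyn")


class TestIndelCds:
    @pytest.mark.parametrize(
        "ref_allele, alt_allele, expected",
        [
            ("ATTT", "A", "nonframeshift"),  # 3 bp deletion
            ("A", "AT", "frameshift"),       # 1 bp insertion
            ("A", "ATTTTTT", "nonframeshift"),  # 6 bp insertion
            ("AT", "A", "frameshift"),       # 1 bp deletion
        ],
    )
    def test_mod_three_rule(self, ref_allele, alt_allele, expected):
        assert classify_indel_cds(Variant("c", 1, ref_allele, alt_allele)) == expected

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            classify_indel_cds(Variant("c", 1, "AT", "AG"))


class TestAnnotateTable:
    def test_partition_identity_and_manifest_agreement(self, small_study):
        ref, genes, _, manifest = small_study
        table = annotate([pv.variant for pv in manifest.variants], genes, ref)
        marginals = marginal_counts(table)
        for vclass in ("SNP", "InDel"):
            m = marginals[vclass]
            assert m["total"] == m.drop("total").sum()  # partition identity
        # per-category counts equal the manifest truth exactly
        truth = pd.Series(
            [pv.category for pv in manifest.variants]
        ).value_counts()
        got = table["category"].value_counts()
        assert got.to_dict() == truth.to_dict()

    def test_functional_identities(self, small_study):
        ref, genes, _, manifest = small_study
        table = annotate([pv.variant for pv in manifest.variants], genes, ref)
        m = marginal_counts(table)
        f = functional_counts(table)
        assert f["SNP"] == m["SNP"]["nonSyn"] + m["SNP"]["splice"]
        assert f["InDel"] == (
            m["InDel"]["frameshift"] + m["InDel"]["nonframeshift"] + m["InDel"]["splice"]
        )

    def test_one_of_each_category_gives_unit_marginals(self):
        ref, genes = simulate.generate_reference(1, 20_000, 5, seed=13)
        mix = {"SNP": {c: 1 / 7 for c in
                       ("nonSyn", "Syn", "splice", "intron", "UTR5", "UTR3", "intergenic")},
               "InDel": simulate.DEFAULT_CATEGORY_MIX["InDel"]}
        _, manifest = simulate.generate_population(
            ref, genes, 1, 2, 7, category_mix=mix, seed=14, snp_fraction=1.0
        )
        table = annotate([pv.variant for pv in manifest.variants], genes, ref)
        m = marginal_counts(table)["SNP"]
        assert list(m.drop("total")) == [1] * 7

    def test_empty_variant_list(self, small_study):
        ref, genes, _, _ = small_study
        table = annotate([], genes, ref)
        m = marginal_counts(table)
        assert m["SNP"]["total"] == 0 and m["InDel"]["total"] == 0

    def test_strand_invariance_under_genome_mirroring(self, small_study):
        ref, genes, _, manifest = small_study
        variants = [pv.variant for pv in manifest.variants]
        a1 = annotate(variants, genes, ref)
        mref, mgenes, mvars = simulate.mirror_study(ref, genes, variants)
        a2 = annotate(mvars, mgenes, mref)
        c1 = sorted(zip(a1["vclass"], a1["category"]))
        c2 = sorted(zip(a2["vclass"], a2["category"]))
        assert c1 == c2
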