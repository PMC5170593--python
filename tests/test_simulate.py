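"""Generator contracts: determinism, gene-model invariants, planting
fidelity, read/depth emission models."""

from __future__ import annotations


import numpy as np
import pytest
from scipy import stats

from brassica_variome import io as vio, simulate
from brassica_variome.annotate import CODON_TABLE, GeneIndex, annotate_variant
from brassica_variome.models import CategoryError, PackingError
from brassica_variome.readqc import QCThresholds, process_pairs


class TestGenerateReference:
    def test_gene_model_invariants(self, small_study):
        ref, genes, _, _ = small_study
        for g in genes:
            assert len(g.exons) >= 2
            for (_, e1), (s2, _) in zip(g.exons, g.exons[1:]):
                assert s2 - e1 - 1 >= 20  # intron floor
            u5, u3 = g.utr_intervals
            assert u5 and u3  # non-empty UTRs
            cds = g.cds_sequence(ref)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            aa = [CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)]
            assert aa[-1] == "*" and "*" not in aa[:-1]

    def test_determinism_byte_identical_outputs(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            ref, genes = simulate.generate_reference(1, 15_000, 4, seed=1)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            vio.write_fasta(ref, fa)
            vio.write_gff3(genes, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError, match="chr01"):
            simulate.generate_reference(1, 10_000, 500, seed=1)
        with pytest.raises(ValueError):
            simulate.generate_reference(1, 1_000, 5, seed=1)

    def test_alphabet_and_lengths(self, small_study):
        ref, _, _, _ = small_study
        for name, seq in ref.chromosomes.items():
            assert set(seq) <= set("ACGT")
            assert len(seq) == 30_000


class TestGeneratePopulation:
    def test_single_category_request_verified_by_annotator(self):
        ref, genes = simulate.generate_reference(1, 20_000, 5, seed=2)
        mix = {
            "SNP": {"nonSyn": 1.0},
            "InDel": simulate.DEFAULT_CATEGORY_MIX["InDel"],
        }
        _, manifest = simulate.generate_population(
            ref, genes, 2, 3, 100, category_mix=mix, seed=3, snp_fraction=1.0
        )
        index = GeneIndex(genes)
        assert len(manifest.variants) == 100
        for pv in manifest.variants:
            assert pv.category == "nonSyn"
            assert annotate_variant(pv.variant, index, ref)[1] == "nonSyn"

    def test_category_fidelity_under_default_mix(self, small_study):
        ref, genes, _, manifest = small_study
        index = GeneIndex(genes)
        for pv in manifest.variants:
            assert annotate_variant(pv.variant, index, ref)[1] == pv.category

    def test_zygosity_fidelity_and_unique_positions(self, small_study):
        _, _, accessions, manifest = small_study
        hom = [a.accession_id for a in accessions if a.zygosity_class == "homozygous_line"]
        for pv in manifest.variants:
            assert not any(pv.genotypes[h] == "het" for h in hom)
        keys = [(pv.variant.chrom, pv.variant.pos) for pv in manifest.variants]
        assert len(keys) == len(set(keys))

    def test_empty_population_is_an_error(self, small_study):
        ref, genes, _, _ = small_study
        with pytest.raises(ValueError):
            simulate.generate_population(ref, genes, 2, 0, 10, seed=1)

    def test_fixed_spectrum_passes_through_to_population_frequency(self):
        ref, genes = simulate.generate_reference(1, 20_000, 5, seed=4)
        _, manifest = simulate.generate_population(
            ref, genes, 3, 10, 120,
            maf_spectrum={"kind": "fixed", "value": 0.5}, seed=5,
        )
        freqs = [pv.population_alt_freq() for pv in manifest.variants]
        # 30 accessions per variant, p = 0.5: the mean over 120 variants has
        # standard error ~0.008
        assert abs(float(np.mean(freqs)) - 0.5) < 0.05

    def test_impossible_category_names_the_category(self):
        ref, genes = simulate.generate_reference(1, 20_000, 0, seed=6)
        mix = {"SNP": {"splice": 1.0}, "InDel": simulate.DEFAULT_CATEGORY_MIX["InDel"]}
        with pytest.raises(CategoryError, match="splice"):
            simulate.generate_population(
                ref, genes, 1, 2, 5, category_mix=mix, seed=7, snp_fraction=1.0
            )

    def test_genebank_accessions_may_be_het(self):
        ref, genes = simulate.generate_reference(1, 20_000, 5, seed=8)
        accs, manifest = simulate.generate_population(
            ref, genes, 2, 4, 80, seed=9, genebank_per_group=2,
            maf_spectrum={"kind": "fixed", "value": 0.5},
        )
        gb = [a.accession_id for a in accs if a.zygosity_class == "genebank"]
        assert gb
        n_het = sum(pv.genotypes[g] == "het" for pv in manifest.variants for g in gb)
        assert n_het > 0  # het genotypes occur for genebank material


class TestEmitReads:
    def test_clean_reads_all_pass_qc(self, small_study):
        ref, _, accessions, manifest = small_study
        pairs, failures = simulate.emit_reads(
            accessions[0], ref, manifest, depth=1, error_rate=0.0,
            qc_failure_rates=None, seed=1,
        )
        assert failures == []
        _, report, _ = process_pairs(pairs, QCThresholds())
        assert report.pairs_retained == report.pairs_in

    def test_coverage_arithmetic(self, small_study):
        ref, _, accessions, manifest = small_study
        pairs, _ = simulate.emit_reads(
            accessions[1], ref, manifest, depth=2, read_length=100, seed=2
        )
        total = sum(
            len(s)
            for s in simulate.build_haplotype(ref, manifest, accessions[1].accession_id).values()
        )
        assert len(pairs) == pytest.approx(2 * total / 200, abs=2)

    def test_duplicate_rate_gives_expected_count(self, small_study):
        ref, _, accessions, manifest = small_study
        pairs, failures = simulate.emit_reads(
            accessions[2], ref, manifest, depth=4, error_rate=0.0,
            qc_failure_rates={"duplicate": 0.1}, seed=3,
        )
        dupes = [f for f in failures if f.kind == "duplicate"]
        n = len(pairs)
        sd = (n * 0.1 * 0.9) ** 0.5
        assert abs(len(dupes) - 0.1 * n) < 4 * sd
        for f in dupes:
            assert f.duplicate_of is not None

    def test_read_length_longer_than_chromosome_raises(self, small_study):
        ref, _, accessions, manifest = small_study
        with pytest.raises(ValueError):
            simulate.emit_reads(
                accessions[0], ref, manifest, depth=1, read_length=50_000, seed=4
            )


class TestEmitAlleleDepths:
    def test_hom_alt_error_free_has_no_reference_reads(self, small_study):
        ref, _, accessions, manifest = small_study
        acc = accessions[0]
        table, _ = simulate.emit_allele_depths(
            acc, manifest, depth=10, error_rate=0.0, seed=1, ref=ref, fp_site_rate=0.0
        )
        alt_sites = {
            (pv.variant.chrom, pv.variant.pos)
            for pv in manifest.variants
            if pv.genotypes[acc.accession_id] == "alt"
        }
        got = set(zip(table["chrom"], table["pos"]))
        assert got == alt_sites  # hom-ref sites absent, hom-alt all present
        assert (table["D_R"] == 0).all()
        assert (table["D_A"] >= 1).all()

    def test_error_only_sites_match_binomial_tail(self):
        """Fraction of error-only sites with D_A >= 3 matches the closed-form
        tail of Binomial(N, e) mixed over N ~ Poisson(10) conditioned >= 1."""
        rng = np.random.default_rng(17)
        depth, e, n_sites = 10.0, 0.05, 10_000
        _, da = simulate.error_only_depths(n_sites, depth, e, rng)
        ns = np.arange(1, 60)
        pois = stats.poisson.pmf(ns, depth) / (1 - stats.poisson.pmf(0, depth))
        expected = float(np.sum(pois * stats.binom.sf(2, ns, e)))
        observed = float(np.mean(da >= 3))
        sd = (expected * (1 - expected) / n_sites) ** 0.5
        assert abs(observed - expected) < 5 * sd + 1e-9

    def test_determinism(self, small_study):
        ref, _, accessions, manifest = small_study
        t1, inj1 = simulate.emit_allele_depths(
            accessions[3], manifest, depth=8, error_rate=0.01, seed=5, ref=ref
        )
        t2, inj2 = simulate.emit_allele_depths(
            accessions[3], manifest, depth=8, error_rate=0.01, seed=5, ref=ref
        )
        assert t1.equals(t2) and inj1 == inj2
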