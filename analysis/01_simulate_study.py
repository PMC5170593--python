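#!/usr/bin/env python
"""Simulate the synthetic resequencing study that the later analysis steps
consume: a 2 x 50 kb genome with 24 gene models, 3 morphotype groups x 5
homozygous accessions, 500 planted variants, paired-end reads at 2x with
planted QC failures, and 10x allele-depth tables with injected error-only
sites.

Large intermediates (FASTQ, depth tables, manifest) land under scratch/run/;
small summary tables land under results/.
"""

from pathlib import Path

import pandas as pd

from brassica_variome import io as vio, simulate

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"
SEED = 20160119


def main() -> None:
    RUN.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    ref, genes = simulate.generate_reference(2, 50_000, 24, seed=SEED)
    accessions, manifest = simulate.generate_population(
        ref, genes, n_groups=3, accessions_per_group=5, n_variants=500, seed=SEED + 1
    )
    vio.write_fasta(ref, RUN / "genome.fa")
    vio.write_gff3(genes, RUN / "genes.gff3")
    vio.write_accessions(accessions, RUN / "accessions.tsv")

    rates = {k: 0.02 for k in ("n_rich", "low_mean_q", "short_after_trim", "duplicate")}
    reads_dir = RUN / "reads"
    reads_dir.mkdir(exist_ok=True)
    frames, error_sites = [], set()
    for i, acc in enumerate(accessions):
        pairs, failures = simulate.emit_reads(
            acc, ref, manifest, depth=2.0, read_length=100, error_rate=0.01,
            qc_failure_rates=rates, seed=SEED + 100 + i,
        )
        manifest.qc_failures.extend(failures)
        vio.write_fastq_pair(
            pairs, reads_dir / f"{acc.accession_id}_1.fastq.gz",
            reads_dir / f"{acc.accession_id}_2.fastq.gz",
        )
        table, injected = simulate.emit_allele_depths(
            acc, manifest, depth=10.0, error_rate=0.01, seed=SEED + 200 + i,
            ref=ref, fp_site_rate=2e-4,
        )
        frames.append(table)
        error_sites.update((c, p) for c, p, _, _ in injected)
    manifest.error_sites = sorted(error_sites)
    depths = pd.concat(frames, ignore_index=True)
    vio.write_tsv(depths, RUN / "depths.tsv")
    vio.save_manifest(manifest, RUN / "manifest")

    by_cat = (
        pd.DataFrame(
            [(pv.variant.vclass, pv.category) for pv in manifest.variants],
            columns=["vclass", "category"],
        )
        .value_counts()
        .rename("planted")
        .reset_index()
        .sort_values(["vclass", "category"])
    )
    vio.write_tsv(by_cat, RESULTS / "01_planted_variants_by_category.tsv")

    print(f"genome: {len(ref.chromosomes)} chromosomes, {ref.total_length:,} bp, "
          f"{len(genes)} genes")
    print(f"population: {len(accessions)} accessions in 3 groups")
    print(f"planted: {len(manifest.variants)} variants "
          f"({sum(pv.variant.vclass == 'SNP' for pv in manifest.variants)} SNPs), "
          f"{len(manifest.qc_failures)} QC failures, "
          f"{len(manifest.error_sites)} error-only depth sites")
    print(f"inputs written to {RUN}")


if __name__ == "__main__":
    main()
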