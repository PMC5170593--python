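"""End-to-end orchestration of the pipeline stages behind one config.

Stages communicate only via files in standard formats (FASTA, GFF3, FASTQ,
TSV, VCF), so each stage is independently testable and, in a non-synthetic
deployment, replaceable by the external tools it emulates. Rerunning with an
identical config and seed reproduces byte-identical data outputs; the run
report is the only file excluded from that contract (it records wall times).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate as ann, io as vio, kasp, readqc, simulate, summarize, varfilter

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "variome_out",
    "genome": {"n_chromosomes": 2, "chrom_length": 50_000, "n_genes": 12},
    "population": {
        "n_groups": 3,
        "accessions_per_group": 5,
        "genebank_per_group": 0,
        "n_variants": 300,
        "snp_fraction": 0.85,
    },
    "reads": {
        "depth": 2.0,
        "read_length": 100,
        "error_rate": 0.01,
        "qc_failure_rates": {
            "n_rich": 0.02,
            "low_mean_q": 0.02,
            "short_after_trim": 0.02,
            "duplicate": 0.02,
        },
    },
    "depths": {"depth": 10.0, "error_rate": 0.01, "fp_site_rate": 2e-4},
    "qc": {},
    "filter": {"maf_on_indels": False},
    "window": 10_000,
    "kasp_flank": 50,
    "inputs": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _merge(DEFAULT_CONFIG, self.raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    @property
    def simulate_inputs(self) -> bool:
        return not self.raw.get("inputs")

    def qc_thresholds(self) -> readqc.QCThresholds:
        return readqc.QCThresholds(**self.raw["qc"])

    def filter_thresholds(self) -> varfilter.FilterThresholds:
        opts = {k: v for k, v in self.raw["filter"].items() if k != "maf_on_indels"}
        return varfilter.FilterThresholds(**opts)

    def validate(self) -> None:
        self.qc_thresholds()
        self.filter_thresholds()
        if int(self.raw["window"]) <= 0:
            raise ValueError("window must be positive")
        for key, path in (self.raw.get("inputs") or {}).items():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input {key!r} missing: {path}")


def run_all(
    config: RunConfig | dict,
    outdir: str | Path | None = None,
    stop_after: str | None = None,
) -> dict:
    """Execute simulate -> readqc -> callfilter -> annotate -> summarize ->
    kasp, writing every intermediate, and return the run report.

    ``stop_after`` truncates the pipeline after the named stage.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    config.validate()
    outdir = Path(outdir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    report: dict = {"version": __version__, "seed": seed, "stages": {}}

    def finish() -> dict:
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report

    def stage(name):
        class _Timer:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                report["stages"][name] = {}
                return report["stages"][name]

            def __exit__(self_t, *exc):
                report["stages"][name]["wall_seconds"] = time.perf_counter() - self_t.t0
                return False

        return _Timer()

    # ---- simulate -------------------------------------------------------
    with stage("simulate") as rec:
        if config.simulate_inputs:
            g = config["genome"]
            p = config["population"]
            ref, genes = simulate.generate_reference(
                int(g["n_chromosomes"]), int(g["chrom_length"]), int(g["n_genes"]),
                seed=int(rng.integers(2**31)),
            )
            accessions, manifest = simulate.generate_population(
                ref,
                genes,
                int(p["n_groups"]),
                int(p["accessions_per_group"]),
                int(p["n_variants"]),
                p.get("category_mix"),
                p.get("maf_spectrum"),
                seed=int(rng.integers(2**31)),
                snp_fraction=float(p.get("snp_fraction", 0.85)),
                genebank_per_group=int(p.get("genebank_per_group", 0)),
            )
            r = config["reads"]
            d = config["depths"]
            manifest.params.update(
                {"read_depth": r["depth"], "read_error_rate": r["error_rate"],
                 "depth": d["depth"], "error_rate": d["error_rate"]}
            )
            vio.write_fasta(ref, outdir / "genome.fa")
            vio.write_gff3(genes, outdir / "genes.gff3")
            vio.write_accessions(accessions, outdir / "accessions.tsv")
            reads_dir = outdir / "reads"
            reads_dir.mkdir(exist_ok=True)
            depth_frames = []
            error_sites: set = set()
            for acc in accessions:
                pairs, failures = simulate.emit_reads(
                    acc, ref, manifest,
                    depth=float(r["depth"]), read_length=int(r["read_length"]),
                    error_rate=float(r["error_rate"]),
                    qc_failure_rates=r.get("qc_failure_rates"),
                    seed=int(rng.integers(2**31)),
                )
                manifest.qc_failures.extend(failures)
                vio.write_fastq_pair(
                    pairs,
                    reads_dir / f"{acc.accession_id}_1.fastq.gz",
                    reads_dir / f"{acc.accession_id}_2.fastq.gz",
                )
                table, injected = simulate.emit_allele_depths(
                    acc, manifest,
                    depth=float(d["depth"]), error_rate=float(d["error_rate"]),
                    seed=int(rng.integers(2**31)),
                    ref=ref, fp_site_rate=float(d["fp_site_rate"]),
                )
                depth_frames.append(table)
                error_sites.update((c, pos) for c, pos, _, _ in injected)
            manifest.error_sites = sorted(error_sites)
            depths = pd.concat(depth_frames, ignore_index=True)
            vio.write_tsv(depths, outdir / "depths.tsv")
            vio.save_manifest(manifest, outdir / "manifest")
            rec.update(
                {"chromosomes": len(ref.chromosomes), "genes": len(genes),
                 "accessions": len(accessions),
                 "planted_variants": len(manifest.variants),
                 "depth_observations": int(len(depths))}
            )
        else:
            inputs = config["inputs"]
            ref = vio.read_fasta(inputs["fasta"])
            genes = vio.read_gff3(inputs["gff3"])
            accessions = vio.read_accessions(inputs["meta"])
            depths = vio.read_tsv(inputs["depths"])
            manifest = None
            rec.update({"accessions": len(accessions),
                        "depth_observations": int(len(depths))})

    if stop_after == "simulate":
        return finish()

    # ---- read QC --------------------------------------------------------
    with stage("readqc") as rec:
        qc_reports = []
        if config.simulate_inputs:
            qc_dir = outdir / "qc"
            qc_dir.mkdir(exist_ok=True)
            t = config.qc_thresholds()
            for acc in accessions:
                rep = readqc.run_read_qc(
                    (str(outdir / "reads" / f"{acc.accession_id}_1.fastq.gz"),
                     str(outdir / "reads" / f"{acc.accession_id}_2.fastq.gz")),
                    (str(qc_dir / f"{acc.accession_id}_1.fastq.gz"),
                     str(qc_dir / f"{acc.accession_id}_2.fastq.gz")),
                    t,
                )
                row = readqc.report_frame(rep)
                row.insert(0, "accession", acc.accession_id)
                qc_reports.append(row)
            qc_table = pd.concat(qc_reports, ignore_index=True)
            vio.write_tsv(qc_table, qc_dir / "qc_report.tsv")
            rec.update(
                {"pairs_in": int(qc_table["pairs_in"].sum()),
                 "pairs_retained": int(qc_table["pairs_retained"].sum())}
            )

    if stop_after == "readqc":
        return finish()

    # ---- variant filtering ---------------------------------------------
    with stage("callfilter") as rec:
        t = config.filter_thresholds()
        matrix, stats = varfilter.run_filter_cascade(
            depths, accessions, t,
            apply_maf_to_indels=bool(config["filter"].get("maf_on_indels", False)),
        )
        var_dir = outdir / "variants"
        var_dir.mkdir(exist_ok=True)
        vio.write_matrix(matrix, var_dir / "matrix.tsv")
        contigs = {c: ref.length(c) for c in ref.chromosomes}
        vio.write_population_vcf(matrix, var_dir / "population.vcf", contigs)
        rec.update(stats)

    if stop_after == "callfilter":
        return finish()

    # ---- annotation -----------------------------------------------------
    with stage("annotate") as rec:
        variants = varfilter.matrix_variants(matrix)
        annotated = ann.annotate(variants, genes, ref)
        ann_dir = outdir / "annotation"
        ann_dir.mkdir(exist_ok=True)
        vio.write_tsv(annotated, ann_dir / "annotated.tsv")
        marginals = ann.marginal_counts(annotated)
        for vclass, series in marginals.items():
            vio.write_tsv(
                series.rename("count").to_frame().reset_index(names="category"),
                ann_dir / f"{vclass.lower()}_marginals.tsv",
            )
        categories = {
            (r.chrom, r.pos, r.ref, r.alt): r.category for r in annotated.itertuples()
        }
        vio.write_population_vcf(
            matrix, ann_dir / "annotated.vcf",
            {c: ref.length(c) for c in ref.chromosomes}, categories,
        )
        rec.update({"variants_annotated": int(len(annotated))})
        if rec["variants_annotated"] != stats["sites_retained"]:
            raise AssertionError("annotate input count != filter output count")

    if stop_after == "annotate":
        return finish()

    # ---- summaries ------------------------------------------------------
    with stage("summarize") as rec:
        sum_dir = outdir / "summary"
        sum_dir.mkdir(exist_ok=True)
        groups = summarize.count_polymorphic_by_group(matrix, annotated, accessions)
        vio.write_tsv(groups, sum_dir / "group_diversity.tsv")
        chrom_lengths = {c: ref.length(c) for c in ref.chromosomes}
        tracks = summarize.windowed_tracks(
            annotated, depths, chrom_lengths, int(config["window"]),
            config.filter_thresholds(),
        )
        vio.write_tsv(tracks, sum_dir / "window_tracks.tsv")
        overall, cds = summarize.indel_length_distribution(annotated)
        vio.write_tsv(overall.rename("count").reset_index(), sum_dir / "indel_lengths.tsv")
        vio.write_tsv(cds.rename("count").reset_index(), sum_dir / "indel_lengths_cds.tsv")
        rec.update({"groups": int(len(groups)), "windows": int(len(tracks))})

    if stop_after == "summarize":
        return finish()

    # ---- KASP selection -------------------------------------------------
    with stage("kasp") as rec:
        all_variants = varfilter.matrix_variants(matrix)
        snps = all_variants[all_variants["vclass"] == "SNP"]
        candidates = kasp.select_kasp_candidates(
            snps, ref, all_variants, int(config["kasp_flank"])
        )
        kasp_dir = outdir / "kasp"
        kasp_dir.mkdir(exist_ok=True)
        vio.write_tsv(kasp.candidates_frame(candidates), kasp_dir / "kasp_candidates.tsv")
        rec.update(
            {"snps_screened": len(candidates),
             "accepted": sum(c.status == "accepted" for c in candidates)}
        )

    return finish()
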