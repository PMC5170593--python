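"""Readers and writers for the standard formats the pipeline speaks.

FASTA via Biopython, FASTQ via pysam (gzipped or plain; Phred+33), GFF3
parsed through gffutils, tables as TSV through pandas, population genotypes
as VCF. Gzip output is written with a zeroed mtime so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .models import (
    AccessionMeta,
    GeneModel,
    PlantedVariant,
    QCFailure,
    ReadPair,
    ReferenceGenome,
    TruthManifest,
    Variant,
    genes_by_chrom,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(ref: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> ReferenceGenome:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceGenome(chroms)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features, 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, lst in genes_by_chrom(genes).items():
            for g in lst:
                lo, hi = g.span
                def line(ftype, s, e, phase, attrs):
                    fh.write(
                        f"{chrom}\tsim\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t{phase}\t{attrs}\n"
                    )
                line("gene", lo, hi, ".", f"ID={g.gene_id}")
                mrna = f"{g.gene_id}.1"
                line("mRNA", lo, hi, ".", f"ID={mrna};Parent={g.gene_id}")
                for i, (s, e) in enumerate(g.exons, 1):
                    line("exon", s, e, ".", f"ID={mrna}.exon{i};Parent={mrna}")
                cds = g.cds_intervals if g.strand == "+" else tuple(reversed(g.cds_intervals))
                done = 0
                for s, e in cds:
                    phase = (3 - done % 3) % 3
                    line("CDS", s, e, str(phase), f"ID={mrna}.cds;Parent={mrna}")
                    done += e - s + 1
                utr5, utr3 = g.utr_intervals
                for s, e in utr5:
                    line("five_prime_UTR", s, e, ".", f"ID={mrna}.utr5;Parent={mrna}")
                for s, e in utr3:
                    line("three_prime_UTR", s, e, ".", f"ID={mrna}.utr3;Parent={mrna}")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models from a GFF3 with one mRNA per gene."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) != 1:
            raise ValueError(f"{gene.id}: expected exactly one mRNA, got {len(mrnas)}")
        exons = sorted(
            (f.start, f.end) for f in db.children(mrnas[0], featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrnas[0], featuretype="CDS"))
        if not exons or not cds:
            raise ValueError(f"{gene.id}: missing exon or CDS features")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTQ (Phred+33, plain or gzipped)
# ---------------------------------------------------------------------------


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def iter_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mates; raises on id mismatch or truncation."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        it2 = iter(f2)
        for r1 in f1:
            r2 = next(it2, None)
            if r2 is None:
                raise ValueError(f"{path2}: fewer records than {path1}")
            if _strip_mate(r1.name) != _strip_mate(r2.name):
                raise ValueError(
                    f"desynchronized mates: {r1.name!r} vs {r2.name!r}"
                )
            if r1.quality is None or r2.quality is None:
                raise ValueError(f"{r1.name}: missing quality string")
            yield ReadPair(
                _strip_mate(r1.name),
                r1.sequence.upper(),
                tuple(ord(c) - 33 for c in r1.quality),
                r2.sequence.upper(),
                tuple(ord(c) - 33 for c in r2.quality),
            )
        if next(it2, None) is not None:
            raise ValueError(f"{path1}: fewer records than {path2}")


def _open_out(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        # fixed mtime and no filename: byte-identical output across runs
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return _io.TextIOWrapper(gz, encoding="ascii")
    return open(path, "w")


def write_fastq_pair(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with _open_out(path1) as o1, _open_out(path2) as o2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            o1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            o2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_accessions(meta: Iterable[AccessionMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"accession": a.accession_id, "morphotype": a.morphotype,
             "zygosity_class": a.zygosity_class}
            for a in meta
        ]
    )
    write_tsv(df, path)


def read_accessions(path: str | Path) -> list[AccessionMeta]:
    df = read_tsv(path)
    return [
        AccessionMeta(r.accession, r.morphotype, r.zygosity_class)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------


def save_manifest(manifest: TruthManifest, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vrows, grows = [], []
    for pv in manifest.variants:
        v = pv.variant
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "vclass": v.vclass, "category": pv.category,
            "signed_length": v.signed_length,
        }
        for g, f in sorted(pv.group_freqs.items()):
            row[f"freq_{g}"] = f
        vrows.append(row)
        for acc, gt in sorted(pv.genotypes.items()):
            grows.append(
                {"chrom": v.chrom, "pos": v.pos, "accession": acc, "genotype": gt}
            )
    write_tsv(pd.DataFrame(vrows), outdir / "variants.tsv")
    write_tsv(pd.DataFrame(grows), outdir / "genotypes.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {"pair_id": f.pair_id, "kind": f.kind,
                 "duplicate_of": f.duplicate_of or ""}
                for f in manifest.qc_failures
            ],
            columns=["pair_id", "kind", "duplicate_of"],
        ),
        outdir / "qc_failures.tsv",
    )
    write_tsv(
        pd.DataFrame(manifest.error_sites, columns=["chrom", "pos"]),
        outdir / "error_sites.tsv",
    )
    with open(outdir / "params.json", "w") as fh:
        json.dump(manifest.params, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(outdir: str | Path) -> TruthManifest:
    outdir = Path(outdir)
    vdf = read_tsv(outdir / "variants.tsv")
    gdf = read_tsv(outdir / "genotypes.tsv")
    geno: dict[tuple[str, int], dict[str, str]] = {}
    for r in gdf.itertuples():
        geno.setdefault((r.chrom, int(r.pos)), {})[r.accession] = r.genotype
    variants = []
    freq_cols = [c for c in vdf.columns if c.startswith("freq_")]
    for r in vdf.itertuples():
        variants.append(
            PlantedVariant(
                Variant(r.chrom, int(r.pos), r.ref, r.alt),
                r.category,
                {c[len("freq_"):]: float(getattr(r, c)) for c in freq_cols},
                geno.get((r.chrom, int(r.pos)), {}),
            )
        )
    fdf = read_tsv(outdir / "qc_failures.tsv")
    failures = [
        QCFailure(r.pair_id, r.kind, r.duplicate_of if isinstance(r.duplicate_of, str) and r.duplicate_of else None)
        for r in fdf.itertuples()
    ]
    edf = read_tsv(outdir / "error_sites.tsv")
    error_sites = [(r.chrom, int(r.pos)) for r in edf.itertuples()]
    with open(outdir / "params.json") as fh:
        params = json.load(fh)
    return TruthManifest(variants, failures, error_sites, params)


# ---------------------------------------------------------------------------
# genotype matrix / VCF
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["chrom", "pos", "ref", "alt"])


_GT = {"ref": "0/0", "alt": "1/1", "het": "0/1", "missing": "./."}
_GT_BACK = {v: k for k, v in _GT.items()}


def write_population_vcf(
    matrix: pd.DataFrame,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    categories: dict[tuple, str] | None = None,
) -> None:
    """Population VCF: one row per variant, one sample column per accession.

    ``categories`` optionally maps (chrom,pos,ref,alt) to an effect category
    written as an EFF INFO field.
    """
    samples = list(matrix.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, l in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect category">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for key, row in matrix.iterrows():
            chrom, pos, ref, alt = key
            info = f"EFF={categories[key]}" if categories and key in categories else "."
            gts = "\t".join(_GT[row[s]] for s in samples)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_population_vcf(path: str | Path) -> pd.DataFrame:
    """Read a population VCF (as written above) back into a genotype matrix."""
    rows = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, _, ref, alt = fields[:5]
            gts = [_GT_BACK.get(g.split(":")[0], "missing") for g in fields[9:]]
            rows.append([chrom, int(pos), ref, alt, *gts])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *samples])
    return df.set_index(["chrom", "pos", "ref", "alt"])
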