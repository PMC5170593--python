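"""Functional annotation of variants against one-transcript gene models.

Every variant receives exactly one category:

* SNPs: nonSyn / Syn / splice / intron / UTR5 / UTR3 / intergenic
* InDels: frameshift / nonframeshift / splice / intron / UTR5 / UTR3 / intergenic

"Functional" variants are nonsynonymous or splice-window SNPs, and coding or
splice-window InDels — the variants that alter protein sequences. The splice
category covers intronic positions within 8 bp of an exon-intron junction;
coding positions that also sit near a junction stay coding (splice is a
subdivision of introns). Stop gain/loss is folded into nonSyn. Coding InDels
are frameshift unless their length is a multiple of three.

InDels are classified at their leftmost affected base: the first deleted base
for deletions, the anchor base for insertions. Variants are expected to be
left-aligned and anchored VCF-style.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .models import (
    FUNCTIONAL_INDEL,
    FUNCTIONAL_SNP,
    INDEL_CATEGORIES,
    SNP_CATEGORIES,
    SPLICE_WINDOW,
    GeneModel,
    ReferenceGenome,
    Variant,
    complement,
    genes_by_chrom,
)

# standard genetic code, stops as '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class GeneIndex:
    """Per-chromosome lookup of the gene model covering a position.

    Gene transcript spans are assumed non-overlapping (the simulator
    guarantees this; real annotations with overlapping genes resolve to the
    first covering gene by start coordinate).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom = genes_by_chrom(genes)
        self._starts = {
            chrom: [g.span[0] for g in lst] for chrom, lst in self._by_chrom.items()
        }

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        lst = self._by_chrom.get(chrom)
        if not lst:
            return None
        i = bisect_right(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        g = lst[i]
        return g if g.span[0] <= pos <= g.span[1] else None

    def genes(self) -> list[GeneModel]:
        return [g for lst in self._by_chrom.values() for g in lst]


def affected_position(variant: Variant) -> int:
    """Leftmost affected genomic base used to place a variant in a region."""
    if variant.vclass == "SNP":
        return variant.pos
    if len(variant.ref) > len(variant.alt):  # deletion: first deleted base
        return variant.pos + 1
    return variant.pos  # insertion: anchor base


def locate(
    variant: Variant,
    index: GeneIndex,
    ref: ReferenceGenome | None = None,
    splice_window: int = SPLICE_WINDOW,
) -> tuple[str | None, str]:
    """Resolve (gene id or None, region) for a variant.

    Region is one of CDS / splice / intron / UTR5 / UTR3 / intergenic.
    """
    if ref is not None and variant.chrom not in ref:
        raise KeyError(f"unknown chromosome {variant.chrom!r}")
    pos = affected_position(variant)
    gene = index.gene_at(variant.chrom, pos)
    if gene is None:
        return None, "intergenic"
    region = gene.region_of(pos, splice_window)
    if region is None:  # pragma: no cover - span check already done
        return None, "intergenic"
    return gene.gene_id, region


def classify_snp_cds(snp: Variant, gene: GeneModel, ref: ReferenceGenome) -> str:
    """Syn/nonSyn call for a coding SNP by translating the affected codon.

    The codon is built in transcript orientation (reverse complement on the
    minus strand); any amino-acid change, including stop gain/loss, is nonSyn.
    """
    genome_base = ref.base(snp.chrom, snp.pos)
    if genome_base != snp.ref:
        raise ValueError(
            f"reference allele mismatch at {snp.chrom}:{snp.pos}: "
            f"variant says {snp.ref!r}, genome has {genome_base!r}"
        )
    idx = gene.cds_index.get(snp.pos)
    if idx is None:
        raise ValueError(f"{snp.chrom}:{snp.pos} is not a CDS position of {gene.gene_id}")
    codon_start = (idx // 3) * 3
    codon_positions = gene.cds_genomic_positions[codon_start : codon_start + 3]
    if gene.strand == "+":
        bases = [ref.base(gene.chrom, p) for p in codon_positions]
        alt_base = snp.alt
    else:
        bases = [complement(ref.base(gene.chrom, p)) for p in codon_positions]
        alt_base = complement(snp.alt)
    offset = idx - codon_start
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    return "Syn" if CODON_TABLE[ref_codon] == CODON_TABLE[alt_codon] else "nonSyn"


def classify_indel_cds(indel: Variant) -> str:
    """Coding InDels shift the reading frame unless their length is 3n."""
    length = abs(indel.signed_length)
    if length == 0:
        raise ValueError(f"{indel.chrom}:{indel.pos} has length 0 — not an InDel")
    return "nonframeshift" if length % 3 == 0 else "frameshift"


def annotate_variant(
    variant: Variant,
    index: GeneIndex,
    ref: ReferenceGenome,
    splice_window: int = SPLICE_WINDOW,
) -> tuple[str | None, str]:
    """(gene id or None, category) for one variant."""
    gene_id, region = locate(variant, index, ref, splice_window)
    if region != "CDS":
        return gene_id, region
    gene = index.gene_at(variant.chrom, affected_position(variant))
    assert gene is not None
    if variant.vclass == "SNP":
        return gene_id, classify_snp_cds(variant, gene, ref)
    return gene_id, classify_indel_cds(variant)


def is_functional(vclass: str, category: str) -> bool:
    if vclass == "SNP":
        return category in FUNCTIONAL_SNP
    return category in FUNCTIONAL_INDEL


def annotate(
    variants: Sequence[Variant] | pd.DataFrame,
    genes: Iterable[GeneModel] | GeneIndex,
    ref: ReferenceGenome,
    splice_window: int = SPLICE_WINDOW,
) -> pd.DataFrame:
    """Annotate a variant set; one row per variant.

    ``variants`` may be a sequence of :class:`Variant` or a DataFrame with
    chrom/pos/ref/alt columns. Returns columns chrom, pos, ref, alt, vclass,
    gene_id, category, functional.
    """
    if isinstance(variants, pd.DataFrame):
        variant_objs = [
            Variant(r.chrom, int(r.pos), r.ref, r.alt) for r in variants.itertuples()
        ]
    else:
        variant_objs = list(variants)
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rows = []
    for v in variant_objs:
        gene_id, category = annotate_variant(v, index, ref, splice_window)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "gene_id": gene_id,
                "category": category,
                "functional": is_functional(v.vclass, category),
            }
        )
    columns = ["chrom", "pos", "ref", "alt", "vclass", "gene_id", "category", "functional"]
    return pd.DataFrame(rows, columns=columns)


def marginal_counts(annotated: pd.DataFrame) -> dict[str, pd.Series]:
    """Category marginals per variant class, in the published column order.

    The partition identity holds by construction: each class's counts sum to
    its total.
    """
    out: dict[str, pd.Series] = {}
    for vclass, cats in (("SNP", SNP_CATEGORIES), ("InDel", INDEL_CATEGORIES)):
        sub = annotated[annotated["vclass"] == vclass]
        counts = sub["category"].value_counts()
        series = pd.Series([int(counts.get(c, 0)) for c in cats], index=list(cats))
        series["total"] = int(series.sum())
        out[vclass] = series
    return out


def functional_counts(annotated: pd.DataFrame) -> dict[str, int]:
    """Counts of protein-changing variants per class."""
    snp = annotated[(annotated["vclass"] == "SNP") & annotated["functional"]]
    indel = annotated[(annotated["vclass"] == "InDel") & annotated["functional"]]
    return {"SNP": len(snp), "InDel": len(indel)}
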