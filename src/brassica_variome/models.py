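"""Core domain types shared across the pipeline stages.

Coordinates are 1-based and intervals are closed, matching GFF3. Variants use
the VCF convention: SNPs have single-base ref/alt; InDels carry one anchor
base (e.g. ref="AT", alt="A" is a 1 bp deletion at the base after `pos`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: intronic bases within this distance of an exon-intron junction are
#: classified as splice-site positions
SPLICE_WINDOW = 8

SNP_CATEGORIES = ("nonSyn", "Syn", "splice", "intron", "UTR5", "UTR3", "intergenic")
INDEL_CATEGORIES = (
    "frameshift",
    "nonframeshift",
    "splice",
    "intron",
    "UTR5",
    "UTR3",
    "intergenic",
)
FUNCTIONAL_SNP = frozenset({"nonSyn", "splice"})
FUNCTIONAL_INDEL = frozenset({"frameshift", "nonframeshift", "splice"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class PackingError(ValueError):
    """Gene models cannot be placed on the requested chromosome."""


class CategoryError(ValueError):
    """A requested variant category has no eligible genomic position."""


@dataclass
class ReferenceGenome:
    """Named chromosome sequences over the alphabet {A,C,G,T}."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"chromosome {name!r} contains invalid characters {bad}")

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based closed."""
        if start < 1 or end > len(self.chromosomes[chrom]):
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return self.chromosomes[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class GeneModel:
    """One representative transcript: strand, exons and the CDS span.

    UTRs and introns are derived from the exon set and the CDS span.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) reversed")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.gene_id}: CDS span reversed")
        for endpoint in (self.cds_start, self.cds_end):
            if not any(s <= endpoint <= e for s, e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS endpoint {endpoint} not exonic")

    @cached_property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @cached_property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @cached_property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return tuple(out)

    @cached_property
    def utr_intervals(self) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
        """(UTR5 intervals, UTR3 intervals) in genomic coordinates."""
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start - 1)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end + 1), e))
        if self.strand == "+":
            return tuple(left), tuple(right)
        return tuple(right), tuple(left)

    def region_of(self, pos: int, splice_window: int = SPLICE_WINDOW) -> str | None:
        """Region of a genomic position inside this gene.

        Returns one of CDS/splice/intron/UTR5/UTR3, or None if the position
        lies outside the transcript span. CDS takes precedence over the splice
        window (the splice category is a subdivision of introns only).
        """
        lo, hi = self.span
        if pos < lo or pos > hi:
            return None
        if self.cds_start <= pos <= self.cds_end and any(
            s <= pos <= e for s, e in self.cds_intervals
        ):
            return "CDS"
        if any(s <= pos <= e for s, e in self.exons):
            # exonic but outside the CDS: untranslated region
            if self.strand == "+":
                return "UTR5" if pos < self.cds_start else "UTR3"
            return "UTR3" if pos < self.cds_start else "UTR5"
        for s, e in self.introns:
            if s <= pos <= e:
                if pos <= s + splice_window - 1 or pos >= e - splice_window + 1:
                    return "splice"
                return "intron"
        return None  # pragma: no cover - exon/intron tiling is exhaustive

    @cached_property
    def cds_genomic_positions(self) -> tuple[int, ...]:
        """Genomic positions of the spliced CDS in transcript (5'→3') order."""
        positions: list[int] = []
        for s, e in self.cds_intervals:
            positions.extend(range(s, e + 1))
        if self.strand == "-":
            positions.reverse()
        return tuple(positions)

    @cached_property
    def cds_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.cds_genomic_positions)}

    def cds_sequence(self, ref: ReferenceGenome) -> str:
        """Spliced CDS in transcript orientation."""
        chunks = [ref.fetch(self.chrom, s, e) for s, e in self.cds_intervals]
        seq = "".join(chunks)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class AccessionMeta:
    """One resequenced line: id, morphotype group and zygosity class."""

    accession_id: str
    morphotype: str
    zygosity_class: str  # "homozygous_line" or "genebank"

    def __post_init__(self) -> None:
        if self.zygosity_class not in ("homozygous_line", "genebank"):
            raise ValueError(f"unknown zygosity_class {self.zygosity_class!r}")


@dataclass(frozen=True)
class Variant:
    """A normalized, anchored variant (VCF-style, 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def signed_length(self) -> int:
        """Insertion lengths positive, deletion lengths negative, SNP zero."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PlantedVariant:
    """A simulated variant plus its ground truth."""

    variant: Variant
    category: str
    group_freqs: dict[str, float]
    genotypes: dict[str, str]  # accession id -> ref | alt | het

    def population_alt_freq(self) -> float:
        """Allele-count alt frequency; a het accession contributes half a vote."""
        votes = {"ref": 0.0, "alt": 1.0, "het": 0.5}
        n = len(self.genotypes)
        return sum(votes[g] for g in self.genotypes.values()) / n if n else 0.0

    def population_maf(self) -> float:
        p = self.population_alt_freq()
        return min(p, 1.0 - p)


@dataclass
class QCFailure:
    """A read pair planted to fail exactly one QC rule."""

    pair_id: str
    kind: str  # n_rich | low_mean_q | short_after_trim | duplicate
    duplicate_of: str | None = None


@dataclass
class TruthManifest:
    """Ground truth for a simulated study: the acceptance oracle."""

    variants: list[PlantedVariant] = field(default_factory=list)
    qc_failures: list[QCFailure] = field(default_factory=list)
    error_sites: list[tuple[str, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(pv.variant.chrom, pv.variant.pos) for pv in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError("planted variant positions are not unique")

    def variant_keys(self) -> set[tuple[str, int, str, str]]:
        return {pv.variant.key for pv in self.variants}

    def failed_pair_ids(self) -> set[str]:
        return {f.pair_id for f in self.qc_failures}


@dataclass
class ReadPair:
    """A paired-end read: sequences over {A,C,G,T,N} with Phred qualities."""

    pair_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.pair_id}: sequence/quality length mismatch")

    @property
    def mates(self) -> tuple[tuple[str, tuple[int, ...]], ...]:
        return ((self.seq1, self.qual1), (self.seq2, self.qual2))


def genes_by_chrom(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    """Group gene models by chromosome, sorted by transcript start."""
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: g.span[0])
    return out
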