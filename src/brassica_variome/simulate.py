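"""Synthetic resequencing study generator with a ground-truth manifest.

Emulates the shape of a crop-resequencing experiment: a small multi-chromosome
genome carrying one-transcript gene models (UTRs, introns, spliced CDS), a
population of morphotype groups of mostly homozygous accessions with planted
SNPs/InDels of known functional category and group frequency, paired-end reads
at a chosen fold-coverage with base-call errors and planted QC failures, and
per-accession allele-depth tables (the information an external aligner+caller
would hand to the variant filters).

Every operation is deterministic for a fixed seed. Planted variants are
validated against the effect annotator at planting time, so the manifest's
true categories agree with re-annotation by construction.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import annotate as ann
from .models import (
    INDEL_CATEGORIES,
    SNP_CATEGORIES,
    SPLICE_WINDOW,
    AccessionMeta,
    CategoryError,
    GeneModel,
    PackingError,
    PlantedVariant,
    QCFailure,
    ReadPair,
    ReferenceGenome,
    TruthManifest,
    Variant,
    revcomp,
)

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

#: default mix of planted variant categories (per variant class). The toy
#: genome is far more gene-dense than a real crop genome, so genic categories
#: are weighted up relative to the published genome-wide proportions; every
#: category gets enough mass to be exercised.
DEFAULT_CATEGORY_MIX: dict[str, dict[str, float]] = {
    "SNP": {
        "nonSyn": 0.15,
        "Syn": 0.15,
        "splice": 0.05,
        "intron": 0.20,
        "UTR5": 0.10,
        "UTR3": 0.10,
        "intergenic": 0.25,
    },
    "InDel": {
        "frameshift": 0.10,
        "nonframeshift": 0.15,
        "splice": 0.05,
        "intron": 0.20,
        "UTR5": 0.10,
        "UTR3": 0.10,
        "intergenic": 0.30,
    },
}

#: default per-group alternative-allele frequency spectrum
DEFAULT_MAF_SPECTRUM = {"kind": "uniform", "low": 0.05, "high": 0.95}

_FRAMESHIFT_LENGTHS = [l for l in range(1, 11) if l % 3 != 0]
_NONFRAMESHIFT_LENGTHS = [3, 6, 9]
_ALL_INDEL_LENGTHS = list(range(1, 11))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _largest_remainder(total: int, weights: dict[str, float]) -> dict[str, int]:
    """Integer allocation of `total` across categories, preserving the sum."""
    raw = {k: total * w for k, w in weights.items()}
    alloc = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = total - sum(alloc.values())
    order = sorted(raw, key=lambda k: (raw[k] - alloc[k], k), reverse=True)
    for k in order[:remainder]:
        alloc[k] += 1
    return alloc


# ---------------------------------------------------------------------------
# reference genome and gene models
# ---------------------------------------------------------------------------


def _build_gene(rng: np.random.Generator) -> dict:
    """One gene in transcript orientation, then optionally strand-flipped.

    Returns the gene-local genomic sequence plus 0-based local exon intervals
    and CDS endpoints. Guarantees: >=2 exons, introns >= 20 bp, non-empty
    UTRs, CDS = ATG + non-stop codons + stop.
    """
    utr5_len = int(rng.integers(20, 61))
    utr3_len = int(rng.integers(20, 61))
    n_codons = int(rng.integers(40, 121))
    cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2)) + str(
        rng.choice(("TAA", "TAG", "TGA"))
    )
    transcript = _random_seq(rng, utr5_len) + cds + _random_seq(rng, utr3_len)
    tlen = len(transcript)

    n_exons = int(rng.integers(2, 5))
    min_exon = 10
    while True:
        cuts = np.sort(rng.choice(np.arange(min_exon, tlen - min_exon + 1),
                                  size=n_exons - 1, replace=False))
        if n_exons == 2 or np.all(np.diff(cuts) >= min_exon):
            break
    bounds = [0, *cuts.tolist(), tlen]
    t_exons = [(bounds[i], bounds[i + 1] - 1) for i in range(n_exons)]
    intron_lens = [int(rng.integers(30, 81)) for _ in range(n_exons - 1)]

    # genomic layout in transcript orientation
    offset = 0
    g_exons: list[tuple[int, int]] = []
    pieces: list[str] = []
    t2g_offsets: list[int] = []
    for i, (a, b) in enumerate(t_exons):
        g_exons.append((a + offset, b + offset))
        t2g_offsets.append(offset)
        pieces.append(transcript[a : b + 1])
        if i < n_exons - 1:
            pieces.append(_random_seq(rng, intron_lens[i]))
            offset += intron_lens[i]
    seq = "".join(pieces)
    glen = len(seq)

    def t2g(tpos: int) -> int:
        for (a, b), off in zip(t_exons, t2g_offsets):
            if a <= tpos <= b:
                return tpos + off
        raise AssertionError("transcript position outside exons")

    cds_lo = t2g(utr5_len)
    cds_hi = t2g(utr5_len + len(cds) - 1)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
        g_exons = [(glen - 1 - b, glen - 1 - a) for a, b in reversed(g_exons)]
        cds_lo, cds_hi = glen - 1 - cds_hi, glen - 1 - cds_lo
    return {
        "seq": seq,
        "exons": g_exons,
        "cds_lo": cds_lo,
        "cds_hi": cds_hi,
        "strand": strand,
    }


def generate_reference(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    *,
    min_gap: int = 150,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome with non-overlapping gene models.

    Genes are distributed across chromosomes as evenly as possible and placed
    with at least ``min_gap`` bp of intergenic sequence around each gene.
    Raises :class:`PackingError` when the requested genes do not fit.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000 bp")
    if n_chromosomes < 1 or n_genes < 0:
        raise ValueError("need >= 1 chromosome and >= 0 genes")
    rng = np.random.default_rng(seed)

    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1

    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_serial = 1
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1:02d}"
        built = [_build_gene(rng) for _ in range(per_chrom[ci])]
        total_gene_len = sum(len(b["seq"]) for b in built)
        n_gaps = len(built) + 1
        slack = chrom_length - total_gene_len - n_gaps * min_gap
        if slack < 0:
            raise PackingError(
                f"{chrom}: {per_chrom[ci]} genes need "
                f"{total_gene_len + n_gaps * min_gap} bp but chrom_length is "
                f"{chrom_length} bp (gene length + {min_gap} bp minimum gaps)"
            )
        extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
        gaps = [min_gap + int(e) for e in extra]

        pieces = []
        cursor = 0
        for gi, b in enumerate(built):
            pieces.append(_random_seq(rng, gaps[gi]))
            cursor += gaps[gi]
            offset = cursor  # 0-based start of the gene block
            exons = tuple(
                (offset + a + 1, offset + b_ + 1) for a, b_ in b["exons"]
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_serial:04d}",
                    chrom=chrom,
                    strand=b["strand"],
                    exons=exons,
                    cds_start=offset + b["cds_lo"] + 1,
                    cds_end=offset + b["cds_hi"] + 1,
                )
            )
            gene_serial += 1
            pieces.append(b["seq"])
            cursor += len(b["seq"])
        pieces.append(_random_seq(rng, gaps[-1]))
        chromosomes[chrom] = "".join(pieces)
        assert len(chromosomes[chrom]) == chrom_length
    return ReferenceGenome(chromosomes), genes


# ---------------------------------------------------------------------------
# population and planted variants
# ---------------------------------------------------------------------------


def _draw_freq(rng: np.random.Generator, spectrum: dict) -> float:
    kind = spectrum.get("kind", "uniform")
    if kind == "fixed":
        return float(spectrum["value"])
    if kind == "uniform":
        return float(rng.uniform(spectrum.get("low", 0.05), spectrum.get("high", 0.95)))
    if kind == "beta":
        return float(rng.beta(spectrum["a"], spectrum["b"]))
    raise ValueError(f"unknown maf_spectrum kind {kind!r}")


class _PositionPools:
    """Eligible genomic positions per category, derived from the gene models."""

    def __init__(self, ref: ReferenceGenome, genes: Sequence[GeneModel]):
        self.cds: list[tuple[GeneModel, int]] = []
        self.splice: list[tuple[GeneModel, int]] = []
        self.intron: list[tuple[GeneModel, int]] = []
        self.utr5: list[tuple[GeneModel, int]] = []
        self.utr3: list[tuple[GeneModel, int]] = []
        for g in genes:
            for s, e in g.cds_intervals:
                self.cds.extend((g, p) for p in range(s, e + 1))
            for s, e in g.introns:
                w = SPLICE_WINDOW
                self.splice.extend((g, p) for p in range(s, s + w))
                self.splice.extend((g, p) for p in range(e - w + 1, e + 1))
                self.intron.extend((g, p) for p in range(s + w, e - w + 1))
            u5, u3 = g.utr_intervals
            for s, e in u5:
                self.utr5.extend((g, p) for p in range(s, e + 1))
            for s, e in u3:
                self.utr3.extend((g, p) for p in range(s, e + 1))
        # intergenic gaps per chromosome (1-based closed intervals)
        self.intergenic: list[tuple[str, int, int]] = []
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ref.chromosomes}
        for g in genes:
            spans[g.chrom].append(g.span)
        for chrom, lst in spans.items():
            lst.sort()
            cursor = 1
            for s, e in lst:
                if s > cursor:
                    self.intergenic.append((chrom, cursor, s - 1))
                cursor = e + 1
            if cursor <= ref.length(chrom):
                self.intergenic.append((chrom, cursor, ref.length(chrom)))

    def snp_pool(self, category: str) -> list:
        return {
            "nonSyn": self.cds,
            "Syn": self.cds,
            "frameshift": self.cds,
            "nonframeshift": self.cds,
            "splice": self.splice,
            "intron": self.intron,
            "UTR5": self.utr5,
            "UTR3": self.utr3,
        }.get(category, [])

    def containing_interval(self, category: str, gene: GeneModel | None, pos: int):
        """Feature interval containing `pos` for span-fit checks."""
        if category == "intergenic":
            for chrom, s, e in self.intergenic:
                if gene is None and s <= pos <= e:
                    return (s, e)
            return None
        assert gene is not None
        if category in ("frameshift", "nonframeshift", "nonSyn", "Syn"):
            intervals = gene.cds_intervals
        elif category in ("splice", "intron"):
            # confine the whole span to one side of the splice-window
            # boundary so the category is independent of which span end
            # anchors the classification (strand-mirror invariance)
            w = SPLICE_WINDOW
            for s, e in gene.introns:
                if s <= pos <= e:
                    if category == "splice":
                        if pos <= s + w - 1:
                            return (s, s + w - 1)
                        if pos >= e - w + 1:
                            return (e - w + 1, e)
                        return None
                    lo, hi = s + w, e - w
                    return (lo, hi) if lo <= pos <= hi else None
            return None
        elif category == "UTR5":
            intervals = gene.utr_intervals[0]
        else:
            intervals = gene.utr_intervals[1]
        for s, e in intervals:
            if s <= pos <= e:
                return (s, e)
        return None


class _Blocked:
    """Per-chromosome occupied positions, enforcing a spacing margin."""

    def __init__(self, margin: int):
        self.margin = margin
        self._taken: dict[str, set[int]] = {}

    def free(self, chrom: str, lo: int, hi: int) -> bool:
        taken = self._taken.get(chrom, set())
        return not any(p in taken for p in range(lo - self.margin, hi + self.margin + 1))

    def take(self, chrom: str, lo: int, hi: int) -> None:
        self._taken.setdefault(chrom, set()).update(range(lo, hi + 1))


def _validate_mix(category_mix: dict[str, dict[str, float]]) -> None:
    for vclass, cats in (("SNP", SNP_CATEGORIES), ("InDel", INDEL_CATEGORIES)):
        mix = category_mix[vclass]
        unknown = set(mix) - set(cats)
        if unknown:
            raise ValueError(f"unknown {vclass} categories {sorted(unknown)}")
        if abs(sum(mix.values()) - 1.0) > 1e-6:
            raise ValueError(f"{vclass} category_mix must sum to 1")


def _plant_snp(
    rng: np.random.Generator,
    category: str,
    pools: _PositionPools,
    index: ann.GeneIndex,
    ref: ReferenceGenome,
    blocked: _Blocked,
    max_attempts: int = 500,
) -> Variant:
    if category == "intergenic":
        candidates = pools.intergenic
    else:
        candidates = pools.snp_pool(category)
    if not candidates:
        raise CategoryError(f"no eligible genomic positions for SNP category {category!r}")
    for _ in range(max_attempts):
        if category == "intergenic":
            chrom, s, e = candidates[rng.integers(len(candidates))]
            pos = int(rng.integers(s, e + 1))
        else:
            gene, pos = candidates[rng.integers(len(candidates))]
            chrom = gene.chrom
        if not blocked.free(chrom, pos, pos):
            continue
        refbase = ref.base(chrom, pos)
        alts = [b for b in "ACGT" if b != refbase]
        rng.shuffle(alts)
        for alt in alts:
            v = Variant(chrom, pos, refbase, alt)
            _, got = ann.annotate_variant(v, index, ref)
            if got == category:
                blocked.take(chrom, pos, pos)
                return v
            if category not in ("nonSyn", "Syn"):
                break  # region mismatch cannot be fixed by another alt allele
    raise CategoryError(
        f"could not place a SNP of category {category!r} after {max_attempts} attempts"
    )


def _plant_indel(
    rng: np.random.Generator,
    category: str,
    pools: _PositionPools,
    index: ann.GeneIndex,
    ref: ReferenceGenome,
    blocked: _Blocked,
    max_attempts: int = 500,
) -> Variant:
    if category == "frameshift":
        lengths = _FRAMESHIFT_LENGTHS
    elif category == "nonframeshift":
        lengths = _NONFRAMESHIFT_LENGTHS
    else:
        lengths = _ALL_INDEL_LENGTHS
    if category == "intergenic":
        candidates = pools.intergenic
    else:
        candidates = pools.snp_pool(category)
    if not candidates:
        raise CategoryError(f"no eligible genomic positions for InDel category {category!r}")
    for _ in range(max_attempts):
        if category == "intergenic":
            chrom, s, e = candidates[rng.integers(len(candidates))]
            left = int(rng.integers(s, e + 1))
            gene = None
        else:
            gene, left = candidates[rng.integers(len(candidates))]
            chrom = gene.chrom
        length = int(rng.choice(lengths))
        is_deletion = bool(rng.random() < 0.5)
        interval = pools.containing_interval(category, gene, left)
        if interval is None:
            continue
        ilo, ihi = interval
        if is_deletion:
            right = left + length - 1
            if right > ihi or left - 1 < 1:
                continue
            if ref.base(chrom, left - 1) == ref.base(chrom, right):
                continue  # not left-aligned: representation could shift left
            if not blocked.free(chrom, left - 1, right):
                continue
            anchor = ref.base(chrom, left - 1)
            v = Variant(chrom, left - 1, anchor + ref.fetch(chrom, left, right), anchor)
            span = (left - 1, right)
        else:
            if left + 1 > ihi:
                continue
            if not blocked.free(chrom, left, left + 1):
                continue
            anchor = ref.base(chrom, left)
            ins = _random_seq(rng, length)
            if ins[-1] == anchor:
                continue  # not left-aligned
            v = Variant(chrom, left, anchor, anchor + ins)
            span = (left, left + 1)
        _, got = ann.annotate_variant(v, index, ref)
        if got != category:
            continue
        blocked.take(chrom, *span)
        return v
    raise CategoryError(
        f"could not place an InDel of category {category!r} after {max_attempts} attempts"
    )


def generate_population(
    ref: ReferenceGenome,
    genes: Sequence[GeneModel],
    n_groups: int,
    accessions_per_group: int,
    n_variants: int,
    category_mix: dict[str, dict[str, float]] | None = None,
    maf_spectrum: dict | None = None,
    seed: int = 0,
    *,
    snp_fraction: float = 0.85,
    genebank_per_group: int = 0,
    min_spacing: int = 3,
) -> tuple[list[AccessionMeta], TruthManifest]:
    """Plant variants with known categories and per-group frequencies.

    Each morphotype group gets ``accessions_per_group`` accessions, the last
    ``genebank_per_group`` of which are (potentially heterozygous) genebank
    material; the rest are homozygous lines and always receive homozygous
    genotypes. Variant positions are validated against the effect annotator at
    planting time; each variant's affected span is blocked with a
    ``min_spacing`` bp margin so variants (and in particular InDels) never
    overlap or abut.
    """
    if accessions_per_group < 1:
        raise ValueError("accessions_per_group must be >= 1")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if genebank_per_group > accessions_per_group:
        raise ValueError("genebank_per_group exceeds accessions_per_group")
    category_mix = category_mix or DEFAULT_CATEGORY_MIX
    _validate_mix(category_mix)
    maf_spectrum = maf_spectrum or DEFAULT_MAF_SPECTRUM
    rng = np.random.default_rng(seed)

    accessions: list[AccessionMeta] = []
    groups = [f"morph{g + 1:02d}" for g in range(n_groups)]
    for group in groups:
        for j in range(accessions_per_group):
            zyg = (
                "genebank"
                if j >= accessions_per_group - genebank_per_group
                else "homozygous_line"
            )
            accessions.append(AccessionMeta(f"{group}_a{j + 1:02d}", group, zyg))

    n_snp = int(round(n_variants * snp_fraction))
    counts = {
        "SNP": _largest_remainder(n_snp, category_mix["SNP"]),
        "InDel": _largest_remainder(n_variants - n_snp, category_mix["InDel"]),
    }

    index = ann.GeneIndex(genes)
    pools = _PositionPools(ref, list(genes))
    blocked = _Blocked(min_spacing)
    planted: list[PlantedVariant] = []
    for vclass, planter in (("SNP", _plant_snp), ("InDel", _plant_indel)):
        for category, n in counts[vclass].items():
            for _ in range(n):
                v = planter(rng, category, pools, index, ref, blocked)
                freqs = {g: _draw_freq(rng, maf_spectrum) for g in groups}
                genotypes: dict[str, str] = {}
                for acc in accessions:
                    f = freqs[acc.morphotype]
                    if acc.zygosity_class == "homozygous_line":
                        genotypes[acc.accession_id] = "alt" if rng.random() < f else "ref"
                    else:
                        dose = int(rng.random() < f) + int(rng.random() < f)
                        genotypes[acc.accession_id] = ("ref", "het", "alt")[dose]
                planted.append(PlantedVariant(v, category, freqs, genotypes))
    planted.sort(key=lambda pv: (pv.variant.chrom, pv.variant.pos))
    manifest = TruthManifest(
        variants=planted,
        params={
            "seed": int(seed),
            "n_groups": n_groups,
            "accessions_per_group": accessions_per_group,
            "genebank_per_group": genebank_per_group,
            "n_variants": n_variants,
            "snp_fraction": snp_fraction,
            "maf_spectrum": dict(maf_spectrum),
        },
    )
    return accessions, manifest


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def build_haplotype(ref: ReferenceGenome, truth: TruthManifest, accession_id: str) -> dict[str, str]:
    """Reference with this accession's homozygous-alt variants applied.

    Heterozygous (genebank) genotypes are left as reference here: the read
    stream is the substrate of read QC, which never inspects genotypes.
    """
    haplotypes = {c: s for c, s in ref.chromosomes.items()}
    per_chrom: dict[str, list[PlantedVariant]] = {}
    for pv in truth.variants:
        if pv.genotypes.get(accession_id) == "alt":
            per_chrom.setdefault(pv.variant.chrom, []).append(pv)
    for chrom, pvs in per_chrom.items():
        seq = haplotypes[chrom]
        for pv in sorted(pvs, key=lambda p: -p.variant.pos):
            v = pv.variant
            assert seq[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref
            seq = seq[: v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref) :]
        haplotypes[chrom] = seq
    return haplotypes


def _read_from(
    rng: np.random.Generator, fragment: str, error_rate: float
) -> tuple[str, tuple[int, ...]]:
    """Simulate base calls over a template: high qualities, occasional errors
    with correspondingly lowered quality."""
    n = len(fragment)
    quals = rng.integers(30, 42, size=n)
    seq = list(fragment)
    if error_rate > 0:
        errs = np.flatnonzero(rng.random(n) < error_rate)
        for i in errs:
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            quals[i] = rng.integers(15, 26)
    return "".join(seq), tuple(int(q) for q in quals)


def emit_reads(
    accession: AccessionMeta,
    ref: ReferenceGenome,
    truth: TruthManifest,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.01,
    qc_failure_rates: dict[str, float] | None = None,
    seed: int = 0,
    *,
    insert_size: int = 350,
    min_mean_quality: float = 20.0,
    min_length_after_trim: int = 40,
) -> tuple[list[ReadPair], list[QCFailure]]:
    """Paired-end reads from the accession's haplotype, plus planted failures.

    ``qc_failure_rates`` maps failure kinds (n_rich, low_mean_q,
    short_after_trim, duplicate) to per-pair probabilities; at most one kind
    is planted per pair, and clean pairs are guaranteed to pass the QC rules
    (distinct fragment starts, no Ns, qualities >= 15 with mean >> 20).
    """
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rates = dict(qc_failure_rates or {})
    unknown = set(rates) - {"n_rich", "low_mean_q", "short_after_trim", "duplicate"}
    if unknown:
        raise ValueError(f"unknown QC failure kinds {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    haplotypes = build_haplotype(ref, truth, accession.accession_id)
    if read_length > min(len(s) for s in haplotypes.values()):
        raise ValueError("read_length exceeds chromosome length")
    total = sum(len(s) for s in haplotypes.values())
    n_pairs = int(round(depth * total / (2 * read_length)))
    per_chrom = _largest_remainder(
        n_pairs, {c: len(s) / total for c, s in haplotypes.items()}
    )

    # distinct fragment starts per chromosome: clean pairs can never be
    # accidental duplicates of one another
    fragments: list[tuple[str, int, int]] = []
    for chrom, k in per_chrom.items():
        clen = len(haplotypes[chrom])
        flen = min(insert_size, clen)
        n_starts = clen - flen + 1
        k = min(k, n_starts)
        starts = rng.choice(n_starts, size=k, replace=False)
        fragments.extend((chrom, int(s), flen) for s in starts)

    kinds = ["n_rich", "low_mean_q", "short_after_trim", "duplicate"]
    pairs: list[ReadPair] = []
    failures: list[QCFailure] = []
    clean_pairs: list[ReadPair] = []
    serial = 0
    for chrom, start, flen in fragments:
        serial += 1
        pair_id = f"{accession.accession_id}:p{serial:06d}"
        u = rng.random()
        kind = None
        acc_p = 0.0
        for k_ in kinds:
            acc_p += rates.get(k_, 0.0)
            if u < acc_p:
                kind = k_
                break

        if kind == "duplicate" and clean_pairs:
            src = clean_pairs[rng.integers(len(clean_pairs))]
            pairs.append(ReadPair(pair_id, src.seq1, src.qual1, src.seq2, src.qual2))
            failures.append(QCFailure(pair_id, "duplicate", duplicate_of=src.pair_id))
            continue
        if kind == "duplicate":
            kind = None  # no source yet; emit a clean pair instead

        frag = haplotypes[chrom][start : start + flen]
        seq1, qual1 = _read_from(rng, frag[:read_length], error_rate)
        seq2, qual2 = _read_from(rng, revcomp(frag[-read_length:]), error_rate)
        mates = [[seq1, list(qual1)], [seq2, list(qual2)]]

        if kind == "n_rich":
            m = int(rng.integers(2))
            L = len(mates[m][0])
            k_n = math.ceil(0.08 * L)
            idx = rng.choice(L, size=k_n, replace=False)
            s = list(mates[m][0])
            for i in idx:
                s[i] = "N"
            mates[m][0] = "".join(s)
        elif kind == "low_mean_q":
            m = int(rng.integers(2))
            L = len(mates[m][0])
            mates[m][1] = list(rng.integers(13, 19, size=L))
        elif kind == "short_after_trim":
            m = int(rng.integers(2))
            L = len(mates[m][0])
            # prefix long enough to keep the untrimmed mean above the
            # mean-quality threshold, short enough to fail the length floor
            p_min = math.ceil((min_mean_quality * L - 12 * L) / (41 - 12)) + 1
            p_max = min_length_after_trim - 1
            if p_min >= p_max:
                raise ValueError("read_length too short to plant a trim failure")
            p = int(rng.integers(p_min, p_max + 1))
            mates[m][1] = [41] * p + [12] * (L - p)

        pair = ReadPair(
            pair_id,
            mates[0][0],
            tuple(int(q) for q in mates[0][1]),
            mates[1][0],
            tuple(int(q) for q in mates[1][1]),
        )
        pairs.append(pair)
        if kind is None:
            clean_pairs.append(pair)
        else:
            failures.append(QCFailure(pair_id, kind))
    return pairs, failures


# ---------------------------------------------------------------------------
# allele-depth emission
# ---------------------------------------------------------------------------


def _site_depth(rng: np.random.Generator, depth: float) -> int:
    n = int(rng.poisson(depth))
    while n < 1:
        n = int(rng.poisson(depth))
    return n


def _observe(rng: np.random.Generator, n: int, alt_dose: float, error_rate: float) -> tuple[int, int]:
    """(D_R, D_A) for one site: each read carries the true allele and flips
    to the other allele with probability ``error_rate``."""
    a_true = n if alt_dose == 1.0 else int(rng.binomial(n, alt_dose)) if alt_dose else 0
    da = a_true - int(rng.binomial(a_true, error_rate)) + int(
        rng.binomial(n - a_true, error_rate)
    )
    return n - da, da


def error_only_depths(
    n_sites: int, depth: float, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Depth draws at sites whose only alternative reads are errors."""
    dr = np.empty(n_sites, dtype=int)
    da = np.empty(n_sites, dtype=int)
    for i in range(n_sites):
        n = _site_depth(rng, depth)
        dr[i], da[i] = _observe(rng, n, 0.0, error_rate)
    return dr, da


def emit_allele_depths(
    accession: AccessionMeta,
    truth: TruthManifest,
    depth: float,
    error_rate: float = 0.01,
    seed: int = 0,
    *,
    ref: ReferenceGenome | None = None,
    fp_site_rate: float = 2e-4,
) -> tuple[pd.DataFrame, list[tuple[str, int, str, str]]]:
    """Per-accession allele-depth table plus the injected error-only sites.

    Rows exist only where the accession shows at least one alternative read —
    the shape of what a variant caller reports. Reference-consistent sites are
    therefore absent (and are treated as reference genotype at population
    merge). Returns (table, injected error-only site list); the second element
    includes injected sites that drew zero alternative reads and hence left no
    row.
    """
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    dose = {"ref": 0.0, "het": 0.5, "alt": 1.0}

    rows = []
    planted_positions = {(pv.variant.chrom, pv.variant.pos) for pv in truth.variants}
    for pv in truth.variants:
        g = dose[pv.genotypes[accession.accession_id]]
        n = _site_depth(rng, depth)
        dr, da = _observe(rng, n, g, error_rate)
        if da >= 1:
            v = pv.variant
            rows.append((v.chrom, v.pos, v.ref, v.alt, accession.accession_id, dr, da))

    injected: list[tuple[str, int, str, str]] = []
    if fp_site_rate > 0:
        if ref is None:
            raise ValueError("ref genome required to inject error-only sites")
        chroms = list(ref.chromosomes)
        lengths = np.array([ref.length(c) for c in chroms], dtype=float)
        n_fp = int(rng.binomial(int(lengths.sum()), fp_site_rate))
        for _ in range(n_fp):
            while True:
                ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
                pos = int(rng.integers(1, int(lengths[ci]) + 1))
                if (chroms[ci], pos) not in planted_positions:
                    break
            refbase = ref.base(chroms[ci], pos)
            alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
            injected.append((chroms[ci], pos, refbase, alt))
            n = _site_depth(rng, depth)
            dr, da = _observe(rng, n, 0.0, error_rate)
            if da >= 1:
                rows.append((chroms[ci], pos, refbase, alt, accession.accession_id, dr, da))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "accession", "D_R", "D_A"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return table, injected


# ---------------------------------------------------------------------------
# mirrored (reverse-complemented) study — strand-invariance plumbing
# ---------------------------------------------------------------------------


def mirror_reference(ref: ReferenceGenome) -> ReferenceGenome:
    """Every chromosome reverse-complemented."""
    return ReferenceGenome({c: revcomp(s) for c, s in ref.chromosomes.items()})


def mirror_gene(gene: GeneModel, chrom_length: int) -> GeneModel:
    """The same gene on the reverse-complemented chromosome."""
    L = chrom_length
    exons = tuple(sorted((L - e + 1, L - s + 1) for s, e in gene.exons))
    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand="-" if gene.strand == "+" else "+",
        exons=exons,
        cds_start=L - gene.cds_end + 1,
        cds_end=L - gene.cds_start + 1,
    )


def mirror_variant(v: Variant, chrom_length: int) -> Variant:
    """A SNP expressed on the reverse-complemented chromosome.

    InDels need the genome for re-anchoring — use :func:`mirror_indel`.
    """
    if v.vclass != "SNP":
        raise ValueError("mirror_variant handles SNPs; use mirror_indel for InDels")
    L = chrom_length
    return Variant(v.chrom, L - v.pos + 1, revcomp(v.ref), revcomp(v.alt))


def mirror_indel(v: Variant, ref: ReferenceGenome) -> Variant:
    """Mirror an anchored InDel using the original genome for re-anchoring."""
    L = ref.length(v.chrom)
    if len(v.ref) > len(v.alt):  # deletion
        s, e = v.pos + 1, v.pos + len(v.ref) - 1
        new_pos = L - e
        anchor = revcomp(ref.base(v.chrom, e + 1))
        return Variant(v.chrom, new_pos, anchor + revcomp(v.ref[1:]), anchor)
    # insertion of alt[1:] between pos and pos+1
    ins = v.alt[1:]
    new_pos = L - v.pos
    anchor = revcomp(ref.base(v.chrom, v.pos + 1))
    return Variant(v.chrom, new_pos, anchor, anchor + revcomp(ins))


def mirror_study(
    ref: ReferenceGenome, genes: Sequence[GeneModel], variants: Iterable[Variant]
) -> tuple[ReferenceGenome, list[GeneModel], list[Variant]]:
    """Reverse-complement a whole study: genome, gene models and variants."""
    mref = mirror_reference(ref)
    mgenes = [mirror_gene(g, ref.length(g.chrom)) for g in genes]
    mvars = []
    for v in variants:
        if v.vclass == "SNP":
            mvars.append(mirror_variant(v, ref.length(v.chrom)))
        else:
            mvars.append(mirror_indel(v, ref))
    return mref, mgenes, mvars
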