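"""KASP assay site selection.

A SNP is usable for kompetitive allele-specific PCR genotyping when its
50 bp flanks are unique in the genome (exact match, both strands) and no
other variant sits within the flanking window. Statuses are mutually
exclusive, recording the first failing criterion:

near-edge check -> flank uniqueness -> co-sited variant check -> accepted.

Only SNPs are screened as candidates; InDels enter only as co-sited
contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import ReferenceGenome, revcomp

STATUSES = (
    "accepted",
    "rejected_nonunique_flank",
    "rejected_cosited_variant",
    "rejected_near_edge",
)


@dataclass
class KaspCandidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    status: str
    left_flank: str = ""
    right_flank: str = ""


def count_occurrences(text: str, pattern: str) -> int:
    """Overlapping occurrence count of `pattern` in `text`."""
    count = start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _genome_occurrences(ref: ReferenceGenome, kmer: str) -> int:
    """Occurrences of a k-mer across all chromosomes, both strands."""
    rc = revcomp(kmer)
    n = 0
    for seq in ref.chromosomes.values():
        n += count_occurrences(seq, kmer)
        if rc != kmer:
            n += count_occurrences(seq, rc)
    return n


def flanks(chrom_seq: str, pos: int, flank: int) -> tuple[str, str] | None:
    """(left, right) flank sequences, or None when the SNP is too close to an
    edge for full-length flanks."""
    if pos - flank < 1 or pos + flank > len(chrom_seq):
        return None
    return chrom_seq[pos - 1 - flank : pos - 1], chrom_seq[pos : pos + flank]


def flank_unique(
    chrom: str, pos: int, ref: ReferenceGenome, flank: int = 50
) -> bool:
    """True iff each flank occurs exactly once genome-wide (both strands).

    The flank's own locus accounts for the single permitted occurrence.
    Raises when the position is too close to a chromosome end.
    """
    fl = flanks(ref.chromosomes[chrom], pos, flank)
    if fl is None:
        raise ValueError(f"{chrom}:{pos} is within {flank} bp of a chromosome end")
    left, right = fl
    return _genome_occurrences(ref, left) == 1 and _genome_occurrences(ref, right) == 1


def flank_clean(
    chrom: str, pos: int, all_variants: pd.DataFrame, flank: int = 50
) -> bool:
    """True iff no other variant lies within `flank` bp of the SNP.

    ``all_variants`` needs chrom/pos columns and may include the candidate
    itself (its own position is excluded from the check).
    """
    sub = all_variants[all_variants["chrom"] == chrom]
    near = sub[(sub["pos"] >= pos - flank) & (sub["pos"] <= pos + flank)]
    return not (near["pos"] != pos).any()


def select_kasp_candidates(
    snps: pd.DataFrame,
    ref: ReferenceGenome,
    all_variants: pd.DataFrame,
    flank: int = 50,
) -> list[KaspCandidate]:
    """Screen candidate SNPs against both assay-design criteria.

    ``snps`` needs chrom/pos/ref/alt columns; ``all_variants`` is the full
    variant set (SNPs and InDels) used for the co-location check. Flank
    sequences are emitted for accepted candidates only.
    """
    out: list[KaspCandidate] = []
    for row in snps.itertuples():
        chrom, pos = row.chrom, int(row.pos)
        fl = flanks(ref.chromosomes[chrom], pos, flank)
        if fl is None:
            out.append(KaspCandidate(chrom, pos, row.ref, row.alt, "rejected_near_edge"))
            continue
        if not flank_unique(chrom, pos, ref, flank):
            out.append(
                KaspCandidate(chrom, pos, row.ref, row.alt, "rejected_nonunique_flank")
            )
            continue
        if not flank_clean(chrom, pos, all_variants, flank):
            out.append(
                KaspCandidate(chrom, pos, row.ref, row.alt, "rejected_cosited_variant")
            )
            continue
        left, right = fl
        out.append(
            KaspCandidate(chrom, pos, row.ref, row.alt, "accepted", left, right)
        )
    return out


def candidates_frame(candidates: list[KaspCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "status": c.status,
                "left_flank": c.left_flank,
                "right_flank": c.right_flank,
            }
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", "status", "left_flank", "right_flank"],
    )
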