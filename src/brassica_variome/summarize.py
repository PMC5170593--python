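"""Population summaries: per-morphotype polymorphism counts, windowed genome
tracks and InDel length distributions."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .models import AccessionMeta
from .varfilter import FilterThresholds, classify_zygosity


def count_polymorphic_by_group(
    matrix: pd.DataFrame,
    annotated: pd.DataFrame,
    meta: Iterable[AccessionMeta],
) -> pd.DataFrame:
    """Polymorphic-locus counts per morphotype group.

    A locus is polymorphic within a group iff at least two distinct
    non-missing genotypes occur among the group's accessions. Functional
    columns restrict to protein-changing categories (nonSyn/splice SNPs;
    frameshift/nonframeshift/splice InDels). Groups with zero accessions are
    an error; a one-accession group necessarily reports zero polymorphic loci.
    """
    meta = list(meta)
    groups: dict[str, list[str]] = {}
    for a in meta:
        groups.setdefault(a.morphotype, []).append(a.accession_id)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} has no accessions")

    key = pd.MultiIndex.from_frame(annotated[["chrom", "pos", "ref", "alt"]])
    is_snp = pd.Series(annotated["vclass"].eq("SNP").to_numpy(), index=key)
    functional = pd.Series(annotated["functional"].to_numpy(), index=key)
    is_snp = is_snp.reindex(matrix.index)
    functional = functional.reindex(matrix.index)
    functional = functional.where(functional.notna(), False).astype(bool)

    rows = []
    for group, members in groups.items():
        sub = matrix[members]
        non_missing = sub.apply(
            lambda row: {g for g in row if g != "missing"}, axis=1
        ) if len(sub) else pd.Series(dtype=object)
        poly = (
            non_missing.map(len).ge(2) if len(sub) else pd.Series(dtype=bool)
        )
        snp_mask = is_snp.where(is_snp.notna(), True).astype(bool)
        rows.append(
            {
                "group": group,
                "n_accessions": len(members),
                "snp_polymorphic": int((poly & snp_mask).sum()),
                "snp_functional_polymorphic": int((poly & snp_mask & functional).sum()),
                "indel_polymorphic": int((poly & ~snp_mask).sum()),
                "indel_functional_polymorphic": int((poly & ~snp_mask & functional).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def windowed_tracks(
    annotated: pd.DataFrame,
    observations: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 500_000,
    t: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Fixed-width window tracks along each chromosome.

    Per window: mean heterozygosity (fraction of pre-filter zygosity calls
    classified het among all observations in the window, over accessions x
    sites), SNP count, InDel count and functional-variant count of the
    retained annotated variants. Windows are non-overlapping, anchored at
    position 1, and reported as BED-like 0-based half-open intervals.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = t or FilterThresholds()

    obs = observations.copy()
    if len(obs):
        obs["is_het"] = [
            classify_zygosity(int(r.D_R), int(r.D_A), t) == "het"
            for r in obs.itertuples()
        ]

    rows = []
    for chrom, clen in chrom_lengths.items():
        anns = annotated[annotated["chrom"] == chrom]
        cobs = obs[obs["chrom"] == chrom] if len(obs) else obs
        for start0 in range(0, clen, window):
            end0 = min(start0 + window, clen)
            lo, hi = start0 + 1, end0  # 1-based closed
            in_win = anns[(anns["pos"] >= lo) & (anns["pos"] <= hi)]
            if len(cobs):
                owin = cobs[(cobs["pos"] >= lo) & (cobs["pos"] <= hi)]
                het = float(owin["is_het"].mean()) if len(owin) else 0.0
            else:
                het = 0.0
            rows.append(
                {
                    "chrom": chrom,
                    "start": start0,
                    "end": end0,
                    "heterozygosity": het,
                    "snp_count": int((in_win["vclass"] == "SNP").sum()),
                    "indel_count": int((in_win["vclass"] == "InDel").sum()),
                    "functional_count": int(in_win["functional"].sum()),
                }
            )
    return pd.DataFrame(rows)


def indel_length_distribution(annotated: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Histograms of signed InDel lengths, overall and CDS-located.

    Insertions are positive, deletions negative; a zero-length entry is an
    input error. The CDS-only histogram covers frameshift + nonframeshift
    InDels exactly.
    """
    indels = annotated[annotated["vclass"] == "InDel"]
    lengths = (indels["alt"].str.len() - indels["ref"].str.len()).astype(int)
    if (lengths == 0).any():
        raise ValueError("zero-length InDel in annotation table")
    overall = lengths.value_counts().sort_index()
    in_cds = indels["category"].isin(["frameshift", "nonframeshift"])
    cds = lengths[in_cds].value_counts().sort_index()
    overall.index.name = cds.index.name = "length"
    return overall, cds


def triplet_fraction(hist: pd.Series) -> float:
    """Mass at lengths that are multiples of three."""
    total = hist.sum()
    if total == 0:
        return float("nan")
    triplet = hist[[i for i in hist.index if i % 3 == 0]].sum()
    return float(triplet / total)
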