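"""Candidate-variant rule and the variant filtering cascade.

Works on per-accession allele-depth observations (D_R reference reads, D_A
alternative reads per site), the information an upstream aligner/caller
produces. The cascade:

1. candidacy — a site is a candidate variant iff strictly more than 10% of
   its reads carry the alternative allele (emulating ``bcftools -p 0.9``);
2. confident alleles — an allele is confident iff covered by >= 3 reads; a
   candidate with no confident allele is discarded as unreliable;
3. zygosity — with r = D_R/(D_R+D_A), a site is heterozygous iff
   0.2 < r < 0.8 (open interval; boundaries are homozygous), hom_alt iff
   r <= 0.2, hom_ref iff r >= 0.8;
4. homozygosity retention — heterozygous calls are dropped for homozygous
   lines (DH/inbred); genebank accessions keep them;
5. population MAF — after merging accessions, sites with minor allele
   frequency < 0.05 are removed (SNPs by default; optionally InDels too).

Genotype semantics at merge: an accession with no observation at a site, or
an observation that fails candidacy (alternative fraction <= 10%), is
reference-consistent and genotyped ``ref``; a candidate observation with no
confident allele, or a heterozygous call in a homozygous line, is ``missing``.
Each accession votes one allele (a homozygous line's two identical alleles
are one vote; a het counts half toward each allele) and missing genotypes are
excluded from the MAF denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import AccessionMeta


@dataclass
class FilterThresholds:
    min_alt_fraction: float = 0.10
    min_allele_depth: int = 3
    het_low: float = 0.2
    het_high: float = 0.8
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.het_low < self.het_high < 1:
            raise ValueError("need 0 < het_low < het_high < 1")
        if not 0 <= self.min_alt_fraction < 1:
            raise ValueError("min_alt_fraction must be in [0, 1)")
        if self.min_allele_depth < 1:
            raise ValueError("min_allele_depth must be >= 1")


def call_candidates(d_r: int, d_a: int, t: FilterThresholds | None = None) -> bool:
    """Candidate iff strictly more than ``min_alt_fraction`` alternative reads."""
    t = t or FilterThresholds()
    total = d_r + d_a
    if total == 0:
        raise ValueError("site has zero depth")
    return d_a / total > t.min_alt_fraction


def confident_alleles(d_r: int, d_a: int, t: FilterThresholds | None = None) -> set[str]:
    """Alleles covered by at least ``min_allele_depth`` reads."""
    t = t or FilterThresholds()
    out = set()
    if d_r >= t.min_allele_depth:
        out.add("ref")
    if d_a >= t.min_allele_depth:
        out.add("alt")
    return out


def classify_zygosity(d_r: int, d_a: int, t: FilterThresholds | None = None) -> str:
    """hom_ref / hom_alt / het from the reference-read ratio r = D_R/(D_R+D_A)."""
    t = t or FilterThresholds()
    total = d_r + d_a
    if total < 1:
        raise ValueError("site has zero depth")
    r = d_r / total
    if t.het_low < r < t.het_high:
        return "het"
    return "hom_alt" if r <= t.het_low else "hom_ref"


def genotype_observation(
    d_r: int, d_a: int, zygosity_class: str, t: FilterThresholds | None = None
) -> str:
    """Genotype one observed site for one accession: ref/alt/het/missing."""
    t = t or FilterThresholds()
    if not call_candidates(d_r, d_a, t):
        return "ref"  # alternative fraction too low: reference-like locus
    confident = confident_alleles(d_r, d_a, t)
    if not confident:
        return "missing"
    zyg = classify_zygosity(d_r, d_a, t)
    if zyg == "het":
        return "missing" if zygosity_class == "homozygous_line" else "het"
    if zyg == "hom_alt":
        return "alt" if "alt" in confident else "missing"
    return "ref" if "ref" in confident else "missing"


def filter_accession_variants(
    obs: pd.DataFrame, meta: AccessionMeta, t: FilterThresholds | None = None
) -> pd.DataFrame:
    """Apply the per-accession cascade to one accession's observation table.

    ``obs`` needs columns chrom, pos, ref, alt, D_R, D_A. Returns the table
    with a ``genotype`` column in {ref, alt, het, missing}.
    """
    t = t or FilterThresholds()
    out = obs.copy()
    out["genotype"] = [
        genotype_observation(int(r.D_R), int(r.D_A), meta.zygosity_class, t)
        for r in obs.itertuples()
    ]
    return out


VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def merge_population(
    calls: Mapping[str, pd.DataFrame],
    accessions: Iterable[AccessionMeta],
    t: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Merge per-accession genotyped calls into a population genotype matrix.

    A site enters the matrix iff at least one accession carries a non-
    reference call (alt or het). Accessions without an observation at a kept
    site are genotyped ``ref``. Raises on conflicting reference alleles at
    one position.
    """
    accessions = list(accessions)
    frames = []
    for acc in accessions:
        df = calls.get(acc.accession_id)
        if df is not None and len(df):
            frames.append(df.assign(accession=acc.accession_id))
    if not frames:
        return _empty_matrix(accessions)
    allobs = pd.concat(frames, ignore_index=True)

    ref_per_pos = allobs.groupby(["chrom", "pos"])["ref"].nunique()
    if (ref_per_pos > 1).any():
        bad = ref_per_pos[ref_per_pos > 1].index[0]
        raise ValueError(f"conflicting reference alleles at {bad[0]}:{bad[1]}")

    keep = allobs.groupby(VARIANT_COLUMNS)["genotype"].apply(
        lambda g: g.isin(["alt", "het"]).any()
    )
    kept_keys = set(keep[keep].index)
    allobs = allobs[
        allobs.set_index(VARIANT_COLUMNS).index.isin(kept_keys)
    ]
    matrix = (
        allobs.pivot_table(
            index=VARIANT_COLUMNS,
            columns="accession",
            values="genotype",
            aggfunc="first",
        )
        if len(allobs)
        else None
    )
    if matrix is None:
        return _empty_matrix(accessions)
    order = [a.accession_id for a in accessions]
    matrix = matrix.reindex(columns=order)
    matrix = matrix.fillna("ref")  # no observation = reference-consistent
    matrix = matrix.sort_index()
    matrix.columns.name = None
    return matrix


def _empty_matrix(accessions: list[AccessionMeta]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_arrays([[], [], [], []], names=VARIANT_COLUMNS)
    return pd.DataFrame(index=idx, columns=[a.accession_id for a in accessions])


def minor_allele_frequency(genotypes: Iterable[str]) -> float:
    """MAF over one row; het counts half toward each allele, missing excluded.

    Returns NaN when every genotype is missing.
    """
    alt = ref = n = 0.0
    for g in genotypes:
        if g == "missing":
            continue
        n += 1
        if g == "alt":
            alt += 1
        elif g == "het":
            alt += 0.5
            ref += 0.5
        else:
            ref += 1
    if n == 0:
        return float("nan")
    return min(alt, ref) / n


def maf_filter(
    matrix: pd.DataFrame,
    t: FilterThresholds | None = None,
    *,
    apply_to_indels: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove rows with MAF strictly below ``min_maf``.

    By default only SNP rows are tested (the published filter is stated for
    SNPs); set ``apply_to_indels`` to filter InDels too. All-missing rows are
    always removed. Returns (retained matrix, removed matrix).
    """
    t = t or FilterThresholds()
    if len(matrix) == 0:
        return matrix, matrix
    mafs = matrix.apply(minor_allele_frequency, axis=1)
    is_snp = np.array(
        [len(ref) == 1 and len(alt) == 1 for _, _, ref, alt in matrix.index]
    )
    all_missing = mafs.isna().to_numpy()
    low = (mafs < t.min_maf).to_numpy()
    tested = is_snp | apply_to_indels
    drop = all_missing | (tested & low)
    return matrix[~drop], matrix[drop]


def run_filter_cascade(
    obs: pd.DataFrame,
    accessions: Iterable[AccessionMeta],
    t: FilterThresholds | None = None,
    *,
    apply_maf_to_indels: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full cascade from a long observation table to a filtered matrix.

    ``obs`` needs columns chrom, pos, ref, alt, accession, D_R, D_A. Returns
    (genotype matrix after MAF filtering, stage-count stats).
    """
    t = t or FilterThresholds()
    accessions = list(accessions)
    by_id = {a.accession_id: a for a in accessions}
    calls: dict[str, pd.DataFrame] = {}
    for acc_id, sub in obs.groupby("accession"):
        if acc_id not in by_id:
            raise KeyError(f"observation for unknown accession {acc_id!r}")
        calls[str(acc_id)] = filter_accession_variants(sub, by_id[str(acc_id)], t)
    merged = merge_population(calls, accessions, t)
    retained, removed = maf_filter(merged, t, apply_to_indels=apply_maf_to_indels)
    stats = {
        "observations": int(len(obs)),
        "sites_merged": int(len(merged)),
        "sites_removed_maf": int(len(removed)),
        "sites_retained": int(len(retained)),
    }
    return retained, stats


def matrix_variants(matrix: pd.DataFrame) -> pd.DataFrame:
    """The variant key columns of a genotype matrix as a plain frame."""
    df = matrix.index.to_frame(index=False)
    df["vclass"] = [
        "SNP" if len(r) == 1 and len(a) == 1 else "InDel"
        for r, a in zip(df["ref"], df["alt"])
    ]
    return df
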