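"""Variant filter cascade: candidacy, confidence, zygosity, merge and MAF."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brassica_variome.models import AccessionMeta
from brassica_variome.varfilter import (
    FilterThresholds,
    call_candidates,
    classify_zygosity,
    confident_alleles,
    filter_accession_variants,
    genotype_observation,
    maf_filter,
    merge_population,
    minor_allele_frequency,
    run_filter_cascade,
)

T = FilterThresholds()
HOM = AccessionMeta("a1", "g1", "homozygous_line")
GEN = AccessionMeta("a2", "g1", "genebank")


class TestCandidateRule:
    @pytest.mark.parametrize(
        "dr, da, expected",
        [(9, 1, False), (8, 2, True), (0, 5, True), (90, 10, False), (89, 11, True)],
    )
    def test_strictly_more_than_ten_percent(self, dr, da, expected):
        assert call_candidates(dr, da, T) is expected

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            call_candidates(0, 0, T)


class TestConfidentAlleles:
    @pytest.mark.parametrize(
        "dr, da, expected",
        [(0, 3, {"alt"}), (2, 2, set()), (5, 5, {"ref", "alt"}), (3, 2, {"ref"})],
    )
    def test_three_read_floor(self, dr, da, expected):
        assert confident_alleles(dr, da, T) == expected


class TestZygosity:
    @pytest.mark.parametrize(
        "dr, da, expected",
        [
            (5, 5, "het"),
            (1, 9, "hom_alt"),
            (2, 8, "hom_alt"),  # r = 0.2 boundary: open interval, homozygous
            (8, 2, "hom_ref"),  # r = 0.8 boundary
            (10, 0, "hom_ref"),
            (0, 10, "hom_alt"),
        ],
    )
    def test_open_interval(self, dr, da, expected):
        assert classify_zygosity(dr, da, T) == expected

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_het_is_symmetric(self, a, b):
        if a + b == 0:
            return
        het_ab = classify_zygosity(a, b, T) == "het"
        het_ba = classify_zygosity(b, a, T) == "het"
        assert het_ab == het_ba


class TestPerAccessionCalls:
    def test_hom_line_het_site_dropped(self):
        assert genotype_observation(5, 5, "homozygous_line", T) == "missing"

    def test_genebank_keeps_het(self):
        assert genotype_observation(5, 5, "genebank", T) == "het"

    def test_clean_hom_alt(self):
        assert genotype_observation(0, 10, "homozygous_line", T) == "alt"

    def test_low_depth_candidate_is_missing(self):
        # candidate (50% alt) but neither allele has 3 reads
        assert genotype_observation(1, 1, "homozygous_line", T) == "missing"

    def test_subthreshold_alt_fraction_is_reference_like(self):
        assert genotype_observation(9, 1, "homozygous_line", T) == "ref"

    def test_table_wrapper(self):
        obs = pd.DataFrame(
            {"chrom": ["c"] * 2, "pos": [10, 20], "ref": ["A", "C"],
             "alt": ["G", "T"], "D_R": [0, 5], "D_A": [10, 5]}
        )
        out = filter_accession_variants(obs, HOM, T)
        assert list(out["genotype"]) == ["alt", "missing"]


def _call_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "D_R", "D_A", "genotype"]
    )


class TestMergePopulation:
    def test_absent_accessions_are_reference(self):
        accs = [AccessionMeta(f"a{i}", "g", "homozygous_line") for i in (1, 2, 3)]
        calls = {"a1": _call_frame([("c", 10, "A", "G", 0, 9, "alt")])}
        m = merge_population(calls, accs, T)
        assert list(m.loc[("c", 10, "A", "G")]) == ["alt", "ref", "ref"]

    def test_unreliable_observation_is_missing(self):
        accs = [AccessionMeta("a1", "g", "homozygous_line"),
                AccessionMeta("a2", "g", "homozygous_line")]
        calls = {
            "a1": _call_frame([("c", 10, "A", "G", 0, 9, "alt")]),
            "a2": _call_frame([("c", 10, "A", "G", 1, 1, "missing")]),
        }
        m = merge_population(calls, accs, T)
        assert list(m.loc[("c", 10, "A", "G")]) == ["alt", "missing"]

    def test_all_reference_sites_do_not_enter_matrix(self):
        accs = [AccessionMeta("a1", "g", "homozygous_line")]
        calls = {"a1": _call_frame([("c", 10, "A", "G", 9, 1, "ref")])}
        assert len(merge_population(calls, accs, T)) == 0

    def test_conflicting_reference_alleles_raise(self):
        accs = [AccessionMeta("a1", "g", "homozygous_line"),
                AccessionMeta("a2", "g", "homozygous_line")]
        calls = {
            "a1": _call_frame([("c", 10, "A", "G", 0, 9, "alt")]),
            "a2": _call_frame([("c", 10, "T", "G", 0, 9, "alt")]),
        }
        with pytest.raises(ValueError, match="conflicting reference"):
            merge_population(calls, accs, T)

    def test_empty_input_gives_empty_matrix(self):
        assert len(merge_population({}, [HOM], T)) == 0


class TestMafFilter:
    @staticmethod
    def _matrix(n_alt, n_ref, n_missing=0):
        gts = ["alt"] * n_alt + ["ref"] * n_ref + ["missing"] * n_missing
        idx = pd.MultiIndex.from_tuples(
            [("c", 1, "A", "G")], names=["chrom", "pos", "ref", "alt"]
        )
        return pd.DataFrame([gts], index=idx,
                            columns=[f"a{i}" for i in range(len(gts))])

    def test_published_boundary_199_accessions(self):
        removed_9 = maf_filter(self._matrix(9, 190), T)[1]
        assert len(removed_9) == 1  # 9/199 = 0.0452 < 0.05
        retained_10 = maf_filter(self._matrix(10, 189), T)[0]
        assert len(retained_10) == 1  # 10/199 = 0.0503 >= 0.05

    def test_even_split_retained(self):
        assert len(maf_filter(self._matrix(5, 5), T)[0]) == 1

    def test_all_missing_row_removed(self):
        assert len(maf_filter(self._matrix(0, 0, 4), T)[0]) == 0

    def test_het_counts_half_each_way(self):
        assert minor_allele_frequency(["het", "ref", "ref", "missing"]) == pytest.approx(
            0.5 / 3
        )

    def test_indels_untested_by_default(self):
        idx = pd.MultiIndex.from_tuples(
            [("c", 1, "AT", "A")], names=["chrom", "pos", "ref", "alt"]
        )
        m = pd.DataFrame([["alt"] + ["ref"] * 99], index=idx,
                         columns=[f"a{i}" for i in range(100)])
        assert len(maf_filter(m, T)[0]) == 1
        assert len(maf_filter(m, T, apply_to_indels=True)[0]) == 0


def _random_obs(rng, n):
    return pd.DataFrame(
        {
            "chrom": "c",
            "pos": np.arange(1, n + 1),
            "ref": "A",
            "alt": "G",
            "accession": "a1",
            "D_R": rng.integers(0, 30, size=n),
            "D_A": rng.integers(1, 30, size=n),
        }
    )


def test_cascade_matches_bruteforce_of_printed_rules():
    """Keep/drop and zygosity agree with direct evaluation of the three
    printed rules on 10,000 random depth pairs."""
    rng = np.random.default_rng(11)
    obs = _random_obs(rng, 10_000)
    for meta in (HOM, GEN):
        got = filter_accession_variants(obs, meta, T)["genotype"]
        for g, dr, da in zip(got, obs["D_R"], obs["D_A"]):
            dr, da = int(dr), int(da)
            if not da / (dr + da) > 0.10:
                expected = "ref"
            elif not (dr >= 3 or da >= 3):
                expected = "missing"
            else:
                r = dr / (dr + da)
                if 0.2 < r < 0.8:
                    expected = "missing" if meta.zygosity_class == "homozygous_line" else "het"
                elif r <= 0.2:
                    expected = "alt" if da >= 3 else "missing"
                else:
                    expected = "ref" if dr >= 3 else "missing"
            assert g == expected


def test_monotonicity_in_depth_and_maf_thresholds():
    rng = np.random.default_rng(23)
    n = 400
    obs = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": "c",
                    "pos": rng.choice(np.arange(1, 80), size=n // 4),
                    "ref": "A",
                    "alt": "G",
                    "accession": acc,
                    "D_R": rng.integers(0, 12, size=n // 4),
                    "D_A": rng.integers(1, 12, size=n // 4),
                }
            ).drop_duplicates(["chrom", "pos"])
            for acc in ("a1", "a2", "a3", "a4")
        ],
        ignore_index=True,
    )
    accs = [AccessionMeta(f"a{i}", "g", "homozygous_line") for i in (1, 2, 3, 4)]
    previous = None
    for min_ad in (1, 2, 3, 5, 8):
        t = FilterThresholds(min_allele_depth=min_ad)
        retained, _ = run_filter_cascade(obs, accs, t)
        if previous is not None:
            assert len(retained) <= previous
        previous = len(retained)
    previous = None
    for maf in (0.0, 0.05, 0.2, 0.4):
        t = FilterThresholds(min_maf=maf)
        retained, _ = run_filter_cascade(obs, accs, t)
        if previous is not None:
            assert len(retained) <= previous
        previous = len(retained)
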