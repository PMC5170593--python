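"""Shared fixtures: one small simulated study reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from brassica_variome import simulate


@pytest.fixture(scope="session")
def small_study():
    """A compact study: 2 x 30 kb chromosomes, 8 genes, 3 groups x 5 lines,
    200 planted variants."""
    ref, genes = simulate.generate_reference(2, 30_000, 8, seed=3)
    accessions, manifest = simulate.generate_population(
        ref, genes, n_groups=3, accessions_per_group=5, n_variants=200, seed=7
    )
    return ref, genes, accessions, manifest


def truth_matrix(accessions, manifest) -> pd.DataFrame:
    """Genotype matrix straight from the manifest's true genotypes."""
    idx = pd.MultiIndex.from_tuples(
        [pv.variant.key for pv in manifest.variants],
        names=["chrom", "pos", "ref", "alt"],
    )
    return pd.DataFrame(
        [[pv.genotypes[a.accession_id] for a in accessions] for pv in manifest.variants],
        index=idx,
        columns=[a.accession_id for a in accessions],
    ).sort_index()


@pytest.fixture(scope="session")
def small_truth_matrix(small_study):
    _, _, accessions, manifest = small_study
    return truth_matrix(accessions, manifest)
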