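import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coabnet import SpectralCountMatrix, SyntheticConfig, TaxonCountMatrix
from coabnet.datatypes import NormalizationResult

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast, fully-featured synthetic configuration."""
    return SyntheticConfig(
        n_taxa=20,
        proteins_per_taxon=(1, 6),
        frac_da=0.3,
        n_modules=2,
        module_size=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from coabnet import generate_metaproteome

    return generate_metaproteome(small_config)


def make_taxon_matrix(counts: np.ndarray, groups: list[str], n_per_group: int = 4,
                      taxa=None) -> TaxonCountMatrix:
    """Build a TaxonCountMatrix straight from an array (tests only)."""
    n_taxa, n_samples = counts.shape
    assert n_samples == len(groups) * n_per_group
    samples = [f"{g}_{i+1}" for g in groups for i in range(n_per_group)]
    taxa = taxa if taxa is not None else [f"T{i:03d}" for i in range(n_taxa)]
    df = pd.DataFrame(counts, index=taxa, columns=samples)
    return TaxonCountMatrix(
        counts=df,
        ranks=pd.Series("species", index=df.index),
        phenotypes=pd.Series(
            [g for g in groups for _ in range(n_per_group)], index=df.columns
        ),
    )


def unit_factors(tcm: TaxonCountMatrix) -> NormalizationResult:
    """A no-op normalization (all factors 1) for controlled simulations."""
    ones = pd.Series(1.0, index=tcm.counts.columns)
    return NormalizationResult(
        factors=ones, tmm=ones.copy(), lib_sizes=tcm.counts.sum(axis=0),
        reference=str(tcm.counts.columns[0]), trim_m=0.3, trim_a=0.05,
    )


def make_spectral_matrix(counts: np.ndarray, lengths, groups=("A", "B"),
                         n_per_group: int = 2) -> SpectralCountMatrix:
    n_prot, n_samples = counts.shape
    samples = [f"{g}{i+1}" for g in groups for i in range(n_per_group)][:n_samples]
    proteins = [f"P{i:02d}" for i in range(n_prot)]
    return SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=proteins, columns=samples),
        lengths=pd.Series(lengths, index=proteins),
        phenotypes=pd.Series(
            ([g for g in groups for _ in range(n_per_group)])[:n_samples],
            index=samples,
        ),
    )
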