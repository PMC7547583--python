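"""Core data containers shared across the pipeline stages.

The pipeline moves a protein x sample spectral-count matrix through
quantification (NSAF), taxon aggregation, normalization, differential
testing and network inference.  The containers here are thin, validated
wrappers around pandas objects so that each stage can state its contract
in terms of a single type.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: taxonomic ranks from most to least specific; a protein's lineage is
#: truncated at its lowest confidently-assigned rank.
RANKS = ("species", "genus", "family")


@dataclass
class SpectralCountMatrix:
    """Protein-level spectral counts with protein lengths and sample phenotypes.

    Parameters
    ----------
    counts
        Integer DataFrame, rows = protein ids, columns = sample ids.
    lengths
        Protein length in amino-acid residues, indexed like ``counts`` rows.
    phenotypes
        Phenotype label per sample, indexed like ``counts`` columns.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    phenotypes: pd.Series

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise ValueError(f"missing protein lengths for {missing[:5]}")
        if (self.lengths <= 0).any():
            raise ValueError("protein lengths must be strictly positive")
        if not self.phenotypes.index.equals(self.counts.columns):
            self.phenotypes = self.phenotypes.reindex(self.counts.columns)
        if self.phenotypes.isna().any():
            raise ValueError("every sample needs a phenotype label")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("spectral counts must be nonnegative")

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> list[str]:
        """Phenotype labels in order of first appearance."""
        return list(dict.fromkeys(self.phenotypes))

    def samples_of(self, group: str) -> list[str]:
        return list(self.phenotypes.index[self.phenotypes == group])


@dataclass
class TaxonomyMap:
    """Protein -> lineage map with a lowest-assigned rank per protein.

    ``table`` is indexed by protein id with one column per rank in
    :data:`RANKS` plus ``lowest_rank``.  Ranks below the lowest assigned
    one hold NaN (e.g. a genus-level protein has species = NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = set(RANKS) | {"lowest_rank"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(need)}")
        bad = ~self.table["lowest_rank"].isin(RANKS)
        if bad.any():
            raise ValueError(
                f"unknown lowest_rank values: {self.table['lowest_rank'][bad].unique()}"
            )

    def taxon_of(self, protein_id: str) -> tuple[str, str]:
        """Return (rank, taxon name) at the protein's lowest assigned rank."""
        row = self.table.loc[protein_id]
        rank = row["lowest_rank"]
        return rank, row[rank]

    def lineage_string(self, protein_id: str) -> str:
        row = self.table.loc[protein_id]
        parts = []
        for rank in reversed(RANKS):  # family -> species
            name = row[rank]
            if isinstance(name, str):
                parts.append(f"{rank}={name}")
        return ";".join(parts)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.table.index


@dataclass
class TaxonCountMatrix:
    """Taxon x sample summed spectral counts.

    ``ranks`` records, per taxon id, the rank the taxon is keyed at
    (species-level and genus-level taxa are distinct rows even when the
    genus contains the species).
    """

    counts: pd.DataFrame
    ranks: pd.Series
    phenotypes: pd.Series

    def __post_init__(self) -> None:
        if not self.ranks.index.equals(self.counts.index):
            self.ranks = self.ranks.reindex(self.counts.index)
        if not self.phenotypes.index.equals(self.counts.columns):
            self.phenotypes = self.phenotypes.reindex(self.counts.columns)
        if self.counts.index.has_duplicates:
            raise ValueError("taxon ids must be unique")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.phenotypes))

    def samples_of(self, group: str) -> list[str]:
        return list(self.phenotypes.index[self.phenotypes == group])


@dataclass
class NormalizationResult:
    """Between-sample scaling factors from trimmed-mean-of-M normalization.

    Two factor sets are exposed:

    ``tmm``
        The pure trimmed-mean-of-M component (relative composition
        correction, edgeR convention), geometric mean 1.  A sample whose
        counts are an exact scalar multiple of another's gets tmm = 1.
    ``factors``
        Effective per-sample scale ``N_j * tmm_j`` rescaled to geometric
        mean 1, where ``N_j`` is the library size.  Dividing counts by
        ``factors`` puts samples on a common scale; this is what the
        differential stage consumes.
    """

    factors: pd.Series
    tmm: pd.Series
    lib_sizes: pd.Series
    reference: str
    trim_m: float
    trim_a: float
    M: dict = field(default_factory=dict, repr=False)
    A: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in (self.factors, self.tmm):
            if (f <= 0).any():
                raise ValueError("normalization factors must be positive")
            gm = float(np.exp(np.mean(np.log(f))))
            if abs(gm - 1.0) > 1e-9:
                raise ValueError(f"geometric mean of factors is {gm}, expected 1")


@dataclass
class GroundTruth:
    """Everything the synthetic generator planted, keyed for recovery tests.

    Attributes
    ----------
    da_taxa
        Comparison name (``"A_vs_B"``) -> set of taxa with a nonzero
        planted log2 fold change in that comparison.
    da_effects
        Taxon -> (affected group, signed log2 fold change).
    module_membership
        Taxon -> module id for taxa inside a planted co-abundance module.
    planted_params
        Per-protein DataFrame with columns mu, phi, a, taxon, length.
    """

    da_taxa: dict[str, set[str]]
    da_effects: dict[str, tuple[str, float]]
    module_membership: dict[str, int]
    planted_params: pd.DataFrame

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for taxon, mod in self.module_membership.items():
            out.setdefault(mod, set()).add(taxon)
        return out

    def union_da(self) -> set[str]:
        u: set[str] = set()
        for taxa in self.da_taxa.values():
            u |= taxa
        return u
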