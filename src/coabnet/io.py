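"""Readers and writers for the pipeline's plain-text formats (TSV/JSON)."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    RANKS,
    GroundTruth,
    NormalizationResult,
    SpectralCountMatrix,
    TaxonCountMatrix,
    TaxonomyMap,
)


def read_counts(
    counts_path: str | Path, samples_path: str | Path
) -> tuple[SpectralCountMatrix, TaxonomyMap]:
    """Read a counts TSV (protein_length_aa + lineage metadata columns) and
    a samples TSV (sample_id, phenotype) back into pipeline containers."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "protein_length_aa" not in df.columns or "lineage" not in df.columns:
        raise ValueError(
            "counts TSV must carry protein_length_aa and lineage columns"
        )
    lengths = df["protein_length_aa"]
    lineage = df["lineage"]
    counts = df.drop(columns=["protein_length_aa", "lineage"]).astype(np.int64)

    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    phenotypes = samples["phenotype"].reindex(counts.columns)

    tax_rows = []
    for pid, lin in lineage.items():
        row = {r: np.nan for r in RANKS}
        for part in str(lin).split(";"):
            rank, _, name = part.partition("=")
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r} in lineage of {pid}")
            row[rank] = name
        lowest = next(r for r in RANKS if isinstance(row[r], str))
        row["protein_id"] = pid
        row["lowest_rank"] = lowest
        tax_rows.append(row)
    taxmap = TaxonomyMap(pd.DataFrame(tax_rows).set_index("protein_id"))
    scm = SpectralCountMatrix(counts=counts, lengths=lengths, phenotypes=phenotypes)
    return scm, taxmap


def write_taxon_counts(path: str | Path, tcm: TaxonCountMatrix) -> None:
    out = tcm.counts.copy()
    out.insert(0, "rank", tcm.ranks)
    out.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxon_counts(
    path: str | Path, samples_path: str | Path
) -> TaxonCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ranks = df["rank"]
    counts = df.drop(columns=["rank"])
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    phenotypes = samples["phenotype"].reindex(counts.columns)
    return TaxonCountMatrix(counts=counts, ranks=ranks, phenotypes=phenotypes)


def write_norm_factors(path: str | Path, norm: NormalizationResult) -> None:
    pd.DataFrame(
        {
            "factor": norm.factors,
            "tmm": norm.tmm,
            "lib_size": norm.lib_sizes,
        }
    ).to_csv(path, sep="\t", index_label="sample_id")


def read_norm_factors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    planted = pd.DataFrame(payload["planted_params"]).set_index("protein_id")
    return GroundTruth(
        da_taxa={c: set(v) for c, v in payload["da_taxa"].items()},
        da_effects={t: (g, f) for t, (g, f) in payload["da_effects"].items()},
        module_membership=payload["module_membership"],
        planted_params=planted,
    )
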