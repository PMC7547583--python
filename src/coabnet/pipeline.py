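"""End-to-end pipeline: simulate -> quantify -> differential -> network.

A single :class:`PipelineConfig` carries every stage parameter plus one
global seed; stage seeds are derived from it with a fixed counter scheme
so partial reruns stay reproducible.  Every intermediate artifact is
written to the run directory, and a manifest records the config and a
SHA-256 digest of each output so a rerun can be verified byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .datatypes import SpectralCountMatrix, TaxonCountMatrix, TaxonomyMap
from .differential import hub_ttest, run_pairwise_da
from .network import bc3net, mst2_reduce, network_stats, select_hubs
from .quantify import (
    aggregate_to_taxa,
    compute_nsaf,
    filter_low_counts,
    log2_transform_impute,
    rescale_counts,
    tmm_normalize,
)
from .simulate import SyntheticConfig, generate_metaproteome, write_dataset

log = logging.getLogger("coabnet")

# fixed per-stage seed offsets (counter scheme)
_STAGE_OFFSET = {"simulate": 0, "impute": 1, "network": 2}


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run, JSON round-trippable."""

    simulate: bool = True
    counts_path: str | None = None
    samples_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    min_count: int = 5
    min_samples: int = 2
    trim_m: float = 0.30
    trim_a: float = 0.05
    downshift: float = 1.8
    width: float = 0.3
    alpha_da: float = 0.05
    alpha_enrich: float = 0.01
    B: int = 100
    alpha_ind: float = 0.05
    alpha_ens: float = 0.05
    n_perm: int = 1000
    bins: int | None = None
    percentile: float = 95.0
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 101 + _STAGE_OFFSET[stage]) % (2**31 - 1)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_json(json.dumps(d["synthetic"]))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write artifacts + manifest, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[dict] = []

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        syn = SyntheticConfig(**{**asdict(config.synthetic),
                                 "seed": config.stage_seed("simulate")})
        scm, taxmap, truth = generate_metaproteome(syn)
        write_dataset(outdir, scm, taxmap, truth)
        stages.append({"stage": "simulate", "n_proteins": scm.n_proteins,
                       "n_samples": scm.n_samples})
        log.info("simulate: %d proteins x %d samples", scm.n_proteins, scm.n_samples)
    else:
        if not (config.counts_path and config.samples_path):
            raise ValueError("counts_path and samples_path required when simulate=False")
        scm, taxmap = cio.read_counts(config.counts_path, config.samples_path)
        stages.append({"stage": "load", "n_proteins": scm.n_proteins,
                       "n_samples": scm.n_samples})

    # --- quantify ---------------------------------------------------------
    nsaf = compute_nsaf(scm)
    nsaf.to_csv(outdir / "nsaf.tsv", sep="\t")
    log2imp = log2_transform_impute(
        nsaf, downshift=config.downshift, width=config.width,
        seed=config.stage_seed("impute"),
    )
    log2imp.to_csv(outdir / "nsaf_log2_imputed.tsv", sep="\t")
    tcm = aggregate_to_taxa(scm, taxmap)
    n_before = tcm.n_taxa
    tcm = filter_low_counts(tcm, config.min_count, config.min_samples)
    cio.write_taxon_counts(outdir / "taxon_counts.tsv", tcm)
    norm = tmm_normalize(tcm, config.trim_m, config.trim_a)
    cio.write_norm_factors(outdir / "norm_factors.tsv", norm)
    stages.append({"stage": "quantify", "taxa_before_filter": n_before,
                   "taxa_after_filter": tcm.n_taxa,
                   "reference_sample": norm.reference})
    log.info("quantify: %d -> %d taxa after filter", n_before, tcm.n_taxa)

    # --- differential -----------------------------------------------------
    da_table, comp_set = run_pairwise_da(tcm, norm, alpha=config.alpha_da)
    da_table.to_csv(outdir / "da_results.tsv", sep="\t", index=False)
    union = sorted(comp_set.union_da)
    pd.Series(union, name="taxon").to_csv(outdir / "union_da.tsv", sep="\t",
                                          index=False)
    stages.append({"stage": "differential", "n_comparisons": len(comp_set.comparisons),
                   "n_union_da": len(union)})
    log.info("differential: %d taxa DA in >= 1 of %d comparisons",
             len(union), len(comp_set.comparisons))

    # --- network ----------------------------------------------------------
    stats: dict = network_stats(nx.Graph())
    hubs_n = 0
    if len(union) >= 3:
        abund = np.log2(rescale_counts(tcm, norm).loc[union] + 1.0)
        net = bc3net(
            abund, B=config.B, alpha_ind=config.alpha_ind,
            alpha_ens=config.alpha_ens, n_perm=config.n_perm,
            bins=config.bins, seed=config.stage_seed("network"),
        )
        mst2 = mst2_reduce(net)
        stats = network_stats(net)
        hubs = select_hubs(net, percentile=config.percentile)
        hubs_n = len(hubs.table)

        rows = [
            {"u": u, "v": v, "weight": d.get("weight", np.nan),
             "support": d.get("support", np.nan),
             "in_mst1": (min(u, v), max(u, v)) in mst2.mst1_edges,
             "in_mst2": (min(u, v), max(u, v)) in mst2.second_edges}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["u", "v", "weight", "support",
                                    "in_mst1", "in_mst2"]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False)
        nx.write_graphml(net, outdir / "network.graphml")
        nx.write_graphml(mst2.graph, outdir / "mst2.graphml")
        stats["mst2"] = network_stats(mst2.graph)
        stats["degree_percentile_threshold"] = hubs.threshold
        (outdir / "network_stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True))
        hubs.table.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        if hubs_n:
            tt = hub_ttest(tcm, list(hubs.table["taxon"]))
            tt.to_csv(outdir / "hub_ttests.tsv", sep="\t", index=False)
    else:
        log.warning("only %d DA taxa; network stage skipped", len(union))
    stages.append({"stage": "network", **{k: v for k, v in stats.items()
                                          if not isinstance(v, dict)},
                   "n_hubs": hubs_n})

    # --- manifest ---------------------------------------------------------
    files = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
        "stages": stages,
        "files": files,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
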