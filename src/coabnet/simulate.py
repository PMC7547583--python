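"""Synthetic metaproteome generator.

Emulates the statistical structure of a cecal-content metaproteomics
experiment with four phenotype groups (5/6-nephrectomy CKD and healthy
mice, each with and without a resistant-starch diet): overdispersed
Poisson-Tweedie spectral counts per protein, multi-protein taxa (some
assignable only above species rank), planted taxon-level fold-change
effects, latent-factor co-abundance modules, and sporadic missing values.

Counts are drawn from the Poisson-Tweedie (PT) family through its three
named special cases, indexed by the shape ``a``:

* ``a = 1``   — Poisson (variance = mean, requires ``phi = 1``);
* ``a = 0``   — negative binomial, drawn as a gamma-Poisson mixture;
* ``a = 0.5`` — Poisson-inverse-Gaussian, drawn as an IG-Poisson mixture.

All cases share the moment parametrization E[X] = mu, Var[X] = phi * mu.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, SpectralCountMatrix, TaxonomyMap

PT_SHAPES = (1.0, 0.0, 0.5)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic metaproteome.

    Defaults mirror a small-cohort cecal metaproteome: 4 phenotype groups
    of 4 animals, a few dozen bacterial taxa each represented by several
    proteins, overdispersed counts (phi up to ~10), a quarter of taxa
    carrying planted effects, and three latent co-abundance modules.
    """

    n_taxa: int = 60
    proteins_per_taxon: tuple[int, int] = (1, 20)
    protein_length_range: tuple[int, int] = (80, 1500)
    groups: tuple[str, ...] = ("CKD", "CKDRS", "HRS", "H")
    n_per_group: int = 4
    baseline_mu_range: tuple[float, float] = (1.0, 30.0)
    phi: float | tuple[float, float] = (1.0, 10.0)
    a: float = 0.0
    frac_da: float = 0.25
    log2fc_range: tuple[float, float] = (2.0, 5.0)
    n_modules: int = 3
    module_size: int = 5
    module_rho: float = 0.9
    latent_sigma: float = 0.35
    frac_unassigned_species: float = 0.1
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.a not in PT_SHAPES:
            raise ValueError(f"a must be one of {PT_SHAPES}")
        if not (0.0 <= self.module_rho < 1.0):
            raise ValueError("module_rho must be in [0, 1)")
        if self.n_modules * self.module_size > self.n_taxa:
            raise ValueError("module_size * n_modules exceeds n_taxa")
        lo, hi = self._phi_bounds()
        if lo < 1.0:
            raise ValueError("phi must be >= 1 (underdispersion unsupported)")
        if self.a == 1.0 and hi > 1.0:
            raise ValueError("a=1 (Poisson) requires phi = 1")

    def _phi_bounds(self) -> tuple[float, float]:
        if isinstance(self.phi, (int, float)):
            return float(self.phi), float(self.phi)
        lo, hi = self.phi
        return float(lo), float(hi)

    def comparisons(self) -> list[str]:
        return [f"{a}_vs_{b}" for a, b in itertools.combinations(self.groups, 2)]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        for key in ("proteins_per_taxon", "protein_length_range", "groups",
                    "baseline_mu_range", "log2fc_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("phi"), list):
            d["phi"] = tuple(d["phi"])
        return cls(**d)


def sample_pt_counts(mu, phi: float, a: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` Poisson-Tweedie counts with E[X] = mu, Var[X] = phi * mu.

    Parameters
    ----------
    mu
        Mean count, a positive scalar or an array broadcastable to ``n``.
    phi
        Dispersion (variance/mean ratio), >= 1.
    a
        Shape index: 1 (Poisson), 0 (negative binomial),
        0.5 (Poisson-inverse-Gaussian).
    seed
        Integer seed or ``numpy.random.Generator``.
    """
    mu = np.asarray(mu, dtype=float)
    if (mu <= 0).any():
        raise ValueError("mu must be positive")
    if phi < 1.0:
        raise ValueError("phi < 1 (underdispersion) is unsupported")
    if a not in PT_SHAPES:
        raise ValueError(f"a must be one of {PT_SHAPES}")
    if a == 1.0 and phi > 1.0:
        raise ValueError("a=1 is Poisson; phi > 1 is inconsistent")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu_vec = np.broadcast_to(mu, (n,) if mu.ndim == 0 else mu.shape).astype(float)
    if phi == 1.0 or a == 1.0:
        return rng.poisson(mu_vec)
    if a == 0.0:
        # gamma-Poisson: Lambda ~ Gamma(mu/(phi-1), scale=phi-1)
        lam = rng.gamma(shape=mu_vec / (phi - 1.0), scale=phi - 1.0)
    else:
        # IG-Poisson: Lambda ~ IG(mean=mu, shape=mu^2/(phi-1)) so that
        # Var(Lambda) = mu^3/shape = (phi-1)*mu and Var(X) = phi*mu.
        shape = mu_vec**2 / (phi - 1.0)
        lam = rng.wald(mu_vec, shape)
    return rng.poisson(lam)


def generate_metaproteome(
    config: SyntheticConfig,
) -> tuple[SpectralCountMatrix, TaxonomyMap, GroundTruth]:
    """Generate a synthetic spectral-count dataset plus its ground truth.

    Proteins are partitioned among taxa; planted log2 fold changes shift
    the mean of every protein of an affected taxon in the affected group;
    module taxa share a per-sample latent log-normal factor scaled by
    ``module_rho``; a fraction of proteins is assigned only at genus or
    family rank; cells are zeroed at ``missing_rate`` with low-abundance
    proteins twice as likely to drop out.
    """
    rng = np.random.default_rng(config.seed)
    n_taxa = config.n_taxa
    groups = list(config.groups)
    samples = [
        f"{g}_{i + 1}" for g in groups for i in range(config.n_per_group)
    ]
    phenotypes = pd.Series(
        [g for g in groups for _ in range(config.n_per_group)],
        index=pd.Index(samples, name="sample_id"),
        name="phenotype",
    )
    n_samples = len(samples)

    taxa = [f"Species_{i:03d}" for i in range(n_taxa)]
    genus_of = {t: f"Genus_{i // 2:03d}" for i, t in enumerate(taxa)}
    family_of = {t: f"Family_{i // 4:03d}" for i, t in enumerate(taxa)}

    # --- protein layout -------------------------------------------------
    lo_p, hi_p = config.proteins_per_taxon
    n_prot_per_taxon = rng.integers(lo_p, hi_p + 1, size=n_taxa)
    protein_taxon: list[str] = []
    protein_ids: list[str] = []
    for t, npt in zip(taxa, n_prot_per_taxon):
        for k in range(npt):
            protein_ids.append(f"{t}_P{k:02d}")
            protein_taxon.append(t)
    n_prot = len(protein_ids)

    lo_l, hi_l = config.protein_length_range
    lengths = rng.integers(lo_l, hi_l + 1, size=n_prot)
    lo_m, hi_m = config.baseline_mu_range
    base_mu = np.exp(rng.uniform(np.log(lo_m), np.log(hi_m), size=n_prot))
    phi_lo, phi_hi = config._phi_bounds()
    phi_per_protein = rng.uniform(phi_lo, phi_hi, size=n_prot)
    a_per_protein = np.full(n_prot, config.a)
    phi_per_protein[a_per_protein == 1.0] = 1.0

    # --- planted differential taxa --------------------------------------
    n_da = int(round(config.frac_da * n_taxa))
    da_order = rng.permutation(n_taxa)[:n_da]
    da_effects: dict[str, tuple[str, float]] = {}
    for idx in da_order:
        taxon = taxa[idx]
        group = groups[rng.integers(len(groups))]
        lfc = float(rng.uniform(*config.log2fc_range))
        if rng.random() < 0.5:
            lfc = -lfc
        da_effects[taxon] = (group, lfc)
    da_taxa = {c: set() for c in config.comparisons()}
    for taxon, (group, _) in da_effects.items():
        for comp in da_taxa:
            a_grp, b_grp = comp.split("_vs_")
            if group in (a_grp, b_grp):
                da_taxa[comp].add(taxon)

    # --- co-abundance modules -------------------------------------------
    # Module members come preferentially from the planted-DA taxa so the
    # modules survive the differential filter that feeds the network stage.
    module_membership: dict[str, int] = {}
    if config.n_modules > 0 and config.module_size > 0:
        preferred = [taxa[i] for i in da_order]
        rest = [t for t in taxa if t not in set(preferred)]
        pool = preferred + list(rng.permutation(rest))
        need = config.n_modules * config.module_size
        chosen = pool[:need]
        for m in range(config.n_modules):
            for t in chosen[m * config.module_size:(m + 1) * config.module_size]:
                module_membership[t] = m

    # --- per-cell means --------------------------------------------------
    group_of_sample = phenotypes.to_numpy()
    mu_cells = np.tile(base_mu[:, None], (1, n_samples))
    for taxon, (group, lfc) in da_effects.items():
        rows = [i for i, t in enumerate(protein_taxon) if t == taxon]
        cols = np.flatnonzero(group_of_sample == group)
        mu_cells[np.ix_(rows, cols)] *= 2.0**lfc
    if config.latent_sigma > 0:
        # Per-sample log-normal biological variability, identical in
        # marginal scale for every taxon; module members share a latent
        # factor with correlation module_rho, non-members are independent.
        rho = config.module_rho
        sigma = config.latent_sigma
        z_mod = rng.standard_normal((max(config.n_modules, 1), n_samples))
        z_taxon = rng.standard_normal((n_taxa, n_samples))
        taxon_index = {t: i for i, t in enumerate(taxa)}
        eps = z_taxon.copy()
        for t, m in module_membership.items():
            ti = taxon_index[t]
            eps[ti] = rho * z_mod[m] + math.sqrt(1.0 - rho**2) * z_taxon[ti]
        factor = np.exp(sigma * eps - 0.5 * sigma**2)
        for i, t in enumerate(protein_taxon):
            mu_cells[i, :] *= factor[taxon_index[t], :]

    # --- draw counts ------------------------------------------------------
    counts = np.empty((n_prot, n_samples), dtype=np.int64)
    for i in range(n_prot):
        counts[i, :] = sample_pt_counts(
            mu_cells[i, :], float(phi_per_protein[i]), float(a_per_protein[i]),
            n_samples, seed=rng,
        )

    # --- MNAR-light missingness ------------------------------------------
    if config.missing_rate > 0:
        w = np.where(base_mu < np.median(base_mu), 2.0, 1.0)
        p_cell = config.missing_rate * w / w.mean()
        drop = rng.random((n_prot, n_samples)) < p_cell[:, None]
        counts[drop] = 0

    # --- taxonomy assignment ---------------------------------------------
    lowest = np.full(n_prot, "species", dtype=object)
    if config.frac_unassigned_species > 0:
        unassigned = rng.random(n_prot) < config.frac_unassigned_species
        to_family = rng.random(n_prot) < 1.0 / 3.0
        lowest[unassigned & ~to_family] = "genus"
        lowest[unassigned & to_family] = "family"
    tax_rows = []
    for i, pid in enumerate(protein_ids):
        t = protein_taxon[i]
        rank = lowest[i]
        tax_rows.append(
            {
                "protein_id": pid,
                "species": t if rank == "species" else np.nan,
                "genus": genus_of[t] if rank in ("species", "genus") else np.nan,
                "family": family_of[t],
                "lowest_rank": rank,
            }
        )
    tax_table = pd.DataFrame(tax_rows).set_index("protein_id")

    counts_df = pd.DataFrame(
        counts, index=pd.Index(protein_ids, name="protein_id"), columns=samples
    )
    lengths_s = pd.Series(lengths, index=counts_df.index, name="protein_length_aa")
    scm = SpectralCountMatrix(counts=counts_df, lengths=lengths_s, phenotypes=phenotypes)
    taxmap = TaxonomyMap(table=tax_table)
    planted = pd.DataFrame(
        {
            "taxon": protein_taxon,
            "mu": base_mu,
            "phi": phi_per_protein,
            "a": a_per_protein,
            "length": lengths,
        },
        index=counts_df.index,
    )
    truth = GroundTruth(
        da_taxa=da_taxa,
        da_effects=da_effects,
        module_membership=module_membership,
        planted_params=planted,
    )
    return scm, taxmap, truth


def write_dataset(
    outdir: str | Path,
    scm: SpectralCountMatrix,
    taxmap: TaxonomyMap,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write counts TSV (+length, +lineage), samples TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lineage = [taxmap.lineage_string(p) for p in scm.counts.index]
    counts_out = scm.counts.copy()
    counts_out.insert(0, "lineage", lineage)
    counts_out.insert(0, "protein_length_aa", scm.lengths)
    paths = {"counts": outdir / "counts.tsv", "samples": outdir / "samples.tsv"}
    counts_out.to_csv(paths["counts"], sep="\t")
    scm.phenotypes.to_frame().to_csv(paths["samples"], sep="\t")
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        payload = {
            "da_taxa": {c: sorted(s) for c, s in truth.da_taxa.items()},
            "da_effects": {t: [g, f] for t, (g, f) in truth.da_effects.items()},
            "module_membership": truth.module_membership,
            "planted_params": truth.planted_params.reset_index().to_dict(
                orient="list"
            ),
        }
        paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
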