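"""Protein- and taxon-level quantification.

Two parallel tracks, kept deliberately separate:

* protein track — spectral counts -> NSAF (length-normalized, per-sample
  sum 1) -> log2 -> downshifted-Gaussian imputation of missing values;
  used for clustering/heatmaps;
* taxon track — raw counts summed per lowest-assigned-rank taxon,
  low-count filtered, TMM-normalized; used for differential testing and
  network inference.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    NormalizationResult,
    SpectralCountMatrix,
    TaxonCountMatrix,
    TaxonomyMap,
)


def compute_nsaf(scm: SpectralCountMatrix) -> pd.DataFrame:
    """Normalized spectral abundance factor per protein and sample.

    NSAF_ij = (SpC_ij / L_i) / sum_k (SpC_kj / L_k); each nonzero sample
    column sums to 1.  All-zero columns stay all-zero (with a warning).
    """
    lengths = scm.lengths.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive for NSAF")
    saf = scm.counts.to_numpy(dtype=float) / lengths[:, None]
    col_sums = saf.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with all-zero counts: {list(scm.counts.columns[zero_cols])}",
            stacklevel=2,
        )
        col_sums = np.where(zero_cols, 1.0, col_sums)
    nsaf = saf / col_sums
    return pd.DataFrame(nsaf, index=scm.counts.index, columns=scm.counts.columns)


def log2_transform_impute(
    nsaf: pd.DataFrame,
    downshift: float = 1.8,
    width: float = 0.3,
    seed=None,
) -> pd.DataFrame:
    """log2-transform NSAF values and impute zeros from a downshifted Gaussian.

    Zeros are treated as missing (below detection limit).  Per sample,
    missing entries are drawn from Normal(m - downshift*s, (width*s)^2)
    where m, s are the mean and SD of that sample's observed log2 values —
    the convention proteomics tools use to mimic the left tail of the
    intensity distribution.
    """
    if downshift < 0:
        raise ValueError("downshift must be >= 0")
    if width <= 0:
        raise ValueError("width must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(nsaf.shape, dtype=float)
    vals = nsaf.to_numpy(dtype=float)
    for j, col in enumerate(nsaf.columns):
        observed = vals[:, j] > 0
        if observed.sum() < 3:
            raise ValueError(
                f"sample {col!r} has {int(observed.sum())} observed values; "
                "need >= 3 to estimate imputation moments"
            )
        logs = np.log2(vals[observed, j])
        m, s = logs.mean(), logs.std(ddof=1)
        out[observed, j] = logs
        n_missing = int((~observed).sum())
        if n_missing:
            out[~observed, j] = rng.normal(m - downshift * s, width * s, n_missing)
    return pd.DataFrame(out, index=nsaf.index, columns=nsaf.columns)


def aggregate_to_taxa(
    scm: SpectralCountMatrix, taxmap: TaxonomyMap
) -> TaxonCountMatrix:
    """Sum protein counts per (lowest-assigned-rank taxon, sample).

    A protein assigned only at genus rank aggregates into a genus-level
    taxon, distinct from any species-level taxon of the same genus; the
    rank used is recorded per taxon.
    """
    missing = [p for p in scm.counts.index if p not in taxmap]
    if missing:
        raise KeyError(f"proteins absent from taxonomy map: {missing[:5]}")
    keys = []
    for pid in scm.counts.index:
        rank, name = taxmap.taxon_of(pid)
        keys.append((rank, name))
    key_index = pd.MultiIndex.from_tuples(keys, names=["rank", "taxon"])
    grouped = scm.counts.groupby(key_index).sum()
    # stable taxon ids: the name itself, qualified by rank above species
    taxon_ids = [
        name if rank == "species" else f"{rank}:{name}"
        for rank, name in grouped.index
    ]
    ranks = pd.Series(
        [rank for rank, _ in grouped.index], index=taxon_ids, name="rank"
    )
    counts = pd.DataFrame(
        grouped.to_numpy(), index=pd.Index(taxon_ids, name="taxon_id"),
        columns=scm.counts.columns,
    ).sort_index()
    ranks = ranks.sort_index()
    return TaxonCountMatrix(counts=counts, ranks=ranks, phenotypes=scm.phenotypes)


def filter_low_counts(
    tcm: TaxonCountMatrix, min_count: int = 5, min_samples: int = 2
) -> TaxonCountMatrix:
    """Drop taxa without >= ``min_count`` counts in >= ``min_samples`` samples.

    The default (5 counts, 2 samples) removes any taxon whose counts fall
    below 5 in all samples but one.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = (tcm.counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-count filter removed every taxon", stacklevel=2)
    return TaxonCountMatrix(
        counts=tcm.counts.loc[keep],
        ranks=tcm.ranks.loc[keep],
        phenotypes=tcm.phenotypes,
    )


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Trimmed-mean-of-M factor of one sample against the reference."""
    both = (obs > 0) & (ref > 0)
    o, r = obs[both], ref[both]
    M = np.log2((o / n_obs) / (r / n_ref))
    A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse asymptotic (delta-method) variance weights
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0, M, A
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not keep.any():
        return 1.0, M, A
    f = 2.0 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    if not np.isfinite(f):
        f = 1.0
    return float(f), M, A


def tmm_normalize(
    tcm: TaxonCountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """Trimmed-mean-of-M-values normalization across samples.

    Per sample j versus a reference r, log-ratios M_g and log-averages A_g
    are computed over taxa nonzero in both, doubly trimmed (``trim_m`` of
    each M tail, ``trim_a`` of each A tail), and averaged with inverse
    asymptotic-variance weights.  The reference is the sample whose
    upper-quartile count fraction is closest to the mean.  Returns both the
    pure TMM component and the effective (library-size-included) factors,
    each rescaled to geometric mean 1.
    """
    if tcm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    counts = tcm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(tcm.counts.columns[lib == 0])
        raise ValueError(f"samples with zero library size: {bad}")
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    tmm = np.ones(counts.shape[1])
    M_all: dict[str, np.ndarray] = {}
    A_all: dict[str, np.ndarray] = {}
    for j, col in enumerate(tcm.counts.columns):
        if j == ref_j:
            continue
        tmm[j], M_all[col], A_all[col] = _tmm_pair(
            counts[:, j], counts[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a
        )
    tmm /= np.exp(np.mean(np.log(tmm)))
    eff = lib * tmm
    eff /= np.exp(np.mean(np.log(eff)))
    cols = tcm.counts.columns
    return NormalizationResult(
        factors=pd.Series(eff, index=cols, name="factor"),
        tmm=pd.Series(tmm, index=cols, name="tmm"),
        lib_sizes=pd.Series(lib, index=cols, name="lib_size"),
        reference=str(cols[ref_j]),
        trim_m=trim_m,
        trim_a=trim_a,
        M=M_all,
        A=A_all,
    )


def rescale_counts(tcm: TaxonCountMatrix, norm: NormalizationResult) -> pd.DataFrame:
    """Counts divided by the effective normalization factor of their sample."""
    return tcm.counts / norm.factors.reindex(tcm.counts.columns)
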