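"""Low-expressor filtering and normalization: CPM, TMM scaling factors,
DESeq-style median-of-ratios size factors, and TPM.

TMM (trimmed mean of M-values) follows the published description: for
each sample against a reference, gene-wise log2 ratios of library-scaled
proportions (M) and mean log2 abundances (A) are computed over genes
positive in both samples, doubly trimmed (30% of M from each tail, 5% of
A from each tail by default), and combined as a weighted mean with
inverse asymptotic-variance weights; the scaling factor is 2 to that
mean, and factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MirCountMatrix

__all__ = [
    "NormFactors",
    "cpm",
    "filter_low_expressors",
    "tmm_factors",
    "median_of_ratios_factors",
    "tpm_normalize",
]


@dataclass
class NormFactors:
    """Per-sample scaling factors plus the library sizes they modify.

    The effective library size of sample j is ``lib_sizes[j] * factors[j]``.
    """

    method: str  # {tmm, median_of_ratios, none}
    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.method not in ("tmm", "median_of_ratios", "none"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        """Depth each sample is scaled by.

        TMM factors modify the raw library size (effective = lib ×
        factor); median-of-ratios size factors already absorb depth, so
        the effective size is the factor times the geometric-mean
        library size (a constant that keeps CPM on the usual scale).
        """
        if self.method == "median_of_ratios":
            geo = math.exp(np.mean(np.log(self.lib_sizes.to_numpy(dtype=float))))
            return self.factors * geo
        return self.lib_sizes * self.factors

    @property
    def offsets(self) -> np.ndarray:
        """Log effective library sizes — GLM offsets."""
        return np.log(self.effective_lib_sizes.to_numpy(dtype=float))


def _as_counts_df(counts: pd.DataFrame | MirCountMatrix) -> pd.DataFrame:
    return counts.counts if isinstance(counts, MirCountMatrix) else counts


def cpm(
    counts: pd.DataFrame | MirCountMatrix,
    factors: NormFactors | None = None,
    log2: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million, optionally on effective (factor-scaled) library sizes.

    Without factors each column sums to 1e6. With ``log2=True`` returns
    log2(CPM) after adding ``prior_count`` to counts (and twice the
    prior to the library size, keeping values finite at zero counts).
    """
    df = _as_counts_df(counts)
    if factors is not None:
        lib = factors.effective_lib_sizes.reindex(df.columns).to_numpy(dtype=float)
    else:
        lib = df.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = [c for c, s in zip(df.columns, lib) if s <= 0]
        raise ValueError(f"zero library size for samples: {bad}")
    if log2:
        adj = df.to_numpy(dtype=float) + prior_count
        vals = np.log2(adj * 1e6 / (lib + 2 * prior_count))
    else:
        vals = df.to_numpy(dtype=float) * 1e6 / lib
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def filter_low_expressors(
    counts: MirCountMatrix,
    cpm_threshold: float = 0.5,
    min_samples_exceeding: int = 2,
) -> tuple[MirCountMatrix, list[str]]:
    """Drop miRs not reaching ``cpm_threshold`` CPM in at least
    ``min_samples_exceeding`` samples (default: 0.5 CPM in more than one
    sample). CPM here uses raw library sizes — filtering precedes factor
    computation. The dropped ids are returned for the preferential-
    expression stage, where one-compartment expression is informative.
    """
    if cpm_threshold < 0:
        raise ValueError("cpm_threshold must be >= 0")
    n_samples = counts.counts.shape[1]
    if min_samples_exceeding > n_samples:
        raise ValueError(
            f"min_samples_exceeding={min_samples_exceeding} exceeds sample count {n_samples}"
        )
    rates = cpm(counts)
    keep = (rates >= cpm_threshold).sum(axis=1) >= min_samples_exceeding
    kept = MirCountMatrix(counts.counts.loc[keep], counts.samples)
    dropped = list(counts.counts.index[~keep])
    return kept, dropped


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper quartile of scaled counts is closest to the mean."""
    uq = np.quantile(counts / lib_sizes, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: pd.DataFrame | MirCountMatrix,
    reference: str | int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    ``reference`` may be a sample id, a column position, or None for the
    automatic upper-quartile choice. Factors are rescaled so their
    geometric mean is exactly 1.
    """
    df = _as_counts_df(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    y = df.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if reference is None:
        ref = _choose_reference(y, lib)
    elif isinstance(reference, str):
        ref = list(df.columns).index(reference)
    else:
        ref = int(reference)

    log_factors = np.zeros(df.shape[1])
    for j in range(df.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors /= math.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormFactors(
        method="tmm",
        factors=pd.Series(factors, index=df.columns),
        lib_sizes=pd.Series(lib, index=df.columns),
    )


def _tmm_pair(
    obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive gene with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic variance of M under binomial sampling; weights are its inverse
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m[keep]) / np.sum(w))
    if abs(f) < 1e-10:
        f = 0.0
    return f


def median_of_ratios_factors(counts: pd.DataFrame | MirCountMatrix) -> NormFactors:
    """DESeq-style size factors: per sample, the median ratio of counts to
    per-gene geometric means over genes positive in all samples; rescaled
    to geometric mean 1."""
    df = _as_counts_df(counts)
    y = df.to_numpy(dtype=float)
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene positive in all samples; size factors undefined")
    yp = y[all_pos]
    geo = np.exp(np.mean(np.log(yp), axis=1))
    sf = np.median(yp / geo[:, None], axis=0)
    sf /= math.exp(np.mean(np.log(sf)))  # geometric mean 1
    lib = y.sum(axis=0)
    return NormFactors(
        method="median_of_ratios",
        factors=pd.Series(sf, index=df.columns),
        lib_sizes=pd.Series(lib, index=df.columns),
    )


def tpm_normalize(
    counts: pd.DataFrame | MirCountMatrix,
    lengths: pd.Series,
) -> pd.DataFrame:
    """Transcripts per million: length-rate columns rescaled to sum 1e6.

    ``lengths`` is nt per miR (annotation span, end − start + 1), indexed
    like the count matrix rows.
    """
    df = _as_counts_df(counts)
    lens = lengths.reindex(df.index)
    if lens.isna().any():
        missing = list(df.index[lens.isna()])
        raise ValueError(f"no length for miRs: {missing}")
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0])
        raise ValueError(f"non-positive lengths for miRs: {bad}")
    rate = df.to_numpy(dtype=float) / lens.to_numpy(dtype=float)[:, None]
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        bad = [c for c, s in zip(df.columns, colsum) if s <= 0]
        raise ValueError(f"all-zero samples: {bad}")
    return pd.DataFrame(rate * 1e6 / colsum, index=df.index, columns=df.columns)
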