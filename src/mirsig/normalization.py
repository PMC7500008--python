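"""Between-sample normalization of miRNA read counts.

Implements the four classical library-size normalization strategies compared
in the analysis — trimmed mean of M-values (TMM), relative log expression
(RLE, median-ratio), upper quartile (UQ) and total count (TC) — plus the CPM
transform

    CPM[m, s] = counts[m, s] / lib_size[s] * 1e6 / factor[s],

expression filtering, and cross-method concordance diagnostics.

TMM follows the classical definition: per-sample log2 ratios (M) and average
log2 abundances (A) against a reference sample, double trimming (30% on M,
5% on A by rank), inverse asymptotic-variance weights, and a final rescaling
of the factor vector to geometric mean 1.  The reference defaults to the
sample whose 75th percentile of counts/library-size is closest to the mean of
that quantity across samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import AlignmentError, NormalizationError, ZeroLibraryError
from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormFactors",
    "ExpressionMatrix",
    "NormComparison",
    "lib_sizes",
    "tmm_factors",
    "rle_factors",
    "uq_factors",
    "tc_factors",
    "factors_by_method",
    "cpm",
    "filter_by_cpm",
    "compare_normalizations",
]

METHODS = ("TMM", "RLE", "UQ", "TC")


@dataclass(frozen=True)
class NormFactors:
    """Per-sample positive scaling factors from one normalization method."""

    method: str
    sample_ids: tuple[str, ...]
    factors: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if f.shape != (len(self.sample_ids),):
            raise AlignmentError("factors not aligned to sample ids")
        if not (np.isfinite(f).all() and (f > 0).all()):
            raise NormalizationError(f"{self.method}: non-positive or non-finite factor")

    def to_series(self) -> pd.Series:
        return pd.Series(self.factors, index=list(self.sample_ids), name="factor")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values (CPM units), miRNAs x samples."""

    values: pd.DataFrame
    norm_method: str

    @property
    def mirna_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def subset_mirnas(self, mirna_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(mirna_ids)], self.norm_method)


@dataclass(frozen=True)
class NormComparison:
    """Pairwise concordance between normalization methods.

    ``spearman_r`` maps a method pair to the Spearman correlation of the
    vectorized log2(CPM + 0.5) matrices; ``max_abs_dlog2_factor`` to the
    largest per-sample absolute log2 factor ratio.
    """

    methods: tuple[str, ...]
    spearman_r: dict[tuple[str, str], float]
    max_abs_dlog2_factor: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method_a": a,
                "method_b": b,
                "spearman_r": self.spearman_r[(a, b)],
                "max_abs_dlog2_factor": self.max_abs_dlog2_factor[(a, b)],
            }
            for a, b in itertools.combinations_with_replacement(self.methods, 2)
        ]
        return pd.DataFrame(rows)


def lib_sizes(counts: CountMatrix) -> np.ndarray:
    """Per-sample total read counts (column sums)."""
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(counts.sample_ids, totals) if t <= 0]
        raise ZeroLibraryError(f"samples with zero total read count: {bad}")
    return totals


def _geomean_one(factors: np.ndarray, method: str) -> np.ndarray:
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise NormalizationError(f"{method}: degenerate factors before rescaling")
    return factors / np.exp(np.mean(np.log(factors)))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (before rescaling)."""
    positive = (obs > 0) & (ref > 0)
    if not positive.any():
        raise NormalizationError("no miRNA with positive counts in both sample and reference")
    o = obs[positive].astype(float)
    r = ref[positive].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:  # identical composition: avoid trimming noise
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n - np.floor(n * trim_m)
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n - np.floor(n * trim_a)
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("TMM trimming removed all miRNAs; factor set to 1")
        return 1.0
    inv_w = 1.0 / w[keep]
    return float(2 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w)))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1."""
    y = counts.values.astype(float)
    totals = lib_sizes(counts)
    if ref is None:
        q75 = np.quantile(y / totals, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref not in counts.sample_ids:
            raise AlignmentError(f"reference sample {ref!r} not in matrix")
        ref_idx = counts.sample_ids.index(ref)
    f = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        f[j] = _tmm_pair_factor(y[:, j], y[:, ref_idx], totals[j], totals[ref_idx], trim_m, trim_a)
    return NormFactors("TMM", tuple(counts.sample_ids), _geomean_one(f, "TMM"))


def rle_factors(counts: CountMatrix) -> NormFactors:
    """Relative-log-expression (median-ratio) factors, geometric mean 1."""
    y = counts.values.astype(float)
    totals = lib_sizes(counts)
    all_positive = (y > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError("RLE requires at least one miRNA positive in every sample")
    sub = y[all_positive]
    ref = np.exp(np.mean(np.log(sub), axis=1))  # per-row geometric mean
    size = np.median(sub / ref[:, None], axis=0)
    return NormFactors("RLE", tuple(counts.sample_ids), _geomean_one(size / totals, "RLE"))


def uq_factors(counts: CountMatrix, quantile: float = 0.75) -> NormFactors:
    """Upper-quartile factors: quantile of each sample's nonzero counts over its library size."""
    y = counts.values.astype(float)
    totals = lib_sizes(counts)
    f = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        nz = y[y[:, j] > 0, j]
        if nz.size == 0:
            raise NormalizationError(f"UQ: sample {counts.sample_ids[j]!r} has no nonzero count")
        f[j] = np.quantile(nz, quantile) / totals[j]
    return NormFactors("UQ", tuple(counts.sample_ids), _geomean_one(f, "UQ"))


def tc_factors(counts: CountMatrix) -> NormFactors:
    """Total-count normalization: all factors 1 (library size alone rescales)."""
    lib_sizes(counts)  # still reject zero-total samples
    return NormFactors("TC", tuple(counts.sample_ids), np.ones(len(counts.sample_ids)))


def factors_by_method(counts: CountMatrix, method: str) -> NormFactors:
    """Dispatch on a method name from {TMM, RLE, UQ, TC}."""
    method = method.upper()
    dispatch = {"TMM": tmm_factors, "RLE": rle_factors, "UQ": uq_factors, "TC": tc_factors}
    if method not in dispatch:
        raise NormalizationError(f"unknown normalization method {method!r}")
    return dispatch[method](counts)


def cpm(counts: CountMatrix, factors: NormFactors) -> ExpressionMatrix:
    """Counts per million with normalization factors.

    value[m, s] = counts[m, s] / lib_size[s] * 1e6 / factor[s]
    """
    if tuple(counts.sample_ids) != tuple(factors.sample_ids):
        raise AlignmentError("normalization factors not aligned to count matrix samples")
    totals = lib_sizes(counts)
    values = counts.values / (totals * factors.factors)[None, :] * 1e6
    df = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(df, factors.method)


def filter_by_cpm(
    expr: ExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> list[str]:
    """miRNA ids whose CPM reaches ``min_cpm`` in at least
    ceil(min_fraction * n_samples) samples, in matrix order."""
    v = expr.values.to_numpy()
    needed = int(np.ceil(min_fraction * v.shape[1]))
    passing = (v >= min_cpm).sum(axis=1) >= needed
    return [m for m, ok in zip(expr.mirna_ids, passing) if ok]


def compare_normalizations(
    counts: CountMatrix, methods: tuple[str, ...] = METHODS
) -> NormComparison:
    """Concordance diagnostics between normalization methods.

    For every method pair: the Spearman correlation between the vectorized
    log2(CPM + 0.5) matrices, and the largest per-sample absolute log2 ratio
    of factors.  A divergent total-count row flags composition bias.
    """
    factor_sets = {m: factors_by_method(counts, m) for m in methods}
    logcpm = {
        m: np.log2(cpm(counts, f).values.to_numpy() + 0.5).ravel()
        for m, f in factor_sets.items()
    }
    r: dict[tuple[str, str], float] = {}
    dlog: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations_with_replacement(methods, 2):
        if a == b:
            rho = 1.0
        else:
            rho = float(spearmanr(logcpm[a], logcpm[b]).statistic)
        delta = float(
            np.max(np.abs(np.log2(factor_sets[a].factors / factor_sets[b].factors)))
        )
        for key in ((a, b), (b, a)):
            r[key] = rho
            dlog[key] = delta
    return NormComparison(tuple(methods), r, dlog)
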