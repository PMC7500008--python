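"""Per-sample lymphatic-dissemination signature scoring and correlation structure.

Given two disjoint miRNA modules — N1-miRs (elevated in node-positive
tumors) and N0-miRs (elevated in node-negative tumors) — each sample is
scored by the difference of its average centered log2 expression over the
two modules (the per-sample "delta average log2 fold change").  Samples with
a negative score form group G0, positive scores form G1, and the enrichment
of G1 within the N1 cohort is assessed by a two-sided Fisher exact test on
the G x N contingency table.  The module structure itself is summarized by
pairwise Spearman correlations (within each module and across modules) and
by per-miRNA correlations with node status and Gleason score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, spearmanr

from .errors import (
    ConstantInputError,
    DomainError,
    GleasonInsufficientError,
    GroupSizeError,
    SetOverlapError,
)
from .normalization import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureResult",
    "CorrelationSummary",
    "centered_log_expression",
    "sample_signature_score",
    "assign_groups",
    "fisher_exact_2x2",
    "spearman",
    "correlation_structure",
    "phenotype_correlations",
    "evaluate_signature",
]


@dataclass(frozen=True)
class SignatureResult:
    """Signature scores, G0/G1 assignment and enrichment versus node status."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray
    groups: tuple[str, ...]  # "G0" / "G1" per sample ("dropped" under tie=drop)
    contingency: np.ndarray  # rows G0, G1; columns N0, N1
    fisher_p: float

    def to_frame(self, node_status: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.scores, "group": self.groups}
        )
        if node_status is not None:
            df["node_status"] = list(node_status)
        return df


@dataclass(frozen=True)
class CorrelationSummary:
    """Spearman correlation structure of the two signature modules."""

    pairwise_r: pd.DataFrame  # square, signature miRNAs
    avg_within_N1: float
    avg_within_N0: float
    avg_cross: float
    node_r: pd.Series  # per-miRNA Spearman r vs the 0/1 node feature
    node_p: pd.Series
    gleason_r: pd.Series | None = None
    gleason_p: pd.Series | None = None
    gleason_vs_node_r: float = float("nan")
    gleason_vs_node_p: float = float("nan")


def centered_log_expression(
    expr: ExpressionMatrix | pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Row-centered log2 expression: log2(CPM + pc) minus its per-miRNA mean.

    Each row has mean zero, so a sample's value is its log2 deviation from
    the cohort-wide (geometric-mean) reference of that miRNA.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    logv = np.log2(df.to_numpy(dtype=float) + pseudocount)
    centered = logv - logv.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=df.index, columns=df.columns)


def _check_sets(cl: pd.DataFrame, n1_set: Sequence[str], n0_set: Sequence[str]) -> None:
    n1_set, n0_set = list(n1_set), list(n0_set)
    if not n1_set or not n0_set:
        raise GroupSizeError("both signature sets must be non-empty")
    overlap = set(n1_set) & set(n0_set)
    if overlap:
        raise SetOverlapError(f"signature sets overlap: {sorted(overlap)}")
    missing = [m for m in (*n1_set, *n0_set) if m not in cl.index]
    if missing:
        raise KeyError(f"signature miRNAs absent from matrix: {missing}")


def sample_signature_score(
    cl: pd.DataFrame, n1_set: Sequence[str], n0_set: Sequence[str]
) -> pd.Series:
    """Delta average log2 FC per sample: mean over N1-miRs minus mean over N0-miRs."""
    _check_sets(cl, n1_set, n0_set)
    score = cl.loc[list(n1_set)].mean(axis=0) - cl.loc[list(n0_set)].mean(axis=0)
    return score.rename("score")


def assign_groups(scores: Sequence[float], tie: str = "G0") -> list[str]:
    """Dichotomize scores: negative -> G0, positive -> G1.

    An exactly-zero score follows the ``tie`` policy ("G0", "G1" or "drop",
    default G0 with a logged warning).
    """
    if tie not in ("G0", "G1", "drop"):
        raise ValueError(f"unknown tie policy {tie!r}")
    out = []
    for s in np.asarray(scores, dtype=float):
        if s < 0:
            out.append("G0")
        elif s > 0:
            out.append("G1")
        else:
            logger.warning("signature score exactly 0; tie policy %r applied", tie)
            out.append("dropped" if tie == "drop" else tie)
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p of a 2x2 table (point-probability rule)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.number):
        raise DomainError("table cells must be non-negative integers")
    if t.sum() == 0:
        raise DomainError("table total must be positive")
    return float(fisher_exact(t.astype(int)).pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and t-approximate p.

    Raises :class:`ConstantInputError` when either vector is constant
    (the rank correlation is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise GroupSizeError("spearman requires two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ConstantInputError("constant vector: Spearman r undefined")
    res = spearmanr(x, y)
    r = float(res.statistic)
    p = 0.0 if abs(r) >= 1.0 - 1e-15 else float(res.pvalue)
    return r, p


def _node_feature(node_status: Sequence[str]) -> np.ndarray:
    return (np.asarray(node_status) == "N1").astype(float)


def correlation_structure(
    expr: ExpressionMatrix | pd.DataFrame,
    n1_set: Sequence[str],
    n0_set: Sequence[str],
) -> tuple[pd.DataFrame, float, float, float]:
    """Pairwise Spearman correlations of the signature miRNAs across samples.

    Returns the full correlation matrix plus the averages over unordered
    within-N1 pairs, within-N0 pairs, and all cross-set pairs.  Constant
    rows are dropped with a warning.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    _check_sets(df, n1_set, n0_set)
    members = list(n1_set) + list(n0_set)
    sub = df.loc[members]
    keep = [m for m in members if np.unique(sub.loc[m].to_numpy()).size > 1]
    dropped = sorted(set(members) - set(keep))
    if dropped:
        logger.warning("dropping constant signature rows from correlations: %s", dropped)
    sub = sub.loc[keep]
    if len(keep) < 2 or sub.shape[1] < 3:
        raise GroupSizeError("too few usable miRNAs/samples for correlation structure")
    stat = spearmanr(sub.to_numpy().T).statistic
    if np.ndim(stat) == 0:  # scipy returns a scalar for exactly two variables
        rmat = np.array([[1.0, float(stat)], [float(stat), 1.0]])
    else:
        rmat = np.asarray(stat)
    pair_r = pd.DataFrame(rmat, index=keep, columns=keep)
    n1_kept = [m for m in n1_set if m in keep]
    n0_kept = [m for m in n0_set if m in keep]

    def _avg(pairs):
        vals = [pair_r.loc[a, b] for a, b in pairs]
        return float(np.mean(vals)) if vals else float("nan")

    avg_n1 = _avg(list(combinations(n1_kept, 2)))
    avg_n0 = _avg(list(combinations(n0_kept, 2)))
    avg_cross = _avg(list(product(n1_kept, n0_kept)))
    return pair_r, avg_n1, avg_n0, avg_cross


def phenotype_correlations(
    expr: ExpressionMatrix | pd.DataFrame,
    node_status: Sequence[str],
    gleason: Sequence[float] | None = None,
    mirna_ids: Sequence[str] | None = None,
    require_gleason: bool = False,
) -> CorrelationSummary:
    """Correlate miRNA expression with node status and (optionally) Gleason.

    Node status is encoded 0/1; Gleason correlations use only samples with a
    score and need at least 3 of them (:class:`GleasonInsufficientError` when
    ``require_gleason`` and fewer are present; otherwise the Gleason block is
    skipped with a warning).  Also reports the Gleason-vs-node correlation.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if mirna_ids is not None:
        df = df.loc[list(mirna_ids)]
    node = _node_feature(node_status)
    if np.unique(node).size < 2:
        raise ConstantInputError("node status is constant; correlation undefined")
    node_r, node_p = {}, {}
    for mid in df.index:
        v = df.loc[mid].to_numpy(dtype=float)
        try:
            node_r[mid], node_p[mid] = spearman(v, node)
        except ConstantInputError:
            logger.warning("constant expression for %s; node correlation skipped", mid)
            node_r[mid], node_p[mid] = float("nan"), float("nan")

    gl_r = gl_p = None
    gvn_r = gvn_p = float("nan")
    if gleason is not None:
        g = np.asarray(gleason, dtype=float)
        have = ~np.isnan(g)
        if have.sum() < 3:
            if require_gleason:
                raise GleasonInsufficientError(
                    f"only {int(have.sum())} samples carry a Gleason score (need >= 3)"
                )
            logger.warning("fewer than 3 Gleason scores; Gleason block skipped")
        else:
            gl_r, gl_p = {}, {}
            for mid in df.index:
                v = df.loc[mid].to_numpy(dtype=float)[have]
                try:
                    gl_r[mid], gl_p[mid] = spearman(v, g[have])
                except ConstantInputError:
                    gl_r[mid], gl_p[mid] = float("nan"), float("nan")
            try:
                gvn_r, gvn_p = spearman(g[have], node[have])
            except ConstantInputError:
                logger.warning("node status constant among Gleason-scored samples")
            gl_r = pd.Series(gl_r, name="gleason_r")
            gl_p = pd.Series(gl_p, name="gleason_p")
    return CorrelationSummary(
        pairwise_r=pd.DataFrame(),
        avg_within_N1=float("nan"),
        avg_within_N0=float("nan"),
        avg_cross=float("nan"),
        node_r=pd.Series(node_r, name="node_r"),
        node_p=pd.Series(node_p, name="node_p"),
        gleason_r=gl_r,
        gleason_p=gl_p,
        gleason_vs_node_r=gvn_r,
        gleason_vs_node_p=gvn_p,
    )


def evaluate_signature(
    expr: ExpressionMatrix | pd.DataFrame,
    node_status: Sequence[str],
    n1_set: Sequence[str],
    n0_set: Sequence[str],
    pseudocount: float = 0.5,
    tie: str = "G0",
) -> SignatureResult:
    """Score samples, assign G0/G1 and test enrichment against node status."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    cl = centered_log_expression(df, pseudocount=pseudocount)
    scores = sample_signature_score(cl, n1_set, n0_set)
    groups = assign_groups(scores.to_numpy(), tie=tie)
    node = np.asarray(node_status)
    table = np.zeros((2, 2), dtype=int)
    for grp, ns in zip(groups, node):
        if grp == "dropped":
            continue
        table[0 if grp == "G0" else 1, 0 if ns == "N0" else 1] += 1
    p = fisher_exact_2x2(table)
    return SignatureResult(
        sample_ids=tuple(str(c) for c in df.columns),
        scores=scores.to_numpy(),
        groups=tuple(groups),
        contingency=table,
        fisher_p=p,
    )
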