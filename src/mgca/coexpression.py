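"""Pearson correlation, co-expression coefficients (CEC) and curve diagnostics.

The correlation coefficient (CC) of a gene pair is the Pearson
product-moment correlation of the two genes' expression vectors across
samples.  The co-expression coefficient of a gene with a gene set is the
mean CC over the set's members,

    CEC(g, S) = (1/M) * sum_{i=1..M} CC(g, s_i),      M = |S|,

and of two gene sets the mean over all cross pairs,

    CEC(A, B) = (1/(N*M)) * sum_{k=1..N} sum_{i=1..M} CC(a_k, b_i).

Self-pairs (CC = 1 by definition) are excluded everywhere and the
denominator adjusted, so a gene's membership in the set it is scored
against never inflates the mean.

A :class:`CCMatrix` caches the full gene-by-gene correlation matrix once;
every CEC afterwards is a vectorized mean over its columns, which is
contract-identical to the explicit pairwise loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import RankedGeneList
from .io import ExpressionMatrix, GeneSet, MgcaDataError

logger = logging.getLogger("mgca")

__all__ = [
    "CCMatrix",
    "CECProfile",
    "NoiseReducedCurve",
    "pearson_cc",
    "cec_gene_vs_set",
    "cec_set_vs_set",
    "noise_reduced_curve",
    "cubic_fit_r2",
    "cc_matrix_subsample",
]


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two sample vectors.

    Both vectors must have the same length (>= 2) and nonzero variance;
    zero-variance genes are expected to have been filtered out upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise MgcaDataError("pearson_cc needs two equal-length vectors of size >= 2")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise MgcaDataError("pearson_cc undefined for a zero-variance vector")
    return float(np.clip((xd @ yd) / np.sqrt(sx * sy), -1.0, 1.0))


@dataclass
class CCMatrix:
    """Cached gene-by-gene Pearson correlation matrix.

    Built once per expression matrix (optionally after a log2(x+1)
    transform) and reused by every permutation; symmetric with unit
    diagonal.
    """

    gene_ids: list[str]
    values: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.gene_ids)}
        if self.values.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise MgcaDataError("CC matrix shape does not match gene list")

    @classmethod
    def from_expression(
        cls, matrix: ExpressionMatrix, log_transform: bool = False
    ) -> "CCMatrix":
        vals = matrix.values
        if log_transform:
            vals = np.log2(vals + 1.0)
        sd = vals.std(axis=1)
        if (sd == 0).any():
            bad = [matrix.gene_ids[i] for i in np.flatnonzero(sd == 0)]
            raise MgcaDataError(
                f"zero-variance genes must be filtered before correlation: {bad[:10]}"
            )
        cc = np.corrcoef(vals)
        cc = (cc + cc.T) / 2.0  # enforce exact symmetry (corrcoef is ~1e-16 off)
        np.clip(cc, -1.0, 1.0, out=cc)
        np.fill_diagonal(cc, 1.0)
        return cls(list(matrix.gene_ids), cc)

    def cc(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def indices_of(self, genes: GeneSet | list[str]) -> np.ndarray:
        return np.array([self.index[g] for g in genes], dtype=np.int64)

    def cec_all_genes(self, member_idx: np.ndarray) -> np.ndarray:
        """CEC of every gene in the matrix with the set given by column indices.

        Self-pairs are excluded: a gene that is itself a member averages over
        the remaining M-1 members.
        """
        m = len(member_idx)
        if m == 0:
            raise MgcaDataError("empty gene set")
        sums = self.values[:, member_idx].sum(axis=1)
        denom = np.full(len(self.gene_ids), m, dtype=float)
        sums[member_idx] -= 1.0  # remove each member's self CC
        denom[member_idx] -= 1.0
        if (denom == 0).any():
            raise MgcaDataError("CEC undefined: a gene's set reduces to itself")
        return sums / denom


def cec_gene_vs_set(gene: str, gene_set: GeneSet, cc_source: CCMatrix) -> float:
    """Mean CC of one gene with a gene set, self-pair excluded."""
    members = [g for g in gene_set if g != gene]
    if not members:
        raise MgcaDataError(
            f"CEC undefined: set {gene_set.name!r} holds only the gene itself"
        )
    row = cc_source.values[cc_source.index[gene]]
    idx = cc_source.indices_of(members)
    return float(row[idx].mean())


def cec_set_vs_set(a: GeneSet, b: GeneSet, cc_source: CCMatrix) -> float:
    """Mean CC over all cross pairs of two sets.

    When both arguments are the same set (by membership), self-pairs are
    excluded and the denominator becomes N*(N-1); shared genes between two
    different sets only drop their own self-pair.
    """
    ia = cc_source.indices_of(a)
    ib = cc_source.indices_of(b)
    block = cc_source.values[np.ix_(ia, ib)]
    shared = len(set(a.gene_ids) & set(b.gene_ids))
    total = float(block.sum()) - shared  # each shared gene contributes one CC=1 self-pair
    denom = len(ia) * len(ib) - shared
    if denom <= 0:
        raise MgcaDataError("CEC undefined: sets share all their (single) members")
    return total / denom


@dataclass
class CECProfile:
    """Per-gene CEC against one target set, aligned to a gene universe."""

    target_set: str
    gene_ids: list[str]
    cec: np.ndarray

    def __post_init__(self) -> None:
        self.cec = np.asarray(self.cec, dtype=float)
        if len(self.gene_ids) != self.cec.size:
            raise MgcaDataError("CEC profile length mismatch")
        if (np.abs(self.cec) > 1 + 1e-12).any():
            raise MgcaDataError("CEC values must lie in [-1, 1]")

    @classmethod
    def from_cc(cls, cc_source: CCMatrix, target: GeneSet) -> "CECProfile":
        idx = cc_source.indices_of(target)
        return cls(target.name, list(cc_source.gene_ids), cc_source.cec_all_genes(idx))

    def value(self, gene: str) -> float:
        return float(self.cec[self.gene_ids.index(gene)])

    def reorder(self, ranked: RankedGeneList) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self.cec[[pos[g] for g in ranked.order]]


@dataclass
class NoiseReducedCurve:
    """Moving average of per-gene CECs along a feature-ranked gene list.

    Point j is the mean CEC over ranks [j-k, j+k] intersected with the list,
    so each point averages at most 2k+1 genes (fewer near the ends).
    """

    feature_name: str
    half_window: int
    values: np.ndarray
    r2_cubic: float | None = None


def noise_reduced_curve(
    cec: CECProfile, ranked: RankedGeneList, k: int
) -> NoiseReducedCurve:
    """Smooth a CEC profile along a ranked list with a +/-k moving average."""
    g = len(ranked)
    if k < 1 or k >= g:
        raise MgcaDataError(f"half-window k={k} must satisfy 1 <= k < {g}")
    x = cec.reorder(ranked)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    j = np.arange(g)
    lo = np.maximum(j - k, 0)
    hi = np.minimum(j + k, g - 1)
    vals = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return NoiseReducedCurve(ranked.feature_name, k, vals)


def cubic_fit_r2(curve: NoiseReducedCurve | np.ndarray) -> float:
    """R^2 of an OLS cubic polynomial of curve value against rank.

    A constant curve has no variance to explain; its R^2 is defined as 0
    with a warning.
    """
    y = curve.values if isinstance(curve, NoiseReducedCurve) else np.asarray(curve, float)
    if y.size < 4:
        raise MgcaDataError("cubic fit needs at least 4 points")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        logger.warning("cubic_fit_r2: constant input, R^2 defined as 0")
        return 0.0
    x = np.arange(y.size, dtype=float)
    # scale rank to [-1, 1] for a well-conditioned Vandermonde system
    xs = 2.0 * x / (y.size - 1) - 1.0
    coef = np.polynomial.polynomial.polyfit(xs, y, 3)
    resid = y - np.polynomial.polynomial.polyval(xs, coef)
    return float(1.0 - (resid @ resid) / ss_tot)


def cc_matrix_subsample(
    cc_source: CCMatrix, ranked: RankedGeneList, stride: int = 100
) -> pd.DataFrame:
    """CC matrix of every stride-th gene along a ranked order.

    Returns a symmetric unit-diagonal DataFrame (gene IDs as labels) meant
    to be written to disk for external heatmap plotting.
    """
    if stride < 1 or stride >= len(ranked):
        raise MgcaDataError(f"stride={stride} must satisfy 1 <= stride < {len(ranked)}")
    picks = ranked.order[::stride]
    idx = cc_source.indices_of(picks)
    block = cc_source.values[np.ix_(idx, idx)]
    return pd.DataFrame(block, index=picks, columns=picks)


def write_cc_submatrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.index.name = "gene_id"
    df.to_csv(Path(path), sep=sep, float_format="%.6g", lineterminator="\n")
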