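"""geNorm expression-stability measure M, stepwise ranking, and pairwise variation V.

For two candidate genes j and k, the pairwise variation is the sample
standard deviation across samples of log2(q_j / q_k) — constant if the two
genes track each other perfectly. A gene's M value is its average pairwise
variation against every other candidate; lower M means more stable.
Ranking proceeds by stepwise exclusion of the highest-M gene until two
genes remain, which share the best rank (their mutual variation cannot be
attributed to either one).

The pairwise variation V(n/n+1) compares normalization factors built from
the n and n+1 most stable genes: V_n = SD of log2(NF_n / NF_{n+1}) across
samples. A V_n below the conventional 0.15 threshold means the (n+1)-th
gene adds nothing and n reference genes suffice.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import ValidationError
from .quantify import RelativeQuantityMatrix, normalization_factor

__all__ = [
    "GeNormResult",
    "PairwiseVariationSeries",
    "pairwise_gene_variation",
    "m_values",
    "rank_stepwise",
    "pairwise_variation_series",
    "GeNorm",
]

#: M values below this are conventionally regarded as stable expression
M_STABLE_THRESHOLD = 1.5

#: pairwise-variation cut-off below which an extra reference gene is unnecessary
V_THRESHOLD = 0.15


def _as_q(q) -> pd.DataFrame:
    df = q.q if isinstance(q, RelativeQuantityMatrix) else pd.DataFrame(q)
    arr = df.to_numpy(dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValidationError("quantities must be positive and finite")
    return df


def pairwise_gene_variation(q, j: str, k: str) -> float:
    """Sample SD across samples of log2(q_j / q_k)."""
    df = _as_q(q)
    if j == k:
        raise ValidationError("pairwise variation of a gene against itself is undefined")
    if df.shape[1] < 2:
        raise ValidationError("pairwise variation needs at least 2 samples")
    ratio = np.log2(df.loc[j].to_numpy(dtype=float)) - np.log2(df.loc[k].to_numpy(dtype=float))
    return float(np.std(ratio, ddof=1))


def m_values(q, gene_set: Sequence[str] | None = None) -> pd.Series:
    """geNorm M per gene: mean pairwise variation against all other genes.

    Vectorized through the sample covariance of log2 quantities:
    Var(L_j - L_k) = C_jj + C_kk - 2 C_jk.
    """
    df = _as_q(q)
    if gene_set is not None:
        df = df.loc[list(gene_set)]
    if df.shape[0] < 2:
        raise ValidationError("M values need at least 2 genes")
    if df.shape[1] < 2:
        raise ValidationError("M values need at least 2 samples")
    L = np.log2(df.to_numpy(dtype=float))
    C = np.cov(L, ddof=1)
    d = np.diag(C)
    var = np.clip(d[:, None] + d[None, :] - 2 * C, 0.0, None)
    sd = np.sqrt(var)
    k = df.shape[0]
    m = (sd.sum(axis=1)) / (k - 1)  # diagonal is zero
    return pd.Series(m, index=df.index, name="M")


@dataclass(frozen=True)
class GeNormResult:
    """Outcome of the stepwise geNorm ranking.

    ``m_values`` are the M values over the full candidate set;
    ``m_at_exclusion`` holds each gene's M at the step it was excluded
    (for the two final genes, their mutual pairwise variation).
    ``ranks`` assigns 1.5 to each gene of the tied best pair, then
    3, 4, ... to the remaining genes in reverse exclusion order.
    """

    m_values: pd.Series
    exclusion_order: tuple
    final_pair: tuple
    m_at_exclusion: pd.Series
    stable_threshold: float = M_STABLE_THRESHOLD

    @property
    def ranking(self) -> list:
        """Genes from most to least stable (final pair first, in gene-id order)."""
        return list(self.final_pair) + list(reversed(self.exclusion_order))

    @property
    def ranks(self) -> pd.Series:
        r = {g: 1.5 for g in self.final_pair}
        for i, g in enumerate(reversed(self.exclusion_order)):
            r[g] = float(i + 3)
        return pd.Series(r, name="rank").reindex(self.m_values.index)

    @property
    def stable(self) -> pd.Series:
        return (self.m_values < self.stable_threshold).rename("stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "M": self.m_values,
                "M_at_exclusion": self.m_at_exclusion.reindex(self.m_values.index),
                "rank": self.ranks,
                "stable": self.stable,
            }
        )


def rank_stepwise(q) -> GeNormResult:
    """Iteratively exclude the highest-M gene until the best pair remains.

    Ties on the maximal M are broken by excluding the lexicographically
    last gene id — an arbitrary but deterministic, recorded rule.
    """
    df = _as_q(q)
    if df.shape[0] < 3:
        raise ValidationError("stepwise geNorm ranking needs at least 3 genes")
    full_m = m_values(df)
    remaining = list(df.index)
    excluded: list = []
    m_at_exclusion: dict = {}
    while len(remaining) > 2:
        ms = m_values(df, remaining)
        worst = ms.max()
        gene = sorted(ms.index[ms == worst], key=str)[-1]
        m_at_exclusion[gene] = float(ms[gene])
        excluded.append(gene)
        remaining.remove(gene)
    final_ms = m_values(df, remaining)
    for g in remaining:
        m_at_exclusion[g] = float(final_ms[g])
    final_pair = tuple(sorted(remaining, key=str))
    return GeNormResult(
        m_values=full_m,
        exclusion_order=tuple(excluded),
        final_pair=final_pair,
        m_at_exclusion=pd.Series(m_at_exclusion, name="M_at_exclusion"),
    )


@dataclass(frozen=True)
class PairwiseVariationSeries:
    """V(n/n+1) values for n = 2 .. K-1 and the resulting optimal gene count.

    ``optimal_n`` is the smallest n with V_n strictly below the threshold,
    or None when every V_n is at or above it (no n suffices under the
    conventional rule; more genes, or judgement, are required).
    """

    v: pd.Series
    threshold: float = V_THRESHOLD

    @property
    def optimal_n(self) -> int | None:
        below = self.v[self.v < self.threshold]
        return int(below.index[0]) if len(below) else None

    def to_frame(self) -> pd.DataFrame:
        labels = [f"V{n}/{n + 1}" for n in self.v.index]
        return pd.DataFrame(
            {"pair": labels, "V": self.v.to_numpy(), "below_threshold": (self.v < self.threshold).to_numpy()},
            index=pd.Index(self.v.index, name="n"),
        )


def pairwise_variation_series(
    q,
    ranking: GeNormResult | Sequence[str],
    threshold: float = V_THRESHOLD,
) -> PairwiseVariationSeries:
    """Compute V(n/n+1) for normalization factors of the n most stable genes.

    ``ranking`` is either a :class:`GeNormResult` or an explicit gene list,
    most stable first.
    """
    df = _as_q(q)
    order = ranking.ranking if isinstance(ranking, GeNormResult) else list(ranking)
    if len(order) < 3:
        raise ValidationError("the V series needs a ranking over at least 3 genes")
    unknown = [g for g in order if g not in df.index]
    if unknown:
        raise ValidationError(f"ranking contains unknown gene(s): {unknown}")
    vs = {}
    for n in range(2, len(order)):
        nf_n = normalization_factor(df, order[:n])
        nf_n1 = normalization_factor(df, order[: n + 1])
        ratio = np.log2(nf_n.to_numpy()) - np.log2(nf_n1.to_numpy())
        vs[n] = float(np.std(ratio, ddof=1))
    return PairwiseVariationSeries(pd.Series(vs, name="V"), threshold=threshold)


class GeNorm(BaseEstimator):
    """geNorm stability ranking as a scikit-learn style estimator.

    ``fit`` expects X with samples in rows and genes in columns, holding
    positive relative quantities (e.g. ``2^-dCt``).

    Parameters
    ----------
    threshold : float, default 0.15
        Pairwise-variation cut-off for the optimal number of genes.
    stable_threshold : float, default 1.5
        M value below which a gene is flagged as stably expressed.

    Attributes
    ----------
    m_values_ : Series of M over the full gene set
    exclusion_order_, final_pair_, ranking_ : stepwise ranking outcome
    ranks_ : Series of ranks (best pair tied at 1.5)
    pairwise_variation_ : :class:`PairwiseVariationSeries`
    optimal_n_ : smallest sufficient number of reference genes, or None
    """

    def __init__(self, threshold: float = V_THRESHOLD, stable_threshold: float = M_STABLE_THRESHOLD):
        self.threshold = threshold
        self.stable_threshold = stable_threshold

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        q = df.T  # internal orientation: genes x samples
        result = rank_stepwise(q)
        result = GeNormResult(
            m_values=result.m_values,
            exclusion_order=result.exclusion_order,
            final_pair=result.final_pair,
            m_at_exclusion=result.m_at_exclusion,
            stable_threshold=self.stable_threshold,
        )
        self.result_ = result
        self.m_values_ = result.m_values
        self.exclusion_order_ = result.exclusion_order
        self.final_pair_ = result.final_pair
        self.ranking_ = result.ranking
        self.ranks_ = result.ranks
        self.pairwise_variation_ = pairwise_variation_series(q, result, self.threshold)
        self.optimal_n_ = self.pairwise_variation_.optimal_n
        self.n_features_in_ = df.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self
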