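"""BestKeeper-style descriptive stability of raw Ct values.

BestKeeper works directly on the Ct scale. Its "SD" is the mean absolute
deviation (MAD) of a gene's Ct values from their arithmetic mean, and its
"CV" is that deviation as a percent of the mean Ct. A gene whose Ct wanders
by more than one cycle on average (SD > 1) is flagged as unacceptable for
normalization. The optional BestKeeper index is the per-sample geometric
mean of the chosen genes' Ct values, against which each gene's Ct row can
be correlated (Pearson).

Note this CV is a percent-of-cycles measure and is a different quantity
from the dimensionless expression CV used in candidate screening; the two
are never comparable.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core_io import CtMatrix, ValidationError

__all__ = ["BestKeeperResult", "bestkeeper_stats", "bestkeeper_index", "BestKeeper"]

#: genes with MAD above this many cycles are unacceptable references
SD_ACCEPTABLE_MAX = 1.0


def _as_ct(ct) -> pd.DataFrame:
    return ct.mean_ct if isinstance(ct, CtMatrix) else pd.DataFrame(ct)


@dataclass(frozen=True)
class BestKeeperResult:
    """Per-gene descriptive statistics of Ct and the (sd, cv) stability ranking.

    ``summary`` is indexed by gene with columns n, geo_mean_ct, mean_ct,
    min_ct, max_ct, sd (mean absolute deviation, cycles), cv (percent of
    mean Ct), acceptable (sd <= 1) and rank.
    """

    summary: pd.DataFrame

    @property
    def ranking(self) -> list:
        return list(self.summary.sort_values("rank").index)

    @property
    def ranks(self) -> pd.Series:
        return self.summary["rank"].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def bestkeeper_stats(
    ct: CtMatrix | pd.DataFrame, sample_subset: Sequence[str] | None = None
) -> BestKeeperResult:
    """Descriptive stability per gene over a sample subset (default: all).

    sd is the mean absolute deviation from the arithmetic mean Ct;
    cv = 100 * sd / mean Ct. Ranking is ascending by (sd, cv, gene id).
    Genes missing in some samples are tolerated with a warning (their
    statistics use the available samples only).
    """
    df = _as_ct(ct)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in df.columns]
        if unknown:
            raise ValidationError(f"unknown sample(s) in subset: {unknown}")
        df = df[list(sample_subset)]
    if df.shape[1] < 2:
        raise ValidationError("BestKeeper statistics need at least 2 samples")
    if df.isna().any().any():
        holes = df.index[df.isna().any(axis=1)].tolist()
        warnings.warn(
            f"gene(s) with missing samples, statistics use available values only: {holes}",
            stacklevel=2,
        )
    arr = df.to_numpy(dtype=float)
    n = np.sum(~np.isnan(arr), axis=1)
    if (n < 2).any():
        bad = df.index[n < 2].tolist()
        raise ValidationError(f"gene(s) observed in fewer than 2 samples: {bad}")
    mean = np.nanmean(arr, axis=1)
    geo = np.exp(np.nanmean(np.log(arr), axis=1))
    sd = np.nanmean(np.abs(arr - mean[:, None]), axis=1)
    cv = 100.0 * sd / mean
    summary = pd.DataFrame(
        {
            "n": n,
            "geo_mean_ct": geo,
            "mean_ct": mean,
            "min_ct": np.nanmin(arr, axis=1),
            "max_ct": np.nanmax(arr, axis=1),
            "sd": sd,
            "cv": cv,
            "acceptable": sd <= SD_ACCEPTABLE_MAX,
        },
        index=df.index,
    )
    order = sorted(summary.index, key=lambda g: (summary.at[g, "sd"], summary.at[g, "cv"], str(g)))
    summary["rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)})
    return BestKeeperResult(summary)


def bestkeeper_index(
    ct: CtMatrix | pd.DataFrame, genes: Sequence[str]
) -> tuple[pd.Series, pd.Series]:
    """BestKeeper index (per-sample geometric mean Ct) and per-gene Pearson r.

    Returns ``(index, correlations)``. A constant gene row has no defined
    correlation with the index; it is reported as NaN with a warning.
    """
    df = _as_ct(ct)
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValidationError("the BestKeeper index needs at least 2 genes")
    unknown = [g for g in genes if g not in df.index]
    if unknown:
        raise ValidationError(f"unknown gene(s): {unknown}")
    if df.shape[1] < 3:
        raise ValidationError("index correlations need at least 3 samples")
    sub = df.loc[genes].to_numpy(dtype=float)
    index = pd.Series(np.exp(np.log(sub).mean(axis=0)), index=df.columns, name="bestkeeper_index")
    corrs = {}
    for g in genes:
        row = df.loc[g].to_numpy(dtype=float)
        if np.allclose(row, row[0]) or np.allclose(index, index.iloc[0]):
            warnings.warn(f"correlation with the index undefined for constant gene {g!r}", stacklevel=2)
            corrs[g] = np.nan
        else:
            corrs[g] = float(stats.pearsonr(row, index.to_numpy()).statistic)
    return index, pd.Series(corrs, name="r_vs_index")


class BestKeeper(BaseEstimator):
    """BestKeeper descriptive stability as a scikit-learn style estimator.

    ``fit`` expects X with samples in rows and genes in columns, holding
    raw (or replicate-averaged) Ct values in cycles.

    Attributes
    ----------
    summary_ : per-gene descriptive statistics frame
    sd_, cv_ : Series of the MAD and percent CV per gene
    acceptable_ : boolean Series (sd <= 1 cycle)
    ranking_ : gene ids ascending by (sd, cv)
    index_, correlations_ : BestKeeper index and per-gene Pearson r
    """

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        ct = df.T
        result = bestkeeper_stats(ct)
        self.result_ = result
        self.summary_ = result.summary
        self.sd_ = result.summary["sd"]
        self.cv_ = result.summary["cv"]
        self.acceptable_ = result.summary["acceptable"]
        self.ranking_ = result.ranking
        self.ranks_ = result.ranks
        if ct.shape[0] >= 2 and ct.shape[1] >= 3:
            self.index_, self.correlations_ = bestkeeper_index(ct, list(ct.index))
        self.n_features_in_ = df.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self
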