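"""Screen an expression matrix for candidate reference genes by coefficient of variation.

A gene whose expression barely moves across conditions is a candidate
internal control. Stability here is the dimensionless coefficient of
variation CV = SD / MV computed per gene across conditions, with the
sample (n-1) standard deviation; candidates are those with CV strictly
below a cut-off (default 0.3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core_io import ExpressionMatrix, ValidationError

__all__ = ["expression_stats", "filter_candidates", "CVScreen"]


def _as_frame(m) -> pd.DataFrame:
    return m.values if isinstance(m, ExpressionMatrix) else pd.DataFrame(m)


def expression_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean (MV), sample SD and CV across conditions.

    Returns a DataFrame indexed by gene with columns ``mv``, ``sd``, ``cv``
    and ``cv_defined``. Genes with zero mean expression get an undefined
    (NaN) CV and are flagged rather than raising, so genome-scale matrices
    survive screening.
    """
    df = _as_frame(m)
    if df.shape[1] < 2:
        raise ValidationError("CV screening needs at least 2 conditions (SD undefined)")
    mv = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    defined = mv > 0
    cv = pd.Series(np.where(defined, sd / mv.where(defined), np.nan), index=df.index)
    return pd.DataFrame({"mv": mv, "sd": sd, "cv": cv, "cv_defined": defined})


def filter_candidates(stats: pd.DataFrame, cv_max: float = 0.3) -> list:
    """Genes with defined CV strictly below ``cv_max``, most stable first.

    Sorted ascending by CV; ties broken lexicographically by gene id.
    """
    if np.isnan(cv_max) or cv_max <= 0:
        raise ValidationError(f"cv_max must be a positive number, got {cv_max}")
    if len(stats) == 0:
        return []
    kept = stats[stats["cv_defined"] & (stats["cv"] < cv_max)]
    order = sorted(kept.index, key=lambda g: (kept.at[g, "cv"], str(g)))
    return order


class CVScreen(BaseEstimator, TransformerMixin):
    """Coefficient-of-variation gene screen as a scikit-learn transformer.

    Follows the sklearn orientation: rows are observations (conditions),
    columns are features (genes). ``fit`` computes per-gene MV/SD/CV;
    ``transform`` keeps only the genes passing the screen.

    Parameters
    ----------
    cv_max : float, default 0.3
        Strict upper bound on the coefficient of variation.

    Attributes
    ----------
    mv_, sd_, cv_ : ndarray of shape (n_genes,)
    support_ : boolean ndarray, True for genes with defined CV < cv_max
    feature_names_in_ : gene identifiers when fitted on a DataFrame
    """

    def __init__(self, cv_max: float = 0.3):
        self.cv_max = cv_max

    def fit(self, X, y=None):
        if np.isnan(self.cv_max) or self.cv_max <= 0:
            raise ValidationError(f"cv_max must be a positive number, got {self.cv_max}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("CVScreen requires a 2-D matrix with >= 2 condition rows")
        if (X < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.n_features_in_ = X.shape[1]
        self.mv_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.cv_ = np.where(self.mv_ > 0, self.sd_ / self.mv_, np.nan)
        self.support_ = (self.mv_ > 0) & (self.cv_ < self.cv_max)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
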