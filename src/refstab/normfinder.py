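"""Model-based (NormFinder-style) expression-stability values.

The model works on log2 relative quantities. Each sample's column is
centered by its mean over genes, removing sample-wide loading effects;
what remains per gene decomposes into an intergroup component (how much
the gene's level shifts between experimental groups — the dangerous kind
of instability for a reference gene) and an intragroup variance (its
residual noise within a group). The per-gene stability value combines a
shrunk estimate of the group shift with its standard error, averaged over
groups; lower is more stable.

Estimation details: within each group the two-way (gene x sample)
residuals give a naive per-gene variance, which is bias-corrected for the
noise shared through sample-centering and floored at zero. The raw group
shifts d are shrunk toward zero in proportion to their sampling variance
relative to the between-gene spread of shifts (an empirical-Bayes step),
so noisy shift estimates do not masquerade as real group effects.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import ValidationError
from .quantify import RelativeQuantityMatrix

__all__ = ["NormFinderResult", "log_quantities", "normfinder_stability", "NormFinder"]


def log_quantities(q) -> pd.DataFrame:
    """Element-wise log2 of a relative-quantity matrix (genes x samples).

    For quantities built with efficiency 2 this equals minus the per-gene
    delta-Ct.
    """
    df = q.q if isinstance(q, RelativeQuantityMatrix) else pd.DataFrame(q)
    arr = df.to_numpy(dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValidationError("quantities must be positive and finite")
    return pd.DataFrame(np.log2(arr), index=df.index, columns=df.columns)


@dataclass(frozen=True)
class NormFinderResult:
    """Per-gene stability values and their variance decomposition.

    ``intragroup_variance`` and ``intergroup_deviation`` are genes x groups
    frames (the deviation is the shrunk group-shift estimate; it is empty
    of meaning — all zeros — in the single-group fallback).
    """

    stability: pd.Series
    intragroup_variance: pd.DataFrame
    intergroup_deviation: pd.DataFrame
    groups: tuple

    @property
    def ranking(self) -> list:
        return sorted(self.stability.index, key=lambda g: (self.stability[g], str(g)))

    @property
    def ranks(self) -> pd.Series:
        return pd.Series(
            {g: float(i + 1) for i, g in enumerate(self.ranking)}, name="rank"
        ).reindex(self.stability.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stability": self.stability, "rank": self.ranks})


def _group_spans(samples: Sequence, groups: Mapping | Sequence | None) -> dict:
    """Map each group label to the integer sample positions it covers."""
    if groups is None:
        labels = ["all"] * len(samples)
    elif isinstance(groups, Mapping):
        missing = [s for s in samples if s not in groups]
        if missing:
            raise ValidationError(f"sample(s) without a group assignment: {missing}")
        labels = [groups[s] for s in samples]
    else:
        labels = list(groups)
        if len(labels) != len(samples):
            raise ValidationError("groups sequence length must match the number of samples")
    spans: dict = {}
    for i, lab in enumerate(labels):
        spans.setdefault(lab, []).append(i)
    return spans


def normfinder_stability(
    logq: pd.DataFrame,
    groups: Mapping | Sequence | None = None,
) -> NormFinderResult:
    """Stability value per gene from log2 quantities (genes x samples).

    ``groups`` maps each sample (column) to its experimental group, or is a
    per-column sequence of labels. With a single group (or ``None``) the
    intergroup component is unidentifiable and the stability value falls
    back to the square root of the bias-corrected intragroup variance.
    """
    Y = pd.DataFrame(logq)
    arr = Y.to_numpy(dtype=float)
    k, n = arr.shape
    if k < 3:
        raise ValidationError("the stability model needs at least 3 genes (sample centering degenerates)")
    if not np.isfinite(arr).all():
        raise ValidationError("log quantities must be finite and complete")
    spans = _group_spans(Y.columns, groups)
    small = [g for g, idx in spans.items() if len(idx) < 2]
    if small:
        raise ValidationError(f"every group needs at least 2 samples; offending group(s): {small}")

    # remove per-sample loading: center each column by its mean over genes
    Z = arr - arr.mean(axis=0, keepdims=True)
    group_names = list(spans)
    G = len(group_names)

    sigma2 = np.empty((k, G))
    dhat = np.empty((k, G))
    n_g = np.array([len(spans[g]) for g in group_names], dtype=float)
    gene_grand = Z.mean(axis=1)
    for gi, gname in enumerate(group_names):
        Zg = Z[:, spans[gname]]
        row_mean = Zg.mean(axis=1)
        # two-way residuals within the group; column means of Z are 0 by construction
        r = Zg - row_mean[:, None]
        s2 = (r**2).sum(axis=1) / (Zg.shape[1] - 1)
        # bias correction for the noise shared through sample centering
        total = s2.sum()
        sigma2[:, gi] = np.clip((s2 - total / (k * (k - 1))) * k / (k - 2), 0.0, None)
        dhat[:, gi] = row_mean - gene_grand

    if G == 1:
        stability = np.sqrt(sigma2[:, 0])
        dev = np.zeros_like(dhat)
    else:
        vard = sigma2 / n_g[None, :]
        gamma2 = max(
            float((dhat**2).sum() / ((k - 1) * (G - 1)) - vard.mean()), 0.0
        )
        shrink = np.divide(
            gamma2, gamma2 + vard, out=np.zeros_like(vard), where=(gamma2 + vard) > 0
        )
        dev = dhat * shrink
        var_new = vard * shrink
        rho = np.abs(dev) + np.sqrt(var_new)
        stability = rho.mean(axis=1)

    return NormFinderResult(
        stability=pd.Series(stability, index=Y.index, name="stability"),
        intragroup_variance=pd.DataFrame(sigma2, index=Y.index, columns=group_names),
        intergroup_deviation=pd.DataFrame(dev, index=Y.index, columns=group_names),
        groups=tuple(group_names),
    )


class NormFinder(BaseEstimator):
    """Model-based stability ranking as a scikit-learn style estimator.

    ``fit`` expects X with samples in rows and genes in columns holding
    positive relative quantities (log-transformed internally), and an
    optional per-sample ``groups`` array.

    Parameters
    ----------
    log_input : bool, default False
        Set True when X already holds log2 quantities.

    Attributes
    ----------
    stability_ : Series of per-gene stability values (lower = more stable)
    ranking_ : gene ids sorted ascending by stability
    intragroup_variance_, intergroup_deviation_ : genes x groups frames
    """

    def __init__(self, log_input: bool = False):
        self.log_input = log_input

    def fit(self, X, y=None, groups=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        mat = df.T  # genes x samples
        logq = pd.DataFrame(mat) if self.log_input else log_quantities(mat)
        result = normfinder_stability(logq, groups)
        self.result_ = result
        self.stability_ = result.stability
        self.ranking_ = result.ranking
        self.ranks_ = result.ranks
        self.intragroup_variance_ = result.intragroup_variance
        self.intergroup_deviation_ = result.intergroup_deviation
        self.n_features_in_ = df.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        return self
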