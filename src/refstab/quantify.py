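"""Ct-to-quantity transforms, normalization factors and delta-delta-Ct fold changes.

Raw Ct values are converted to relative quantities with the efficiency-
corrected formula ``q = E^-(Ct - min Ct)`` anchored at each gene's minimum
Ct, so quantities lie in (0, 1] with the most expressed sample at 1. With
the ideal efficiency E = 2 this is exactly ``2^-dCt``. A normalization
factor (NF) is the per-sample geometric mean of the selected reference
genes' quantities. Target-gene validation uses the classical
``2^-ddCt`` fold change against a control sample group.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CtMatrix, EfficiencyTable, ValidationError

__all__ = [
    "RelativeQuantityMatrix",
    "FoldChangeResult",
    "relative_quantities",
    "normalization_factor",
    "ddct_fold_change",
    "fold_changes_vs_control",
]


@dataclass(frozen=True)
class RelativeQuantityMatrix:
    """Relative quantities in (0, 1], genes in rows, samples in columns.

    Per gene the maximum over samples is 1 (the sample at the gene's
    minimum Ct).
    """

    q: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.q.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any() or (arr > 1 + 1e-12).any():
            raise ValidationError("relative quantities must lie in (0, 1]")

    @property
    def gene_ids(self) -> list:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list:
        return list(self.q.columns)


def _efficiencies(eff, genes) -> pd.Series:
    if eff is None:
        eff = EfficiencyTable()
    elif isinstance(eff, Mapping) and not isinstance(eff, EfficiencyTable):
        eff = EfficiencyTable(eff)
    e = pd.Series({g: eff[g] for g in genes}, dtype=float)
    if (e <= 1).any():
        bad = e[e <= 1].index.tolist()
        raise ValidationError(f"amplification efficiency must exceed 1; offending gene(s): {bad}")
    return e


def relative_quantities(
    ct: CtMatrix, eff: EfficiencyTable | Mapping[str, float] | None = None
) -> RelativeQuantityMatrix:
    """Convert mean Ct to relative quantities ``E^-(Ct - per-gene min Ct)``."""
    df = ct.mean_ct
    e = _efficiencies(eff, df.index)
    dct = df.sub(df.min(axis=1), axis=0)
    q = np.power(e.to_numpy()[:, None], -dct.to_numpy())
    return RelativeQuantityMatrix(pd.DataFrame(q, index=df.index, columns=df.columns))


def normalization_factor(
    q: RelativeQuantityMatrix | pd.DataFrame, ref_genes: Sequence[str]
) -> pd.Series:
    """Per-sample geometric mean of the reference genes' relative quantities.

    Duplicate entries in ``ref_genes`` are ignored (the geometric mean over
    a set of genes).
    """
    df = q.q if isinstance(q, RelativeQuantityMatrix) else q
    refs = list(dict.fromkeys(ref_genes))
    if not refs:
        raise ValidationError("reference gene list must be non-empty")
    unknown = [g for g in refs if g not in df.index]
    if unknown:
        raise ValidationError(f"unknown reference gene(s): {unknown}")
    nf = np.exp(np.log(df.loc[refs].to_numpy(dtype=float)).mean(axis=0))
    return pd.Series(nf, index=df.columns, name="nf")


@dataclass(frozen=True)
class FoldChangeResult:
    """2^-ddCt fold change of a target gene, treated vs control samples."""

    target_gene: str
    ref_genes: tuple
    fold: float
    ddct: float
    dct_control: float
    dct_treated: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [self.target_gene],
                "refs": [",".join(self.ref_genes)],
                "dct_control": [self.dct_control],
                "dct_treated": [self.dct_treated],
                "ddct": [self.ddct],
                "fold": [self.fold],
            }
        )


def ddct_fold_change(
    ct: CtMatrix,
    target: str,
    refs: Sequence[str],
    control_samples: Sequence[str],
    treated_samples: Sequence[str],
) -> FoldChangeResult:
    """Classical 2^-ddCt relative quantification.

    Per sample, dCt = Ct(target) - mean over references of Ct(ref); the
    arithmetic mean of reference Ct values is equivalent to a geometric-mean
    normalization factor on the quantity scale. dCt is averaged within the
    control and treated sample groups; ddCt is their difference and the
    fold change 2^-ddCt.
    """
    refs = list(dict.fromkeys(refs))
    if not refs or not len(control_samples) or not len(treated_samples):
        raise ValidationError("refs, control_samples and treated_samples must be non-empty")
    if target in refs:
        raise ValidationError(f"target gene {target!r} overlaps the reference set")
    df = ct.mean_ct
    for g in [target, *refs]:
        if g not in df.index:
            raise ValidationError(f"gene {g!r} not present in the Ct matrix")
    for s in [*control_samples, *treated_samples]:
        if s not in df.columns:
            raise ValidationError(f"sample {s!r} not present in the Ct matrix")
    dct = df.loc[target] - df.loc[refs].mean(axis=0)
    dct_control = float(dct[list(control_samples)].mean())
    dct_treated = float(dct[list(treated_samples)].mean())
    ddct = dct_treated - dct_control
    return FoldChangeResult(
        target_gene=target,
        ref_genes=tuple(refs),
        fold=float(2.0 ** -ddct),
        ddct=float(ddct),
        dct_control=dct_control,
        dct_treated=dct_treated,
    )


def fold_changes_vs_control(
    ct: CtMatrix,
    target: str,
    refs: Sequence[str],
    control_group: str,
) -> pd.DataFrame:
    """Fold change of ``target`` in every non-control group vs the control group.

    One row per treated group, columns ``group``, ``ddct``, ``fold``.
    """
    groups = ct.group_labels()
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} not present")
    control = [s for s in ct.sample_ids if ct.groups[s] == control_group]
    rows = []
    for g in groups:
        if g == control_group:
            continue
        treated = [s for s in ct.sample_ids if ct.groups[s] == g]
        res = ddct_fold_change(ct, target, refs, control, treated)
        rows.append({"group": g, "ddct": res.ddct, "fold": res.fold})
    return pd.DataFrame(rows).set_index("group")
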