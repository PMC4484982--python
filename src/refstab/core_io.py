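"""Shared containers, readers/writers and replicate aggregation for qPCR stability analysis.

The analysis pipeline operates on three kinds of tabular data:

* an expression matrix (genes x conditions, FPKM-like non-negative values)
  used to screen candidate reference genes;
* a long-format table of raw cycle-threshold (Ct) measurements with
  biological and technical replicate structure;
* the aggregated Ct matrix (genes x samples) that the stability methods
  consume.

All file formats are plain CSV/TSV with a mandatory header row; the
delimiter is inferred from the extension and can be overridden.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "CtRecord",
    "CtMatrix",
    "EfficiencyTable",
    "CT_COLUMNS",
    "read_expression_matrix",
    "read_ct_table",
    "validate_ct_records",
    "records_to_frame",
    "aggregate_replicates",
    "write_report",
    "read_report",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural or numerical invariant."""


#: required columns of a long-format Ct table (order-free, header-named)
CT_COLUMNS = ("sample_id", "group_label", "gene_id", "bio_rep", "tech_rep", "ct")

#: soft plausibility bounds for Ct values (cycles); values outside warn only
CT_WARN_RANGE = (5.0, 40.0)


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what} identifier(s): {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative expression values (FPKM role), genes in rows, conditions in columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 1:
            raise ValidationError("expression matrix has no genes")
        if df.shape[1] < 2:
            raise ValidationError(
                "expression matrix needs at least 2 conditions (SD/CV undefined otherwise)"
            )
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "condition")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = df.stack()[~np.isfinite(arr).flatten()]
            gene, cond = bad.index[0]
            raise ValidationError(f"non-finite expression value for gene {gene!r}, condition {cond!r}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value {arr[i, j]} for gene "
                f"{df.index[i]!r}, condition {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class CtRecord:
    """One raw qPCR measurement: a Ct value for (sample, gene, bio rep, tech rep)."""

    sample_id: str
    group_label: str
    gene_id: str
    bio_rep: int
    tech_rep: int
    ct: float


def records_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    """Assemble :class:`CtRecord` objects into a validated long-format table."""
    df = pd.DataFrame([vars(r) for r in records], columns=list(CT_COLUMNS))
    return validate_ct_records(df)


def validate_ct_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table; returns the (typed) table itself.

    Checks: required columns present, Ct finite and > 0 (warn outside the
    plausible cycle range), replicate indices are positive integers, and
    no duplicate (sample, gene, bio_rep, tech_rep) key.
    """
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table is missing column(s): {missing}")
    df = df.loc[:, list(CT_COLUMNS)].copy()
    if len(df) == 0:
        return df
    try:
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["ct"], errors="coerce")
        line = int(np.flatnonzero(bad.isna())[0])
        raise ValidationError(f"non-numeric Ct value {df['ct'].iloc[line]!r} at data row {line + 1}")
    ct = df["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        line = int(np.flatnonzero(~(np.isfinite(ct) & (ct > 0)))[0])
        raise ValidationError(f"Ct must be finite and > 0; offending value {ct[line]} at data row {line + 1}")
    lo, hi = CT_WARN_RANGE
    n_odd = int(((ct < lo) | (ct > hi)).sum())
    if n_odd:
        warnings.warn(
            f"{n_odd} Ct value(s) outside the plausible range ({lo}, {hi}) cycles",
            stacklevel=2,
        )
    for col in ("bio_rep", "tech_rep"):
        reps = pd.to_numeric(df[col], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.round()).any():
            raise ValidationError(f"{col} must be an integer >= 1")
        df[col] = reps.astype(int)
    key = ["sample_id", "gene_id", "bio_rep", "tech_rep"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = df.loc[dup, key].iloc[0].tolist()
        raise ValidationError(f"duplicate replicate key (sample, gene, bio, tech) = {tuple(rows)}")
    grp = df.groupby("sample_id")["group_label"].nunique()
    if (grp > 1).any():
        bad = grp[grp > 1].index.tolist()
        raise ValidationError(f"sample(s) assigned to more than one group: {bad}")
    return df


def read_expression_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a genes-x-conditions expression matrix from CSV/TSV.

    The first column holds gene identifiers; every remaining column must be
    numeric. Row and column order are preserved.
    """
    df = pd.read_csv(path, sep=_detect_sep(path, sep), index_col=0)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            gene = df.index[int(np.flatnonzero(bad.isna())[0])]
            raise ValidationError(
                f"non-numeric expression value for gene {gene!r}, condition {col!r}"
            )
    return ExpressionMatrix(df)


def read_ct_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a long-format Ct table (one row per technical replicate)."""
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    return validate_ct_records(df)


@dataclass(frozen=True)
class CtMatrix:
    """Replicate-aggregated mean Ct values, genes in rows, samples in columns.

    ``groups`` maps each sample to its experimental group (e.g. treatment);
    ``n_replicates`` records how many raw measurements entered each cell.
    A CtMatrix must be complete: every (gene, sample) cell present and
    finite — the stability methods cannot handle holes.
    """

    mean_ct: pd.DataFrame
    groups: Mapping[str, str]
    n_replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.mean_ct
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            holes = [
                (df.index[i], df.columns[j]) for i, j in np.argwhere(~np.isfinite(arr))
            ]
            raise ValidationError(f"incomplete Ct matrix; missing (gene, sample) cells: {holes[:10]}")
        unknown = [s for s in df.columns if s not in self.groups]
        if unknown:
            raise ValidationError(f"sample(s) without a group assignment: {unknown}")

    @property
    def gene_ids(self) -> list:
        return list(self.mean_ct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.mean_ct.columns)

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def group_labels(self) -> list[str]:
        """Distinct group labels in sample-column order."""
        out: list[str] = []
        for s in self.mean_ct.columns:
            g = self.groups[s]
            if g not in out:
                out.append(g)
        return out

    def subset(self, group: str) -> "CtMatrix":
        """Restrict to the samples of one experimental group."""
        cols = [s for s in self.mean_ct.columns if self.groups[s] == group]
        if not cols:
            raise ValidationError(f"no samples in group {group!r}")
        nrep = None if self.n_replicates is None else self.n_replicates[cols]
        return CtMatrix(self.mean_ct[cols], {s: group for s in cols}, nrep)


class EfficiencyTable(Mapping):
    """Per-gene qPCR amplification efficiency E (dimensionless base, ideal 2).

    Genes absent from the table default to E = 2 (100 % efficiency).
    Values must satisfy 1 < E <= 2.2; values outside [1.8, 2.1] warn.
    """

    DEFAULT = 2.0

    def __init__(self, efficiencies: Mapping[str, float] | None = None) -> None:
        eff = dict(efficiencies or {})
        for gene, e in eff.items():
            e = float(e)
            if not np.isfinite(e) or e <= 1.0 or e > 2.2:
                raise ValidationError(
                    f"amplification efficiency for {gene!r} must satisfy 1 < E <= 2.2, got {e}"
                )
            if not (1.8 <= e <= 2.1):
                warnings.warn(
                    f"amplification efficiency {e} for {gene!r} outside the usual [1.8, 2.1]",
                    stacklevel=2,
                )
            eff[gene] = e
        self._eff = eff

    def __getitem__(self, gene: str) -> float:
        return self._eff.get(gene, self.DEFAULT)

    def __iter__(self):
        return iter(self._eff)

    def __len__(self) -> int:
        return len(self._eff)

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "EfficiencyTable":
        df = pd.read_csv(path, sep=_detect_sep(path, sep))
        gene_col, eff_col = df.columns[0], df.columns[1]
        return cls(dict(zip(df[gene_col], pd.to_numeric(df[eff_col]))))


def aggregate_replicates(
    records: pd.DataFrame | Iterable[CtRecord],
    method: str = "two_stage",
) -> CtMatrix:
    """Collapse replicate-level Ct records to one mean Ct per (gene, sample).

    ``method='two_stage'`` (default) first averages technical replicates
    within each biological replicate, then averages the biological-replicate
    means; ``method='pooled'`` takes the plain mean over all measurements.
    The two agree exactly for balanced designs (equal technical counts per
    biological replicate).
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    else:
        records = validate_ct_records(records)
    if len(records) == 0:
        raise ValidationError("cannot aggregate an empty Ct table")
    if method not in {"two_stage", "pooled"}:
        raise ValidationError(f"unknown aggregation method {method!r}")

    if method == "two_stage":
        bio_means = (
            records.groupby(["gene_id", "sample_id", "bio_rep"], sort=False)["ct"].mean()
        )
        cell_means = bio_means.groupby(["gene_id", "sample_id"], sort=False).mean()
    else:
        cell_means = records.groupby(["gene_id", "sample_id"], sort=False)["ct"].mean()
    counts = records.groupby(["gene_id", "sample_id"], sort=False)["ct"].size()

    genes = list(dict.fromkeys(records["gene_id"]))
    samples = list(dict.fromkeys(records["sample_id"]))
    mean_ct = cell_means.unstack("sample_id").reindex(index=genes, columns=samples)
    nrep = counts.unstack("sample_id").reindex(index=genes, columns=samples)
    if mean_ct.isna().any().any():
        holes = [
            (g, s)
            for g in genes
            for s in samples
            if pd.isna(mean_ct.at[g, s])
        ]
        raise ValidationError(
            f"every gene must be measured in every sample; missing cells: {holes[:20]}"
        )
    groups = dict(
        records.drop_duplicates("sample_id")[["sample_id", "group_label"]].itertuples(
            index=False, name=None
        )
    )
    return CtMatrix(mean_ct, groups, nrep.astype(int))


def write_report(
    result,
    path: str | Path,
    format: str | None = None,
    digits: int = 3,
) -> None:
    """Write a stage output to TSV or JSON with fixed float precision.

    ``result`` may be a DataFrame or any object exposing ``to_frame()``.
    Column order is taken from the frame and is deterministic; floats are
    rendered with ``digits`` decimals (default 3, matching the precision
    conventional in published stability tables).
    """
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        frame.to_csv(path, sep="\t", float_format=f"%.{digits}f")
    elif format == "json":
        payload = json.loads(frame.round(digits).to_json(orient="table"))
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="table")
    return pd.read_csv(path, sep="\t", index_col=0)
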