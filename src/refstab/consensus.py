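"""Consensus ranking across stability methods and the full-study driver.

Different stability algorithms rarely agree exactly, so the standard
practice is to run several and aggregate their per-gene ranks. The default
aggregation is the geometric mean of ranks (the RefFinder-style
convention), with the arithmetic mean as an alternative; tied ranks (the
geNorm best pair) enter as mean ranks (1.5 each).

:func:`run_full_analysis` orchestrates the whole workflow: optional CV
screening of an expression matrix, then geNorm + NormFinder + BestKeeper
on all samples and on each experimental-group subset, a consensus ranking
per subset, the pairwise-variation series, and optional delta-delta-Ct
validation of target genes against the top consensus references.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator

from . import __version__ as _pkg_version
from .bestkeeper import BestKeeperResult, bestkeeper_stats
from .candidate_mining import expression_stats, filter_candidates
from .core_io import CtMatrix, EfficiencyTable, ExpressionMatrix, ValidationError, write_report
from .genorm import GeNormResult, PairwiseVariationSeries, pairwise_variation_series, rank_stepwise
from .normfinder import NormFinderResult, log_quantities, normfinder_stability
from .quantify import fold_changes_vs_control, relative_quantities

__all__ = [
    "ConsensusRanking",
    "aggregate_ranks",
    "RankAggregator",
    "AnalysisConfig",
    "SubsetReport",
    "ReportBundle",
    "run_full_analysis",
]


@dataclass(frozen=True)
class ConsensusRanking:
    """Aggregate of several per-method rank maps.

    ``table`` is indexed by gene and holds one rank column per method, the
    aggregate ``score`` and the integer ``final_rank`` (a permutation of
    1..K, score ties broken by gene id).
    """

    table: pd.DataFrame
    method: str

    @property
    def ranking(self) -> list:
        return list(self.table.sort_values("final_rank").index)

    @property
    def ranks(self) -> pd.Series:
        return self.table["final_rank"].astype(float)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def aggregate_ranks(
    rankings: Mapping[str, Mapping[str, float]] | Sequence[Mapping[str, float]],
    method: str = "geometric_mean",
) -> ConsensusRanking:
    """Combine per-method rank maps into a consensus ranking.

    All rank maps must cover the same gene set; tied ranks are encoded as
    mean ranks. ``method`` is ``'geometric_mean'`` (default) or
    ``'arithmetic_mean'``.
    """
    if method not in {"geometric_mean", "arithmetic_mean"}:
        raise ValidationError(f"unknown aggregation method {method!r}")
    if not isinstance(rankings, Mapping):
        rankings = {f"method_{i + 1}": r for i, r in enumerate(rankings)}
    if len(rankings) == 0:
        raise ValidationError("need at least one ranking to aggregate")
    gene_sets = {name: set(r.keys() if isinstance(r, Mapping) else r.index) for name, r in rankings.items()}
    ref_name = next(iter(gene_sets))
    ref = gene_sets[ref_name]
    for name, gs in gene_sets.items():
        if gs != ref:
            diff = sorted(gs.symmetric_difference(ref), key=str)
            raise ValidationError(
                f"rank maps {ref_name!r} and {name!r} cover different genes; symmetric difference: {diff}"
            )
    table = pd.DataFrame({name: pd.Series(dict(r)) for name, r in rankings.items()})
    scores = gmean(table, axis=1) if method == "geometric_mean" else table.mean(axis=1).to_numpy()
    table["score"] = scores
    order = sorted(table.index, key=lambda g: (table.at[g, "score"], str(g)))
    table["final_rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)})
    return ConsensusRanking(table, method)


class RankAggregator(BaseEstimator):
    """Rank aggregation as a scikit-learn style estimator.

    ``fit`` expects X with genes in rows and one column of ranks per method
    (a DataFrame or array).
    """

    def __init__(self, method: str = "geometric_mean"):
        self.method = method

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        result = aggregate_ranks({str(c): df[c] for c in df.columns}, self.method)
        self.result_ = result
        self.table_ = result.table
        self.ranking_ = result.ranking
        self.ranks_ = result.ranks
        return self


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full workflow, all with study-conventional defaults."""

    cv_max: float = 0.3
    v_threshold: float = 0.15
    aggregation: str = "geometric_mean"
    control_group: str | None = None
    top_n_refs: int = 3  # at least three genes for reliable normalization
    targets: tuple = ()  # target gene ids for ddCt validation
    efficiencies: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "cv_max": self.cv_max,
            "v_threshold": self.v_threshold,
            "aggregation": self.aggregation,
            "control_group": self.control_group,
            "top_n_refs": self.top_n_refs,
            "targets": list(self.targets),
            "efficiencies": dict(self.efficiencies or {}),
        }


@dataclass(frozen=True)
class SubsetReport:
    """The three method results plus their consensus for one sample subset."""

    genorm: GeNormResult
    normfinder: NormFinderResult
    bestkeeper: BestKeeperResult
    consensus: ConsensusRanking
    v_series: PairwiseVariationSeries


@dataclass(frozen=True)
class ReportBundle:
    """Everything :func:`run_full_analysis` produces, writable as TSV + manifest."""

    subsets: dict
    mining: pd.DataFrame | None
    candidates: list | None
    validation: pd.DataFrame | None
    config: AnalysisConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []

        def _emit(frame, name):
            write_report(frame, outdir / name)
            files.append(name)

        if self.mining is not None:
            _emit(self.mining, "mining.tsv")
        for label, rep in self.subsets.items():
            _emit(rep.genorm.to_frame(), f"genorm_{label}.tsv")
            _emit(rep.normfinder.to_frame(), f"normfinder_{label}.tsv")
            _emit(rep.bestkeeper.to_frame(), f"bestkeeper_{label}.tsv")
            _emit(rep.consensus.to_frame(), f"consensus_{label}.tsv")
            _emit(rep.v_series.to_frame(), f"pairwise_variation_{label}.tsv")
        if self.validation is not None:
            _emit(self.validation, "validation.tsv")
        cfg = self.config.to_dict()
        manifest = {
            "package": "refstab",
            "version": _pkg_version,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "files": files,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _analyse_subset(ct: CtMatrix, config: AnalysisConfig, grouped: bool) -> SubsetReport:
    q = relative_quantities(ct, config.efficiencies)
    gn = rank_stepwise(q)
    vs = pairwise_variation_series(q, gn, config.v_threshold)
    groups = None
    if grouped:
        sizes = pd.Series([ct.groups[s] for s in ct.sample_ids]).value_counts()
        if (sizes >= 2).all() and len(sizes) >= 2:
            groups = {s: ct.groups[s] for s in ct.sample_ids}
        else:
            warnings.warn(
                "some groups have fewer than 2 samples; "
                "falling back to the single-group stability model",
                stacklevel=3,
            )
    nf = normfinder_stability(log_quantities(q), groups)
    bk = bestkeeper_stats(ct)
    consensus = aggregate_ranks(
        {"genorm": gn.ranks, "normfinder": nf.ranks, "bestkeeper": bk.ranks},
        config.aggregation,
    )
    return SubsetReport(gn, nf, bk, consensus, vs)


def run_full_analysis(
    ct: CtMatrix,
    expression: ExpressionMatrix | None = None,
    config: AnalysisConfig | None = None,
) -> ReportBundle:
    """Run the complete reference-gene selection workflow.

    Stability is assessed on all samples and within each experimental
    group; each subset gets a geNorm, NormFinder and BestKeeper result
    plus their consensus and the pairwise-variation series. When
    ``config.targets`` and ``config.control_group`` are set, each target
    gene's fold change per treated group is computed against the top
    ``top_n_refs`` consensus genes of the all-samples ranking. The run is
    deterministic given inputs and configuration.
    """
    config = config or AnalysisConfig()
    mining = None
    candidates = None
    if expression is not None:
        mining = expression_stats(expression)
        candidates = filter_candidates(mining, config.cv_max)

    targets = list(config.targets)
    candidate_ct = ct
    if targets:
        keep = [g for g in ct.gene_ids if g not in targets]
        candidate_ct = CtMatrix(ct.mean_ct.loc[keep], ct.groups, ct.n_replicates)

    subsets: dict = {"all": _analyse_subset(candidate_ct, config, grouped=True)}
    for label in candidate_ct.group_labels():
        sub = candidate_ct.subset(label)
        if len(sub.sample_ids) < 3:
            warnings.warn(f"group {label!r} has fewer than 3 samples; subset analysis skipped", stacklevel=2)
            continue
        subsets[label] = _analyse_subset(sub, config, grouped=False)

    validation = None
    if targets:
        if config.control_group is None:
            raise ValidationError("ddCt validation needs config.control_group")
        refs = subsets["all"].consensus.ranking[: config.top_n_refs]
        rows = []
        for target in targets:
            if target not in ct.gene_ids:
                raise ValidationError(f"target gene {target!r} not present in the Ct matrix")
            folds = fold_changes_vs_control(ct, target, refs, config.control_group)
            for group, row in folds.iterrows():
                rows.append(
                    {
                        "target": target,
                        "group": group,
                        "refs": ",".join(refs),
                        "ddct": row["ddct"],
                        "fold": row["fold"],
                    }
                )
        validation = pd.DataFrame(rows).set_index(["target", "group"])

    return ReportBundle(
        subsets=subsets,
        mining=mining,
        candidates=candidates,
        validation=validation,
        config=config,
    )
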