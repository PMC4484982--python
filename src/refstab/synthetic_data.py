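"""Seeded generators for Ct tables and expression matrices with known structure.

The Ct generator follows the standard additive error model on the cycle
scale: a gene's measurement is its baseline Ct, plus a group effect (the
treatment-dependent shift that makes a gene a *bad* reference), plus a
biological-replicate effect and technical noise, both Gaussian:

    Ct[g, s, b, t] = baseline_g + effect_g[group(s)] + B_{g,s,b} + eps_{g,s,b,t}
    B ~ N(0, sigma_bio^2),  eps ~ N(0, sigma_tech^2)

Every draw is driven by one integer seed; each gene gets its own
deterministic substream (derived from the seed and a hash of the gene id),
so adding a gene to a design never perturbs the other genes' values.

:func:`stress_design` builds the default study layout this package is
organised around: a control plus three abiotic stress treatments (osmotic/
PEG, cold, salt) sampled over a 0/3/6/12 h time course (control at 0 h
only: 13 samples), with 3 biological x 3 technical replicates and 12
candidate genes whose baselines span the realistic 16-30 cycle range.
Three of the twelve are built stable (no group effects, ~0.1 cycle total
noise); the other nine carry 0.5-2.5 cycle treatment shifts.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import CT_COLUMNS, ExpressionMatrix, ValidationError, validate_ct_records

__all__ = [
    "GeneProfile",
    "SimulationConfig",
    "simulate_ct",
    "simulate_expression",
    "stress_panel_profiles",
    "stress_design",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class GeneProfile:
    """Generative parameters of one simulated gene.

    ``baseline_ct`` is the unstressed mean Ct (cycles); ``group_effects``
    maps group labels to additive Ct shifts (cycles; absent groups shift
    by 0); the sigmas are biological and technical noise SDs in cycles.
    """

    gene_id: str
    baseline_ct: float
    group_effects: Mapping[str, float] = field(default_factory=dict)
    sigma_bio: float = 0.0
    sigma_tech: float = 0.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_ct <= 0:
            raise ValidationError("baseline_ct must be positive")
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValidationError("noise SDs must be non-negative")

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_bio, self.sigma_tech))


@dataclass(frozen=True)
class SimulationConfig:
    """A full simulated design: gene profiles, sample layout and seed.

    ``groups`` maps each group label either to an integer sample count
    (sample ids are generated as ``<group>_s<i>``) or to an explicit
    sequence of sample ids. The seed is mandatory: there is no implicit
    randomness anywhere.
    """

    profiles: Sequence[GeneProfile]
    groups: Mapping[str, int | Sequence[str]]
    n_bio: int = 3
    n_tech: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValidationError("n_bio and n_tech must be >= 1")
        ids = [p.gene_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene ids in profiles")

    def sample_layout(self) -> list[tuple[str, str]]:
        """(sample_id, group_label) pairs in deterministic order."""
        layout = []
        for group, members in self.groups.items():
            if isinstance(members, int):
                names = [f"{group}_s{i + 1}" for i in range(members)]
            else:
                names = list(members)
            layout.extend((s, group) for s in names)
        if len({s for s, _ in layout}) != len(layout):
            raise ValidationError("duplicate sample ids in the design")
        return layout


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    # substream per gene: stable across platforms and gene-set composition
    return np.random.default_rng([int(seed) % _SEED_MOD, zlib.crc32(gene_id.encode())])


def simulate_ct(config: SimulationConfig) -> pd.DataFrame:
    """Draw a long-format Ct table under the additive cycle-scale error model."""
    layout = config.sample_layout()
    rows: list[tuple] = []
    for profile in config.profiles:
        rng = _gene_rng(config.seed, profile.gene_id)
        for sample_id, group in layout:
            effect = profile.group_effects.get(group, 0.0)
            bio = rng.normal(0.0, profile.sigma_bio, size=config.n_bio)
            tech = rng.normal(0.0, profile.sigma_tech, size=(config.n_bio, config.n_tech))
            base = profile.baseline_ct + effect
            for b in range(config.n_bio):
                for t in range(config.n_tech):
                    rows.append(
                        (sample_id, group, profile.gene_id, b + 1, t + 1, base + bio[b] + tech[b, t])
                    )
    df = pd.DataFrame(rows, columns=list(CT_COLUMNS))
    return validate_ct_records(df)


def simulate_expression(
    gene_cvs: Mapping[str, float],
    means: Mapping[str, float],
    n_conditions: int,
    seed: int,
) -> ExpressionMatrix:
    """Draw an FPKM-style matrix whose rows target given means and CVs.

    Each gene's values are log-normal with parameters solved from the
    requested mean m and coefficient of variation c:
    sigma^2 = ln(1 + c^2), mu = ln(m) - sigma^2 / 2. A CV of 0 yields a
    constant row at the mean.
    """
    if n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    missing = set(gene_cvs) ^ set(means)
    if missing:
        raise ValidationError(f"gene_cvs and means must cover the same genes; differ on {sorted(missing)}")
    rows = {}
    for gene, c in gene_cvs.items():
        m = float(means[gene])
        c = float(c)
        if m <= 0:
            raise ValidationError(f"mean for {gene!r} must be positive, got {m}")
        if c < 0 or not np.isfinite(c):
            raise ValidationError(f"target CV for {gene!r} must be finite and >= 0, got {c}")
        if c == 0:
            rows[gene] = np.full(n_conditions, m)
            continue
        sigma2 = np.log1p(c**2)
        if not np.isfinite(sigma2):
            raise ValidationError(f"target CV {c} for {gene!r} implies non-finite log-variance")
        mu = np.log(m) - sigma2 / 2
        rng = _gene_rng(seed, gene)
        rows[gene] = rng.lognormal(mu, np.sqrt(sigma2), size=n_conditions)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"cond_{i + 1}" for i in range(n_conditions)])
    return ExpressionMatrix(df)


#: treated groups of the default abiotic-stress design
STRESS_GROUPS = ("PEG", "COLD", "SALT")


def stress_panel_profiles() -> list[GeneProfile]:
    """Default 12-gene panel: 3 stable references among 9 treatment-responsive genes.

    Stable genes carry no group effects and ~0.1 cycle total noise
    (sigma_bio 0.08, sigma_tech 0.06); the rest shift by 0.5-2.5 cycles
    under at least one treatment with moderately larger replicate noise.
    Baselines span the realistic 16-30 cycle range of abundant (rRNA-like)
    to scarce transcripts.
    """
    stable = dict(sigma_bio=0.08, sigma_tech=0.06)
    profiles = [
        GeneProfile("REF1", 23.4, {}, **stable),
        GeneProfile("REF2", 21.8, {}, **stable),
        GeneProfile("REF3", 24.6, {}, **stable),
        GeneProfile("VAR1", 16.0, {"PEG": 1.2, "COLD": 0.8, "SALT": 2.0}, 0.5, 0.2),
        GeneProfile("VAR2", 18.5, {"PEG": -0.8, "COLD": 1.5, "SALT": 0.6}, 0.4, 0.2),
        GeneProfile("VAR3", 20.2, {"PEG": 0.6, "COLD": -1.1, "SALT": 0.9}, 0.3, 0.15),
        GeneProfile("VAR4", 22.0, {"PEG": 2.5, "COLD": 0.7, "SALT": -0.6}, 0.4, 0.2),
        GeneProfile("VAR5", 25.3, {"PEG": -1.4, "COLD": 0.9, "SALT": 1.1}, 0.5, 0.25),
        GeneProfile("VAR6", 26.5, {"PEG": 0.9, "COLD": 2.2, "SALT": 0.8}, 0.3, 0.2),
        GeneProfile("VAR7", 27.4, {"PEG": 0.5, "COLD": -0.9, "SALT": 1.6}, 0.6, 0.3),
        GeneProfile("VAR8", 28.8, {"PEG": 1.8, "COLD": 1.0, "SALT": -1.2}, 0.4, 0.2),
        GeneProfile("VAR9", 30.0, {"PEG": -0.7, "COLD": 1.3, "SALT": 2.4}, 0.5, 0.25),
    ]
    return profiles


def stress_design(
    seed: int,
    profiles: Sequence[GeneProfile] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
) -> SimulationConfig:
    """The default study layout: control at 0 h plus 3 treatments x 4 time points.

    Yields 13 samples (CK_0h and ``<GROUP>_<t>h`` for t in 0/3/6/12) with
    3 biological x 3 technical replicates by default.
    """
    time_points = (0, 3, 6, 12)
    groups: dict[str, Sequence[str]] = {"CK": ["CK_0h"]}
    for g in STRESS_GROUPS:
        groups[g] = [f"{g}_{t}h" for t in time_points]
    return SimulationConfig(
        profiles=list(profiles) if profiles is not None else stress_panel_profiles(),
        groups=groups,
        n_bio=n_bio,
        n_tech=n_tech,
        seed=seed,
    )
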