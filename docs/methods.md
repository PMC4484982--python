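# Methods

This note records the statistical conventions, model assumptions and
design decisions behind `refstab`, at the level of detail a user needs to
judge whether the defaults fit their experiment.

## Data model and replicate aggregation

A qPCR study is represented as a long table of cycle-threshold (Ct)
records keyed by (sample, gene, biological replicate, technical
replicate), with each sample assigned to one experimental group
(treatment). Aggregation to one mean Ct per (gene, sample) is **two-stage**
by default: technical replicates are averaged within each biological
replicate, then the biological-replicate means are averaged. For balanced
designs (equal technical counts per biological replicate) this equals the
pooled mean over all measurements; for unbalanced ones two-stage is the
defensible choice because it does not let a biological replicate with more
technical measurements dominate. The pooled mean remains available via
`aggregate_replicates(..., method="pooled")`.

Validation is strict where the downstream algorithms are strict: geNorm
and the model-based stability method require a complete genes × samples
matrix, so missing (gene, sample) cells are hard errors at aggregation
time. BestKeeper tolerates per-gene missing samples with a warning.
Ct values must be finite and positive; values outside (5, 40) cycles only
warn, since they are implausible rather than impossible. Delimiters are
inferred from file extension (`.tsv` → tab, otherwise comma) and can be
overridden.

## CV screening

Candidate mining computes, per gene across conditions, the mean expression
MV, the **sample** standard deviation SD (n−1 denominator) and CV = SD/MV.
The n−1 convention is used throughout the package; on the bundled
screening table it reproduces the published CV column to the printed
3 decimals, which the population SD does not. Printed values are rendered
round-half-up style at 3 decimals; one row of the bundled table
(recomputed CV 0.0897, printed 0.089) sits exactly on a truncation-vs-
rounding ambiguity, so the reproduction check requires 11 of 12 rows
rather than all 12. The screening cut-off is strict (CV < 0.3). Genes with
zero mean get an undefined CV and a flag instead of an error, so
genome-scale matrices survive screening.

## Relative quantities and normalization factors

Stability algorithms that work on expression levels consume relative
quantities q = E^−ΔCt, where ΔCt is the gene's Ct minus its minimum Ct
over samples and E is the per-gene amplification efficiency (default 2,
i.e. perfect doubling; efficiencies are consumed as inputs, never
estimated here). Quantities therefore lie in (0, 1] with the most
expressed sample at 1; anchoring removes per-gene constants and is
irrelevant to every downstream statistic (all are location-invariant on
the log scale). A normalization factor (NF) is the per-sample geometric
mean of the chosen reference genes' quantities — the geometric mean is
required because an arithmetic mean would be dominated by the most
abundant gene.

ΔΔCt fold changes average ΔCt (target minus mean reference Ct) within the
control and treated sample groups and report 2^−ΔΔCt. With multiple
reference genes the arithmetic mean on the Ct scale is used, which is
identical to dividing by a geometric-mean NF on the quantity scale.
Replicate-level error propagation is out of scope; fold changes are point
estimates.

## geNorm

Pairwise variation between genes j and k is the sample SD (n−1) of
log₂(q_j/q_k) across samples; M_j is the mean over all k ≠ j. Ranking is
stepwise: recompute M on the remaining set, exclude the highest-M gene
(ties broken by excluding the lexicographically last gene id — arbitrary
but deterministic and recorded), until two genes remain; these are
reported as a tied best pair (their mutual variation cannot be attributed
to either member). Genes with M below 1.5 are flagged as conventionally
"stable". The n−1 SD convention matches the rest of the package; switching
to n would scale every pairwise SD by the same √((n−1)/n) factor and
cannot change any ranking.

V(n/n+1) is the SD across samples of log₂(NF_n/NF_{n+1}), with NF_n built
from the n most stable genes in ranking order (a user-supplied order is
accepted). `optimal_n` is the smallest n with V_n strictly below the
threshold (default 0.15), or none if no n qualifies — the threshold is a
guideline, not a law, and is exposed as a parameter.

## Model-based stability (NormFinder-style)

Input is the genes × samples matrix of log₂ quantities. Each sample's
column is centered by its mean over genes, removing sample-wide loading
effects (this is why at least 3 genes are required). Within each group g
with n_g ≥ 2 samples, the two-way residuals give a naive per-gene variance
s²; because centering shares noise across genes, s² is bias-corrected as
σ̂² = max(0, (s² − Σs²/(k(k−1))) · k/(k−2)) for k genes (method-of-moments;
negative estimates floored at zero). The raw intergroup deviation d̂ is the
gene's group mean of centered values minus its grand mean. The spread of
true deviations γ² is estimated from Σd̂²/((k−1)(G−1)) minus the mean
sampling variance (floored at 0), and each d̂ is shrunk by
γ²/(γ² + σ̂²/n_g) — an empirical-Bayes step that stops noisy deviation
estimates from masquerading as real group effects. The stability value is
the mean over groups of |d̃| + √(Var(d̃)); lower is more stable. With a
single group the intergroup part is unidentifiable and the value falls
back to √σ̂², a plain (bias-corrected) variance ranking — documented as a
deviation from the grouped model.

Group structure is configuration, never guessed: the full-study driver
uses the Ct table's treatment labels when every group has ≥ 2 aggregated
samples and otherwise falls back, with a warning, to the single-group
model (in the default simulated design the control contributes one sample,
so the grouped model is applied to the treated samples or via the
fallback).

## BestKeeper

BestKeeper statistics stay on the Ct scale. Its "SD" is the **mean
absolute deviation** from the **arithmetic** mean Ct and its "CV" is
100·SD/mean Ct (percent of cycles — a different quantity from the
screening CV and never compared with it). These conventions are pinned by
an arithmetic consistency check: a gene with mean Ct 23.37 and MAD 0.68
must print CV 2.91, which the MAD-around-arithmetic-mean convention
reproduces exactly (the geometric-mean variant does not). Ranking is
ascending by (sd, cv, gene id); the SD > 1 cycle rule is a flag, not a
filter, since unacceptable genes are still worth tabulating. The optional
BestKeeper index is the per-sample geometric mean Ct of chosen genes with
per-gene Pearson correlations against it; the regression block of the
original program is not implemented (unused in this workflow).

## Consensus ranking

Per-method ranks (geNorm's tied pair as 1.5 each) are aggregated by the
geometric mean of ranks by default — the RefFinder convention — with the
arithmetic mean as an option; final ranks break score ties by gene id.
No published aggregation rule reproduces every literature table computed
with ad-hoc or undocumented combinations, so the package documents its own
rule rather than guessing; a gene strictly best in all methods is rank 1
under either rule.

## Synthetic data

The Ct generator uses the standard additive error model on the cycle
scale: baseline + per-group effect + N(0, σ²_bio) biological effect shared
across technical replicates + N(0, σ²_tech) technical noise. Noise is
Gaussian in cycles because that is the scale all three algorithms operate
on and the conventional qPCR error model. One integer seed drives
everything; each gene draws from a substream derived from the seed and a
CRC-32 of its gene id, so extending a panel never perturbs existing genes.

The default `stress_design` mirrors a 4-treatment abiotic-stress study:
control (CK, sampled at 0 h) plus PEG/COLD/SALT each at 0/3/6/12 h —
13 samples — with 3 biological × 3 technical replicates and 12 genes whose
baselines span 16–30 cycles (rRNA-abundant to scarce). Three genes are
built stable (no group effects, σ_bio 0.08 + σ_tech 0.06 ≈ 0.1 cycles
total); nine carry 0.5–2.5-cycle treatment shifts with 0.15–0.6-cycle
noise, values chosen as realistic for moderately stress-responsive
transcripts. Group effects are constant within a treatment (no explicit
time-course trend), so the generator emulates between-treatment
instability — the property the three algorithms measure on the full sample
set — but not slow temporal drift, amplification-efficiency drift,
outlier replicates or heavy-tailed noise. Passing recovery tests on this
generator therefore shows the algorithms separate group-responsive from
quiet genes under Gaussian cycle noise; it does not certify behaviour on
pathological real-world runs.

The expression-matrix generator draws per-gene log-normal rows with
parameters solved from a requested mean and CV (σ² = ln(1+cv²),
μ = ln(mean) − σ²/2), which makes CV-targeted screening fixtures exact in
expectation.

## Numerical and testing conventions

All SDs are n−1 unless stated (BestKeeper's MAD is a mean, not an SD).
Vectorized statistics (geNorm M via the log-quantity covariance matrix,
the model-based variance components) are tested to 1e−10 against
independent explicit-loop implementations, invariances (per-sample shifts,
per-gene offsets, CV scaling, NF log-linearity) are property-tested, and
parameter recovery is measured over 100 seeded simulations of the default
design (the three quiet genes must reach the top 4 of 12 per method in
≥ 95 % of runs; observed 100 %). Reports render floats at 3 decimals and
are byte-identical across reruns on identical input. Problem sizes in the
test-suite simulations (6–12 genes, 8–13 samples, 100 seeds) are chosen to
exercise every code path at interactive runtimes.

## Known limitations

* Efficiencies are consumed, not estimated; no amplification-curve
  processing.
* No confidence intervals on fold changes or stability values.
* The model-based method's best-pair search (combined stability of two
  genes) is not implemented.
* Aggregated subset analyses with < 3 samples are skipped with a warning.
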