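"""Independent brute-force implementations used only as test oracles.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def sd_n_minus_1(values) -> float:
    values = list(values)
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def genorm_m_oracle(q: pd.DataFrame) -> dict:
    """M per gene by double loop over all gene pairs."""
    genes = list(q.index)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [
                math.log2(q.at[j, s] / q.at[k, s]) for s in q.columns
            ]
            sds.append(sd_n_minus_1(ratios))
        out[j] = sum(sds) / len(sds)
    return out


def genorm_v_oracle(q: pd.DataFrame, order: list) -> dict:
    """V(n/n+1) by explicitly building each normalization-factor vector."""
    def nf(genes):
        return [
            math.exp(sum(math.log(q.at[g, s]) for g in genes) / len(genes))
            for s in q.columns
        ]

    out = {}
    for n in range(2, len(order)):
        a, b = nf(order[:n]), nf(order[: n + 1])
        out[n] = sd_n_minus_1([math.log2(x / y) for x, y in zip(a, b)])
    return out


def normfinder_oracle(logq: pd.DataFrame, groups: dict) -> dict:
    """Stability values by explicit loops over the variance-decomposition model.

    Returns dict with 'stability', 'sigma2' and 'dev' keyed per gene (and
    per group for the latter two).
    """
    genes = list(logq.index)
    samples = list(logq.columns)
    k = len(genes)
    labels = sorted(set(groups.values()), key=lambda g: samples.index(
        next(s for s in samples if groups[s] == g)))
    # sample-centering
    z = {}
    for s in samples:
        col_mean = sum(logq.at[g, s] for g in genes) / k
        for g in genes:
            z[(g, s)] = logq.at[g, s] - col_mean
    grand = {g: sum(z[(g, s)] for s in samples) / len(samples) for g in genes}

    sigma2, dhat = {}, {}
    for lab in labels:
        cols = [s for s in samples if groups[s] == lab]
        n = len(cols)
        row_mean = {g: sum(z[(g, s)] for s in cols) / n for g in genes}
        s2 = {
            g: sum((z[(g, s)] - row_mean[g]) ** 2 for s in cols) / (n - 1)
            for g in genes
        }
        total = sum(s2.values())
        for g in genes:
            corrected = (s2[g] - total / (k * (k - 1))) * k / (k - 2)
            sigma2[(g, lab)] = max(corrected, 0.0)
            dhat[(g, lab)] = row_mean[g] - grand[g]

    G = len(labels)
    if G == 1:
        stability = {g: math.sqrt(sigma2[(g, labels[0])]) for g in genes}
        dev = {key: 0.0 for key in dhat}
    else:
        n_of = {lab: sum(1 for s in samples if groups[s] == lab) for lab in labels}
        vard = {key: sigma2[key] / n_of[key[1]] for key in sigma2}
        gamma2 = sum(d**2 for d in dhat.values()) / ((k - 1) * (G - 1)) - (
            sum(vard.values()) / len(vard)
        )
        gamma2 = max(gamma2, 0.0)
        dev, stability = {}, {}
        for g in genes:
            rho = []
            for lab in labels:
                shrink = gamma2 / (gamma2 + vard[(g, lab)]) if gamma2 + vard[(g, lab)] > 0 else 0.0
                d_new = dhat[(g, lab)] * shrink
                var_new = vard[(g, lab)] * shrink
                dev[(g, lab)] = d_new
                rho.append(abs(d_new) + math.sqrt(var_new))
            stability[g] = sum(rho) / len(rho)
    return {"stability": stability, "sigma2": sigma2, "dev": dev}


def bestkeeper_oracle(ct: pd.DataFrame) -> dict:
    """Per-gene MAD-based SD and percent CV by explicit loops."""
    out = {}
    for g in ct.index:
        row = [ct.at[g, s] for s in ct.columns]
        mean = sum(row) / len(row)
        sd = sum(abs(v - mean) for v in row) / len(row)
        out[g] = {"mean": mean, "sd": sd, "cv": 100.0 * sd / mean}
    return out


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
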