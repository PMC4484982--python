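"""Bundled example data.

``candidate_fpkm`` is a published-style screening table: RNA-seq FPKM
values of 12 classical housekeeping candidates (actins, tubulins, GAPDHs,
18S rRNA, a metallothionein-like protein, fructose-bisphosphate aldolase
and histone H3) measured in a legume forb under four conditions — control
(CK), osmotic stress (PEG), cold and salt. It is the worked example for
coefficient-of-variation screening; ``CANDIDATE_FPKM_PUBLISHED_CV`` holds
the CV values as printed alongside the table (3 decimals), against which
recomputation can be checked.
"""

from __future__ import annotations

from importlib import resources

from .core_io import ExpressionMatrix, read_expression_matrix

__all__ = ["load_candidate_fpkm", "CANDIDATE_FPKM_PUBLISHED_CV"]

#: CV values printed with the screening table (rounded to 3 decimals)
CANDIDATE_FPKM_PUBLISHED_CV: dict[str, float] = {
    "18S": 0.054,
    "ACT101": 0.089,
    "ACTB": 0.188,
    "ACT7": 0.137,
    "ACT11": 0.071,
    "TUA": 0.132,
    "TUB": 0.152,
    "GAPDH1": 0.159,
    "GAPDH2": 0.075,
    "MET": 0.148,
    "FBA": 0.215,
    "HIS": 0.104,
}


def load_candidate_fpkm() -> ExpressionMatrix:
    """Load the bundled 12-gene x 4-condition FPKM screening matrix."""
    with resources.as_file(
        resources.files("refstab").joinpath("data/candidate_fpkm.tsv")
    ) as path:
        return read_expression_matrix(path)
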