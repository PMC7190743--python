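"""Recomputation of the published summary statistics from deposited data.

The study's per-variant summary data (normalized means, SEM, n and nominal
p-values for every assay) are deposited at doi:10.5683/SP2/DQOKPB and in
the journal's Source Data file; they are not redistributed here.  Given a
long-format export of that summary (tab-delimited with columns
variant_id, assay, n_f, sem, n, p_vs_wt, p_vs_null), this module re-runs
the downstream pipeline stages on it: cross-assay Pearson correlations,
per-assay phenotype-category tallies and the final four-tier
classification counts.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import classify, mechanism, phenotype
from .normalize import SCORE_COLUMNS
from .registry import default_assays

#: default location where a user can drop the deposited summary export
DEFAULT_SOURCE_PATH = Path("data") / "pten_source_summary.tsv"


def load_source_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"source summary {path} is missing column(s): {', '.join(missing)}")
    return df


def reproduce_source_summary(scores: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Deterministic recomputations on a per-variant summary table.

    Returns cross-assay Pearson correlations (pairwise-complete variants),
    per-assay category counts under each assay's headline vocabulary, and
    the final classification tallies with the stability-inclusion rule.
    """
    assays = default_assays()
    corr = mechanism.correlation_matrix(scores)
    calls = phenotype.call_scores(scores, alpha)
    counts = {a: phenotype.category_counts(calls, a) for a in scores["assay"].unique()}
    classification = classify.classify_study(scores, assays)
    return {
        "correlations": corr,
        "category_counts": counts,
        "label_counts": classify.label_counts(classification),
        "classification": classification,
    }
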