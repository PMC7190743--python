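"""Five-way phenotype calls per variant x assay, and dominant-negative tests.

A call combines the normalized mean with the two control contrasts:

1. not significant vs WT                      -> WT-like
2. significant vs WT and mean > 1             -> gain of function
3. significant vs null and mean < 0           -> dominant negative
   (reported as "below LoF" for assays without an endogenous-protein
   readout, i.e. yeast and fly)
4. significant vs null and 0 < mean < 1       -> partial LoF
5. not significant vs null, significant vs WT -> complete LoF
otherwise                                     -> indeterminate

The rules are evaluated in this order; a variant with missing p-values is
NOT_TESTED.  A variant non-significant against both controls is
indeterminate (excluded from category tallies) rather than silently
WT-like.
"""

from __future__ import annotations

import enum
import math

import numpy as np
import pandas as pd
from scipy import stats

from .registry import call_style


class Phenotype(enum.Enum):
    WT_LIKE = "WT_LIKE"
    GOF = "GOF"
    PARTIAL_LOF = "PARTIAL_LOF"
    COMPLETE_LOF = "COMPLETE_LOF"
    DOMINANT_NEGATIVE = "DOMINANT_NEGATIVE"
    INDETERMINATE = "INDETERMINATE"
    NOT_TESTED = "NOT_TESTED"


class RescueOutcome(enum.Enum):
    ABROGATED = "ABROGATED"
    RETAINED = "RETAINED"
    NOT_TESTED = "NOT_TESTED"


def call_phenotype(mean: float, p_vs_wt: float, p_vs_null: float, alpha: float = 0.05) -> Phenotype:
    """Apply the five-way decision rule to one normalized score."""
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in (mean, p_vs_wt, p_vs_null)):
        return Phenotype.NOT_TESTED
    if p_vs_wt >= alpha:
        return Phenotype.WT_LIKE
    if mean > 1.0:
        return Phenotype.GOF
    if p_vs_null < alpha and mean < 0.0:
        return Phenotype.DOMINANT_NEGATIVE
    if p_vs_null < alpha and 0.0 < mean < 1.0:
        return Phenotype.PARTIAL_LOF
    if p_vs_null >= alpha:
        return Phenotype.COMPLETE_LOF
    return Phenotype.INDETERMINATE


def call_scores(scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Phenotype calls for a normalized score table (variant_id, assay,
    n_f, p_vs_wt, p_vs_null).  Controls keep their defining identity and
    are not called."""
    out = scores.copy()
    out["call"] = [
        call_phenotype(r.n_f, r.p_vs_wt, r.p_vs_null, alpha).value
        for r in scores.itertuples()
    ]
    return out[["variant_id", "assay", "n_f", "call"]]


def category_counts(calls: pd.DataFrame, assay: str) -> dict:
    """Per-category tallies for one assay, using that assay's headline
    vocabulary: for yeast and fly assays dominant-negative ("below LoF")
    calls fold into the complete-LoF headline count; HEK-style assays keep
    them separate.  Tallies cover tested, determinate variants only and
    always partition them."""
    sub = calls[(calls["assay"] == assay) & (~calls["call"].isin(["NOT_TESTED", "INDETERMINATE"]))]
    counts = sub["call"].value_counts().to_dict()
    style = call_style(assay)
    out = {
        "n_tested": int(len(sub)),
        "wt_like": counts.get("WT_LIKE", 0),
        "gof": counts.get("GOF", 0),
        "partial_lof": counts.get("PARTIAL_LOF", 0),
    }
    dn = counts.get("DOMINANT_NEGATIVE", 0)
    complete = counts.get("COMPLETE_LOF", 0)
    if style in ("yeast", "fly"):
        out["complete_lof"] = complete + dn  # headline count includes below-LoF
        out["below_lof"] = dn
        out["dominant_negative"] = 0
    else:
        out["complete_lof"] = complete
        out["below_lof"] = 0
        out["dominant_negative"] = dn
    return out


def _ttest_from_summary(m1, sem1, n1, m2, sem2, n2) -> float:
    """Pooled-variance two-sample Student's t from summary statistics."""
    if n1 < 2 or n2 < 2:
        return float("nan")
    sd1, sd2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    if sd1 == 0 and sd2 == 0:
        return 1.0 if m1 == m2 else 0.0
    res = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.pvalue)


def dn_rescue_test(
    parental: pd.Series | dict,
    ko: pd.Series | dict | None,
    alpha: float = 0.05,
) -> RescueOutcome:
    """Does knocking out endogenous PTEN abrogate a dominant-negative effect?

    ``parental`` and ``ko`` are normalized-score records with n_f, sem and
    n.  ABROGATED when the parental-vs-KO two-sample Student's t test is
    significant at ``alpha`` and the KO mean is no longer below the null
    level (n_f >= 0); RETAINED otherwise (substrate-switching candidates).
    """
    if ko is None:
        return RescueOutcome.NOT_TESTED
    p = _ttest_from_summary(
        parental["n_f"], parental["sem"], parental["n"], ko["n_f"], ko["sem"], ko["n"]
    )
    if math.isnan(p):
        return RescueOutcome.NOT_TESTED
    if p < alpha and ko["n_f"] >= 0.0:
        return RescueOutcome.ABROGATED
    return RescueOutcome.RETAINED


def stability_shift(parental_stability: float, ko_stability: float, threshold: float = 0.10) -> bool:
    """Flag variants whose stability (WT=1 scale) moves by more than the
    threshold between parental and knockout backgrounds."""
    return abs(parental_stability - ko_stability) > threshold
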