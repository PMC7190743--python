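"""Four-tier variant classification from binary LoF calls across assays.

Each assay a variant was tested in contributes a binary call: LoF when the
normalized function is below 50% of WT, WT-like otherwise.  Stability
assays are special: a stability value enters the tally only when the
protein is unstable (binary LoF true), because WT-like stability is not
predictive of WT-like function while instability does predict dysfunction.
The score s = n_LoF / n_assays then maps to a label, first match wins:

- Pathogenic:        s >= 0.75 and LoF in at least 3 assays
- Likely Pathogenic: s > 0.5   and LoF in at least 2 assays
- Likely Benign:     s < 0.25  and WT-like in at least 2 assays
- VUS:               everything else (including too little or conflicting data)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .registry import STABILITY, AssayDef

LOF_CUTOFF = 0.5


class Label(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    VUS = "VUS"


@dataclass
class ClassificationResult:
    variant_id: str
    n_assays: int
    n_lof: int
    n_wt_like: int
    score: float
    label: Label
    note: str = ""


def binary_lof(n_f: float, cutoff: float = LOF_CUTOFF) -> bool:
    """LoF iff normalized function is strictly below the cutoff (<50% of
    WT effect); exactly 50% counts as WT-like."""
    if n_f is None or (isinstance(n_f, float) and math.isnan(n_f)):
        raise ValueError("binary_lof needs a non-missing normalized value")
    return n_f < cutoff


def include_stability(stability_nf: float, cutoff: float = LOF_CUTOFF) -> bool:
    """A stability assay joins a variant's tally only when the protein is
    unstable; stable (or hyper-stable) values contribute nothing."""
    return binary_lof(stability_nf, cutoff)


def _label_from_counts(n_assays: int, n_lof: int) -> Label:
    n_wt = n_assays - n_lof
    score = n_lof / n_assays
    if score >= 0.75 and n_lof >= 3:
        return Label.PATHOGENIC
    if score > 0.5 and n_lof >= 2:
        return Label.LIKELY_PATHOGENIC
    if score < 0.25 and n_wt >= 2:
        return Label.LIKELY_BENIGN
    return Label.VUS


def classify_variant(
    variant_id: str,
    values: dict[str, float],
    assays: dict[str, AssayDef],
    cutoff: float = LOF_CUTOFF,
    stability_filter: bool = True,
) -> ClassificationResult:
    """Classify one variant from its per-assay normalized values.

    ``values`` maps assay name to normalized mean; missing values (NaN)
    are excluded from the denominator ("number of assays performed").
    """
    n_lof = n_assays = 0
    for name, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        is_stability = name in assays and assays[name].kind == STABILITY
        if is_stability and stability_filter and not include_stability(v, cutoff):
            continue
        n_assays += 1
        n_lof += int(binary_lof(v, cutoff))
    if n_assays == 0:
        return ClassificationResult(variant_id, 0, 0, 0, float("nan"), Label.VUS, note="no data")
    return ClassificationResult(
        variant_id,
        n_assays,
        n_lof,
        n_assays - n_lof,
        n_lof / n_assays,
        _label_from_counts(n_assays, n_lof),
    )


def classify_study(
    scores: pd.DataFrame,
    assays: dict[str, AssayDef],
    cutoff: float = LOF_CUTOFF,
    stability_filter: bool = True,
    exclude: tuple[str, ...] = ("WT", "EV", "GFP", "untransfected"),
) -> pd.DataFrame:
    """Classification table for a normalized score frame (variant_id,
    assay, n_f), mirroring the per-variant binary-call matrix."""
    wide = scores.pivot_table(index="variant_id", columns="assay", values="n_f", aggfunc="first")
    rows = []
    for vid, row in wide.iterrows():
        if vid in exclude:
            continue
        res = classify_variant(str(vid), row.to_dict(), assays, cutoff, stability_filter)
        rows.append(
            {
                "variant_id": res.variant_id,
                "n_assays": res.n_assays,
                "n_lof": res.n_lof,
                "n_wt_like": res.n_wt_like,
                "score": res.score,
                "label": res.label.value,
                "note": res.note,
            }
        )
    return pd.DataFrame(rows)


def label_counts(classification: pd.DataFrame) -> dict:
    counts = classification["label"].value_counts().to_dict()
    return {label.value: int(counts.get(label.value, 0)) for label in Label}
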