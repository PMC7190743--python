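"""Control-anchored rescaling of adjusted values onto the 0-1 function axis.

Every assay is reported on a common scale with the null control at 0 and
wild type at 1: n = (y - m_null) / (m_wt - m_null), applied to the
random-effect-adjusted values.  The map is affine, so it automatically
orients assays whose raw measurement decreases with PTEN function (the WT
anchor is simply below the null anchor); the per-assay ``orientation``
metadata is validated against the sign of the estimated control
separation rather than applied a second time.  Standard errors are
rescaled by the same factor 1/|m_wt - m_null|, the unique linear choice
consistent with the affine map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import mixed_model
from .registry import AssayDef

SCORE_COLUMNS = ["variant_id", "assay", "n_f", "sem", "n", "p_vs_wt", "p_vs_null"]


class UnnormalizableAssayError(ValueError):
    """WT and null control means do not separate; no 0-1 axis exists."""


def rescale_to_controls(
    adjusted: pd.DataFrame,
    wt_label: str,
    null_label: str,
    orientation: int = 1,
) -> pd.DataFrame:
    """Per-genotype normalized scores from per-row adjusted values.

    ``adjusted`` needs columns genotype and value.  Genotype means are
    normalized so the WT mean is exactly 1 and the null mean exactly 0;
    per-genotype SEMs are divided by the control separation.  Raises
    :class:`UnnormalizableAssayError` when the controls fail to separate
    beyond 1e-6 of the pooled SD.
    """
    groups = adjusted.groupby("genotype")["value"]
    means = groups.mean()
    for label in (wt_label, null_label):
        if label not in means.index:
            raise ValueError(f"control genotype {label!r} absent from adjusted values")
    m_wt, m_null = means[wt_label], means[null_label]
    sep = m_wt - m_null
    pooled_sd = float(adjusted["value"].std(ddof=1)) if len(adjusted) > 1 else 0.0
    if abs(sep) < 1e-6 * max(pooled_sd, np.finfo(float).tiny):
        raise UnnormalizableAssayError(
            f"controls {wt_label!r} and {null_label!r} do not separate (|diff|={abs(sep):.3g})"
        )
    if orientation * np.sign(sep) < 0:
        warnings.warn(
            f"declared orientation {orientation:+d} disagrees with the estimated "
            f"control separation (WT - null = {sep:.3g}); the control anchoring wins",
            stacklevel=2,
        )
    sems = groups.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    out = pd.DataFrame(
        {
            "genotype": means.index,
            "n_f": np.where(
                means.index == wt_label,
                1.0,
                np.where(means.index == null_label, 0.0, (means - m_null) / sep),
            ),
            "sem": (sems / abs(sep)).to_numpy(),
            "n": groups.size().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def score_assay(
    replicates: pd.DataFrame,
    assay: AssayDef,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit, contrast and normalize one assay's replicate table.

    Returns the per-variant normalized score table (the structure of the
    study's summary sheets): variant_id, assay, n_f, sem, n, p_vs_wt,
    p_vs_null.  Controls carry their defining values (WT n_f = 1 exactly,
    null n_f = 0 exactly) with p = NaN against themselves.
    """
    sub = replicates[replicates["assay"] == assay.name] if "assay" in replicates.columns else replicates
    if sub.empty:
        raise ValueError(f"no rows for assay {assay.name!r}")
    fit = mixed_model.fit_mixed_model(sub[["genotype", "batch", "value"]])
    adjusted = pd.DataFrame(
        {"genotype": fit.data["genotype"].to_numpy(), "value": fit.adjusted_values}
    )
    scores = rescale_to_controls(adjusted, assay.wt_label, assay.null_label, assay.orientation)
    p_wt = mixed_model.contrast_pvalues(fit, assay.wt_label).set_index("genotype")["p_value"]
    p_null = mixed_model.contrast_pvalues(fit, assay.null_label).set_index("genotype")["p_value"]
    scores["p_vs_wt"] = scores["genotype"].map(p_wt)
    scores["p_vs_null"] = scores["genotype"].map(p_null)
    scores.insert(1, "assay", assay.name)
    return scores.rename(columns={"genotype": "variant_id"})[SCORE_COLUMNS]


def score_study(
    replicates: pd.DataFrame,
    assays: dict[str, AssayDef],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Normalized scores for every assay present in the replicate table."""
    present = replicates["assay"].unique()
    missing = [a for a in present if a not in assays]
    if missing:
        raise ValueError(f"assays without a registry entry: {missing}")
    return pd.concat(
        [score_assay(replicates, assays[a], alpha) for a in present], ignore_index=True
    )
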