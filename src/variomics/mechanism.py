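"""Stability-dependence analysis: nF - nS, domains, correlations, COSMIC strata.

Subtracting a variant's normalized stability (nS) from its normalized
function (nF) separates two mechanisms of dysfunction: delta ~ 0 means
function tracks stability (instability, hence haploinsufficiency, is the
likely mechanism), while delta near -1 means the protein is more broken
than its abundance explains (substrate-binding or catalytic damage).  The
stability-independent domains are the N-terminal/PIP3-binding region
(AA 1-55), the WPD-loop (AA 92-93) and the P-loop (AA 123-131) of the
403-residue reference protein; for yeast assays nS is the yeast abundance
measure, for all other assays the HEK293 stability measure.
"""

from __future__ import annotations

import enum
import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .registry import STABILITY, AssayDef
from .roster import SPECIAL_TOKENS

PROTEIN_LENGTH = 403
STABILITY_INDEPENDENT_RANGES = ((1, 55), (92, 93), (123, 131))

_VARIANT_RE = re.compile(r"^([ACDEFGHIKLMNPQRSTVWY])(\d+)([ACDEFGHIKLMNPQRSTVWY]|X|\*)$")


class Domain(enum.Enum):
    STABILITY_INDEPENDENT = "STABILITY_INDEPENDENT"
    STABILITY_DEPENDENT = "STABILITY_DEPENDENT"
    UNASSIGNED = "UNASSIGNED"


class Stratum(enum.Enum):
    ZERO = "ZERO"
    ONE_TO_SEVEN = "ONE_TO_SEVEN"
    EIGHT_PLUS = "EIGHT_PLUS"


def parse_variant_position(variant_id: str):
    """Parse an HGVS-protein-style id into (ref, position, alt).

    ``alt`` is "*" for a nonsense (stop) variant written with X or *.
    Registered special tokens (WT, EV, 4A, C124S-4A, ...) return None:
    they have no single amino-acid position.
    """
    if variant_id in SPECIAL_TOKENS:
        return None
    m = _VARIANT_RE.match(variant_id)
    if not m:
        raise ValueError(f"unparseable variant id: {variant_id!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if not 1 <= pos <= PROTEIN_LENGTH:
        raise ValueError(f"{variant_id!r}: position {pos} outside 1..{PROTEIN_LENGTH}")
    return ref, pos, "*" if alt in ("X", "*") else alt


def domain_class(position: int) -> Domain:
    """Stability-independent iff the residue lies in AA 1-55, 92-93 or 123-131."""
    if not 1 <= position <= PROTEIN_LENGTH:
        raise ValueError(f"position {position} outside 1..{PROTEIN_LENGTH}")
    for lo, hi in STABILITY_INDEPENDENT_RANGES:
        if lo <= position <= hi:
            return Domain.STABILITY_INDEPENDENT
    return Domain.STABILITY_DEPENDENT


def variant_domain(variant_id: str) -> Domain:
    parsed = parse_variant_position(variant_id)
    if parsed is None:
        return Domain.UNASSIGNED
    return domain_class(parsed[1])


def stability_source(assay_name: str) -> str:
    """Which stability assay supplies nS: yeast abundance for yeast assays,
    HEK293 stability for everything else."""
    return "yeast_abundance" if assay_name.startswith("yeast") else "hek_stability"


def mechanism_scores(
    scores: pd.DataFrame,
    assays: dict[str, AssayDef],
    exclude: tuple[str, ...] = ("WT", "EV", "GFP", "untransfected"),
) -> pd.DataFrame:
    """Delta table: variant x functional assay with nF, nS, delta and domain."""
    wide = scores.pivot_table(index="variant_id", columns="assay", values="n_f", aggfunc="first")
    rows = []
    for name, assay in assays.items():
        if assay.kind == STABILITY or name not in wide.columns:
            continue
        src = stability_source(name)
        if src not in wide.columns:
            continue
        for vid in wide.index:
            if vid in exclude:
                continue
            n_f, n_s = wide.at[vid, name], wide.at[vid, src]
            if pd.isna(n_f) or pd.isna(n_s):
                continue
            rows.append(
                {
                    "variant_id": vid,
                    "assay": name,
                    "n_f": float(n_f),
                    "n_s": float(n_s),
                    "delta": float(n_f) - float(n_s),
                    "domain": variant_domain(str(vid)).value,
                }
            )
    return pd.DataFrame(rows)


def combine_deltas(mech: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean delta across assays (one interpretation of pooling
    all models into a single distribution)."""
    out = (
        mech.groupby(["variant_id", "domain"], as_index=False)["delta"].mean()
    )
    return out


def delta_distribution_test(mech: pd.DataFrame):
    """Two-sided pooled-variance t test of delta between domain groups.

    Returns (group means dict, t statistic, p value).  Variants without an
    assignable position are excluded; each group needs >= 2 members.
    """
    indep = mech.loc[mech["domain"] == Domain.STABILITY_INDEPENDENT.value, "delta"].to_numpy()
    dep = mech.loc[mech["domain"] == Domain.STABILITY_DEPENDENT.value, "delta"].to_numpy()
    if len(indep) < 2 or len(dep) < 2:
        raise ValueError("each domain group needs at least two members")
    t, p = stats.ttest_ind(indep, dep, equal_var=True)
    means = {
        Domain.STABILITY_INDEPENDENT.value: float(np.mean(indep)),
        Domain.STABILITY_DEPENDENT.value: float(np.mean(dep)),
    }
    return means, float(t), float(p)


def correlation_matrix(
    scores: pd.DataFrame,
    subset: Domain | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between assays over variants.

    ``subset`` restricts to variants in one domain group.  Pairs sharing
    fewer than ``min_shared`` variants are set to missing.
    """
    df = scores.copy()
    if subset is not None:
        df = df[df["variant_id"].map(lambda v: variant_domain(str(v)) == subset)]
    wide = df.pivot_table(index="variant_id", columns="assay", values="n_f", aggfunc="first")
    return wide.corr(method="pearson", min_periods=min_shared)


def cosmic_stratum(count: int) -> Stratum:
    """COSMIC report-count stratum: 0, 1-7, or 8+."""
    if count < 0:
        raise ValueError("COSMIC count must be non-negative")
    if count == 0:
        return Stratum.ZERO
    if count <= 7:
        return Stratum.ONE_TO_SEVEN
    return Stratum.EIGHT_PLUS


def cosmic_stratified_test(
    scores: pd.DataFrame,
    cosmic_counts: pd.Series | dict,
    exclude: tuple[str, ...] = ("WT", "EV", "GFP", "untransfected"),
):
    """Per-assay stratum means plus a two-way fixed-effects ANOVA
    (factors: stratum and assay) on normalized function.

    Empty strata are dropped with a warning.  Returns (means frame,
    ANOVA table from the standard type-II decomposition).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = pd.Series(cosmic_counts)
    df = scores[~scores["variant_id"].isin(exclude)].copy()
    df = df[df["variant_id"].isin(counts.index)]
    df["stratum"] = df["variant_id"].map(lambda v: cosmic_stratum(int(counts[v])).value)
    present = set(df["stratum"].unique())
    missing = [s.value for s in Stratum if s.value not in present]
    if missing:
        warnings.warn(f"empty COSMIC strata dropped: {', '.join(missing)}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("need at least two COSMIC strata represented")
    means = df.groupby(["assay", "stratum"], as_index=False)["n_f"].agg(["mean", "sem", "count"])
    if df["assay"].nunique() > 1:
        model = smf.ols("n_f ~ C(stratum) + C(assay)", data=df).fit()
    else:
        model = smf.ols("n_f ~ C(stratum)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return means, anova
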