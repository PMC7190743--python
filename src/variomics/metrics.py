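"""Raw per-assay measurements, computed exactly as each assay defines them.

Flow-cytometry gating and background-subtracted median ratios, the worm
chemotaxis index, western-blot densitometry double normalization, yeast
colony-size ratios and the rolling median used for expression-vs-response
visualization.  Orientation (which way a raw measure moves with PTEN
function) is deliberately NOT applied here; raw metrics stay faithful to
each assay's native scale and the control-anchored normalization stage
orients them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default sfGFP gate for the pAKT assay: above untransfected to 100x above
GFP_GATE_LOW = 300.0
GFP_GATE_HIGH = 20_000.0
#: rfp level below which a cell counts as untransfected
RFP_NEGATIVE_THRESHOLD = 300.0


class UnscorableError(ValueError):
    """A raw measurement cannot be computed from the given record."""


@dataclass(frozen=True)
class ChemotaxisCount:
    """Worms in the NaCl zone (A) and the control zone (B); middle-zone
    worms are uncounted."""

    A: int
    B: int

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("zone counts must be non-negative")


@dataclass(frozen=True)
class DensitometryRecord:
    band: float
    loading: float
    wt_reference: float  # WT band/loading on the same blot


@dataclass(frozen=True)
class ColonyPair:
    size_control: float       # +Ura plate
    size_experimental: float  # -Ura plate


def chemotaxis_index(c: ChemotaxisCount) -> float:
    """(A - B)/(A + B), in [-1, 1]."""
    if c.A + c.B == 0:
        raise UnscorableError("unscorable plate: no worms in either zone (A + B = 0)")
    return (c.A - c.B) / (c.A + c.B)


def gate_pakt(
    cells: pd.DataFrame,
    gfp_low: float = GFP_GATE_LOW,
    gfp_high: float = GFP_GATE_HIGH,
    rfp_threshold: float = RFP_NEGATIVE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a well into (transfected, in-well untransfected) subsets.

    Transfected: gfp in (gfp_low, gfp_high].  Untransfected: gfp below the
    lower gate AND rfp-negative.  Cells above the upper gate fall in
    neither subset, so the two gates never overlap.
    """
    if not gfp_low < gfp_high:
        raise ValueError("gfp_low must be below gfp_high")
    gfp = cells["gfp"]
    transfected = cells[(gfp > gfp_low) & (gfp <= gfp_high)]
    untransfected = cells[(gfp <= gfp_low) & (cells["rfp"] <= rfp_threshold)]
    if transfected.empty:
        warnings.warn("empty transfected gate; downstream effect will be missing", stacklevel=2)
    return transfected, untransfected


def _median_ratio(cells: pd.DataFrame, num: str, den: str, bg_num: float, bg_den: float) -> tuple[float, int]:
    """Median of (num-bg)/(den-bg); cells with non-positive denominators are
    dropped (clipping would bias the median), and the dropped count returned."""
    n = cells[num].to_numpy(dtype=float) - bg_num
    d = cells[den].to_numpy(dtype=float) - bg_den
    keep = d > 0
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        return float("nan"), dropped
    return float(np.median(n[keep] / d[keep])), dropped


def pakt_effect(
    cells: pd.DataFrame,
    background: dict,
    gfp_low: float = GFP_GATE_LOW,
    gfp_high: float = GFP_GATE_HIGH,
    rfp_threshold: float = RFP_NEGATIVE_THRESHOLD,
) -> float:
    """In-well-normalized pAKT/AKT effect for one well.

    Median over transfected cells of (af647-bg)/(af405-bg) minus the same
    median over the in-well untransfected cells.  Zero means no effect; a
    functional variant drives the difference negative, a dominant negative
    pushes it above the untransfected level.
    """
    transfected, untransfected = gate_pakt(cells, gfp_low, gfp_high, rfp_threshold)
    if transfected.empty or untransfected.empty:
        return float("nan")
    m_t, drop_t = _median_ratio(transfected, "af647", "af405", background["af647"], background["af405"])
    m_u, drop_u = _median_ratio(untransfected, "af647", "af405", background["af647"], background["af405"])
    dropped = drop_t + drop_u
    if dropped > 0.5 * len(cells):
        warnings.warn(f"{dropped} of {len(cells)} cells dropped (non-positive denominator)", stacklevel=2)
    return m_t - m_u


def stability_ratio(
    cells: pd.DataFrame,
    background: dict,
    gfp_cap: float = GFP_GATE_HIGH,
    rfp_threshold: float = RFP_NEGATIVE_THRESHOLD,
) -> float:
    """Median background-subtracted gfp/rfp over rfp-positive cells.

    Gate: rfp above the untransfected level and gfp below ``gfp_cap``.
    Returns NaN (with a warning) when the gate is empty; per-day WT
    normalization to 1 happens downstream.
    """
    gated = cells[(cells["rfp"] > rfp_threshold) & (cells["gfp"] < gfp_cap)]
    if gated.empty:
        warnings.warn("empty stability gate; returning missing value", stacklevel=2)
        return float("nan")
    value, _ = _median_ratio(gated, "gfp", "rfp", background["gfp"], background["rfp"])
    return value


def densitometry_abundance(rec: DensitometryRecord) -> float:
    """(band/loading) / wt_reference: loading-control then WT double
    normalization on the same blot."""
    if rec.loading <= 0:
        raise UnscorableError("loading control must be positive")
    if rec.wt_reference <= 0:
        raise UnscorableError("WT reference (band/loading) must be positive")
    return (rec.band / rec.loading) / rec.wt_reference


def colony_ratio(p: ColonyPair) -> float:
    """-Ura / +Ura colony-size ratio; smaller means a stronger negative
    genetic interaction."""
    if p.size_control <= 0:
        raise UnscorableError("unscorable colony pair: control (+Ura) size must be positive")
    if p.size_experimental < 0:
        raise ValueError("colony sizes must be non-negative")
    return p.size_experimental / p.size_control


def rolling_median(pairs, window: int = 101):
    """Centered rolling median of ratios along expression-sorted pairs.

    ``pairs`` is a sequence of (expression, ratio) sorted by expression.
    The window must be odd and >= 3; at the edges it shrinks to whatever
    points are available.  With fewer points than the window, every output
    is the global median.  Returns a list of (expression, smoothed ratio).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    expr = [p[0] for p in pairs]
    if any(b < a for a, b in zip(expr, expr[1:])):
        raise ValueError("pairs must be sorted by expression")
    ratios = np.asarray([p[1] for p in pairs], dtype=float)
    n = len(ratios)
    if n == 0:
        return []
    if n < window:
        g = float(np.median(ratios))
        return [(e, g) for e in expr]
    half = window // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out.append((expr[i], float(np.median(ratios[lo:hi]))))
    return out


def per_day_wt_normalize(values: pd.DataFrame, wt_label: str = "WT") -> pd.Series:
    """Normalize per-well raw measures to the same-day WT mean = 1.

    ``values`` needs columns genotype, day, value; returns the normalized
    value series aligned with the input rows.
    """
    out = pd.Series(index=values.index, dtype=float)
    for day, group in values.groupby("day", sort=False):
        wt = group.loc[group["genotype"] == wt_label, "value"]
        if wt.empty or wt.mean() == 0:
            raise UnscorableError(f"no usable WT reference on day {day!r}")
        out.loc[group.index] = group["value"] / wt.mean()
    return out
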