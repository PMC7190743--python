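"""Variant roster: ground-truth specifications for simulated PTEN variants.

A roster entry carries everything the synthetic-data generator needs to
emit realistic measurements with known truth: a normalized functional score
(WT=1, null=0; negative for dominant negatives, >1 for gain of function), a
normalized stability (WT=1), a ground-truth phenotype class, a COSMIC
report count and disease-category labels.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

_VARIANT_RE = re.compile(r"^([ACDEFGHIKLMNPQRSTVWY])(\d+)([ACDEFGHIKLMNPQRSTVWY]|X|\*)$")

#: ids that are legal roster tokens but carry no single amino-acid position
SPECIAL_TOKENS = frozenset({"WT", "EV", "GFP", "4A", "C124S-4A", "untransfected"})


class TrueClass(enum.Enum):
    WT_LIKE = "WT_LIKE"
    GOF = "GOF"
    PARTIAL_LOF = "PARTIAL_LOF"
    COMPLETE_LOF = "COMPLETE_LOF"
    DOMINANT_NEGATIVE = "DOMINANT_NEGATIVE"


class Category(enum.Enum):
    ASD = "ASD"
    PHTS = "PHTS"
    SOMATIC_CANCER = "SOMATIC_CANCER"
    POPULATION = "POPULATION"
    BIOCHEMICAL = "BIOCHEMICAL"
    PREDICTED_HIGH = "PREDICTED_HIGH"
    PREDICTED_LOW = "PREDICTED_LOW"


@dataclass(frozen=True)
class VariantSpec:
    variant_id: str
    true_function: float
    true_stability: float
    true_class: TrueClass
    cosmic_count: int = 0
    categories: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.cosmic_count < 0:
            raise ValueError("cosmic_count must be non-negative")
        if self.variant_id not in SPECIAL_TOKENS and not _VARIANT_RE.match(self.variant_id):
            raise ValueError(f"unparseable variant id {self.variant_id!r}")
        c, f = self.true_class, self.true_function
        if c is TrueClass.DOMINANT_NEGATIVE and not f < 0:
            raise ValueError(f"{self.variant_id}: dominant negative requires true_function < 0")
        if c is TrueClass.COMPLETE_LOF and abs(f) > 0.05:
            raise ValueError(f"{self.variant_id}: complete LoF requires true_function ~ 0")
        if c is TrueClass.GOF and not f > 1:
            raise ValueError(f"{self.variant_id}: gain of function requires true_function > 1")


def _v(vid, f, s, cls, cosmic=0, cats=()):
    return VariantSpec(vid, f, s, cls, cosmic, frozenset(Category(c) for c in cats))


def default_roster() -> list[VariantSpec]:
    """30 variants spanning all five ground-truth classes, plus controls.

    Ids are real PTEN variants; positions are chosen so that the
    dominant-negative and catalytically dead entries fall inside the
    substrate-binding/catalytic regions (N-terminus/PBD 1-55, WPD-loop
    92-93, P-loop 123-131) while stability-driven loss of function sits
    outside them, with true_stability tracking true_function for the latter
    group only.  Functional scores are on the WT=1/null=0 axis.
    """
    W, G, P, C, D = (TrueClass.WT_LIKE, TrueClass.GOF, TrueClass.PARTIAL_LOF,
                     TrueClass.COMPLETE_LOF, TrueClass.DOMINANT_NEGATIVE)
    roster = [
        # controls (always present; EV doubles as the null genotype)
        _v("WT", 1.0, 1.0, W),
        _v("EV", 0.0, 0.0, C),
        # WT-like (stability ~WT, function exactly WT)
        _v("P354Q", 1.0, 1.0, W, 0, ["ASD", "POPULATION"]),
        _v("T78A", 1.0, 0.95, W, 0, ["ASD"]),
        _v("T202I", 1.0, 1.0, W, 0, ["ASD"]),
        _v("D268E", 1.0, 1.05, W, 0, ["POPULATION"]),
        _v("I135V", 1.0, 0.9, W, 0, ["PHTS"]),
        _v("N340H", 1.0, 1.0, W, 0, ["PHTS"]),
        # gain of function
        _v("4A", 1.5, 0.5, G, 0, ["BIOCHEMICAL"]),
        _v("N117S", 1.2, 1.0, G, 0, ["PHTS"]),
        # partial LoF, stability-dependent (function tracks stability)
        _v("T167N", 0.5, 0.5, P, 1, ["ASD"]),
        _v("Y176C", 0.6, 0.6, P, 1, ["ASD"]),
        _v("L70V", 0.4, 0.45, P, 0, ["ASD"]),
        _v("E157G", 0.55, 0.55, P, 2, ["ASD"]),
        _v("Y65C", 0.35, 0.4, P, 1, ["ASD", "PREDICTED_HIGH"]),
        _v("K342N", 0.7, 0.7, P, 0, ["PHTS"]),
        # complete LoF, stability-dependent (unstable, outside catalytic domains)
        _v("D326N", 0.0, 0.15, C, 3, ["ASD", "PHTS", "PREDICTED_HIGH"]),
        _v("C105F", 0.0, 0.2, C, 4, ["ASD", "PHTS"]),
        _v("R335X", 0.0, 0.1, C, 21, ["ASD", "PHTS", "SOMATIC_CANCER"]),
        _v("F341V", 0.0, 0.25, C, 2, ["ASD", "PREDICTED_HIGH"]),
        _v("L345Q", 0.0, 0.2, C, 1, ["PHTS"]),
        # complete LoF, stability-independent (stable but dead: catalytic pocket)
        _v("H93Q", 0.0, 0.9, C, 2, ["ASD", "PHTS"]),
        _v("T131I", 0.0, 0.85, C, 6, ["ASD", "PHTS"]),
        _v("R130X", 0.0, 0.8, C, 196, ["ASD", "PHTS", "SOMATIC_CANCER"]),
        # dominant negative (catalytic/substrate-binding domains, stable-ish)
        _v("C124S", -0.5, 0.8, D, 9, ["BIOCHEMICAL", "SOMATIC_CANCER"]),
        _v("G129E", -0.45, 0.75, D, 12, ["BIOCHEMICAL", "PHTS", "SOMATIC_CANCER"]),
        _v("R130Q", -0.6, 0.85, D, 286, ["ASD", "PHTS", "SOMATIC_CANCER"]),
        _v("A126D", -0.4, 0.8, D, 8, ["SOMATIC_CANCER"]),
        _v("H123Q", -0.35, 0.9, D, 1, ["ASD"]),
        _v("P38H", -0.5, 0.85, D, 10, ["ASD", "SOMATIC_CANCER"]),
        _v("G36E", -0.3, 0.9, D, 1, ["ASD"]),
        _v("C124S-4A", -0.4, 0.6, D, 0, ["BIOCHEMICAL"]),
    ]
    return roster


def roster_truth_frame(roster):
    """Ground-truth sidecar as a DataFrame keyed by variant_id."""
    import pandas as pd

    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in roster],
            "true_function": [v.true_function for v in roster],
            "true_stability": [v.true_stability for v in roster],
            "true_class": [v.true_class.value for v in roster],
            "cosmic_count": [v.cosmic_count for v in roster],
            "categories": [";".join(sorted(c.value for c in v.categories)) for v in roster],
        }
    )
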