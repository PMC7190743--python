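"""Assay registry: per-assay metadata the pipeline needs.

Each assay is described by the labels of its positive (wild-type PTEN) and
negative (no functional PTEN) controls, the direction in which its raw
measurement moves with PTEN function, and whether it reads out function or
protein stability/abundance.  The raw anchor values (``raw_wt``,
``raw_null``) are only used by the synthetic-data generator to place
simulated measurements on a realistic assay-specific scale; the analysis
itself never consumes them, it re-estimates the control anchors from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FUNCTION = "function"
STABILITY = "stability"


@dataclass(frozen=True)
class AssayDef:
    """Metadata for a single assay.

    orientation: +1 when the raw measurement increases with PTEN function
    (e.g. worm chemotaxis index), -1 when it decreases (e.g. pAKT effect,
    colony-size ratio in a negative genetic interaction).
    """

    name: str
    kind: str = FUNCTION  # "function" or "stability"
    orientation: int = 1
    wt_label: str = "WT"
    null_label: str = "EV"
    # synthetic-data anchors: raw value at truth=0 (null) and truth=1 (WT)
    raw_null: float = 0.0
    raw_wt: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (FUNCTION, STABILITY):
            raise ValueError(f"unknown assay kind {self.kind!r}")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    def raw_from_truth(self, truth: float) -> float:
        """Map a ground-truth score (WT=1, null=0) onto the raw assay scale."""
        return self.raw_null + (self.raw_wt - self.raw_null) * truth


def default_assays() -> dict[str, AssayDef]:
    """The default multi-model assay panel.

    Six functional assays (yeast genetic interaction, fly eclosion delay,
    worm chemotaxis, HEK293 pAKT/AKT effect, rat excitatory-synapse density,
    rat dendritic arbor length) plus two stability assays (yeast western
    densitometry, HEK293 sfGFP/RFP flow ratio).  Raw anchors are plausible
    magnitudes for each readout; orientation encodes which way the raw
    measure moves as PTEN function increases.
    """
    defs = [
        # more PTEN function -> smaller colonies in the sentinel strain
        AssayDef("yeast_dvac14", FUNCTION, -1, raw_null=1.0, raw_wt=0.35),
        # more PTEN function -> slower development (hours to eclosion)
        AssayDef("fly_eclosion", FUNCTION, 1, raw_null=96.0, raw_wt=122.0),
        # chemotaxis index; the null background reverses NaCl preference
        AssayDef("worm_chemotaxis", FUNCTION, 1, raw_null=-0.35, raw_wt=0.72),
        # in-well-normalized pAKT/AKT effect; more function -> lower pAKT
        AssayDef("hek_pakt", FUNCTION, -1, raw_null=0.0, raw_wt=-0.8),
        # PSD-95 puncta per um dendrite; PTEN suppresses synaptogenesis
        AssayDef("rat_psd95", FUNCTION, -1, raw_null=0.46, raw_wt=0.30),
        # total dendritic arbor length (um); PTEN restrains growth
        AssayDef("rat_dendrite", FUNCTION, -1, raw_null=1500.0, raw_wt=1050.0),
        # band/loading densitometry, double-normalized downstream
        AssayDef("yeast_abundance", STABILITY, 1, raw_null=0.0, raw_wt=1.0),
        # median (sfGFP-bg)/(RFP-bg), day-normalized to WT=1
        AssayDef("hek_stability", STABILITY, 1, raw_null=0.0, raw_wt=1.0),
    ]
    return {a.name: a for a in defs}


def with_overrides(base: AssayDef, **kwargs) -> AssayDef:
    return replace(base, **kwargs)


# assays whose phenotype vocabulary folds dominant-negative/"below LoF"
# calls into the headline complete-LoF tally (organisms without the
# endogenous-protein readout that distinguishes true dominant negativity)
BELOW_LOF_STYLE = frozenset({"yeast", "fly"})


def call_style(assay_name: str) -> str:
    """Headline-count convention for an assay: 'yeast', 'fly' or 'hek'."""
    prefix = assay_name.split("_", 1)[0]
    return prefix if prefix in ("yeast", "fly") else "hek"
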