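"""Synthetic-data generator for the multi-assay variant-profiling pipeline.

Emulates the replicate structure of the real study: per-assay replicate
tables with genotype fixed effects, additive batch random intercepts and
Gaussian residual noise; per-cell flow-cytometry wells (stability and
pAKT/AKT readouts); and worm chemotaxis zone counts.  Every generated
record has a known ground truth so each downstream stage can be tested
without any external download.

Noise magnitudes (``sigma_batch``, ``sigma_resid``) are expressed as
fractions of each assay's WT-null dynamic range, so a value of 0.15 means
a residual SD of 15% of the control separation regardless of the raw units
of the assay.  The defaults are calibrated so that WT and the null control
separate at p < 0.05 at the study's replicate counts (e.g. n=16 for yeast
sentinels); they are not fits to the real per-assay variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import ChemotaxisCount
from .registry import FUNCTION, AssayDef, default_assays
from .roster import TrueClass, VariantSpec, roster_truth_frame

REPLICATE_COLUMNS = ["assay", "genotype", "batch", "replicate", "value"]
CELL_COLUMNS = ["well", "cell_id", "gfp", "rfp", "af647", "af405", "transfected"]

DEFAULT_BACKGROUND = {"gfp": 100.0, "rfp": 80.0, "af647": 50.0, "af405": 60.0}


@dataclass
class SimulationConfig:
    """Knobs of the generator; all SDs are >= 0 and runs are seed-reproducible."""

    n_batches: int = 4
    reps_per_batch: int = 4
    sigma_batch: float = 0.05   # batch random-intercept SD, fraction of WT-null span
    sigma_resid: float = 0.15   # residual SD, fraction of WT-null span
    n_cells_per_well: int = 2000
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    seed: int = 0
    # flow-cytometry shape parameters
    transfected_fraction: float = 0.45
    rfp_expression_median: float = 3000.0
    rfp_expression_sigma: float = 0.6
    gfp_gain: float = 1.0
    pakt_baseline: float = 1.2  # untransfected pAKT/AKT ratio
    pakt_span: float = 0.75     # fractional pAKT reduction at full function, saturated expression
    expression_half_saturation: float = 1000.0
    # chemotaxis
    scored_fraction: float = 0.8  # worms reaching either zone (rest uncounted)

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.reps_per_batch < 1:
            raise ValueError("n_batches and reps_per_batch must be >= 1")
        if self.sigma_batch < 0 or self.sigma_resid < 0:
            raise ValueError("noise SDs must be non-negative")


def _truth_for(spec: VariantSpec, assay: AssayDef) -> float:
    return spec.true_function if assay.kind == FUNCTION else spec.true_stability


def _check_controls(roster, assay: AssayDef) -> None:
    ids = {v.variant_id for v in roster}
    for role, label in (("WT", assay.wt_label), ("null", assay.null_label)):
        if label not in ids:
            raise ValueError(
                f"roster is missing the {role} control {label!r} required by assay {assay.name!r}"
            )


def simulate_replicates(
    roster: list[VariantSpec],
    config: SimulationConfig,
    assays: dict[str, AssayDef] | None = None,
) -> pd.DataFrame:
    """Long-format replicate table: assay, genotype, batch, replicate, value.

    Each value is ``raw(truth) + span * (u_batch + eps)`` with
    ``u ~ N(0, sigma_batch^2)`` per (assay, batch) and
    ``eps ~ N(0, sigma_resid^2)`` i.i.d.; every genotype appears in every
    batch.  With both SDs zero each replicate equals the assay's raw map of
    the genotype's ground truth exactly.
    """
    if assays is None:
        assays = default_assays()
    rng = np.random.default_rng(config.seed)
    rows = []
    for assay in assays.values():
        _check_controls(roster, assay)
        span = abs(assay.raw_wt - assay.raw_null)
        u = rng.normal(0.0, config.sigma_batch, size=config.n_batches) if config.sigma_batch > 0 else np.zeros(config.n_batches)
        for spec in roster:
            truth = _truth_for(spec, assay)
            raw = assay.raw_from_truth(truth)
            for b in range(config.n_batches):
                eps = (
                    rng.normal(0.0, config.sigma_resid, size=config.reps_per_batch)
                    if config.sigma_resid > 0
                    else np.zeros(config.reps_per_batch)
                )
                for r in range(config.reps_per_batch):
                    rows.append(
                        (assay.name, spec.variant_id, f"b{b + 1}", r + 1, raw + span * (u[b] + eps[r]))
                    )
    return pd.DataFrame(rows, columns=REPLICATE_COLUMNS)


def _effective_function(spec: VariantSpec, ko_background: bool) -> float:
    """Dominant negativity requires endogenous protein: its (negative)
    magnitude is multiplied by an endogenous-protein indicator that is 1 in
    the parental line and 0 in the knockout."""
    f = spec.true_function
    if f < 0 and ko_background:
        return 0.0
    return f


def simulate_flow_well(
    spec: VariantSpec,
    config: SimulationConfig,
    ko_background: bool = False,
    well: str = "w1",
    rng: np.random.Generator | None = None,
    day_gain: float = 1.0,
) -> pd.DataFrame:
    """One flow-cytometry well: a mixture of transfected and untransfected cells.

    Transfected expression (rfp) is log-normal; gfp tracks
    ``true_stability * rfp * gain``; the pAKT/AKT proxy ratio
    (af647-bg)/(af405-bg) decreases with expression for functional variants
    and rises above the untransfected baseline for dominant negatives
    unless ``ko_background`` removes the endogenous-protein-dependent
    effect.  Channel intensities are truncated at zero.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells_per_well
    if n < 100:
        warnings.warn(f"n_cells_per_well={n} < 100: per-well medians will be unstable", stacklevel=2)
    bg = config.background
    transfected = rng.random(n) < config.transfected_fraction

    rfp_expr = np.where(
        transfected,
        rng.lognormal(np.log(config.rfp_expression_median), config.rfp_expression_sigma, n),
        0.0,
    )
    rfp = np.maximum(0.0, rfp_expr + bg["rfp"] + rng.normal(0.0, 20.0, n))
    gfp_signal = spec.true_stability * rfp_expr * config.gfp_gain * day_gain
    gfp = np.maximum(0.0, gfp_signal + bg["gfp"] + rng.normal(0.0, 25.0, n))

    f_eff = _effective_function(spec, ko_background)
    sat = gfp_signal / (gfp_signal + config.expression_half_saturation)
    ratio = config.pakt_baseline * (1.0 - config.pakt_span * f_eff * sat)
    ratio = ratio * np.exp(rng.normal(0.0, 0.08, n))

    akt = rng.lognormal(np.log(800.0), 0.3, n)
    af405 = np.maximum(0.0, akt + bg["af405"] + rng.normal(0.0, 10.0, n))
    af647 = np.maximum(0.0, ratio * akt + bg["af647"] + rng.normal(0.0, 10.0, n))

    return pd.DataFrame(
        {
            "well": well,
            "cell_id": np.arange(n),
            "gfp": gfp,
            "rfp": rfp,
            "af647": af647,
            "af405": af405,
            "transfected": transfected.astype(int),
        }
    )


def simulate_flow_study(
    roster: list[VariantSpec],
    config: SimulationConfig,
    n_wells: int = 3,
    ko_background: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wells for every roster entry, grouped into experiment days.

    Each day holds one well per variant (including WT, for per-day WT
    normalization) and has its own multiplicative gain drift.  Returns the
    concatenated cell table and a well map (well, genotype, day).
    """
    rng = np.random.default_rng(config.seed)
    tables, wellmap = [], []
    for d in range(n_wells):  # one day per replicate well
        day = f"d{d + 1}"
        day_gain = float(np.exp(rng.normal(0.0, 0.1)))
        for spec in roster:
            well = f"{day}_{spec.variant_id}"
            tables.append(
                simulate_flow_well(spec, config, ko_background, well=well, rng=rng, day_gain=day_gain)
            )
            wellmap.append((well, spec.variant_id, day))
    cells = pd.concat(tables, ignore_index=True)
    return cells, pd.DataFrame(wellmap, columns=["well", "genotype", "day"])


def preference_from_truth(true_function: float, assay: AssayDef | None = None) -> float:
    """Map a ground-truth function score onto a NaCl zone preference.

    The chemotaxis index is 2p - 1 for preference p, so the assay's raw
    anchors (null index, WT index) define the affine map; the result is
    clipped to (0.02, 0.98) to keep plates scorable.
    """
    if assay is None:
        assay = default_assays()["worm_chemotaxis"]
    index = assay.raw_from_truth(true_function)
    return float(np.clip((1.0 + index) / 2.0, 0.02, 0.98))


def simulate_chemotaxis(
    spec: VariantSpec,
    n_worms: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    preference: float | None = None,
) -> ChemotaxisCount:
    """Zone counts (A, B) from a binomial split of the scored worms.

    Worms reach either zone with probability ``scored_fraction`` (the rest
    stay in the middle and are uncounted), and scored worms fall in the
    NaCl zone with the preference mapped from ``true_function``.
    """
    if n_worms <= 0:
        raise ValueError("n_worms must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if preference is None:
        preference = preference_from_truth(spec.true_function)
    n_scored = int(rng.binomial(n_worms, config.scored_fraction))
    a = int(rng.binomial(n_scored, preference)) if n_scored else 0
    return ChemotaxisCount(A=a, B=n_scored - a)


def simulate_study(
    roster: list[VariantSpec],
    config: SimulationConfig,
    assays: dict[str, AssayDef] | None = None,
) -> dict:
    """Replicate table + ground-truth sidecar for the default study."""
    if assays is None:
        assays = default_assays()
    return {
        "replicates": simulate_replicates(roster, config, assays),
        "truth": roster_truth_frame(roster),
        "assays": assays,
    }


def write_replicates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_cells(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_truth(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
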