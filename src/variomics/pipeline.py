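"""End-to-end orchestration: replicates -> scores -> calls -> classification
-> mechanism outputs, with every stage's table written to the output
directory plus a JSON run manifest.  A stage failure aborts with the stage
name attached."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import classify, mechanism, normalize, phenotype
from .io import PipelineConfig, write_manifest, write_table

log = logging.getLogger("variomics")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    replicates: pd.DataFrame,
    cosmic_counts: dict | pd.Series | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full analysis on a replicate table.

    Returns a bundle dict with the scores, calls, classification,
    mechanism table, correlation matrices and (if COSMIC counts were
    given) the stratified ANOVA.  When ``outdir`` is set, each table is
    written as delimited text and a manifest.json records parameters and
    per-file hashes; two runs with identical inputs and seed produce
    byte-identical bundles.
    """
    config.validate(replicates)

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            out = fn()
        except Exception as e:  # noqa: BLE001 - abort with stage name
            raise StageError(name, e) from e
        if isinstance(out, pd.DataFrame):
            log.info("stage %s: %d rows", name, len(out))
        return out

    scores = stage("normalize", lambda: normalize.score_study(replicates, config.assays, config.alpha))
    calls = stage("call", lambda: phenotype.call_scores(scores, config.alpha))
    classification = stage(
        "classify",
        lambda: classify.classify_study(
            scores, config.assays, config.lof_cutoff, config.stability_filter
        ),
    )
    mech = stage("mechanism", lambda: mechanism.mechanism_scores(scores, config.assays))
    corr_all = stage("correlation", lambda: mechanism.correlation_matrix(scores))

    bundle = {
        "scores": scores,
        "calls": calls,
        "classification": classification,
        "mechanism": mech,
        "correlation": corr_all,
        "label_counts": classify.label_counts(classification),
    }
    if not mech.empty:
        for subset, key in (
            (mechanism.Domain.STABILITY_DEPENDENT, "correlation_dependent"),
            (mechanism.Domain.STABILITY_INDEPENDENT, "correlation_independent"),
        ):
            bundle[key] = mechanism.correlation_matrix(scores, subset=subset)
    if cosmic_counts is not None:
        means, anova = stage(
            "cosmic", lambda: mechanism.cosmic_stratified_test(scores, cosmic_counts)
        )
        bundle["cosmic_means"] = means
        bundle["cosmic_anova"] = anova

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {}
        for name in ("scores", "calls", "classification", "mechanism"):
            path = outdir / f"{name}.tsv"
            write_table(bundle[name], path)
            tables[name] = path
        for name in ("correlation", "correlation_dependent", "correlation_independent"):
            if name in bundle:
                path = outdir / f"{name}.tsv"
                write_table(bundle[name].reset_index(), path)
                tables[name] = path
        if "cosmic_anova" in bundle:
            path = outdir / "cosmic_anova.tsv"
            write_table(bundle["cosmic_anova"].reset_index(), path)
            tables["cosmic_anova"] = path
        write_manifest(outdir, config, tables, extra={"label_counts": bundle["label_counts"]})
    return bundle
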