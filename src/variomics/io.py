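"""Table readers/writers, pipeline configuration and the run manifest.

All tables are UTF-8 with Unix newlines; reals are serialized with 10
significant digits.  The replicate dialect is tab-delimited with header
exactly (assay, genotype, batch, replicate, value); cell tables are
comma-delimited as written by the generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .registry import AssayDef, default_assays

log = logging.getLogger("variomics")

REPLICATE_HEADER = ["assay", "genotype", "batch", "replicate", "value"]
FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    assays: dict[str, AssayDef] = field(default_factory=default_assays)
    alpha: float = 0.05
    lof_cutoff: float = 0.5
    gfp_gate_low: float = 300.0
    gfp_gate_high: float = 20_000.0
    stability_filter: bool = True
    seed: int = 0
    outdir: str = "variomics_out"

    def validate(self, replicates: pd.DataFrame | None = None) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.lof_cutoff < 1:
            raise ValueError("lof_cutoff must be in (0, 1)")
        if not self.gfp_gate_low < self.gfp_gate_high:
            raise ValueError("gfp_gate_low must be below gfp_gate_high")
        if replicates is not None:
            missing = sorted(set(replicates["assay"].unique()) - set(self.assays))
            if missing:
                raise ValueError(f"assays without a registry entry: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        assays = {
            name: AssayDef(name=name, **spec) for name, spec in raw.pop("assays", {}).items()
        } or default_assays()
        return cls(assays=assays, **raw)


def read_replicates(path) -> pd.DataFrame:
    """Read a replicate table, validating the header and value column.

    Rows with a missing value are dropped (count logged); a non-numeric
    value raises with the offending 1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REPLICATE_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"replicate table {path} is missing column(s): {', '.join(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    declared_na = df["value"].isna() | df["value"].str.strip().isin(["NA", "NaN", "nan", ""])
    bad = values.isna() & ~declared_na
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"non-numeric value {df.loc[bad.idxmax(), 'value']!r} at line {line} of {path}")
    df["value"] = values
    n_dropped = int(values.isna().sum())
    if n_dropped:
        log.info("dropped %d row(s) with missing values from %s", n_dropped, path)
    out = df[~values.isna()].reset_index(drop=True)
    out["replicate"] = pd.to_numeric(out["replicate"], errors="coerce").astype("Int64")
    return out


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["well", "cell_id", "gfp", "rfp", "af647", "af405"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing column(s): {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config: PipelineConfig, tables: dict, extra: dict | None = None) -> Path:
    """JSON run manifest: parameters, seed, and the sha256 of every output
    table, so each emitted file is tied to the run that produced it."""
    outdir = Path(outdir)
    manifest = {
        "package": "variomics",
        "seed": config.seed,
        "alpha": config.alpha,
        "lof_cutoff": config.lof_cutoff,
        "stability_filter": config.stability_filter,
        "assays": sorted(config.assays),
        "outputs": {name: file_sha256(path) for name, path in tables.items()},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
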