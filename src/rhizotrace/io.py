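"""CSV schemas, validated readers/writers, run configuration and the pipeline driver.

All files are plain CSV with a commented (#) provenance header carrying the
package version, seed and config hash, so every output is auditable and a
rerun with the same inputs and config is byte-identical (timestamps are
confined to the log).  Units are encoded in column names (c14_bq_per_g,
net_rhizo_c_mg_per_kg, ...) so files are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import fit_instrument_correction, process_biomarkers
from .rhizodeposition import COMPARTMENTS, DepthInterval, partition_samples
from .rms import rms_profile
from .stats import anova_tukey, merge_rule

logger = logging.getLogger("rhizotrace")

__all__ = [
    "SAMPLE_COLUMNS",
    "BIOMARKER_COLUMNS",
    "RunConfig",
    "read_samples",
    "read_biomarkers",
    "read_table",
    "write_table",
    "run_pipeline",
]

SAMPLE_COLUMNS = [
    "plot_id",
    "species",
    "n_rate",
    "depth_top_cm",
    "depth_bottom_cm",
    "compartment",
    "dry_mass_g",
    "soil_mass_kg",
    "c_mg_per_g",
    "n_mg_per_g",
    "d13c_permil",
    "d15n_permil",
    "c14_bq_per_g",
    "is_labeled",
]

BIOMARKER_COLUMNS = [
    "plot_id",
    "species",
    "n_rate",
    "depth_top_cm",
    "depth_bottom_cm",
    "matrix",
    "compound",
    "biomarker_class",
    "concentration_ug_per_g",
    "d13c_measured",
    "run_index",
    "peak_amount",
    "is_labeled",
]

#: Accepted spelling variants for compartment labels.
COMPARTMENT_ALIASES = {
    "bulk soil": "bulk_soil",
    "bulksoil": "bulk_soil",
    "bulk": "bulk_soil",
    "rhizosphere": "rhizosphere_soil",
    "rhizosphere soil": "rhizosphere_soil",
    "roots": "root",
    "root fragment": "root_fragment",
    "root fragments": "root_fragment",
    "root_fragments": "root_fragment",
    "washed root": "root_fragment",
}


def normalize_compartment(value: str) -> str:
    key = str(value).strip().lower().replace("-", " ")
    key_us = key.replace(" ", "_")
    if key_us in COMPARTMENTS:
        return key_us
    if key in COMPARTMENT_ALIASES:
        return COMPARTMENT_ALIASES[key]
    raise ValueError(f"unknown compartment {value!r}")


def read_table(path) -> pd.DataFrame:
    """Read a CSV, skipping commented provenance lines.

    ``float_precision='round_trip'`` so numeric columns survive a
    write-then-read cycle bit-exactly.
    """
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a CSV with a commented provenance header; full numeric precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# rhizotrace v{__version__}\n")
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        # default float formatting is the shortest round-trip repr
        df.to_csv(fh, index=False)


def read_samples(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a compartment-sample table.

    Returns (validated table, unmatched-background report).  Row-level
    problems are reported with 1-based data line numbers.
    """
    df = read_table(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} missing required columns {missing}")
    problems = []
    comps = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            comps.append(normalize_compartment(row["compartment"]))
        except ValueError as e:
            problems.append(f"line {line}: {e}")
            comps.append(None)
        for col in ("dry_mass_g", "soil_mass_kg", "c_mg_per_g", "n_mg_per_g"):
            v = row[col]
            if pd.notna(v) and v < 0:
                problems.append(f"line {line}: negative {col} ({v})")
        if pd.notna(row["c14_bq_per_g"]) and row["c14_bq_per_g"] < 0:
            problems.append(f"line {line}: negative c14_bq_per_g")
        if pd.notna(row["d13c_permil"]) and row["d13c_permil"] <= -1000:
            problems.append(f"line {line}: d13c_permil <= -1000")
    if problems:
        raise ValueError("invalid sample rows:\n" + "\n".join(problems))
    df = df.assign(compartment=comps)
    df["is_labeled"] = df["is_labeled"].astype(bool)
    if df.empty:
        logger.warning("sample table %s has an empty data section", path)

    bg_keys = df[~df["is_labeled"]][["compartment", "depth_top_cm", "depth_bottom_cm"]]
    bg_set = set(map(tuple, bg_keys.to_numpy()))
    labeled = df[df["is_labeled"]]
    unmatched = labeled[
        [
            tuple(r) not in bg_set
            for r in labeled[["compartment", "depth_top_cm", "depth_bottom_cm"]].to_numpy()
        ]
    ]
    if len(unmatched):
        logger.warning("%d labeled rows have no matching background", len(unmatched))
    return df, unmatched.copy()


def read_biomarkers(path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"biomarker table {path} missing required columns {missing}")
    df["is_labeled"] = df["is_labeled"].astype(bool)
    return df


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serializable, hashed into outputs."""

    samples_path: str | None = None
    biomarkers_path: str | None = None
    calibration_path: str | None = None
    output_dir: str = "rhizotrace_out"
    seed: int = 0
    r_vpdb: float = 0.0111802
    r_air_n2: float = 0.0036765
    log_base: float = 10.0
    alpha: float = 0.05
    strict_clvr: bool = False
    reagent_d13c: dict = field(default_factory=dict)
    bulk_density_path: str | None = None
    compound_table_path: str | None = None
    compare_variables: list = field(
        default_factory=lambda: ["clvr_percent", "net_rhizo_c_mg_per_kg"]
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # output_dir is excluded: where results land has no bearing on them
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.config_hash()}


def _read_bulk_density(path) -> dict:
    df = read_table(path)
    need = {"depth_top_cm", "depth_bottom_cm", "bulk_density_g_cm3"}
    if not need.issubset(df.columns):
        raise ValueError(f"bulk density table missing columns {sorted(need - set(df.columns))}")
    return {
        DepthInterval(r.depth_top_cm, r.depth_bottom_cm): r.bulk_density_g_cm3
        for r in df.itertuples()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute partition -> CSIA -> RMS -> compare and write the output bundle.

    Returns the in-memory tables keyed by stage name.  Each stage failure is
    re-raised tagged with the stage that produced it.
    """
    out = Path(config.output_dir)
    prov = config.provenance()
    bundle: dict[str, object] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    if config.samples_path:
        samples, unmatched = stage("read_samples", lambda: read_samples(config.samples_path))
        bd = _read_bulk_density(config.bulk_density_path) if config.bulk_density_path else None
        partition = stage(
            "partition",
            lambda: partition_samples(samples, strict_literal=config.strict_clvr, bulk_density=bd),
        )
        bundle["partition"] = partition
        write_table(partition, out / "partition.csv", prov)
        if len(unmatched):
            write_table(unmatched, out / "unmatched_backgrounds.csv", prov)

    if config.biomarkers_path:
        markers = stage("read_biomarkers", lambda: read_biomarkers(config.biomarkers_path))
        correction = None
        if config.calibration_path:
            cal = read_table(config.calibration_path)
            correction = {}
            for cls, sub in cal.groupby("biomarker_class"):
                correction[cls] = fit_instrument_correction(sub)
        if not config.reagent_d13c:
            raise RuntimeError(
                "pipeline stage 'csia' failed: reagent_d13c is required (per biomarker class); "
                "it is reagent-batch specific and has no default"
            )
        from .biomarkers import load_compound_table

        table = load_compound_table(config.compound_table_path)
        corrected, pools = stage(
            "csia",
            lambda: process_biomarkers(markers, config.reagent_d13c, correction, table),
        )
        bundle["csia_records"] = corrected
        bundle["pools"] = pools
        write_table(corrected, out / "biomarkers_corrected.csv", prov)
        write_table(pools, out / "pool_summaries.csv", prov)
        rms_df = stage("rms", lambda: rms_profile(pools, log_base=config.log_base))
        bundle["rms"] = rms_df
        write_table(rms_df, out / "rms.csv", prov)

    if "partition" in bundle:
        part = bundle["partition"]

        def do_compare():
            merged, report = merge_rule(part, config.compare_variables, alpha=config.alpha)
            results = {}
            for var in config.compare_variables:
                results[var] = anova_tukey(
                    merged.dropna(subset=[var]),
                    var,
                    ["treatment", "depth_top_cm"],
                    tukey_factor="treatment",
                    alpha=config.alpha,
                )
            return merged, report, results

        merged, report, results = stage("compare", do_compare)
        bundle["merged"] = merged
        bundle["merge_report"] = report
        bundle["comparisons"] = results
        write_table(merged, out / "partition_merged.csv", prov)
        with open(out / "comparison_report.txt", "w") as fh:
            fh.write(report.summary() + "\n\n")
            for var, res in results.items():
                fh.write(res.summary() + "\n\n")
    return bundle
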