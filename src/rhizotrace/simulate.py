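"""Forward simulation of a dual-labeled (13C/14C + 15N) field experiment.

The generator emulates the study design that the pipeline analyzes: three
replicate field plots of lucerne and of kernza (the kernza plots split into
100 and 200 kg N ha-1 subplots), repeatedly pulse-labeled with 13C/14C-CO2
over two months (labeling-solution volume following the 5 mL per 20 cm of
plant height rule) plus a trace 15N surface application, then destructively
sampled over four depth intervals into bulk soil, rhizosphere soil, roots,
and root fragments washed from a bulk-soil subsample.

For each plot x treatment x depth the configured tracer dose is partitioned

    belowground dose -> root : rhizodeposit = (1 - f) : f

with f the true C-lost-via-rhizodeposition fraction, the rhizodeposit split
between bulk and rhizosphere soil, and a share of root tracer rerouted into
the root-fragment compartment (which physically sits inside the bulk soil,
so the bulk reading includes it — exactly the contamination the adjusted-
bulk correction removes).  Biomarker 13C in the rhizosphere is split between
the amino-sugar (necromass) and PLFA (living biomass) pools by a per-depth
necromass fraction, which fixes the true RMS.

Measurement noise is multiplicative lognormal (given CV) on masses,
concentrations, activities and peak amounts — how scintillation counting and
gravimetric errors behave — and additive Gaussian (in per-mil) on delta
values, how IRMS errors behave.  All randomness flows from one seed;
per-plot substreams are derived deterministically so adding plots never
reshuffles existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .isotope import AIR_N2, VPDB, atom_percent_to_delta, delta_to_atom_percent
from .rhizodeposition import DEFAULT_DEPTHS, DepthInterval

__all__ = ["ScenarioConfig", "SimulationResult", "dose_schedule", "generate"]

#: Pulse volume rule: 5 mL of labeling solution per started 20 cm of height.
ML_PER_STEP = 5.0
HEIGHT_STEP_CM = 20.0

# Tracer content of the labeling solution (bicarbonate, 99 atom% 13C).
KBQ_14C_PER_ML = 11.0
G_BICARB_PER_ML = 0.1
_MW_NAH13CO3 = 22.990 + 1.008 + 13.003 + 3 * 15.999
MG_13C_PER_ML = G_BICARB_PER_ML * 0.99 * (13.003 / _MW_NAH13CO3) * 1000.0


def dose_schedule(height_series_cm) -> float:
    """Total labeling-solution volume (mL) over a pulse sequence.

    One pulse per entry; each pulse uses 5 mL per started 20 cm of the
    current plant height.  Heights must be non-decreasing and within
    [0, 150] cm.
    """
    h = np.asarray(height_series_cm, float)
    if h.size == 0:
        return 0.0
    if np.any(h < 0) or np.any(h > 150):
        raise ValueError("plant heights must lie within [0, 150] cm")
    if np.any(np.diff(h) < 0):
        raise ValueError("plant heights must be non-decreasing across pulses")
    return float(np.sum(ML_PER_STEP * np.ceil(h / HEIGHT_STEP_CM)))


def _default_pulse_heights() -> tuple[float, ...]:
    # three pulses per week over two months, canopy growing 20 -> 110 cm
    return tuple(np.round(np.linspace(20.0, 110.0, 26), 1))


@dataclass
class ScenarioConfig:
    """All knobs of the simulated experiment; defaults emulate the field study."""

    seed: int = 0
    n_plots: int = 3
    depth_intervals: tuple[DepthInterval, ...] = DEFAULT_DEPTHS
    #: true fraction of belowground tracer lost via rhizodeposition, per depth
    true_clvr_fraction: tuple[float, ...] = (0.25, 0.20, 0.15, 0.10)
    #: true root C concentration per depth (mg C kg-1 soil)
    root_c_mg_per_kg: tuple[float, ...] = (800.0, 300.0, 120.0, 50.0)
    #: share of belowground tracer reaching each depth
    belowground_depth_weights: tuple[float, ...] = (0.55, 0.25, 0.13, 0.07)
    shoot_allocation_fraction: float = 0.6
    pulse_heights_cm: tuple[float, ...] = field(default_factory=_default_pulse_heights)
    #: explicit doses override the schedule-derived defaults when set
    total_14c_dose_bq: float | None = None
    total_13c_dose_mg: float | None = None
    #: 15N applied per plot (mg excess 15N; ~1 kg N ha-1 at 98 atom% on 0.75 m2)
    n15_dose_mg: float = 73.5
    #: per-depth rhizodeposition fraction for N; None -> same as carbon
    true_clvr_n_fraction: tuple[float, ...] | None = None

    background_d13c: float = -27.0
    background_d15n: float = 2.0
    background_activity_bq_per_g: float = 0.3

    noise_cv: float = 0.10
    delta_noise_sd_permil: float = 0.2

    bulk_to_rhizo_ratio: float = 3.0
    fragment_fraction_of_root: float = 0.15
    soil_mass_kg_per_cm: float = 0.12
    rhizosphere_mass_fraction: float = 0.05
    fragment_subsample_kg: float = 0.15
    soil_c_mg_per_g: tuple[float, ...] = (12.0, 8.0, 4.0, 2.0)
    soil_n_mg_per_g: tuple[float, ...] = (1.2, 0.8, 0.4, 0.2)
    root_c_mg_per_g: float = 420.0
    root_n_mg_per_g: float = 15.0

    #: share of rhizosphere 13C excess incorporated into AS + PLFA pools
    biomarker_incorporation_fraction: float = 0.05
    aa_incorporation_fraction: float = 0.02
    #: share of biomarker 13C entering the amino-sugar (necromass) pool, per depth
    necromass_fraction_by_depth: tuple[float, ...] = (0.35, 0.50, 0.65, 0.80)
    plfa_conc_ug_per_g: tuple[float, ...] = (40.0, 25.0, 12.0, 6.0)
    as_conc_ug_per_g: tuple[float, ...] = (800.0, 500.0, 250.0, 120.0)
    aa_conc_ug_per_g: tuple[float, ...] = (300.0, 200.0, 100.0, 50.0)
    #: natural-abundance delta13C of each biomarker class
    class_background_d13c: dict = field(
        default_factory=lambda: {"PLFA": -32.0, "AS": -22.0, "AA": -25.0}
    )
    reagent_d13c: dict = field(
        default_factory=lambda: {"PLFA": -40.0, "AS": -35.0, "AA": -38.0}
    )
    #: instrument bias per class: (offset permil, drift permil/run, slope permil/log-amount)
    instrument_bias: dict = field(
        default_factory=lambda: {
            "PLFA": (0.30, 0.010, -0.15),
            "AS": (0.20, 0.0, 0.0),
            "AA": (0.10, 0.0, 0.0),
        }
    )
    n_background_replicates: int = 3

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def total_solution_ml(self) -> float:
        return dose_schedule(self.pulse_heights_cm)

    @property
    def c14_dose_bq(self) -> float:
        if self.total_14c_dose_bq is not None:
            return self.total_14c_dose_bq
        return self.total_solution_ml * KBQ_14C_PER_ML * 1000.0

    @property
    def c13_dose_mg(self) -> float:
        if self.total_13c_dose_mg is not None:
            return self.total_13c_dose_mg
        return self.total_solution_ml * MG_13C_PER_ML

    @property
    def n_depths(self) -> int:
        return len(self.depth_intervals)

    def validate(self) -> None:
        errors = []
        per_depth = [
            "true_clvr_fraction",
            "root_c_mg_per_kg",
            "belowground_depth_weights",
            "soil_c_mg_per_g",
            "soil_n_mg_per_g",
            "necromass_fraction_by_depth",
            "plfa_conc_ug_per_g",
            "as_conc_ug_per_g",
            "aa_conc_ug_per_g",
        ]
        for name in per_depth:
            if len(getattr(self, name)) != self.n_depths:
                errors.append(f"{name}: expected {self.n_depths} entries")
        if self.true_clvr_n_fraction is not None and len(self.true_clvr_n_fraction) != self.n_depths:
            errors.append(f"true_clvr_n_fraction: expected {self.n_depths} entries")
        for name in ("true_clvr_fraction", "necromass_fraction_by_depth", "belowground_depth_weights"):
            vals = getattr(self, name)
            if any(not 0 <= v <= 1 for v in vals):
                errors.append(f"{name}: fractions must lie in [0, 1]")
        for name in ("shoot_allocation_fraction", "rhizosphere_mass_fraction", "fragment_fraction_of_root"):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"{name}: must lie in [0, 1]")
        if self.noise_cv < 0:
            errors.append("noise_cv: must be >= 0")
        if errors:
            raise ValueError("invalid ScenarioConfig: " + "; ".join(errors))

    def treatments(self) -> list[tuple[str, str, int]]:
        """(plot_id, species, n_rate) rows; kernza plots carry two N subplots."""
        rows = []
        for i in range(1, self.n_plots + 1):
            rows.append((f"L{i}", "lucerne", 0))
            rows.append((f"K{i}", "kernza", 100))
            rows.append((f"K{i}", "kernza", 200))
        return rows


@dataclass
class SimulationResult:
    samples: pd.DataFrame
    biomarkers: pd.DataFrame
    calibration: pd.DataFrame
    truth: pd.DataFrame
    config: ScenarioConfig


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _delta_from_ape(background_delta: float, ape: float, standard) -> float:
    """Delta value of a pool whose atom%-excess over background is ``ape``."""
    return atom_percent_to_delta(delta_to_atom_percent(background_delta, standard) + ape, standard)


def _compound_weights(cls: str, table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["biomarker_class"] == cls]
    # fixed, slightly uneven mixture so pools are not trivially symmetric
    w = np.linspace(1.5, 0.5, len(sub))
    return sub.assign(weight=w / w.sum())


def generate(config: ScenarioConfig, *, include_biomarkers: bool = True) -> SimulationResult:
    """Simulate the experiment; returns sample, biomarker, calibration and truth tables.

    ``include_biomarkers=False`` skips the biomarker/calibration tables (the
    mass-balance path is unaffected; Monte-Carlo studies of %ClvR recovery
    run several times faster).
    """
    table = bm.load_compound_table()
    depths = config.depth_intervals
    f_c = np.asarray(config.true_clvr_fraction, float)
    f_n = np.asarray(
        config.true_clvr_n_fraction if config.true_clvr_n_fraction is not None else config.true_clvr_fraction,
        float,
    )
    w_depth = np.asarray(config.belowground_depth_weights, float)
    w_depth = w_depth / w_depth.sum()
    bg_c14 = config.c14_dose_bq * (1 - config.shoot_allocation_fraction)
    bg_c13 = config.c13_dose_mg * (1 - config.shoot_allocation_fraction)
    bg_n15 = config.n15_dose_mg * (1 - config.shoot_allocation_fraction)
    bulk_share = config.bulk_to_rhizo_ratio / (1.0 + config.bulk_to_rhizo_ratio)

    ap_bg_c = delta_to_atom_percent(config.background_d13c, VPDB)
    ap_bg_n = delta_to_atom_percent(config.background_d15n, AIR_N2)

    sample_rows: list[dict] = []
    marker_rows: list[dict] = []
    truth_rows: list[dict] = []
    run_counter = {cls: 0 for cls in bm.BIOMARKER_CLASSES}

    class_weights = {cls: _compound_weights(cls, table) for cls in bm.BIOMARKER_CLASSES}

    treatments = config.treatments()
    for t_idx, (plot_id, species, n_rate) in enumerate(treatments):
        rng = np.random.default_rng([config.seed % (2**31), 7919, t_idx])
        rng_m = np.random.default_rng([config.seed % (2**31), 7919, t_idx, 1])
        for d_idx, depth in enumerate(depths):
            soil_mass_kg = config.soil_mass_kg_per_cm * depth.thickness_cm
            rhizo_mass_g = config.rhizosphere_mass_fraction * soil_mass_kg * 1000.0
            bulk_mass_g = soil_mass_kg * 1000.0 - rhizo_mass_g
            root_c_mg = config.root_c_mg_per_kg[d_idx] * soil_mass_kg
            root_mass_g = root_c_mg / config.root_c_mg_per_g

            # --- tracer partition (pre-noise truth) ------------------------
            pools = {}
            for iso, bg_dose, frac in (("c14", bg_c14, f_c), ("c13", bg_c13, f_c), ("n15", bg_n15, f_n)):
                b = bg_dose * w_depth[d_idx]
                rhizodep = frac[d_idx] * b
                root_total = b - rhizodep
                frag = config.fragment_fraction_of_root * root_total
                pools[iso] = {
                    "bulk": rhizodep * bulk_share,
                    "rhizo": rhizodep * (1.0 - bulk_share),
                    "root": root_total - frag,
                    "frag": frag,
                }

            frag_mass_g = config.fragment_fraction_of_root * root_mass_g
            frag_sub_mass_g = frag_mass_g * config.fragment_subsample_kg / (bulk_mass_g / 1000.0)

            compartments = {
                "bulk_soil": dict(
                    mass_g=bulk_mass_g,
                    soil_kg=soil_mass_kg,
                    c_conc=config.soil_c_mg_per_g[d_idx],
                    n_conc=config.soil_n_mg_per_g[d_idx],
                    # bulk reading physically includes the unrecovered fragments
                    c14=pools["c14"]["bulk"] + pools["c14"]["frag"],
                    c13=pools["c13"]["bulk"] + pools["c13"]["frag"],
                    n15=pools["n15"]["bulk"] + pools["n15"]["frag"],
                ),
                "rhizosphere_soil": dict(
                    mass_g=rhizo_mass_g,
                    soil_kg=soil_mass_kg,
                    c_conc=config.soil_c_mg_per_g[d_idx],
                    n_conc=config.soil_n_mg_per_g[d_idx],
                    c14=pools["c14"]["rhizo"],
                    c13=pools["c13"]["rhizo"],
                    n15=pools["n15"]["rhizo"],
                ),
                "root": dict(
                    mass_g=root_mass_g,
                    soil_kg=soil_mass_kg,
                    c_conc=config.root_c_mg_per_g,
                    n_conc=config.root_n_mg_per_g,
                    c14=pools["c14"]["root"],
                    c13=pools["c13"]["root"],
                    n15=pools["n15"]["root"],
                ),
                "root_fragment": dict(
                    mass_g=frag_sub_mass_g,
                    soil_kg=config.fragment_subsample_kg,
                    c_conc=config.root_c_mg_per_g,
                    n_conc=config.root_n_mg_per_g,
                    c14=pools["c14"]["frag"] * config.fragment_subsample_kg / (bulk_mass_g / 1000.0),
                    c13=pools["c13"]["frag"] * config.fragment_subsample_kg / (bulk_mass_g / 1000.0),
                    n15=pools["n15"]["frag"] * config.fragment_subsample_kg / (bulk_mass_g / 1000.0),
                ),
            }

            for comp, v in compartments.items():
                mass = v["mass_g"] * _lognormal_factor(rng, config.noise_cv)
                c_conc = v["c_conc"] * _lognormal_factor(rng, config.noise_cv)
                n_conc = v["n_conc"] * _lognormal_factor(rng, config.noise_cv)
                activity = (
                    config.background_activity_bq_per_g + v["c14"] / v["mass_g"]
                ) * _lognormal_factor(rng, config.noise_cv)
                c_content_mg = v["c_conc"] * v["mass_g"]
                n_content_mg = v["n_conc"] * v["mass_g"]
                ape13 = 100.0 * v["c13"] / c_content_mg
                ape15 = 100.0 * v["n15"] / n_content_mg
                d13 = atom_percent_to_delta(ap_bg_c + ape13, VPDB) + rng.normal(
                    0.0, config.delta_noise_sd_permil
                )
                d15 = atom_percent_to_delta(ap_bg_n + ape15, AIR_N2) + rng.normal(
                    0.0, config.delta_noise_sd_permil
                )
                sample_rows.append(
                    {
                        "plot_id": plot_id,
                        "species": species,
                        "n_rate": n_rate,
                        "depth_top_cm": depth.top_cm,
                        "depth_bottom_cm": depth.bottom_cm,
                        "compartment": comp,
                        "dry_mass_g": mass,
                        "soil_mass_kg": v["soil_kg"],
                        "c_mg_per_g": c_conc,
                        "n_mg_per_g": n_conc,
                        "d13c_permil": d13,
                        "d15n_permil": d15,
                        "c14_bq_per_g": activity,
                        "is_labeled": True,
                    }
                )

            # --- biomarkers in the rhizosphere -----------------------------
            rhizo_13c_ug_per_g = 1000.0 * pools["c13"]["rhizo"] / rhizo_mass_g
            marker_13c = config.biomarker_incorporation_fraction * rhizo_13c_ug_per_g
            h = config.necromass_fraction_by_depth[d_idx]
            pool_13c = {"AS": h * marker_13c, "PLFA": (1 - h) * marker_13c}
            pool_conc = {
                "AS": config.as_conc_ug_per_g[d_idx],
                "PLFA": config.plfa_conc_ug_per_g[d_idx],
                "AA": config.aa_conc_ug_per_g[d_idx],
            }
            pool_13c["AA"] = config.aa_incorporation_fraction * rhizo_13c_ug_per_g

            true_apes = {}
            for cls in ("AS", "PLFA", "AA"):
                sub = class_weights[cls]
                conc = pool_conc[cls] * sub["weight"].to_numpy()
                c_content = conc * sub["carbon_fraction"].to_numpy()
                ape_pool = 100.0 * pool_13c[cls] / c_content.sum()
                true_apes[cls] = ape_pool
                if not include_biomarkers:
                    continue
                d_analyte = _delta_from_ape(config.class_background_d13c[cls], ape_pool, VPDB)
                for j, compound in enumerate(sub.index):
                    marker_rows.append(
                        _marker_row(
                            config,
                            rng_m,
                            run_counter,
                            plot_id,
                            species,
                            n_rate,
                            depth,
                            "rhizosphere_soil",
                            compound,
                            cls,
                            conc[j],
                            d_analyte,
                            table,
                            labeled=True,
                        )
                    )

            truth_rows.append(
                {
                    "plot_id": plot_id,
                    "species": species,
                    "n_rate": n_rate,
                    "depth_top_cm": depth.top_cm,
                    "depth_bottom_cm": depth.bottom_cm,
                    "true_clvr_percent": 100.0 * f_c[d_idx],
                    "true_net_rhizo_c_mg_per_kg": f_c[d_idx] / (1 - f_c[d_idx]) * config.root_c_mg_per_kg[d_idx],
                    "true_root_c_mg_per_kg": config.root_c_mg_per_kg[d_idx],
                    "true_clvr_n_percent": 100.0 * f_n[d_idx],
                    "true_rms": math.log10(true_apes["AS"] / true_apes["PLFA"]),
                    "true_necromass_fraction": h,
                }
            )

    # --- unlabeled backgrounds (shared across treatments) ------------------
    rng_bg = np.random.default_rng([config.seed % (2**31), 104729])
    rng_bgm = np.random.default_rng([config.seed % (2**31), 104729, 1])
    for rep in range(1, config.n_background_replicates + 1):
        for d_idx, depth in enumerate(depths):
            soil_mass_kg = config.soil_mass_kg_per_cm * depth.thickness_cm
            for comp in ("bulk_soil", "rhizosphere_soil", "root", "root_fragment"):
                is_root = comp in ("root", "root_fragment")
                sample_rows.append(
                    {
                        "plot_id": f"BG{rep}",
                        "species": "background",
                        "n_rate": 0,
                        "depth_top_cm": depth.top_cm,
                        "depth_bottom_cm": depth.bottom_cm,
                        "compartment": comp,
                        "dry_mass_g": 100.0 * _lognormal_factor(rng_bg, config.noise_cv),
                        "soil_mass_kg": soil_mass_kg,
                        "c_mg_per_g": (config.root_c_mg_per_g if is_root else config.soil_c_mg_per_g[d_idx])
                        * _lognormal_factor(rng_bg, config.noise_cv),
                        "n_mg_per_g": (config.root_n_mg_per_g if is_root else config.soil_n_mg_per_g[d_idx])
                        * _lognormal_factor(rng_bg, config.noise_cv),
                        "d13c_permil": config.background_d13c
                        + rng_bg.normal(0.0, config.delta_noise_sd_permil),
                        "d15n_permil": config.background_d15n
                        + rng_bg.normal(0.0, config.delta_noise_sd_permil),
                        "c14_bq_per_g": config.background_activity_bq_per_g
                        * _lognormal_factor(rng_bg, config.noise_cv),
                        "is_labeled": False,
                    }
                )
        # unlabeled biomarker backgrounds
        for d_idx, depth in enumerate(depths):
            if not include_biomarkers:
                break
            for cls in ("AS", "PLFA", "AA"):
                sub = class_weights[cls]
                conc = (
                    {"AS": config.as_conc_ug_per_g, "PLFA": config.plfa_conc_ug_per_g, "AA": config.aa_conc_ug_per_g}[cls][d_idx]
                    * sub["weight"].to_numpy()
                )
                for j, compound in enumerate(sub.index):
                    marker_rows.append(
                        _marker_row(
                            config,
                            rng_bgm,
                            run_counter,
                            f"BG{rep}",
                            "background",
                            0,
                            depth,
                            "rhizosphere_soil",
                            compound,
                            cls,
                            conc[j],
                            config.class_background_d13c[cls],
                            table,
                            labeled=False,
                        )
                    )

    # --- calibration standards ---------------------------------------------
    rng_cal = np.random.default_rng([config.seed % (2**31), 1299709])
    cal_rows = []
    for cls in bm.BIOMARKER_CLASSES:
        offset, drift, amount_slope = config.instrument_bias[cls]
        n_runs = max(run_counter[cls], 12)
        # amounts shuffled against run order so drift and amount terms stay separable
        amount_levels = (3.2, 320.0, 10.0, 100.0, 32.0, 1000.0)
        for true_delta in (-30.0, -25.0, -20.0):
            for k in range(6):
                run_index = round(k * (n_runs - 1) / 5)
                amount = amount_levels[k]
                measured = (
                    true_delta
                    + offset
                    + drift * run_index
                    + amount_slope * math.log(amount)
                    + rng_cal.normal(0.0, config.delta_noise_sd_permil)
                )
                cal_rows.append(
                    {
                        "biomarker_class": cls,
                        "true_delta": true_delta,
                        "measured_delta": measured,
                        "amount": amount,
                        "run_index": run_index,
                    }
                )

    samples = pd.DataFrame(sample_rows)
    markers = pd.DataFrame(marker_rows)
    calibration = pd.DataFrame(cal_rows)
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(samples=samples, biomarkers=markers, calibration=calibration, truth=truth, config=config)


def _marker_row(
    config: ScenarioConfig,
    rng: np.random.Generator,
    run_counter: dict,
    plot_id: str,
    species: str,
    n_rate: int,
    depth: DepthInterval,
    matrix: str,
    compound: str,
    cls: str,
    concentration: float,
    delta_analyte: float,
    table: pd.DataFrame,
    *,
    labeled: bool,
) -> dict:
    """One biomarker record: forward dilution + instrument bias + noise."""
    n_c = float(table.loc[compound, "n_carbon"])
    n_add = float(table.loc[compound, "n_carbon_added"])
    offset, drift, amount_slope = config.instrument_bias[cls]
    run_index = run_counter[cls]
    run_counter[cls] = run_index + 1
    conc_meas = concentration * _lognormal_factor(rng, config.noise_cv)
    amount = max(concentration * 0.05, 1e-6) * _lognormal_factor(rng, config.noise_cv)
    d_diluted = bm.dilute_delta(delta_analyte, n_c, n_add, config.reagent_d13c[cls])
    d_measured = (
        d_diluted
        + offset
        + drift * run_index
        + amount_slope * math.log(amount)
        + rng.normal(0.0, config.delta_noise_sd_permil)
    )
    return {
        "plot_id": plot_id,
        "species": species,
        "n_rate": n_rate,
        "depth_top_cm": depth.top_cm,
        "depth_bottom_cm": depth.bottom_cm,
        "matrix": matrix,
        "compound": compound,
        "biomarker_class": cls,
        "concentration_ug_per_g": conc_meas,
        "d13c_measured": d_measured,
        "run_index": run_index,
        "peak_amount": amount,
        "is_labeled": labeled,
    }
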