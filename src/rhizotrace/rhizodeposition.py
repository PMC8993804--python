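"""Tracer mass balance: root C, adjusted bulk 14C, %ClvR and net rhizodeposition.

The partitioning logic, per depth interval and plot:

* each soil/root compartment's tracer pool is its per-gram enrichment
  (excess over the unlabeled background) multiplied by the compartment mass;
* the bulk-soil pool is adjusted by subtracting the tracer found in root
  fragments washed from a subsample (scaled to the full bulk mass), because
  those fragments are root material physically sitting in the bulk soil;
* %ClvR (percent of belowground C lost via rhizodeposition) is the soil
  tracer share of the total belowground tracer:

      %ClvR = 100 * (rhizosphere + adjusted bulk)
                  / (adjusted bulk + rhizosphere + root incl. fragments)

* net rhizodeposition = %ClvR * root C / (100 - %ClvR), which is the unique
  quantity satisfying net / (net + root C) = %ClvR / 100.

The default denominator uses the adjusted bulk pool and folds the fragment
tracer into the root pool so numerator + remainder = denominator exactly
(mass conservation).  A strict-literal mode is available that keeps the raw
bulk pool and the bare root pool in the denominator, reproducing the
published formula verbatim; the two differ only when fragments carry tracer.

The nitrogen path runs the identical algebra with mg excess-15N pools
(atom% excess x N content) in place of 14C activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope import AIR_N2, VPDB, ReferenceStandard, atom_percent_excess

logger = logging.getLogger(__name__)

__all__ = [
    "DepthInterval",
    "DEFAULT_DEPTHS",
    "TracerPools",
    "TracerPartition",
    "root_c_concentration",
    "fragment_14c",
    "adjusted_bulk_14c",
    "percent_clvr",
    "net_rhizodeposition",
    "concentration_to_area_stock",
    "partition_samples",
    "COMPARTMENTS",
]

COMPARTMENTS = ("bulk_soil", "rhizosphere_soil", "root", "root_fragment")


@dataclass(frozen=True, order=True)
class DepthInterval:
    """A half-open sampling interval [top, bottom) in cm below the surface."""

    top_cm: float
    bottom_cm: float

    def __post_init__(self) -> None:
        if not (0 <= self.top_cm < self.bottom_cm):
            raise ValueError(
                f"invalid depth interval [{self.top_cm}, {self.bottom_cm}): "
                "need 0 <= top < bottom"
            )

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm

    def __str__(self) -> str:  # e.g. "0-25"
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return f"{fmt(self.top_cm)}-{fmt(self.bottom_cm)}"


#: The default sampling design: 0-25, 25-50, 50-100, 100-150 cm.
DEFAULT_DEPTHS = (
    DepthInterval(0, 25),
    DepthInterval(25, 50),
    DepthInterval(50, 100),
    DepthInterval(100, 150),
)


@dataclass
class TracerPools:
    """Per-depth tracer pools (Bq for 14C; mg excess-15N for the N analogs)."""

    c14_rhizosphere: float
    c14_bulk_raw: float
    c14_fragments: float
    c14_root: float
    c14_bulk_adjusted: float = field(init=False)
    n15_rhizosphere: float | None = None
    n15_bulk_raw: float | None = None
    n15_fragments: float | None = None
    n15_root: float | None = None
    n15_bulk_adjusted: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.c14_bulk_adjusted = adjusted_bulk_14c(self.c14_bulk_raw, self.c14_fragments)
        if self.n15_bulk_raw is not None and self.n15_fragments is not None:
            self.n15_bulk_adjusted = adjusted_bulk_14c(self.n15_bulk_raw, self.n15_fragments)


@dataclass(frozen=True)
class TracerPartition:
    """The mass-balance result for one plot x species x depth."""

    depth: DepthInterval
    clvr_percent: float
    root_c: float  # mg C kg-1 soil
    net_rhizo_c: float  # mg C kg-1 soil
    clvr_n_percent: float | None = None
    net_rhizo_n: float | None = None  # mg N kg-1 soil


def root_c_concentration(root_dry_matter_g, c_concentration_mg_per_g, soil_mass_sampled_kg, *, label=None):
    """Root C per kg of sampled soil: dry matter x C concentration / soil mass."""
    if np.any(np.asarray(soil_mass_sampled_kg) <= 0):
        where = f" for {label}" if label else ""
        raise ValueError(f"soil mass sampled must be > 0{where}")
    return root_dry_matter_g * c_concentration_mg_per_g / soil_mass_sampled_kg


def fragment_14c(fragment_enrichment_bq_per_g, fragment_mass_g, subsample_mass_kg, full_sample_mass_kg):
    """Tracer content of unrecovered root fragments, scaled to the full soil mass.

    Fragments are washed from a subsample of the bulk soil; their tracer
    content (enrichment x fragment mass) is scaled up to the entire soil
    volume sampled by the mass ratio full / subsample.
    """
    if not 0 < subsample_mass_kg <= full_sample_mass_kg:
        raise ValueError(
            f"subsample mass ({subsample_mass_kg} kg) must be positive and not "
            f"exceed the full sample mass ({full_sample_mass_kg} kg)"
        )
    return fragment_enrichment_bq_per_g * fragment_mass_g * (full_sample_mass_kg / subsample_mass_kg)


def adjusted_bulk_14c(bulk_bq: float, fragments_bq: float) -> float:
    """Bulk-soil tracer minus fragment tracer; clamped at zero with a warning.

    A fragment content exceeding the bulk content indicates measurement
    noise, not negative soil tracer, so the deficit is logged and the pool
    set to zero.
    """
    diff = bulk_bq - fragments_bq
    if diff < 0:
        logger.warning(
            "adjusted bulk pool negative (bulk=%.6g, fragments=%.6g, deficit=%.6g); clamped to 0",
            bulk_bq,
            fragments_bq,
            -diff,
        )
        return 0.0
    return diff


def percent_clvr(pools: TracerPools, *, isotope: str = "c14", strict_literal: bool = False, label=None) -> float:
    """Percent of belowground tracer lost via rhizodeposition.

    Numerator: rhizosphere + adjusted bulk soil tracer.  Denominator, default
    (mass-conserving) mode: adjusted bulk + rhizosphere + root incl. fragment
    tracer.  ``strict_literal`` keeps raw bulk and the bare root pool in the
    denominator instead.
    """
    pre = f"{isotope}_"
    rhizo = getattr(pools, pre + "rhizosphere")
    adj = getattr(pools, pre + "bulk_adjusted")
    raw = getattr(pools, pre + "bulk_raw")
    frag = getattr(pools, pre + "fragments")
    root = getattr(pools, pre + "root")
    if any(v is None for v in (rhizo, adj, raw, frag, root)):
        raise ValueError(f"missing {isotope} channel{' for ' + str(label) if label else ''}")
    numerator = rhizo + adj
    if strict_literal:
        denominator = raw + rhizo + root
    else:
        denominator = adj + rhizo + (root + frag)
    if denominator <= 0:
        raise ValueError(
            f"no tracer recovered (denominator <= 0){' for ' + str(label) if label else ''}"
        )
    return 100.0 * numerator / denominator


def net_rhizodeposition(clvr_percent: float, root_c: float) -> float:
    """Net rhizodeposited C (same units as root_c): clvr x root_c / (100 - clvr)."""
    if not 0 <= clvr_percent < 100:
        raise ValueError(f"%ClvR must be in [0, 100), got {clvr_percent}")
    return clvr_percent * root_c / (100.0 - clvr_percent)


def concentration_to_area_stock(conc_mg_per_kg, bulk_density_g_cm3, depth: DepthInterval):
    """Convert a soil concentration (mg kg-1) to an area stock (Mg ha-1).

    mg kg-1 x BD (g cm-3) x thickness (cm) x 0.1 gives kg ha-1; / 1000 -> Mg ha-1.
    """
    if np.any(np.asarray(bulk_density_g_cm3) <= 0):
        raise ValueError(f"bulk density must be > 0 for depth {depth}")
    kg_per_ha = conc_mg_per_kg * bulk_density_g_cm3 * depth.thickness_cm * 0.1
    return kg_per_ha / 1000.0


# ---------------------------------------------------------------------------
# Table-level partitioning
# ---------------------------------------------------------------------------

_GROUP_KEYS = ["plot_id", "species", "n_rate", "depth_top_cm", "depth_bottom_cm"]
_BG_KEYS = ["compartment", "depth_top_cm", "depth_bottom_cm"]


def _background_lookup(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean background reading per (compartment, depth), from unlabeled rows."""
    bg = samples[~samples["is_labeled"].astype(bool)]
    if bg.empty:
        raise ValueError("no unlabeled background rows in sample table")
    return (
        bg.groupby(_BG_KEYS)[["d13c_permil", "d15n_permil", "c14_bq_per_g"]]
        .mean()
        .rename(columns=lambda c: "bg_" + c)
    )


def partition_samples(
    samples: pd.DataFrame,
    *,
    strict_literal: bool = False,
    c_standard: ReferenceStandard = VPDB,
    n_standard: ReferenceStandard = AIR_N2,
    bulk_density: dict | None = None,
) -> pd.DataFrame:
    """Run the full tracer mass balance on a validated sample table.

    One output row per plot x species x n_rate x depth with %ClvR, root C,
    net rhizodeposited C, the 15N analogs, the intermediate tracer pools,
    and (if ``bulk_density`` maps DepthInterval -> g cm-3) Mg ha-1 stocks.

    Per-plot computation first; averaging across plot replicates is left to
    the caller so the replicate structure is never pooled away.
    """
    labeled = samples[samples["is_labeled"].astype(bool)]
    bg = _background_lookup(samples)
    rows = []
    for key, grp in labeled.groupby(_GROUP_KEYS, sort=True):
        plot_id, species, n_rate, top, bottom = key
        depth = DepthInterval(top, bottom)
        label = f"{plot_id}/{species}/N{n_rate}/{depth}"
        comp = {}
        for _, r in grp.iterrows():
            comp[r["compartment"]] = r
        missing = [c for c in ("bulk_soil", "rhizosphere_soil", "root") if c not in comp]
        if missing:
            raise ValueError(f"missing compartments {missing} for {label}")

        def excess14(row):
            b = bg.loc[(row["compartment"], top, bottom)]
            return row["c14_bq_per_g"] - b["bg_c14_bq_per_g"]

        def excess15_mg(row):
            b = bg.loc[(row["compartment"], top, bottom)]
            if pd.isna(row.get("d15n_permil")) or pd.isna(b["bg_d15n_permil"]):
                return None
            ape = atom_percent_excess(row["d15n_permil"], b["bg_d15n_permil"], n_standard, label=label)
            n_mg = row["n_mg_per_g"] * row["dry_mass_g"]
            return ape / 100.0 * n_mg

        bulk, rhizo, root = comp["bulk_soil"], comp["rhizosphere_soil"], comp["root"]
        c14_bulk = excess14(bulk) * bulk["dry_mass_g"]
        c14_rhizo = excess14(rhizo) * rhizo["dry_mass_g"]
        c14_root = excess14(root) * root["dry_mass_g"]
        if "root_fragment" in comp:
            frag = comp["root_fragment"]
            c14_frag = fragment_14c(
                excess14(frag),
                frag["dry_mass_g"],
                frag["soil_mass_kg"],
                bulk["dry_mass_g"] / 1000.0,
            )
        else:
            frag = None
            c14_frag = 0.0

        n15 = {}
        for name, row in (("bulk_raw", bulk), ("rhizosphere", rhizo), ("root", root)):
            n15[name] = excess15_mg(row)
        if frag is not None and n15["bulk_raw"] is not None:
            fr = excess15_mg(frag)
            n15["fragments"] = (
                None
                if fr is None
                else fr * (bulk["dry_mass_g"] / 1000.0) / frag["soil_mass_kg"]
            )
        else:
            n15["fragments"] = 0.0 if n15["bulk_raw"] is not None else None

        pools = TracerPools(
            c14_rhizosphere=c14_rhizo,
            c14_bulk_raw=c14_bulk,
            c14_fragments=c14_frag,
            c14_root=c14_root,
            n15_rhizosphere=n15["rhizosphere"],
            n15_bulk_raw=n15["bulk_raw"],
            n15_fragments=n15["fragments"],
            n15_root=n15["root"],
        )
        clvr = percent_clvr(pools, strict_literal=strict_literal, label=label)
        root_c = root_c_concentration(
            root["dry_mass_g"], root["c_mg_per_g"], root["soil_mass_kg"], label=label
        )
        net_c = net_rhizodeposition(clvr, root_c)

        clvr_n = net_n = None
        if all(n15[k] is not None for k in ("bulk_raw", "rhizosphere", "root", "fragments")):
            clvr_n = percent_clvr(pools, isotope="n15", strict_literal=strict_literal, label=label)
            root_n = root["dry_mass_g"] * root["n_mg_per_g"] / root["soil_mass_kg"]
            net_n = net_rhizodeposition(clvr_n, root_n)

        out = {
            "plot_id": plot_id,
            "species": species,
            "n_rate": n_rate,
            "depth_top_cm": top,
            "depth_bottom_cm": bottom,
            "clvr_percent": clvr,
            "root_c_mg_per_kg": root_c,
            "net_rhizo_c_mg_per_kg": net_c,
            "clvr_n_percent": clvr_n,
            "net_rhizo_n_mg_per_kg": net_n,
            "c14_bulk_raw_bq": c14_bulk,
            "c14_bulk_adjusted_bq": pools.c14_bulk_adjusted,
            "c14_rhizosphere_bq": c14_rhizo,
            "c14_fragments_bq": c14_frag,
            "c14_root_bq": c14_root,
        }
        if bulk_density is not None:
            bd = bulk_density.get(depth)
            if bd is None:
                raise ValueError(f"no bulk density supplied for depth {depth}")
            out["root_c_mg_ha"] = concentration_to_area_stock(root_c, bd, depth)
            out["net_rhizo_c_mg_ha"] = concentration_to_area_stock(net_c, bd, depth)
        rows.append(out)
    result = pd.DataFrame(rows)
    return result.sort_values(_GROUP_KEYS).reset_index(drop=True)
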