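"""Compound-specific stable isotope probing of microbial biomarkers.

Measured delta13C of derivatized compounds is corrected in a fixed order:

1. instrument effects — offset, drift over run index, and amount dependence
   (linear in log peak amount), fitted by least squares on co-run standards;
2. derivatization dilution — the carbon atoms added by derivatization dilute
   the analyte signal; a two-pool mixing balance recovers the analyte delta.

Corrected deltas are converted to atom-percent excess over the unlabeled
background of the same compound, multiplied by the compound's carbon content
(concentration x carbon mass fraction from its molecular formula) to give
13C incorporation, and summed into pools: PLFA (living microbial biomass),
amino sugars (necromass), and amino acids (exudate quality).  Each pool's
weighted atom% 13C excess is total 13C incorporation / total pool C x 100.

Per-compound carbon counts and formulas ship in a bundled reference table
(``rhizotrace/data/compounds.csv``); users may substitute their own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .isotope import VPDB, ReferenceStandard, atom_percent_to_delta, delta_to_atom_percent

__all__ = [
    "AS_COMPOUNDS",
    "AA_COMPOUNDS",
    "BIOMARKER_CLASSES",
    "load_compound_table",
    "carbon_mass_fraction",
    "dilute_delta",
    "correct_derivatization_dilution",
    "CorrectionModel",
    "fit_instrument_correction",
    "apply_correction",
    "biomarker_13c_incorporation",
    "PoolSummary",
    "pool_summary",
    "process_biomarkers",
]

BIOMARKER_CLASSES = ("PLFA", "AS", "AA")

#: The four detected amino sugars whose sum defines the necromass pool.
AS_COMPOUNDS = frozenset({"GlcN", "GalN", "MurN", "ManN"})

#: The 11-entry amino acid panel (Asx/Glx/Pro-Thr are chromatographic sums).
AA_COMPOUNDS = frozenset(
    {
        "alanine",
        "Asx",
        "Glx",
        "glycine",
        "isoleucine",
        "lysine",
        "phenylalanine",
        "Pro/Thr",
        "serine",
        "tyrosine",
        "valine",
    }
)

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_mass_fraction(formula: str) -> float:
    """Mass fraction of carbon in a molecular formula like ``C6H13NO5``."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(1):
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or "C" not in counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    try:
        mw = sum(_ATOMIC_MASS[el] * n for el, n in counts.items())
    except KeyError as e:
        raise ValueError(f"unknown element {e} in formula {formula!r}") from None
    return _ATOMIC_MASS["C"] * counts["C"] / mw


def load_compound_table(path=None) -> pd.DataFrame:
    """Load the compound reference table (bundled by default), indexed by compound.

    Adds a ``carbon_fraction`` column computed from the molecular formula and
    validates class membership of the AS and AA panels.
    """
    if path is None:
        src = resources.files("rhizotrace.data").joinpath("compounds.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    required = {"compound", "biomarker_class", "formula", "n_carbon", "n_carbon_added"}
    if not required.issubset(table.columns):
        raise ValueError(f"compound table missing columns {sorted(required - set(table.columns))}")
    bad_class = set(table["biomarker_class"]) - set(BIOMARKER_CLASSES)
    if bad_class:
        raise ValueError(f"unknown biomarker classes {sorted(bad_class)}")
    bad_as = set(table.loc[table["biomarker_class"] == "AS", "compound"]) - AS_COMPOUNDS
    if bad_as:
        raise ValueError(f"compounds outside the amino-sugar panel: {sorted(bad_as)}")
    bad_aa = set(table.loc[table["biomarker_class"] == "AA", "compound"]) - AA_COMPOUNDS
    if bad_aa:
        raise ValueError(f"compounds outside the amino-acid panel: {sorted(bad_aa)}")
    table = table.set_index("compound")
    table["carbon_fraction"] = [carbon_mass_fraction(f) for f in table["formula"]]
    return table


# ---------------------------------------------------------------------------
# Derivatization dilution
# ---------------------------------------------------------------------------


def dilute_delta(delta_analyte, n_analyte, n_added, delta_reagent, *, scale="delta", standard=VPDB):
    """Forward model: delta of the derivative from analyte + reagent carbons.

    ``scale='delta'`` applies the linear mixing approximation standard in
    CSIA; ``scale='atom_fraction'`` mixes exactly on the atom-fraction scale.
    """
    if n_added == 0:
        return delta_analyte
    if scale == "delta":
        return (n_analyte * delta_analyte + n_added * delta_reagent) / (n_analyte + n_added)
    if scale == "atom_fraction":
        ap_a = delta_to_atom_percent(delta_analyte, standard)
        ap_r = delta_to_atom_percent(delta_reagent, standard)
        ap_m = (n_analyte * ap_a + n_added * ap_r) / (n_analyte + n_added)
        return atom_percent_to_delta(ap_m, standard)
    raise ValueError(f"unknown scale {scale!r}")


def correct_derivatization_dilution(
    delta_measured, n_analyte, n_added, delta_reagent, *, scale="delta", standard=VPDB
):
    """Undo the isotopic dilution by derivatization carbon.

    delta_analyte = ((n_a + n_d) * delta_measured - n_d * delta_reagent) / n_a

    on the delta scale (default; standard linear-mixing CSIA correction), or
    the exact analog on the atom-fraction scale.  Identity when n_added = 0.
    """
    if n_analyte < 1:
        raise ValueError(f"n_analyte must be >= 1, got {n_analyte}")
    if n_added < 0:
        raise ValueError(f"n_added must be >= 0, got {n_added}")
    if n_added == 0:
        return delta_measured
    if scale == "delta":
        return ((n_analyte + n_added) * delta_measured - n_added * delta_reagent) / n_analyte
    if scale == "atom_fraction":
        ap_m = delta_to_atom_percent(delta_measured, standard)
        ap_r = delta_to_atom_percent(delta_reagent, standard)
        ap_a = ((n_analyte + n_added) * ap_m - n_added * ap_r) / n_analyte
        return atom_percent_to_delta(ap_a, standard)
    raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# Instrument correction (offset / drift / amount dependence)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectionModel:
    """Additive instrument bias: offset + drift * run_index + amount_slope * log(amount).

    All coefficients zero is the identity correction.
    """

    offset: float = 0.0
    drift_slope: float = 0.0
    amount_slope: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.offset == self.drift_slope == self.amount_slope == 0.0


def fit_instrument_correction(
    calibration: pd.DataFrame, terms: tuple[str, ...] = ("offset", "drift", "amount")
) -> CorrectionModel:
    """Least-squares fit of the instrument bias from co-run standards.

    ``calibration`` needs columns true_delta, measured_delta, and run_index /
    amount for the corresponding terms.  The response is measured - true.
    A requested slope term with no spread in its covariate is rank-deficient
    and raises, naming the deficient term.
    """
    if len(calibration) < 2:
        raise ValueError("need at least 2 calibration points")
    resid = np.asarray(calibration["measured_delta"] - calibration["true_delta"], float)
    cols = []
    names = []
    if "offset" in terms:
        cols.append(np.ones(len(calibration)))
        names.append("offset")
    if "drift" in terms:
        x = np.asarray(calibration["run_index"], float)
        if np.ptp(x) == 0:
            raise ValueError("rank-deficient design: no spread in run_index for drift term")
        cols.append(x)
        names.append("drift")
    if "amount" in terms:
        a = np.asarray(calibration["amount"], float)
        if np.any(a <= 0):
            raise ValueError("peak amounts must be > 0 for the log-amount term")
        la = np.log(a)
        if np.ptp(la) == 0:
            raise ValueError("rank-deficient design: no spread in amount for amount term")
        cols.append(la)
        names.append("amount")
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
    coef = dict(zip(names, beta))
    return CorrectionModel(
        offset=float(coef.get("offset", 0.0)),
        drift_slope=float(coef.get("drift", 0.0)),
        amount_slope=float(coef.get("amount", 0.0)),
    )


def apply_correction(model: CorrectionModel, delta_measured, amount=None, run_index=None):
    """Remove the fitted instrument bias from a measured delta."""
    out = np.asarray(delta_measured, float)
    out = out - model.offset
    if model.drift_slope != 0.0:
        if run_index is None:
            raise ValueError("run_index required: model has a drift term")
        out = out - model.drift_slope * np.asarray(run_index, float)
    if model.amount_slope != 0.0:
        if amount is None:
            raise ValueError("amount required: model has an amount term")
        out = out - model.amount_slope * np.log(np.asarray(amount, float))
    return float(out) if np.ndim(delta_measured) == 0 else out


# ---------------------------------------------------------------------------
# Incorporation and pool aggregation
# ---------------------------------------------------------------------------


def biomarker_13c_incorporation(
    concentration_ug_per_g,
    carbon_fraction,
    delta_corrected,
    delta_background,
    standard: ReferenceStandard = VPDB,
):
    """13C incorporation (ug excess-13C per g matrix) for one compound.

    (AP(corrected) - AP(background)) / 100 x concentration x carbon fraction.
    """
    ape = delta_to_atom_percent(delta_corrected, standard) - delta_to_atom_percent(
        delta_background, standard
    )
    return concentration_ug_per_g * carbon_fraction * ape / 100.0


@dataclass(frozen=True)
class PoolSummary:
    """Aggregated biomarker pool for one sample and class."""

    sample_id: str
    biomarker_class: str
    total_concentration: float  # ug g-1
    total_c: float  # ug C g-1
    total_13c_excess: float  # ug 13C g-1
    weighted_ape: float  # atom%
    n_compounds: int = 0
    meta: dict = field(default_factory=dict, compare=False)


_ALLOWED = {"AS": AS_COMPOUNDS, "AA": AA_COMPOUNDS}


def pool_summary(records: pd.DataFrame, compound_table: pd.DataFrame | None = None) -> PoolSummary:
    """Aggregate corrected records of one sample x class into a PoolSummary.

    ``records`` needs columns compound, biomarker_class, concentration_ug_per_g,
    c_content_ug_per_g, incorporation_ug_13c_per_g (as produced by
    :func:`process_biomarkers`), all from one sample and one class.
    An empty record set is an absent pool and raises rather than returning zero.
    """
    if len(records) == 0:
        raise ValueError("empty pool: no biomarker records for this sample/class")
    classes = set(records["biomarker_class"])
    if len(classes) != 1:
        raise ValueError(f"records span multiple classes: {sorted(classes)}")
    cls = classes.pop()
    allowed = _ALLOWED.get(cls)
    if allowed is not None:
        bad = set(records["compound"]) - allowed
        if bad:
            raise ValueError(f"compounds {sorted(bad)} not allowed in class {cls}")
    if compound_table is not None:
        unknown = set(records["compound"]) - set(compound_table.index)
        if unknown:
            raise ValueError(f"compounds missing from reference table: {sorted(unknown)}")
    total_conc = float(records["concentration_ug_per_g"].sum())
    total_c = float(records["c_content_ug_per_g"].sum())
    total_exc = float(records["incorporation_ug_13c_per_g"].sum())
    wape = 100.0 * total_exc / total_c if total_c > 0 else float("nan")
    sample_id = str(records["sample_id"].iloc[0]) if "sample_id" in records else ""
    return PoolSummary(
        sample_id=sample_id,
        biomarker_class=cls,
        total_concentration=total_conc,
        total_c=total_c,
        total_13c_excess=total_exc,
        weighted_ape=wape,
        n_compounds=len(records),
    )


_SAMPLE_KEYS = ["plot_id", "species", "n_rate", "depth_top_cm", "depth_bottom_cm", "matrix"]


def process_biomarkers(
    records: pd.DataFrame,
    reagent_delta: dict[str, float],
    correction: dict[str, CorrectionModel] | None = None,
    compound_table: pd.DataFrame | None = None,
    *,
    standard: ReferenceStandard = VPDB,
    dilution_scale: str = "delta",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct a biomarker record table and aggregate it into pool summaries.

    Order of corrections is fixed: instrument first, then derivatization
    dilution.  Backgrounds are the unlabeled rows, matched per (compound,
    depth, matrix) and averaged.  ``reagent_delta`` maps biomarker class to
    the delta13C of the derivatization reagent carbon — it has no default
    because it is reagent-batch specific.

    Returns (corrected per-record table for labeled rows, pool-summary table
    with one row per sample x class).
    """
    table = compound_table if compound_table is not None else load_compound_table()
    df = records.copy()
    unknown = set(df["compound"]) - set(table.index)
    if unknown:
        raise ValueError(f"compounds missing from reference table: {sorted(unknown)}")
    tbl_cls = table["biomarker_class"]
    mismatch = df[df["biomarker_class"] != tbl_cls.reindex(df["compound"]).to_numpy()]
    if len(mismatch):
        raise ValueError(
            "biomarker_class disagrees with reference table for compounds "
            f"{sorted(set(mismatch['compound']))}"
        )
    missing_reagent = set(df["biomarker_class"]) - set(reagent_delta)
    if missing_reagent:
        raise ValueError(f"no reagent delta13C supplied for classes {sorted(missing_reagent)}")

    n_carbon = table["n_carbon"].reindex(df["compound"]).to_numpy(float)
    n_added = table["n_carbon_added"].reindex(df["compound"]).to_numpy(float)
    c_frac = table["carbon_fraction"].reindex(df["compound"]).to_numpy(float)
    reagent = df["biomarker_class"].map(reagent_delta).to_numpy(float)

    corrected = np.empty(len(df), float)
    for i, (_, row) in enumerate(df.iterrows()):
        d = row["d13c_measured"]
        model = (correction or {}).get(row["biomarker_class"])
        if model is not None:
            d = apply_correction(model, d, amount=row.get("peak_amount"), run_index=row.get("run_index"))
        corrected[i] = correct_derivatization_dilution(
            d, n_carbon[i], n_added[i], reagent[i], scale=dilution_scale, standard=standard
        )
    df["d13c_corrected"] = corrected
    df["c_content_ug_per_g"] = df["concentration_ug_per_g"].to_numpy(float) * c_frac

    labeled = df[df["is_labeled"].astype(bool)].copy()
    bg = df[~df["is_labeled"].astype(bool)]
    if bg.empty:
        raise ValueError("no unlabeled background biomarker rows")
    bg_keys = ["compound", "depth_top_cm", "depth_bottom_cm", "matrix"]
    bg_mean = bg.groupby(bg_keys)["d13c_corrected"].mean()
    idx = pd.MultiIndex.from_frame(labeled[bg_keys])
    matched = bg_mean.reindex(idx)
    if matched.isna().any():
        miss = labeled.loc[matched.isna().to_numpy(), ["compound", "depth_top_cm", "depth_bottom_cm"]]
        pairs = sorted({(r.compound, f"{r.depth_top_cm}-{r.depth_bottom_cm}") for r in miss.itertuples()})
        raise ValueError(f"no background for compound/depth pairs: {pairs}")
    labeled["d13c_background"] = matched.to_numpy()
    labeled["incorporation_ug_13c_per_g"] = biomarker_13c_incorporation(
        labeled["concentration_ug_per_g"].to_numpy(float),
        table["carbon_fraction"].reindex(labeled["compound"]).to_numpy(float),
        labeled["d13c_corrected"].to_numpy(float),
        labeled["d13c_background"].to_numpy(float),
        standard,
    )

    keys = [k for k in _SAMPLE_KEYS if k in labeled.columns]
    pool_rows = []
    for key, grp in labeled.groupby(keys + ["biomarker_class"], sort=True):
        sample_id = "_".join(str(k) for k in key[:-1])
        ps = pool_summary(grp.assign(sample_id=sample_id), table)
        row = dict(zip(keys, key[:-1]))
        row.update(
            biomarker_class=key[-1],
            total_concentration_ug_per_g=ps.total_concentration,
            total_c_ug_per_g=ps.total_c,
            total_13c_excess_ug_per_g=ps.total_13c_excess,
            weighted_ape=ps.weighted_ape,
            n_compounds=ps.n_compounds,
        )
        pool_rows.append(row)
    pools = pd.DataFrame(pool_rows)
    return labeled.reset_index(drop=True), pools
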