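"""Isotope-ratio bookkeeping: delta notation, atom percent, and tracer enrichment.

All heavy-isotope abundances are carried on the atom-percent (0-100) scale.
delta13C is per-mil versus VPDB; delta15N per-mil versus atmospheric N2.
14C is handled on the activity scale (Bq per g dry sample) throughout and is
never converted to atom percent: the mass balance only ever uses activity
differences and activity x mass products, so no decay or specific-activity
conversion is needed.

Enrichment ("excess") of a labeled sample is the difference between the
labeled and unlabeled (background) reading, on the atom-percent scale for
13C/15N and on the activity scale for 14C.  A labeled reading below its
background yields a negative excess which is preserved and flagged, not
clamped, so that pool totals remain additive; callers choose the clamping
policy where the physics demands non-negative pools.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceStandard",
    "VPDB",
    "AIR_N2",
    "IsotopeReading",
    "Enrichment",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "c14_excess",
    "tracer_mass",
    "enrichment",
]


@dataclass(frozen=True)
class ReferenceStandard:
    """An isotope reference scale: a name and its heavy/light isotope ratio."""

    name: str
    isotope_ratio: float

    def __post_init__(self) -> None:
        if not self.isotope_ratio > 0:
            raise ValueError(
                f"isotope ratio of standard {self.name!r} must be > 0, "
                f"got {self.isotope_ratio}"
            )


#: Vienna PeeDee Belemnite 13C/12C ratio (absolute ratio, Craig-corrected value).
VPDB = ReferenceStandard("VPDB", 0.0111802)
#: Atmospheric N2 15N/14N ratio.
AIR_N2 = ReferenceStandard("air-N2", 0.0036765)


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def delta_to_atom_percent(delta, standard: ReferenceStandard = VPDB, *, label: str | None = None):
    """Convert a delta value (per-mil) to atom percent of the heavy isotope.

    AP = 100 * R * (delta/1000 + 1) / (1 + R * (delta/1000 + 1))

    Accepts scalars or array-likes.  Values at or below -1000 per-mil are
    outside the physical domain (atom fraction would leave (0, 1)) and raise.
    """
    arr, scalar = _as_array(delta)
    if np.any(arr <= -1000.0) or np.any(~np.isfinite(arr)):
        where = f" in {label}" if label else ""
        raise ValueError(f"delta value(s) <= -1000 permil or non-finite{where}: domain error")
    r = standard.isotope_ratio * (arr / 1000.0 + 1.0)
    ap = 100.0 * r / (1.0 + r)
    return float(ap) if scalar else ap


def atom_percent_to_delta(ap, standard: ReferenceStandard = VPDB, *, label: str | None = None):
    """Inverse of :func:`delta_to_atom_percent`; exact closed form.

    Requires 0 < ap < 100.
    """
    arr, scalar = _as_array(ap)
    if np.any(arr <= 0.0) or np.any(arr >= 100.0) or np.any(~np.isfinite(arr)):
        where = f" in {label}" if label else ""
        raise ValueError(f"atom percent outside (0, 100){where}: domain error")
    frac = arr / 100.0
    r = frac / (1.0 - frac)
    delta = (r / standard.isotope_ratio - 1.0) * 1000.0
    return float(delta) if scalar else delta


def atom_percent_excess(
    labeled_delta,
    background_delta,
    standard: ReferenceStandard = VPDB,
    *,
    label: str | None = None,
):
    """Atom-percent excess: AP(labeled) - AP(background).

    Antisymmetric in its arguments; zero when the readings are equal; negative
    (below background) results are returned as-is for the caller to flag.
    """
    if labeled_delta is None or background_delta is None:
        where = f" for {label}" if label else ""
        raise ValueError(f"missing isotope channel{where}: cannot compute excess")
    return delta_to_atom_percent(labeled_delta, standard, label=label) - delta_to_atom_percent(
        background_delta, standard, label=label
    )


def c14_excess(labeled_activity, background_activity, *, label: str | None = None):
    """14C enrichment: difference in activity (Bq g-1) labeled minus background."""
    if labeled_activity is None or background_activity is None:
        where = f" for {label}" if label else ""
        raise ValueError(f"missing 14C activity{where}: cannot compute excess")
    la, scalar_a = _as_array(labeled_activity)
    ba, scalar_b = _as_array(background_activity)
    if np.any(la < 0) or np.any(ba < 0):
        where = f" for {label}" if label else ""
        raise ValueError(f"negative 14C activity{where}")
    out = la - ba
    return float(out) if (scalar_a and scalar_b) else out


def tracer_mass(c_content, ape):
    """Heavy-isotope excess mass: C content x atom-percent excess / 100.

    With c_content in mg C and ape in atom%, the result is mg excess 13C
    (the same product rule applies to any pool and isotope on the AP scale).
    """
    c, sc = _as_array(c_content)
    a, sa = _as_array(ape)
    if np.any(c < 0):
        raise ValueError("carbon content must be >= 0")
    out = c * a / 100.0
    return float(out) if (sc and sa) else out


@dataclass(frozen=True)
class IsotopeReading:
    """One sample's isotope measurements.

    delta15N and activity14C are optional: not every compartment is measured
    on every channel.
    """

    delta13C: float
    delta15N: float | None = None
    activity14C: float | None = None
    is_labeled: bool = True

    def __post_init__(self) -> None:
        if self.delta13C is not None and self.delta13C <= -1000.0:
            raise ValueError(f"delta13C must exceed -1000 permil, got {self.delta13C}")
        if self.activity14C is not None and self.activity14C < 0:
            raise ValueError(f"14C activity must be >= 0, got {self.activity14C}")


@dataclass(frozen=True)
class Enrichment:
    """Excess of a labeled reading over background, per channel.

    Negative values are legal (below-background) and flagged rather than
    clamped, so downstream mass balances stay additive.
    """

    atom_pct_excess13C: float | None = None
    atom_pct_excess15N: float | None = None
    excess14C: float | None = None

    @property
    def below_background(self) -> dict[str, bool]:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v is not None and v < 0
        return out


def enrichment(
    labeled: IsotopeReading,
    background: IsotopeReading,
    *,
    c_standard: ReferenceStandard = VPDB,
    n_standard: ReferenceStandard = AIR_N2,
    label: str | None = None,
) -> Enrichment:
    """Compute per-channel excess of ``labeled`` over ``background``.

    Channels missing from either reading are left as None; the 13C channel is
    mandatory for both readings.
    """
    ape13 = atom_percent_excess(labeled.delta13C, background.delta13C, c_standard, label=label)
    ape15 = None
    if labeled.delta15N is not None and background.delta15N is not None:
        ape15 = atom_percent_excess(labeled.delta15N, background.delta15N, n_standard, label=label)
    exc14 = None
    if labeled.activity14C is not None and background.activity14C is not None:
        exc14 = c14_excess(labeled.activity14C, background.activity14C, label=label)
    return Enrichment(atom_pct_excess13C=ape13, atom_pct_excess15N=ape15, excess14C=exc14)
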