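"""Relative microbial stabilization (RMS): a log-ratio necromass/biomass index.

RMS = log( weighted atom% 13C excess of the amino-sugar pool
         / weighted atom% 13C excess of the PLFA pool )

Amino sugars persist in soil after microbial death (necromass); PLFAs turn
over within days of cell lysis (living biomass).  RMS > 0 therefore means
rhizodeposit carbon predominantly entered the necromass pathway, the
precursor of stabilized soil organic matter; RMS < 0 means it sits in the
short-lived living-biomass pool.  The index is comparative between depths
and species only — it says nothing about absolute stability.

Log base defaults to 10 and is carried in every output so values computed
under different bases are never compared silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .biomarkers import PoolSummary
from .rhizodeposition import DepthInterval

__all__ = ["RMSValue", "rms", "rms_profile", "REPORTED_MAX_DEPTH_CM"]

#: Depths at or below this bottom are within the study's reported RMS range.
REPORTED_MAX_DEPTH_CM = 100.0


@dataclass(frozen=True)
class RMSValue:
    """RMS for one sample; ``defined`` is False when either pool APE is <= 0."""

    sample_id: str
    value: float | None
    interpretation: str  # necromass_dominated / biomass_dominated / balanced / undefined
    log_base: float = 10.0
    defined: bool = True
    reason: str | None = None
    depth: DepthInterval | None = None
    in_reported_range: bool = True


def _interpret(value: float) -> str:
    if value > 0:
        return "necromass_dominated"
    if value < 0:
        return "biomass_dominated"
    return "balanced"


def rms(as_pool: PoolSummary, plfa_pool: PoolSummary, *, log_base: float = 10.0) -> RMSValue:
    """RMS from one sample's amino-sugar and PLFA pool summaries.

    Non-positive weighted APE in either pool (below background or zero
    incorporation) yields an explicitly undefined RMS with a reason, never a
    silent NaN.
    """
    if as_pool.biomarker_class != "AS" or plfa_pool.biomarker_class != "PLFA":
        raise ValueError(
            f"expected (AS, PLFA) pools, got ({as_pool.biomarker_class}, {plfa_pool.biomarker_class})"
        )
    if as_pool.sample_id != plfa_pool.sample_id:
        raise ValueError(
            f"pools from different samples: {as_pool.sample_id!r} vs {plfa_pool.sample_id!r}"
        )
    for pool, name in ((as_pool, "AS"), (plfa_pool, "PLFA")):
        if not pool.weighted_ape > 0:
            reason = (
                f"{name} pool weighted APE not positive "
                f"({pool.weighted_ape:.4g}: "
                f"{'below background' if pool.weighted_ape < 0 else 'zero incorporation'})"
            )
            return RMSValue(
                sample_id=as_pool.sample_id,
                value=None,
                interpretation="undefined",
                log_base=log_base,
                defined=False,
                reason=reason,
            )
    value = math.log(as_pool.weighted_ape / plfa_pool.weighted_ape, log_base)
    return RMSValue(
        sample_id=as_pool.sample_id,
        value=value,
        interpretation=_interpret(value),
        log_base=log_base,
    )


_KEYS = ["plot_id", "species", "n_rate", "depth_top_cm", "depth_bottom_cm"]


def rms_profile(pools: pd.DataFrame, *, log_base: float = 10.0) -> pd.DataFrame:
    """RMS per plot x species x depth from a pool-summary table.

    ``pools`` is the output of :func:`rhizotrace.biomarkers.process_biomarkers`
    (one row per sample x class).  Groups lacking an AS or PLFA pool, or with
    a non-positive pool APE, are carried with ``defined = False`` markers;
    rows are ordered by group keys then depth top.  Depths whose bottom
    exceeds 100 cm are tagged as outside the study's reported range.
    """
    keys = [k for k in _KEYS if k in pools.columns]
    rows = []
    for key, grp in pools.groupby(keys, sort=True):
        info = dict(zip(keys, key))
        sample_id = "_".join(str(v) for v in key)
        by_class = {c: g for c, g in grp.groupby("biomarker_class")}
        value = None
        reason = None
        if "AS" not in by_class or "PLFA" not in by_class:
            missing = sorted({"AS", "PLFA"} - set(by_class))
            reason = f"missing pool(s): {missing}"
        else:

            def to_summary(g: pd.DataFrame, cls: str) -> PoolSummary:
                r = g.iloc[0]
                return PoolSummary(
                    sample_id=sample_id,
                    biomarker_class=cls,
                    total_concentration=r["total_concentration_ug_per_g"],
                    total_c=r["total_c_ug_per_g"],
                    total_13c_excess=r["total_13c_excess_ug_per_g"],
                    weighted_ape=r["weighted_ape"],
                )

            rv = rms(to_summary(by_class["AS"], "AS"), to_summary(by_class["PLFA"], "PLFA"), log_base=log_base)
            value, reason = rv.value, rv.reason
        interpretation = "undefined" if value is None else _interpret(value)
        bottom = info.get("depth_bottom_cm")
        rows.append(
            {
                **info,
                "rms": value,
                "log_base": log_base,
                "interpretation": interpretation,
                "defined_flag": value is not None,
                "reason": reason,
                "in_reported_range": bool(bottom is None or bottom <= REPORTED_MAX_DEPTH_CM),
            }
        )
    out = pd.DataFrame(rows)
    sort_cols = [k for k in ("plot_id", "species", "n_rate", "depth_top_cm") if k in out.columns]
    return out.sort_values(sort_cols).reset_index(drop=True) if len(out) else out
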