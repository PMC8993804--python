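"""Treatment-comparison statistics for pipeline outputs.

The workflow mirrors standard agronomic practice: check homogeneity of
variance (Fligner-Killeen) and normality (Shapiro-Wilk), log-transform when
either fails and the data allow it, run a fixed-effects ANOVA with treatment
and depth factors on plot means (the plot replicate, n = 3, is the
experimental unit), and follow up with Tukey HSD pairwise comparisons and a
compact letter display at alpha = 0.05.

The kernza fertilizer subplots (100 vs 200 kg N ha-1) are merged — averaged
within field plot and relabeled plain "kernza" — only when no requested
variable differs between the two rates at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AssumptionReport",
    "ComparisonResult",
    "check_assumptions",
    "anova_tukey",
    "compact_letter_display",
    "MergeReport",
    "merge_rule",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class AssumptionReport:
    fligner_p: float
    shapiro_p: float
    transform: str  # "none" or "log"

    @property
    def ok_without_transform(self) -> bool:
        return self.transform == "none"


def check_assumptions(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    *,
    alpha: float = ALPHA_DEFAULT,
) -> AssumptionReport:
    """Fligner-Killeen + Shapiro-Wilk; decide whether to log-transform.

    The log transform is triggered when either test rejects at ``alpha``; it
    requires strictly positive data and otherwise raises (offset handling is
    left to the caller).  Shapiro-Wilk runs on within-group residuals.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by_group = [values[groups == g] for g in pd.unique(groups)]
    if len(by_group) < 2 or any(len(g) < 2 for g in by_group):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    fligner_p = float(sps.fligner(*by_group).pvalue)
    resid = np.concatenate([g - g.mean() for g in by_group])
    shapiro_p = float(sps.shapiro(resid).pvalue)
    transform = "none"
    if fligner_p < alpha or shapiro_p < alpha:
        if np.any(values <= 0):
            raise ValueError(
                "log transform required (assumption test rejected) but data contain "
                "non-positive values; apply an offset or transform manually"
            )
        transform = "log"
    return AssumptionReport(fligner_p=fligner_p, shapiro_p=shapiro_p, transform=transform)


@dataclass
class ComparisonResult:
    variable: str
    factors: list[str]
    anova_table: pd.DataFrame  # per-factor F and p
    tukey: pd.DataFrame | None  # pairwise comparisons on the requested factor
    letters: dict[str, str] | None
    transform_applied: str
    assumptions: AssumptionReport | None
    alpha: float = ALPHA_DEFAULT

    @property
    def f_statistics(self) -> dict[str, float]:
        return dict(self.anova_table["F"].dropna())

    @property
    def p_values(self) -> dict[str, float]:
        return dict(self.anova_table["PR(>F)"].dropna())

    def summary(self) -> str:
        lines = [f"ANOVA for {self.variable} (transform: {self.transform_applied})"]
        lines.append(self.anova_table.to_string())
        if self.tukey is not None:
            lines.append("\nTukey HSD:")
            lines.append(self.tukey.to_string(index=False))
        if self.letters:
            lines.append("\nGroups sharing a letter do not differ at alpha={:.2f}:".format(self.alpha))
            for g, s in self.letters.items():
                lines.append(f"  {g}: {s}")
        return "\n".join(lines)


def compact_letter_display(
    groups: list[str], significant_pairs: set[tuple[str, str]], group_order: list[str] | None = None
) -> dict[str, str]:
    """Assign significance letters: groups sharing a letter are not separated.

    Standard insert-and-absorb algorithm over the significant-pair matrix;
    ties broken by the supplied group order (typically descending mean).
    """
    order = group_order if group_order is not None else sorted(groups)
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = []
    seen: list[str] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in sig for other in s):
                s.add(g)
                placed = True
        if not placed:
            # start a new set seeded with every earlier group compatible with g
            new = {g} | {h for h in seen if frozenset((g, h)) not in sig}
            letter_sets.append(new)
        seen.append(g)
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets) if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {g: [] for g in order}
    for letter, s in zip(alphabet, letter_sets):
        for g in order:
            if g in s:
                out[g].append(letter)
    return {g: "".join(v) for g, v in out.items()}


def anova_tukey(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    *,
    tukey_factor: str | None = None,
    alpha: float = ALPHA_DEFAULT,
    auto_transform: bool = True,
    include_tukey: bool = True,
) -> ComparisonResult:
    """Fixed-effects ANOVA with optional log transform and Tukey HSD follow-up.

    ``factors`` are treated as categorical.  Assumptions are checked against
    the crossed factor-combination groups; when ``auto_transform`` and a
    check rejects, the response is log-transformed (requires positive data).
    Tukey HSD runs on ``tukey_factor`` (default: the first factor).
    """
    df = data[[response] + factors].dropna().copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level; nothing to compare")
    combo = df[factors].astype(str).agg("|".join, axis=1)
    # assumption checks need replication within groups; skip gracefully without
    assumptions = None
    transform = "none"
    counts = combo.value_counts()
    if auto_transform and len(counts) >= 2 and counts.min() >= 2:
        assumptions = check_assumptions(df[response], combo, alpha=alpha)
        transform = assumptions.transform
    y = df[response]
    if transform == "log":
        y = np.log(y)
    df["_y"] = y
    formula = "_y ~ " + " + ".join(f"C(Q('{f}'))" for f in factors)
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index=lambda s: _clean_term(s, factors))

    tukey_factor = tukey_factor or factors[0]
    tukey_df = None
    letters = None
    if include_tukey and df[tukey_factor].nunique() >= 2:
        res = pairwise_tukeyhsd(df["_y"], df[tukey_factor].astype(str), alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tukey_df["p-adj"] = np.asarray(res.pvalues, float)
        # unadjusted pairwise p from the same pooled-variance t statistic
        glabels = df[tukey_factor].astype(str)
        gstats = df.groupby(glabels)["_y"].agg(["mean", "count"])
        mse = float(res.variance)
        df_resid = len(df) - len(gstats)
        p_raw = []
        for a, b in zip(tukey_df["group1"], tukey_df["group2"]):
            na, nb = gstats.loc[str(a), "count"], gstats.loc[str(b), "count"]
            diff = gstats.loc[str(b), "mean"] - gstats.loc[str(a), "mean"]
            se = np.sqrt(mse * (1 / na + 1 / nb))
            t = diff / se if se > 0 else 0.0
            p_raw.append(2 * sps.t.sf(abs(t), df_resid))
        tukey_df["p-raw"] = p_raw
        sig_pairs = {
            (str(a), str(b))
            for a, b, rej in zip(tukey_df["group1"], tukey_df["group2"], res.reject)
            if rej
        }
        means = df.groupby(tukey_factor)["_y"].mean().sort_values(ascending=False)
        letters = compact_letter_display(
            list(means.index.astype(str)), sig_pairs, list(means.index.astype(str))
        )
    return ComparisonResult(
        variable=response,
        factors=list(factors),
        anova_table=table,
        tukey=tukey_df,
        letters=letters,
        transform_applied=transform,
        assumptions=assumptions,
        alpha=alpha,
    )


def _clean_term(term: str, factors: list[str]) -> str:
    for f in factors:
        if f"Q('{f}')" in term:
            return f
    return term


@dataclass(frozen=True)
class MergeReport:
    merged: bool
    p_values: dict[str, float] = field(default_factory=dict)
    note: str = ""

    def summary(self) -> str:
        lines = [f"K100/K200 merge decision: {'merged' if self.merged else 'kept separate'}"]
        for var, p in self.p_values.items():
            lines.append(f"  {var}: p = {p:.4g}")
        if self.note:
            lines.append(f"  note: {self.note}")
        return "\n".join(lines)


_PAIR_KEYS = ["plot_id", "depth_top_cm", "depth_bottom_cm"]


def merge_rule(
    data: pd.DataFrame,
    variables: list[str],
    *,
    alpha: float = ALPHA_DEFAULT,
    species_col: str = "species",
    rate_col: str = "n_rate",
) -> tuple[pd.DataFrame, MergeReport]:
    """Merge the kernza 100/200 kg N subplots when no variable separates them.

    Subplots are paired within field plot x depth; each variable is tested
    with a paired t-test across those pairs.  If every requested variable has
    p >= alpha, subplot values are averaged within plot and the treatment
    label becomes plain "kernza"; otherwise the table is returned unchanged.
    A ``treatment`` column is always added.  Idempotent: a table without both
    rates present is returned as-is.
    """
    df = data.copy()
    kern = df[df[species_col] == "kernza"]
    rates = sorted(kern[rate_col].dropna().unique())
    if len(rates) < 2:
        df["treatment"] = np.where(
            df[species_col] == "kernza", "kernza", df[species_col]
        )
        return df, MergeReport(merged=True, note="single kernza rate present; nothing to merge")
    if len(rates) > 2:
        raise ValueError(f"expected two kernza N rates, found {rates}")
    lo = kern[kern[rate_col] == rates[0]].set_index(_PAIR_KEYS)
    hi = kern[kern[rate_col] == rates[1]].set_index(_PAIR_KEYS)
    if not lo.index.sort_values().equals(hi.index.sort_values()):
        only_lo = set(lo.index) - set(hi.index)
        only_hi = set(hi.index) - set(lo.index)
        raise ValueError(f"unpaired kernza subplots: only-{rates[0]}={sorted(only_lo)}, only-{rates[1]}={sorted(only_hi)}")
    hi = hi.reindex(lo.index)
    p_values = {}
    for var in variables:
        a, b = lo[var].to_numpy(float), hi[var].to_numpy(float)
        if np.allclose(a, b):
            p_values[var] = 1.0
        else:
            p_values[var] = float(sps.ttest_rel(a, b).pvalue)
    merged = all(p >= alpha for p in p_values.values())
    if not merged:
        df["treatment"] = np.where(
            df[species_col] == "kernza",
            "kernza-" + df[rate_col].astype("Int64").astype(str),
            df[species_col],
        )
        return df, MergeReport(merged=False, p_values=p_values)
    other = df[df[species_col] != "kernza"].copy()
    group_cols = [c for c in _PAIR_KEYS + [species_col] if c in kern.columns]
    num_cols = [c for c in kern.columns if c not in group_cols + [rate_col] and pd.api.types.is_numeric_dtype(kern[c])]
    merged_kern = kern.groupby(group_cols, as_index=False)[num_cols].mean()
    merged_kern[rate_col] = pd.NA
    out = pd.concat([other, merged_kern], ignore_index=True)
    out["treatment"] = np.where(out[species_col] == "kernza", "kernza", out[species_col])
    sort_cols = [c for c in ["species", "plot_id", "depth_top_cm"] if c in out.columns]
    out = out.sort_values(sort_cols).reset_index(drop=True)
    return out, MergeReport(merged=True, p_values=p_values)
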