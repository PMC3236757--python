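"""Cohort-level inference on network metrics.

Per-cost two-way (group x condition) ANOVA on the global metrics, post-hoc
t-tests, per-participant Z-scored nodal maps with three-tier per-node
significance flags, and Pearson correlations between the economical
small-world metrics and duration of disease in patients.

Two ANOVA modes are provided.  The default ``"crossed"`` mode treats the 60
observations (15 + 15 subjects x 2 conditions) as a fully-crossed two-way
layout, giving error df = 56 for each effect — the degrees of freedom under
which the study-scale F statistics are reported.  The ``"mixed"`` mode is
the conventional mixed design (condition within-subject, group between),
giving error df = 28 at study scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "AnovaResult",
    "SignificanceTier",
    "significance_tiers",
    "anova_2x2",
    "posthoc_ttests",
    "zscore_map",
    "nodal_tests",
    "duration_correlation",
]

EFFECTS = ("group", "condition", "interaction")


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    metric: str = ""
    band: str = ""
    cost: float = np.nan

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if np.isfinite(self.F) and self.F < 0:
            raise ValueError("F statistic must be nonnegative")
        if not (0 <= self.p <= 1):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class SignificanceTier:
    tier: str  # uncorrected | fpc | fdr_label
    threshold: float


def significance_tiers(n_nodes: int) -> tuple[SignificanceTier, ...]:
    """The three per-node reporting thresholds: 0.05, 1/N and 0.05/N.

    For N = 58 these evaluate to 0.05, 0.017 and 0.00086 (to printed
    precision).  The strictest tier is arithmetically a Bonferroni
    threshold; it is labeled ``fdr_label`` to match the reporting
    convention without asserting a step-up FDR procedure.
    """
    return (
        SignificanceTier("uncorrected", 0.05),
        SignificanceTier("fpc", 1.0 / n_nodes),
        SignificanceTier("fdr_label", 0.05 / n_nodes),
    )


def _check_design(df: pd.DataFrame) -> None:
    groups = set(df["group"])
    conds = set(df["condition"])
    if len(groups) != 2 or len(conds) != 2:
        raise ValueError(f"need two groups x two conditions, got {groups} x {conds}")
    counts = df.groupby(["group", "condition"], observed=True).size()
    if len(counts) != 4 or (counts < 1).any():
        raise ValueError("insufficient data: every group x condition cell must be non-empty")


def _crossed_anova(df: pd.DataFrame) -> dict[str, tuple[float, tuple[int, int], float]]:
    """Balanced fully-crossed two-way ANOVA by direct sums of squares.

    Direct computation keeps the all-values-equal degenerate case well
    defined (F = 0, p = 1) where a regression fit would return NaN.
    """
    y = df["value"].to_numpy(dtype=float)
    g = df["group"].to_numpy()
    c = df["condition"].to_numpy()
    n = y.size
    grand = y.mean()
    glevels = np.unique(g)
    clevels = np.unique(c)
    df_err_all = n - 4
    if df_err_all <= 0:
        raise ValueError("insufficient data: no error degrees of freedom")
    if np.ptp(y) == 0 or float(((y - grand) ** 2).sum()) <= 1e-18 * n * max(grand**2, 1.0):
        # all observations (numerically) identical: nothing to test
        return {e: (0.0, (1, df_err_all), 1.0) for e in EFFECTS}

    ss_total = float(((y - grand) ** 2).sum())
    fitted = np.empty_like(y)
    ss_g = sum(
        (g == gl).sum() * (y[g == gl].mean() - grand) ** 2 for gl in glevels
    )
    ss_c = sum(
        (c == cl).sum() * (y[c == cl].mean() - grand) ** 2 for cl in clevels
    )
    ss_cells = 0.0
    for gl in glevels:
        for cl in clevels:
            mask = (g == gl) & (c == cl)
            cell_mean = y[mask].mean()
            fitted[mask] = cell_mean
            ss_cells += mask.sum() * (cell_mean - grand) ** 2
    ss_int = ss_cells - ss_g - ss_c
    ss_err = float(((y - fitted) ** 2).sum())
    df_err = n - 4

    out = {}
    for effect, ss in (("group", ss_g), ("condition", ss_c), ("interaction", ss_int)):
        ss = max(float(ss), 0.0)
        if df_err <= 0:
            raise ValueError("insufficient data: no error degrees of freedom")
        mse = ss_err / df_err
        if mse == 0:
            f_stat, p = (0.0, 1.0) if ss <= 1e-12 * max(ss_total, 1.0) else (np.inf, 0.0)
        else:
            f_stat = ss / 1.0 / mse
            p = float(scipy.stats.f.sf(f_stat, 1, df_err))
        out[effect] = (float(f_stat), (1, df_err), p)
    return out


def _mixed_anova(df: pd.DataFrame) -> dict[str, tuple[float, tuple[int, int], float]]:
    """Balanced 2 x 2 mixed ANOVA: group between-subject, condition within."""
    if "subject" not in df.columns:
        raise ValueError("mixed mode requires a 'subject' column")
    wide = df.pivot_table(index=["subject", "group"], columns="condition", values="value")
    if wide.isna().any().any():
        raise ValueError("mixed mode requires both conditions for every subject")
    conds = list(wide.columns)
    y = wide.to_numpy()  # subjects x 2 conditions
    groups = wide.index.get_level_values("group").to_numpy()
    glevels = np.unique(groups)
    n_subj = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    ss_between_subj = 2.0 * float(((subj_means - grand) ** 2).sum())
    ss_group = 2.0 * sum(
        (groups == gl).sum() * (subj_means[groups == gl].mean() - grand) ** 2
        for gl in glevels
    )
    ss_subj_within = ss_between_subj - ss_group
    df_subj_within = n_subj - 2

    cond_means = y.mean(axis=0)
    ss_cond = n_subj * float(((cond_means - grand) ** 2).sum())
    ss_cells = 0.0
    for gi, gl in enumerate(glevels):
        for ci in range(len(conds)):
            cell = y[groups == gl, ci]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
    ss_int = ss_cells - ss_group - ss_cond
    ss_total = float(((y - grand) ** 2).sum())
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_int
    df_err_within = n_subj - 2

    def f_and_p(ss_eff: float, ss_err: float, df_err: int):
        ss_eff = max(float(ss_eff), 0.0)
        if df_err <= 0:
            raise ValueError("insufficient data: no error degrees of freedom")
        mse = ss_err / df_err
        if mse <= 0:
            return (0.0, 1.0) if ss_eff <= 1e-12 * max(ss_total, 1.0) else (np.inf, 0.0)
        f_stat = ss_eff / mse
        return float(f_stat), float(scipy.stats.f.sf(f_stat, 1, df_err))

    fg, pg = f_and_p(ss_group, ss_subj_within, df_subj_within)
    fc, pc = f_and_p(ss_cond, ss_err_within, df_err_within)
    fi, pi = f_and_p(ss_int, ss_err_within, df_err_within)
    return {
        "group": (fg, (1, df_subj_within), pg),
        "condition": (fc, (1, df_err_within), pc),
        "interaction": (fi, (1, df_err_within), pi),
    }


def anova_2x2(
    table: pd.DataFrame,
    metric: str | None = None,
    band: str | None = None,
    cost: float | None = None,
    mode: str = "crossed",
) -> list[AnovaResult]:
    """Two-way group x condition ANOVA on one metric at one cost.

    ``table`` holds tidy rows with at least ``group``, ``condition`` and
    ``value`` columns (plus ``subject`` for the mixed mode); ``metric``,
    ``band`` and ``cost`` filter the table when the corresponding columns
    are present.  Returns one :class:`AnovaResult` per effect.
    """
    df = table
    for col, val in (("metric", metric), ("band", band)):
        if val is not None and col in df.columns:
            df = df[df[col] == val]
    if cost is not None and "cost" in df.columns:
        df = df[np.isclose(df["cost"].to_numpy(dtype=float), cost)]
    if df.empty:
        raise ValueError("no rows match the requested metric/band/cost")
    _check_design(df)
    if mode == "crossed":
        res = _crossed_anova(df)
    elif mode == "mixed":
        res = _mixed_anova(df)
    else:
        raise ValueError(f"unknown ANOVA mode {mode!r}")
    return [
        AnovaResult(
            effect=e, F=f, df=d, p=p,
            metric=metric or "", band=band or "", cost=np.nan if cost is None else cost,
        )
        for e, (f, d, p) in res.items()
    ]


def posthoc_ttests(
    table: pd.DataFrame,
    metric: str | None = None,
    band: str | None = None,
    cost: float | None = None,
) -> pd.DataFrame:
    """Post-hoc contrasts after the 2 x 2 ANOVA.

    Paired t-test rest vs task within each group and two-sample t-test
    between groups within each condition.  Degenerate cases (zero variance)
    are flagged rather than raised: a zero mean difference gives p = 1, a
    nonzero mean difference with zero variance gives p = 0.
    """
    df = table
    for col, val in (("metric", metric), ("band", band)):
        if val is not None and col in df.columns:
            df = df[df[col] == val]
    if cost is not None and "cost" in df.columns:
        df = df[np.isclose(df["cost"].to_numpy(dtype=float), cost)]
    _check_design(df)
    rows = []

    for group in sorted(set(df["group"])):
        sub = df[df["group"] == group]
        wide = sub.pivot_table(index="subject", columns="condition", values="value")
        if wide.shape[0] < 2 or wide.isna().any().any():
            raise ValueError(f"insufficient paired data for group {group!r}")
        conds = sorted(wide.columns)
        a, b = wide[conds[0]].to_numpy(), wide[conds[1]].to_numpy()
        diff = a - b
        scale = max(np.abs(diff).max(), np.abs(a).max(), 1e-300)
        degenerate = np.std(diff) <= 1e-9 * scale
        if degenerate:
            t, p = (0.0, 1.0) if abs(diff.mean()) <= 1e-9 * scale else (np.inf, 0.0)
        else:
            t, p = scipy.stats.ttest_rel(a, b)
        rows.append(
            {
                "contrast": f"{conds[0]} vs {conds[1]}",
                "within": group,
                "kind": "paired",
                "t": float(t),
                "p": float(p),
                "n": int(wide.shape[0]),
                "degenerate": bool(degenerate),
            }
        )

    for cond in sorted(set(df["condition"])):
        sub = df[df["condition"] == cond]
        groups = sorted(set(sub["group"]))
        a = sub[sub["group"] == groups[0]]["value"].to_numpy(dtype=float)
        b = sub[sub["group"] == groups[1]]["value"].to_numpy(dtype=float)
        if min(a.size, b.size) < 2:
            raise ValueError(f"insufficient data for group contrast in condition {cond!r}")
        scale = max(np.abs(a).max(), np.abs(b).max(), 1e-300)
        degenerate = max(np.std(a), np.std(b)) <= 1e-9 * scale
        if degenerate:
            t, p = (0.0, 1.0) if abs(a.mean() - b.mean()) <= 1e-9 * scale else (np.inf, 0.0)
        else:
            t, p = scipy.stats.ttest_ind(a, b)
        rows.append(
            {
                "contrast": f"{groups[0]} vs {groups[1]}",
                "within": cond,
                "kind": "two-sample",
                "t": float(t),
                "p": float(p),
                "n": int(a.size + b.size),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def zscore_map(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score a per-node map across nodes (population SD by default).

    Standardization rescales each participant's map to mean 0 and unit
    variance across nodes without changing its topography (node ranking).
    A zero-variance map is degenerate and maps to all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("nodal map must be a 1-D vector of >= 2 values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("zero-variance nodal map: Z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def nodal_tests(
    maps: pd.DataFrame,
    node_labels: list[str] | None = None,
    mode: str = "crossed",
    prestandardized: bool = False,
) -> pd.DataFrame:
    """Per-node 2 x 2 ANOVA of Z-scored nodal maps with tier flags.

    ``maps`` is tidy: one row per (subject, condition, node) with columns
    ``subject``, ``group``, ``condition``, ``node``, ``value``.  Each
    participant map (subject x condition) is Z-scored across nodes first
    (unless ``prestandardized``), then every node gets the group x
    condition ANOVA and each effect is flagged at the three thresholds
    0.05, 1/N and 0.05/N.
    """
    required = {"subject", "group", "condition", "node", "value"}
    if not required.issubset(maps.columns):
        raise ValueError(f"maps must have columns {sorted(required)}")
    nodes = list(node_labels) if node_labels is not None else sorted(set(maps["node"]))
    if set(maps["node"]) != set(nodes):
        raise ValueError("node labels of the maps do not match the requested labels")

    df = maps.copy()
    if not prestandardized:
        pieces = []
        for _, sub in df.groupby(["subject", "condition"], observed=True):
            sub = sub.copy()
            sub["value"] = zscore_map(sub["value"].to_numpy(dtype=float))
            pieces.append(sub)
        df = pd.concat(pieces, ignore_index=True)

    tiers = significance_tiers(len(nodes))
    rows = []
    for node in nodes:
        node_df = df[df["node"] == node]
        cells = {}
        for (gname, cname), sub in node_df.groupby(["group", "condition"], observed=True):
            vals = sub["value"]
            cells[f"mean_{gname}_{cname}"] = float(vals.mean())
            cells[f"sem_{gname}_{cname}"] = (
                float(vals.sem(ddof=1)) if len(vals) > 1 else np.nan
            )
        for res in anova_2x2(node_df, mode=mode):
            row = {
                "node": node,
                "effect": res.effect,
                "F": res.F,
                "p": res.p,
                "df_num": res.df[0],
                "df_den": res.df[1],
                **cells,
            }
            for tier in tiers:
                row[tier.tier] = bool(res.p < tier.threshold)
            rows.append(row)
    return pd.DataFrame(rows)


def duration_correlation(
    table: pd.DataFrame,
    durations: pd.Series | dict,
    metric: str | None = None,
    band: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation between a patient metric and duration, per cost.

    ``table`` is restricted to patients; ``durations`` maps subject id to
    duration of disease in years.  Returns one row per (condition, cost)
    with R, the two-sided p-value and n; a constant metric leaves R
    undefined (NaN) with a ``degenerate`` flag.
    """
    df = table
    for col, val in (("metric", metric), ("band", band)):
        if val is not None and col in df.columns:
            df = df[df[col] == val]
    if df.empty:
        raise ValueError("no rows to correlate")
    dur = pd.Series(durations, dtype=float)
    rows = []
    if "cost" in df.columns:
        costs = df["cost"].to_numpy(dtype=float)
        cost_values = sorted(set(costs[~np.isnan(costs)]))
        if np.isnan(costs).any():
            cost_values.append(float("nan"))  # cost-free scalar metrics (maxCE)
    else:
        cost_values = [np.nan]
    for cond in sorted(set(df["condition"])):
        for cost in cost_values:
            sub = df[df["condition"] == cond]
            if "cost" in df.columns:
                cvals = sub["cost"].to_numpy(dtype=float)
                mask = np.isnan(cvals) if np.isnan(cost) else np.isclose(cvals, cost)
                sub = sub[mask]
            sub = sub.set_index("subject")["value"]
            common = [s for s in sub.index if s in dur.index]
            if len(common) < 3:
                raise ValueError("need at least 3 patients with durations")
            x = dur.loc[common].to_numpy()
            y = sub.loc[common].to_numpy(dtype=float)
            degenerate = np.ptp(y) == 0 or np.ptp(x) == 0
            if degenerate:
                warnings.warn("constant metric or duration: correlation undefined")
                r, p = np.nan, np.nan
            else:
                r, p = scipy.stats.pearsonr(x, y)
            rows.append(
                {
                    "condition": cond,
                    "cost": cost,
                    "R": float(r),
                    "p": float(p),
                    "n": len(common),
                    "degenerate": bool(degenerate),
                }
            )
    return pd.DataFrame(rows)
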