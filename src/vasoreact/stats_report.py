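"""Group-comparison harness for per-vessel (or per-cell) summaries.

Test selection mirrors standard physiology practice: Shapiro-Wilk
normality per group and a variance check (Brown-Forsythe between groups,
F-test against a named control) gate the use of parametric tests; the
omnibus comparison is a one-way ANOVA or Kruskal-Wallis, followed by
all-pairs (Tukey) or many-to-one (vs control) post hoc comparisons with
Benjamini-Hochberg false-discovery-rate correction across the declared
family. Two-group designs use paired/unpaired t or their nonparametric
counterparts. Results are reported as mean ± SEM with exact degrees of
freedom and tiered significance markers (* p<0.05, ** p<0.01,
*** p<0.001).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupTable", "TestPlan", "choose_test", "run_plan", "report", "stars", "bh_adjust"]

ALPHA = 0.05


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over one family."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupTable:
    """Observations of one metric across labelled groups.

    ``data`` columns: ``value``, ``group`` and optionally ``pair_id`` for
    paired designs (pair ids must match one-to-one across both groups).
    """

    data: pd.DataFrame
    metric: str = "value"
    units: str = ""

    def __post_init__(self):
        required = {"value", "group"}
        if not required <= set(self.data.columns):
            raise ValueError("GroupTable needs 'value' and 'group' columns")
        self.data = self.data.reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def values_of(self, group: str) -> np.ndarray:
        return self.data.loc[self.data["group"] == group, "value"].to_numpy(dtype=float)

    @property
    def paired(self) -> bool:
        return "pair_id" in self.data.columns

    def summaries(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            v = self.values_of(g)
            rows.append(
                {
                    "group": g,
                    "n": v.size,
                    "mean": v.mean(),
                    "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class TestPlan:
    omnibus: str  # paired_t | t | wilcoxon | mannwhitney | anova | kruskal
    posthoc: str | None  # tukey | vs_control | pairwise | None
    control: str | None
    parametric: bool
    normality: dict = field(default_factory=dict)  # group -> (W, p) or None
    variance: dict = field(default_factory=dict)


def _normality(table: GroupTable) -> tuple[dict, bool]:
    results: dict = {}
    all_normal = True
    for g in table.groups:
        v = table.values_of(g)
        if v.size < 3:
            warnings.warn(
                f"group '{g}' has n={v.size} < 3: normality untestable, "
                "falling back to nonparametric tests",
                stacklevel=3,
            )
            results[g] = None
            all_normal = False
            continue
        if np.ptp(v) == 0:
            results[g] = None
            all_normal = False
            continue
        w, p = stats.shapiro(v)
        results[g] = (float(w), float(p))
        if p < ALPHA:
            all_normal = False
    return results, all_normal


def _variance_check(table: GroupTable, control: str | None) -> tuple[dict, bool]:
    groups = [table.values_of(g) for g in table.groups]
    if control is not None:
        # F-test of variance ratio for each group against the control
        ctrl = table.values_of(control)
        out = {}
        equal = True
        for g in table.groups:
            if g == control:
                continue
            v = table.values_of(g)
            f = v.var(ddof=1) / ctrl.var(ddof=1)
            dfn, dfd = v.size - 1, ctrl.size - 1
            p = 2 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
            out[g] = {"test": "F", "stat": float(f), "df": (dfn, dfd), "p": float(p)}
            if p < ALPHA:
                equal = False
        return out, equal
    stat, p = stats.levene(*groups, center="median")  # Brown-Forsythe
    return {"all": {"test": "Brown-Forsythe", "stat": float(stat), "p": float(p)}}, p >= ALPHA


def choose_test(
    table: GroupTable, control: str | None = None, paired: bool | None = None
) -> TestPlan:
    """Build the test plan: normality and variance gates, then the test.

    ``control`` names the reference group for many-to-one post hoc
    comparisons (pharmacology vs the untreated condition); without it,
    multi-group designs use all-pairs comparisons.
    """
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if paired is None:
        paired = table.paired and len(groups) == 2
    normality, all_normal = _normality(table)
    variance, var_ok = _variance_check(table, control if len(groups) > 2 else None)
    parametric = bool(all_normal and var_ok)
    if len(groups) == 2:
        if paired:
            omnibus = "paired_t" if parametric else "wilcoxon"
        else:
            omnibus = "t" if parametric else "mannwhitney"
        posthoc = None
    else:
        omnibus = "anova" if parametric else "kruskal"
        posthoc = "vs_control" if control is not None else "tukey" if parametric else "pairwise"
    return TestPlan(omnibus, posthoc, control, parametric, normality, variance)


def _pair_values(table: GroupTable) -> tuple[np.ndarray, np.ndarray]:
    a, b = table.groups
    da = table.data[table.data["group"] == a].set_index("pair_id")["value"]
    db = table.data[table.data["group"] == b].set_index("pair_id")["value"]
    common = da.index.intersection(db.index)
    if len(common) != len(da) or len(common) != len(db):
        raise ValueError("pair ids do not match one-to-one across groups")
    return da.loc[common].to_numpy(float), db.loc[common].to_numpy(float)


def _check_degenerate(table: GroupTable) -> None:
    for g in table.groups:
        v = table.values_of(g)
        if v.size >= 2 and np.ptp(v) == 0:
            raise ValueError(
                f"group '{g}' has zero variance: test statistic undefined"
            )


def run_plan(table: GroupTable, plan: TestPlan) -> dict:
    """Execute the plan; returns a JSON-serializable results dict."""
    res: dict = {
        "metric": table.metric,
        "units": table.units,
        "plan": asdict(plan),
        "summaries": table.summaries().to_dict(orient="records"),
    }
    g = table.groups
    if plan.omnibus == "paired_t":
        x, y = _pair_values(table)
        d = x - y
        if np.ptp(d) == 0 and d.size:
            # identical pairs: difference has zero variance, no evidence
            stat, p, df = 0.0, 1.0, d.size - 1
        else:
            t_res = stats.ttest_rel(x, y)
            stat, p, df = float(t_res.statistic), float(t_res.pvalue), d.size - 1
        res["omnibus"] = {"test": "paired t", "stat": stat, "df": df, "p": p}
    elif plan.omnibus == "wilcoxon":
        x, y = _pair_values(table)
        if np.ptp(x - y) == 0:
            res["omnibus"] = {"test": "Wilcoxon", "stat": 0.0, "df": None, "p": 1.0}
        else:
            w = stats.wilcoxon(x, y)
            res["omnibus"] = {"test": "Wilcoxon", "stat": float(w.statistic), "df": None, "p": float(w.pvalue)}
    elif plan.omnibus == "t":
        _check_degenerate(table)
        x, y = table.values_of(g[0]), table.values_of(g[1])
        t_res = stats.ttest_ind(x, y)
        res["omnibus"] = {
            "test": "unpaired t",
            "stat": float(t_res.statistic),
            "df": x.size + y.size - 2,
            "p": float(t_res.pvalue),
        }
    elif plan.omnibus == "mannwhitney":
        x, y = table.values_of(g[0]), table.values_of(g[1])
        u = stats.mannwhitneyu(x, y, alternative="two-sided")
        # report the smaller of U and its complement, the tabled convention
        u_small = min(float(u.statistic), x.size * y.size - float(u.statistic))
        res["omnibus"] = {"test": "Mann-Whitney", "stat": u_small, "df": (x.size, y.size), "p": float(u.pvalue)}
    elif plan.omnibus == "anova":
        _check_degenerate(table)
        vals = [table.values_of(x) for x in g]
        f_res = stats.f_oneway(*vals)
        df1 = len(g) - 1
        df2 = sum(v.size for v in vals) - len(g)
        res["omnibus"] = {"test": "one-way ANOVA", "stat": float(f_res.statistic), "df": (df1, df2), "p": float(f_res.pvalue)}
    elif plan.omnibus == "kruskal":
        vals = [table.values_of(x) for x in g]
        k = stats.kruskal(*vals)
        res["omnibus"] = {"test": "Kruskal-Wallis", "stat": float(k.statistic), "df": len(g) - 1, "p": float(k.pvalue)}
    else:
        raise ValueError(f"unknown omnibus test {plan.omnibus!r}")
    res["omnibus"]["significance"] = stars(res["omnibus"]["p"])

    if plan.posthoc:
        res["posthoc"] = _posthoc(table, plan)
    return res


def _posthoc(table: GroupTable, plan: TestPlan) -> list[dict]:
    g = table.groups
    if plan.posthoc == "vs_control":
        pairs = [(x, plan.control) for x in g if x != plan.control]
    else:
        pairs = list(itertools.combinations(g, 2))
    rows = []
    for a, b in pairs:
        x, y = table.values_of(a), table.values_of(b)
        if plan.parametric:
            t_res = stats.ttest_ind(x, y)
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "test": "t",
                    "stat": float(t_res.statistic),
                    "df": x.size + y.size - 2,
                    "p": float(t_res.pvalue),
                }
            )
        else:
            u = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "test": "Mann-Whitney",
                    "stat": float(u.statistic),
                    "df": (x.size, y.size),
                    "p": float(u.pvalue),
                }
            )
    adjusted = bh_adjust([r["p"] for r in rows])
    for r, p_adj in zip(rows, adjusted):
        r["p_adj"] = float(p_adj)
        r["significance"] = stars(p_adj)
    return rows


def report(results: list[dict], path_json=None, path_md=None) -> str:
    """Render results as machine-readable JSON and a human-readable table.

    Returns the Markdown text; writes to the given paths when provided.
    Running the same inputs twice produces identical files.
    """
    lines = []
    for res in results:
        lines.append(f"## {res.get('metric', 'metric')} ({res.get('units', '')})")
        lines.append("")
        lines.append("| group | n | mean ± SEM |")
        lines.append("|---|---|---|")
        for s in res.get("summaries", []):
            lines.append(f"| {s['group']} | {s['n']} | {s['mean']:.3g} ± {s['sem']:.3g} |")
        omni = res.get("omnibus")
        if omni:
            lines.append("")
            df = omni.get("df")
            lines.append(
                f"{omni['test']}: statistic = {omni['stat']:.4g}, df = {df}, "
                f"p = {omni['p']:.4g} ({omni['significance']})"
            )
        for row in res.get("posthoc", []) or []:
            lines.append(
                f"- {row['a']} vs {row['b']}: {row['test']} = {row['stat']:.4g}, "
                f"p = {row['p']:.4g}, FDR-adjusted p = {row['p_adj']:.4g} ({row['significance']})"
            )
        lines.append("")
    md = "\n".join(lines)
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(results, fh, indent=2, default=_jsonable)
    if path_md is not None:
        with open(path_md, "w") as fh:
            fh.write(md)
    return md


def _jsonable(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
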