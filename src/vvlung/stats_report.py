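"""Statistical layer: power-based sample size, summaries, standard tests.

The sample-size computation for a two-sample t-test is implemented from the
noncentral t distribution: for n per group (equal allocation) the test
statistic under the alternative has noncentrality d*sqrt(n/2) and
2n-2 degrees of freedom; the returned n is the smallest integer >= 2 whose
power reaches the request. Descriptive summaries follow the field's
conventions (mean +/- SD for parametric, median [IQR] for nonparametric
variables, IQR by linear interpolation).

Hypothesis tests (paired t, mixed two-way repeated-measures ANOVA with
Bonferroni post-hoc, Kruskal-Wallis with Dunn's post-hoc) are dispatch
plumbing around established routines; Dunn's rank-based z comparisons are
computed here with a tie correction and Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, InvalidPlanError

__all__ = [
    "PowerSpec",
    "ttest_power",
    "ttest_sample_size",
    "monte_carlo_power",
    "summarize_groups",
    "dunn_test",
    "run_standard_tests",
]


@dataclass(frozen=True)
class PowerSpec:
    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.8
    sides: str = "two"
    allocation_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise InvalidArgumentError("power must lie in (0, 1)")
        if self.effect_size_d <= 0:
            raise InvalidArgumentError("effect size d must be positive")
        if self.sides not in ("one", "two"):
            raise InvalidArgumentError("sides must be 'one' or 'two'")
        if self.allocation_ratio <= 0:
            raise InvalidArgumentError("allocation_ratio must be positive")


def ttest_power(d: float, n1: int, alpha: float = 0.05, sides: str = "two",
                allocation_ratio: float = 1.0) -> float:
    """Exact power of the two-sample t-test from the noncentral t distribution."""
    n2 = int(round(allocation_ratio * n1))
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    if sides == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc))


def ttest_sample_size(spec: PowerSpec, n_max: int = 10000) -> int:
    """Smallest n per group whose t-test power reaches the requested level."""
    for n in range(2, n_max + 1):
        if ttest_power(spec.effect_size_d, n, spec.alpha, spec.sides,
                       spec.allocation_ratio) >= spec.power:
            return n
    raise InvalidArgumentError(
        f"required sample size exceeds n_max={n_max} (effect size too small)"
    )


def monte_carlo_power(d: float, n: int, alpha: float = 0.05, reps: int = 100_000,
                      seed: int = 0) -> float:
    """Simulated rejection rate of the two-sided two-sample t-test.

    Independent oracle for :func:`ttest_power`: draws ``reps`` pairs of
    N(0,1) and N(d,1) groups of size n and applies the pooled-variance
    t-test, fully vectorized.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=(reps, n))
    y = rng.normal(d, 1.0, size=(reps, n))
    sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2.0
    t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * 2.0 / n)
    tcrit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
    return float(np.mean(np.abs(t) >= tcrit))


def _fmt(x: float) -> str:
    return f"{x:.3g}"


def summarize_groups(groups: dict, style: str = "mean_sd") -> pd.DataFrame:
    """Per-group descriptive summary formatted by the field's conventions.

    ``mean_sd`` rows read "m +/- s"; ``median_iqr`` rows read
    "med [q1-q3]" with quartiles by linear interpolation. A single-value
    group has an undefined SD and is flagged.
    """
    if style not in ("mean_sd", "median_iqr"):
        raise InvalidArgumentError(f"unknown style {style!r}")
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise InsufficientDataError(f"group {name!r} is empty")
        if style == "mean_sd":
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else math.nan
            rows.append(
                {
                    "group": name,
                    "n": v.size,
                    "mean": mean,
                    "sd": sd,
                    "formatted": f"{_fmt(mean)} ± {_fmt(sd)}" if v.size > 1 else f"{_fmt(mean)} (SD undefined)",
                    "flagged": v.size < 2,
                }
            )
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "group": name,
                    "n": v.size,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "formatted": f"{_fmt(med)} [{_fmt(q1)}–{_fmt(q3)}]",
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def dunn_test(values, groups, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc rank comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] * (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t)/(12(N-1)); two-sided normal p,
    Bonferroni-adjusted over the pairwise family.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least two groups")
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            se = math.sqrt(var_unit * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if p_adjust == "bonferroni" else p
            rows.append({"group_a": gi, "group_b": gj, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def run_standard_tests(dataset: pd.DataFrame, plan: list) -> pd.DataFrame:
    """Dispatch the study's standard tests over a tidy dataset.

    ``dataset`` columns: animal, group, time, variable, value. ``plan`` is
    a list of dicts with keys ``variable`` and ``test`` in
    {"paired_t", "mixed_anova_bonferroni", "kruskal_dunn"}. Returns one
    tidy table of test rows (variable, test, effect, statistic, p, p_adj).
    """
    required = {"animal", "group", "time", "variable", "value"}
    missing = required - set(dataset.columns)
    if missing:
        raise InvalidArgumentError(f"dataset missing columns: {sorted(missing)}")
    rows = []
    for item in plan:
        var = item.get("variable")
        test = item.get("test")
        sub = dataset[dataset["variable"] == var]
        if sub.empty:
            raise InvalidPlanError(f"variable {var!r} absent from dataset")
        if test == "paired_t":
            times = list(pd.unique(sub["time"]))
            if len(times) != 2:
                raise InvalidPlanError("paired_t needs exactly two time levels")
            wide = sub.pivot_table(index="animal", columns="time", values="value")
            diffs = wide[times[1]] - wide[times[0]]
            if np.allclose(diffs, 0.0):
                # degenerate paired comparison of a variable against itself
                statistic, pvalue = 0.0, 1.0
            else:
                res = stats.ttest_rel(wide[times[0]], wide[times[1]])
                statistic, pvalue = float(res.statistic), float(res.pvalue)
            rows.append({"variable": var, "test": test, "effect": f"{times[0]} vs {times[1]}",
                         "statistic": statistic, "p": pvalue, "p_adj": pvalue})
        elif test == "mixed_anova_bonferroni":
            import pingouin as pg

            def _p(row, *names):
                for name in names:
                    if name in row:
                        return float(row[name])
                raise InvalidPlanError(f"unexpected pingouin output columns: {list(row.index)}")

            aov = pg.mixed_anova(data=sub, dv="value", within="time",
                                 between="group", subject="animal")
            for _, r in aov.iterrows():
                p = _p(r, "p_unc", "p-unc")
                rows.append({"variable": var, "test": test, "effect": r["Source"],
                             "statistic": float(r["F"]), "p": p, "p_adj": p})
            ph = pg.pairwise_tests(data=sub, dv="value", within="time", between="group",
                                   subject="animal", padjust="bonf")
            for _, r in ph.iterrows():
                p_unc = _p(r, "p_unc", "p-unc")
                try:
                    p_adj = _p(r, "p_corr", "p-corr")
                except InvalidPlanError:
                    p_adj = p_unc
                if math.isnan(p_adj):
                    p_adj = p_unc
                t_stat = float(r["T"]) if "T" in r and np.isfinite(r["T"]) else math.nan
                rows.append({"variable": var, "test": "bonferroni_posthoc",
                             "effect": f"{r['Contrast']}: {r['A']} vs {r['B']}",
                             "statistic": t_stat, "p": p_unc, "p_adj": p_adj})
        elif test == "kruskal_dunn":
            by_group = [g["value"].to_numpy() for _, g in sub.groupby("group", sort=True)]
            if len(by_group) < 2:
                raise InvalidPlanError("kruskal_dunn needs at least two groups")
            kw = stats.kruskal(*by_group)
            rows.append({"variable": var, "test": test, "effect": "between groups",
                         "statistic": float(kw.statistic), "p": float(kw.pvalue),
                         "p_adj": float(kw.pvalue)})
            dunn = dunn_test(sub["value"].to_numpy(), sub["group"].to_numpy())
            for _, r in dunn.iterrows():
                rows.append({"variable": var, "test": "dunn_posthoc",
                             "effect": f"{r['group_a']} vs {r['group_b']}",
                             "statistic": float(r["z"]), "p": float(r["p"]),
                             "p_adj": float(r["p_adj"])})
        else:
            raise InvalidPlanError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
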