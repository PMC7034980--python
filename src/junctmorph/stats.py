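"""Group comparison and control-normalised phenotype fingerprints.

Per-junction parameter distributions are typically non-normal, so two
groups are compared with the two-sided Mann-Whitney U test; three or more
groups with one-way ANOVA followed by the Games-Howell post-hoc test
(Welch-type statistic against a studentized-range reference, robust to
unequal group sizes and variances).  Normality statistics (Shapiro-Wilk
and Kolmogorov-Smirnov against a fitted normal) are reported as
diagnostics only; the p < 0.05 convention is reported, never hard-coded
into conclusions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["compare_groups", "normalize_profile", "plot_fingerprint"]


def _group_values(table, parameter, grouping):
    if parameter not in table.columns:
        raise ValueError(f"unknown parameter column {parameter!r}")
    if grouping not in table.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    groups = {}
    for name, sub in table.groupby(grouping, sort=True):
        vals = pd.to_numeric(sub[parameter], errors="coerce").dropna()
        groups[name] = vals.to_numpy(dtype=float)
    return groups


def _normality(values):
    out = {"n": int(len(values))}
    if len(values) >= 3 and np.ptp(values) > 0:
        out["shapiro_p"] = float(sstats.shapiro(values).pvalue)
        z = (values - values.mean()) / values.std(ddof=1)
        out["ks_p"] = float(sstats.kstest(z, "norm").pvalue)
    else:
        out["shapiro_p"] = math.nan
        out["ks_p"] = math.nan
    return out


def compare_groups(
    table: pd.DataFrame, parameter: str, grouping: str
) -> dict:
    """Statistical comparison of one parameter across groups.

    Two groups: Mann-Whitney U (two-sided).  Three or more: one-way ANOVA
    with Games-Howell pairwise post-hoc p-values.  Requires at least two
    groups with >= 3 observations each.
    """
    groups = _group_values(table, parameter, grouping)
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least two groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(
                f"group {name!r} has only {len(vals)} observations (< 3)"
            )
    report = {
        "parameter": parameter,
        "grouping": grouping,
        "groups": sorted(groups),
        "normality": {name: _normality(v) for name, v in groups.items()},
        "alpha": 0.05,
    }
    names = sorted(groups)
    if len(groups) == 2:
        u, p = sstats.mannwhitneyu(
            groups[names[0]], groups[names[1]], alternative="two-sided"
        )
        report.update(test="mann-whitney", statistic=float(u), p=float(p))
        report["pairwise"] = None
    else:
        f, p = sstats.f_oneway(*[groups[n] for n in names])
        import pingouin as pg  # deferred: heavy import

        data = pd.DataFrame({
            "value": np.concatenate([groups[n] for n in names]),
            "group": np.repeat(
                names, [len(groups[n]) for n in names]
            ),
        })
        gh = pg.pairwise_gameshowell(data=data, dv="value", between="group")
        report.update(test="anova+games-howell", statistic=float(f), p=float(p))
        report["pairwise"] = gh[["A", "B", "diff", "T", "df", "pval"]]
    return report


def normalize_profile(
    table: pd.DataFrame,
    control_group: str,
    grouping: str = "group",
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Control-normalised phenotype fingerprint.

    For each parameter and each non-control group: 100 x (treated median /
    control median), with the Mann-Whitney significance flag of the
    treated-vs-control comparison.  Medians are used because per-junction
    data are non-parametric.  Parameters with a zero control median are
    flagged non-normalizable.
    """
    if grouping not in table.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    group_names = sorted(table[grouping].unique().tolist())
    if control_group not in group_names:
        raise ValueError(f"control group {control_group!r} not in table")
    if parameters is None:
        parameters = [
            c for c in table.columns
            if c.startswith(("m1_", "m2_"))
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    control = table[table[grouping] == control_group]
    for name in group_names:
        if name == control_group:
            continue
        treated = table[table[grouping] == name]
        for param in parameters:
            cvals = pd.to_numeric(control[param], errors="coerce").dropna()
            tvals = pd.to_numeric(treated[param], errors="coerce").dropna()
            cmed = float(cvals.median()) if len(cvals) else math.nan
            tmed = float(tvals.median()) if len(tvals) else math.nan
            if not math.isfinite(cmed) or cmed == 0:
                rows.append({
                    "group": name, "parameter": param,
                    "normalized": math.nan, "p": math.nan,
                    "significant": False, "flag": "non-normalizable",
                })
                continue
            p = math.nan
            if len(cvals) >= 3 and len(tvals) >= 3:
                p = float(sstats.mannwhitneyu(
                    tvals, cvals, alternative="two-sided"
                ).pvalue)
            rows.append({
                "group": name,
                "parameter": param,
                "normalized": 100.0 * tmed / cmed,
                "p": p,
                "significant": bool(p < 0.05) if math.isfinite(p) else False,
                "flag": "",
            })
    return pd.DataFrame(
        rows,
        columns=["group", "parameter", "normalized", "p", "significant",
                 "flag"],
    )


def plot_fingerprint(profile: pd.DataFrame, path) -> None:
    """Bubble-chart rendering of a fingerprint table (one row per group,
    one column per parameter; bubble size tracks |deviation from 100|,
    open circles mark non-significant deviations)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = sorted(profile["parameter"].unique())
    groups = sorted(profile["group"].unique())
    fig, ax = plt.subplots(
        figsize=(1.2 * max(4, len(params)), 1.0 * max(2, len(groups)) + 1)
    )
    for gi, g in enumerate(groups):
        for pi, p in enumerate(params):
            sub = profile[(profile["group"] == g)
                          & (profile["parameter"] == p)]
            if sub.empty or not math.isfinite(sub["normalized"].iloc[0]):
                continue
            val = float(sub["normalized"].iloc[0])
            sig = bool(sub["significant"].iloc[0])
            size = 40 + 4 * min(abs(val - 100.0), 150.0)
            color = "tab:red" if val > 100 else "tab:blue"
            ax.scatter(
                pi, gi, s=size,
                facecolors=color if sig else "none",
                edgecolors=color,
            )
            ax.annotate(
                f"{val:.0f}", (pi, gi), textcoords="offset points",
                xytext=(0, 12), ha="center", fontsize=7,
            )
    ax.set_xticks(range(len(params)))
    ax.set_xticklabels(params, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(groups)))
    ax.set_yticklabels(groups)
    ax.set_title("Control-normalised fingerprint (control = 100)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
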