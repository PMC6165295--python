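"""Group summaries and significance testing (one-way ANOVA, Tukey HSD).

Thin, validated wrappers over scipy's reference implementations, returning
tidy pandas frames. Results are expressed as mean ± standard error with
n per group; pairwise comparisons use Tukey's studentized-range correction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def summarize(values: Sequence[float], groups: Sequence[str]) -> pd.DataFrame:
    """Per-group n, mean and standard error (sd/√n, ddof=1).

    Requires at least 2 values per group so the SE is defined.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    out = []
    for g, sub in df.groupby("group", sort=False):
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {g!r} has n={n} < 2; SE undefined")
        out.append(
            {
                "group": g,
                "n": n,
                "mean": float(sub["value"].mean()),
                "se": float(sub["value"].std(ddof=1) / np.sqrt(n)),
            }
        )
    return pd.DataFrame(out)


def _check_groups(groups: Sequence[Sequence[float]], min_k: int = 2):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < min_k:
        raise ValueError(f"need at least {min_k} groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has n={g.size} < 2")
    return arrays


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p) with p from F(k−1, N−k).

    Degenerate case: identical group means give F = 0, p = 1.
    """
    arrays = _check_groups(groups)
    res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(f):  # zero within-group variance etc.
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
    return f, p


def tukey_hsd(
    *groups: Sequence[float], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns a frame with one row per unordered pair: mean difference
    (group_b − group_a) and studentized-range adjusted p value.  With k = 2
    the adjustment degenerates to the ordinary pooled two-sample result.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(arrays[j].mean() - arrays[i].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def group_report(
    values: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table-style report: mean ± SE per group per measure, with ANOVA p.

    ``values``: tidy frame, one row per sample; every numeric column except
    ``group_col`` is a measure.  Adds a significance marker column per
    measure ('*' when the one-way ANOVA across groups has p < alpha).
    """
    measures = [
        c for c in values.columns if c != group_col and pd.api.types.is_numeric_dtype(values[c])
    ]
    group_names = list(dict.fromkeys(values[group_col]))
    rows = {}
    anova_p = {}
    for m in measures:
        arrays = [
            values.loc[values[group_col] == g, m].dropna().to_numpy()
            for g in group_names
        ]
        usable = [a for a in arrays if a.size >= 2]
        if len(usable) == len(arrays) and len(arrays) >= 2:
            _, p = one_way_anova(*arrays)
        else:
            p = float("nan")
        anova_p[m] = p
        for g, a in zip(group_names, arrays):
            cell = (
                f"{a.mean():.2f} ± {a.std(ddof=1) / np.sqrt(a.size):.2f}"
                if a.size >= 2
                else (f"{a.mean():.2f}" if a.size else "—")
            )
            rows.setdefault(g, {})[m] = cell
    out = pd.DataFrame(rows).T
    out.index.name = group_col
    marker = {
        m: ("*" if np.isfinite(anova_p[m]) and anova_p[m] < alpha else "")
        for m in measures
    }
    out.loc["anova_p"] = {m: f"{anova_p[m]:.4g}{marker[m]}" for m in measures}
    return out
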