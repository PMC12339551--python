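"""Treatment comparisons: one-way ANOVA, Duncan's multiple range test with a
compact letter display, and topsoil-vs-subsoil Welch contrasts.

Duncan's test compares the ``r``-mean range of each pair of sorted group
means against a critical value built from the studentized-range distribution
at the protected level ``1 − (1 − α)^(r−1)``; a pair differs only if every
range containing it is significant. Letters are assigned on means sorted
descending, starting at "a": groups sharing a letter are not significantly
different. Unequal replicate counts use the harmonic-mean n in the standard
error.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


class GroupStatsError(ValueError):
    """Degenerate or invalid input to a group comparison."""


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float


@dataclass(frozen=True)
class DuncanResult:
    letters: dict[str, str]        # group -> letter string, e.g. "ab"
    means: dict[str, float]
    alpha: float
    different: dict[tuple[str, str], bool]  # unordered pair -> significant


@dataclass(frozen=True)
class ContrastResult:
    stat: float
    p_value: float
    significant: bool


def _as_groups(samples) -> tuple[list[str], list[np.ndarray]]:
    """Accept a dict {name: values} or iterable of (name, values)."""
    items = samples.items() if isinstance(samples, dict) else list(samples)
    names, values = [], []
    for name, vals in items:
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise GroupStatsError(
                f"group {name!r} needs >= 2 replicate values"
            )
        names.append(str(name))
        values.append(arr)
    if len(names) < 2:
        raise GroupStatsError("need >= 2 groups")
    if len(set(names)) != len(names):
        raise GroupStatsError("duplicate group labels")
    return names, values


def one_way_anova(samples) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    F is the between-group mean square over the within-group mean square;
    the p-value comes from the F distribution with (k−1, N−k) df.
    """
    names, values = _as_groups(samples)
    k = len(values)
    ns = np.array([v.size for v in values])
    n_total = int(ns.sum())
    grand = np.concatenate(values).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0 and ss_between == 0:
        raise GroupStatsError("zero total variance: ANOVA undefined")
    if ss_within == 0:
        raise GroupStatsError("zero within-group variance: F undefined")
    ms_within = ss_within / df_within
    f = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(f, p, df_between, df_within, ms_within)


def _duncan_critical_ranges(
    k: int, df_within: int, ms_within: float, n_harmonic: float, alpha: float
) -> np.ndarray:
    """Least significant ranges R_r for range sizes r = 2..k (index r-2).

    R_r = q(1 − (1−α)^(r−1); r, df) × sqrt(MS_within / n_h), the "special
    protection level" that distinguishes Duncan's test from Tukey-style use
    of the studentized range.
    """
    se = np.sqrt(ms_within / n_harmonic)
    rs = np.arange(2, k + 1)
    protected = 1.0 - (1.0 - alpha) ** (rs - 1)
    q = stats.studentized_range.ppf(1.0 - protected, rs, df_within)
    return q * se


def duncan_mrt(samples, alpha: float = DEFAULT_ALPHA) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Means are sorted descending; the pair (i, j) is declared different only
    if |mean_i − mean_j| exceeds the least significant range for its span
    *and* no enclosing range is non-significant (the standard containment
    rule, which keeps the non-different sets contiguous). Letters are then
    assigned to the maximal homogeneous runs, "a" first.
    """
    if not 0 < alpha < 1:
        raise GroupStatsError("alpha must be in (0, 1)")
    names, values = _as_groups(samples)
    anova = one_way_anova(zip(names, values))
    k = len(names)
    ns = np.array([v.size for v in values], dtype=float)
    n_h = k / np.sum(1.0 / ns)
    lsr = _duncan_critical_ranges(k, anova.df_within, anova.ms_within, n_h, alpha)

    means = np.array([v.mean() for v in values])
    order = np.argsort(-means, kind="stable")
    sorted_names = [names[i] for i in order]
    sorted_means = means[order]

    def range_significant(a: int, b: int) -> bool:
        # span r = b - a + 1 means, critical range lsr[r - 2]
        return (sorted_means[a] - sorted_means[b]) > lsr[b - a - 1]

    # Containment rule: i, j differ iff every enclosing range is significant.
    differ = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            differ[i, j] = differ[j, i] = all(
                range_significant(a, b)
                for a in range(0, i + 1)
                for b in range(j, k)
            )

    # Maximal homogeneous runs on the sorted order -> letters.
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            differ[a, j + 1] for a in range(i, j + 1)
        ):
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))  # runs contained in an earlier one are absorbed
    letters_sorted = ["" for _ in range(k)]
    alphabet = string.ascii_lowercase
    for idx, (i, j) in enumerate(runs):
        letter = alphabet[idx % 26] * (idx // 26 + 1)
        for g in range(i, j + 1):
            letters_sorted[g] += letter

    letters = {sorted_names[i]: letters_sorted[i] for i in range(k)}
    pairwise = {
        tuple(sorted((sorted_names[i], sorted_names[j]))): bool(differ[i, j])
        for i in range(k)
        for j in range(i + 1, k)
    }
    return DuncanResult(
        letters=letters,
        means={n: float(m) for n, m in zip(sorted_names, sorted_means)},
        alpha=alpha,
        different=pairwise,
    )


def depth_contrast(
    topsoil_values, subsoil_values, alpha: float = DEFAULT_ALPHA
) -> ContrastResult:
    """Two-sided Welch two-sample comparison between soil depths."""
    a = np.asarray(topsoil_values, dtype=float)
    b = np.asarray(subsoil_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GroupStatsError("each depth needs >= 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # Both constant: no sampling variance to test against.
        if a[0] == b[0]:
            return ContrastResult(0.0, 1.0, False)
        return ContrastResult(np.inf, 0.0, True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ContrastResult(float(t), float(p), bool(p < alpha))


# ---------------------------------------------------------------------------
# Table-level comparisons
# ---------------------------------------------------------------------------

def compare_table(
    estimates: pd.DataFrame,
    responses,
    group: str = "treatment",
    within=("depth", "day"),
    depth_key: str = "depth",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment letters within each stratum plus depth contrasts.

    Returns ``(letters, contrasts)``: ``letters`` is long-format
    (response, *within, group, mean, sd, n, letter); ``contrasts`` holds the
    Welch topsoil-vs-subsoil test per response × remaining keys × group.
    """
    within = list(within)
    letter_rows, contrast_rows = [], []
    for response in responses:
        for keys, stratum in estimates.groupby(within, observed=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            samples = {
                str(g): sub[response].to_numpy(float)
                for g, sub in stratum.groupby(group, observed=True)
            }
            try:
                res = duncan_mrt(samples, alpha=alpha)
                letters = res.letters
            except GroupStatsError:
                letters = {g: "" for g in samples}
            for g, vals in samples.items():
                letter_rows.append(
                    {
                        "response": response,
                        **dict(zip(within, keys)),
                        group: g,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                        "n": len(vals),
                        "letter": letters.get(g, ""),
                    }
                )
        # Depth contrasts within the remaining keys × group.
        others = [c for c in within if c != depth_key]
        if depth_key in estimates.columns:
            grouping = others + [group]
            for keys, sub in estimates.groupby(grouping, observed=True):
                keys = keys if isinstance(keys, tuple) else (keys,)
                depths = {
                    str(d): s[response].to_numpy(float)
                    for d, s in sub.groupby(depth_key, observed=True)
                }
                if len(depths) != 2:
                    continue
                (da, va), (db, vb) = sorted(depths.items(), reverse=True)
                try:
                    c = depth_contrast(va, vb, alpha=alpha)
                except GroupStatsError:
                    continue
                contrast_rows.append(
                    {
                        "response": response,
                        **dict(zip(grouping, keys)),
                        "stat": c.stat,
                        "p_value": c.p_value,
                        "significant": c.significant,
                    }
                )
    return pd.DataFrame(letter_rows), pd.DataFrame(contrast_rows)
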