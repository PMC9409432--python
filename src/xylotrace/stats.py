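"""Group statistics for gallery morphometry.

One-way ANOVA — computable either from raw per-gallery values or, exactly
equivalently, from per-group (n, mean, SE) summaries — and Duncan's new
multiple range test with a compact letter display, plus a report generator
that tabulates mean +/- SE per gallery type with ANOVA F/p and Duncan
letters for each of the seven gallery parameters.

Duncan's test compares the range of every span of p consecutive ordered
means against a studentized-range critical value taken at the protection
level ``1 - (1 - alpha)**(p - 1)``, stepping down and never testing inside
an accepted span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import METRIC_COLUMNS

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "DuncanResult",
    "anova_oneway",
    "anova_from_summary",
    "duncan_mrt",
    "summarize_metrics",
]


@dataclass
class GroupSummary:
    """n, mean and standard error of one group (SE = SD / sqrt(n))."""

    group: str
    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.n == 1 and self.se > 0:
            raise ValueError(
                f"group {self.group!r}: n = 1 cannot carry a positive SE"
            )

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class DuncanResult:
    """Ordered means, pairwise significance and compact letter display."""

    groups: list[str]  # sorted by ascending mean
    means: np.ndarray
    significant: np.ndarray  # (k, k) bool, True = significantly different
    letters: dict[str, str] = field(default_factory=dict)


def _group_arrays(groups: dict) -> tuple[list[str], list[np.ndarray]]:
    names = list(groups)
    vals = [np.asarray(groups[g], dtype=float).ravel() for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 1 for v in vals):
        raise ValueError("every group needs at least one value")
    return names, vals


def anova_oneway(groups: dict) -> AnovaResult:
    """One-way fixed-effects ANOVA on ``{group: values}``.

    Edge cases: all values identical gives F = 0, p = 1; zero within-group
    variance with unequal means gives an infinite F and p = 0.
    """
    names, vals = _group_arrays(groups)
    k = len(names)
    ns = np.array([len(v) for v in vals])
    N = int(ns.sum())
    if N <= k:
        raise ValueError("need more observations than groups")
    means = np.array([v.mean() for v in vals])
    grand = float(np.concatenate(vals).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((v - m) ** 2).sum() for v, m in zip(vals, means)))
    df_b, df_w = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, SE).

    Exactly equivalent to :func:`anova_oneway` on any raw data with these
    summaries: the within-group sum of squares is rebuilt from
    ``sd = se * sqrt(n)``.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two group summaries")
    ns = np.array([s.n for s in summaries])
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    k = len(summaries)
    N = int(ns.sum())
    if N <= k:
        raise ValueError("need more observations than groups")
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, N - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(float(F), df_b, df_w, float(sps.f.sf(F, df_b, df_w)))


def _duncan_critical(p_span: int, df_w: int, alpha: float) -> float:
    """Duncan's critical studentized range for a span of ``p_span`` means:
    the range quantile at protection level (1 - alpha)^(p_span - 1)."""
    protection = (1.0 - alpha) ** (p_span - 1)
    return float(sps.studentized_range.ppf(protection, p_span, df_w))


def duncan_mrt(groups: dict, alpha: float = 0.05) -> DuncanResult:
    """Duncan's new multiple range test on ``{group: values}``.

    Means are ordered; every span of p consecutive means is tested against
    ``q*(p, df_w, protection) * sqrt(MSW / n_h)`` (n_h = harmonic mean of the
    span's group sizes), stepping down from the full range and declaring
    everything inside an accepted (non-significant) span homogeneous.
    Letters are derived from the resulting homogeneous spans.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    names, vals = _group_arrays(groups)
    anova = anova_oneway(groups)
    if anova.df_within < 1:
        raise ValueError("Duncan's test needs at least one within-group df")
    ns = np.array([len(v) for v in vals])
    means = np.array([v.mean() for v in vals])
    msw = float(
        sum(((v - v.mean()) ** 2).sum() for v in vals) / anova.df_within
    )
    order = np.argsort(means)
    names_s = [names[i] for i in order]
    means_s = means[order]
    ns_s = ns[order]
    k = len(names_s)

    # step-down span testing with the non-testing rule
    homogeneous = np.zeros((k, k), dtype=bool)  # span [i, j] accepted
    significant = np.zeros((k, k), dtype=bool)
    if msw == 0.0:
        for i in range(k):
            for j in range(i + 1, k):
                significant[i, j] = significant[j, i] = means_s[j] > means_s[i]
    else:
        accepted: list[tuple[int, int]] = []
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                if any(a <= i and j <= b for a, b in accepted):
                    homogeneous[i, j] = True  # inside an accepted span
                    continue
                n_h = span / float((1.0 / ns_s[i : j + 1]).sum())
                crit = _duncan_critical(span, anova.df_within, alpha)
                rng = means_s[j] - means_s[i]
                if rng <= crit * np.sqrt(msw / n_h):
                    homogeneous[i, j] = True
                    accepted.append((i, j))
        for i in range(k):
            for j in range(i + 1, k):
                significant[i, j] = significant[j, i] = not homogeneous[i, j]

    letters = _compact_letters(names_s, significant)
    return DuncanResult(
        groups=names_s, means=means_s, significant=significant, letters=letters
    )


def _compact_letters(names_s: list[str], significant: np.ndarray) -> dict[str, str]:
    """Letters over means sorted ascending: maximal runs of mutually
    non-different groups share a letter (spans are contiguous by the
    step-down construction)."""
    k = len(names_s)
    spans = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not significant[i, j + 1]:
            j += 1
        spans.append((i, j))
        i += 1
    # drop spans contained in another
    maximal = [
        (a, b)
        for a, b in spans
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in spans)
    ]
    maximal = sorted(set(maximal))
    letters = {n: "" for n in names_s}
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for t in range(a, b + 1):
            letters[names_s[t]] += ch
    return letters


def summarize_metrics(
    metrics: pd.DataFrame, alpha: float = 0.05, min_group: int = 2
) -> pd.DataFrame:
    """Tabulate per-type mean +/- SE, ANOVA and Duncan letters per parameter.

    ``metrics`` is the per-gallery table (columns ``type`` plus the seven
    parameters).  Types with a single gallery report their mean with a
    missing SE and are excluded from ANOVA/Duncan.  Returns a tidy frame with
    one row per (parameter, type) and per-parameter F and p.
    """
    if "type" not in metrics.columns:
        raise ValueError("metrics table needs a 'type' column")
    usable = metrics[metrics["type"].isin(["C", "S", "Y"])]
    if len(usable) == 0:
        raise ValueError("no complete typed galleries to summarize")
    rows = []
    for param in METRIC_COLUMNS:
        by_type = {
            t: g[param].to_numpy() for t, g in usable.groupby("type", sort=False)
        }
        big = {t: v for t, v in by_type.items() if len(v) >= min_group}
        anova = letters = None
        if len(big) >= 2:
            anova = anova_oneway(big)
            letters = duncan_mrt(big, alpha=alpha).letters
        for t, v in by_type.items():
            rows.append(
                {
                    "parameter": param,
                    "type": t,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "se": float(np.std(v, ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1
                    else np.nan,
                    "letter": (letters or {}).get(t, ""),
                    "F": anova.F if anova else np.nan,
                    "p": anova.p if anova else np.nan,
                }
            )
    order = {t: i for i, t in enumerate(["C", "S", "Y"])}
    out = pd.DataFrame(rows)
    out["_o"] = out["type"].map(order)
    out = out.sort_values(["parameter", "_o"]).drop(columns="_o")
    out["parameter"] = pd.Categorical(out["parameter"], METRIC_COLUMNS, ordered=True)
    return out.sort_values(["parameter", "type"], kind="stable").reset_index(drop=True)
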