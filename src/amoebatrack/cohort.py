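"""Replicate aggregation and condition comparison.

Per-condition fits are summarized as mean +/- dispersion (sample SD by
default, SEM on request) with censored colonization times capped at the
recording window and counted.  Conditions are compared per metric by one-way
ANOVA followed by Tukey's HSD, and the pairwise outcomes are condensed into a
compact letter display: conditions sharing a letter are not significantly
different at the chosen alpha.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import FitResult

__all__ = [
    "ReplicateSummary",
    "GroupComparison",
    "aggregate",
    "compare_conditions",
    "compact_letter_display",
    "summary_table",
    "METRICS",
]

# metrics reported per condition; tc/tg use censoring-aware reported values
METRICS = ("cIA", "cCA", "rel_colonization", "tx", "tp", "tc", "tg")


@dataclass
class ReplicateSummary:
    """Mean +/- dispersion of each behavioral parameter for one condition."""

    condition: str
    n: int
    dispersion: str  # "sd" or "sem"
    stats: dict  # metric -> (mean, dispersion)
    values: dict  # metric -> raw per-replicate values (for group comparison)
    n_censored_tc: int
    window_end: float
    small_n: bool = False

    def cell(self, metric: str, decimals: int = 1) -> str:
        """Table cell text; all-censored tc/tg render as '>window'."""
        if metric in ("tc", "tg") and self.n_censored_tc == self.n:
            return f">{self.window_end:g}"
        m, d = self.stats[metric]
        return f"{m:.{decimals}f} ± {d:.{decimals}f}"


def _metric_values(fit: FitResult) -> dict:
    p = fit.params
    return {
        "cIA": p.cIA,
        "cCA": p.cCA,
        "rel_colonization": fit.relative_colonization,
        "tx": p.tx,
        "tp": p.tp,
        "tc": fit.tc_reported,  # censored values capped at the window end
        "tg": fit.tg_reported,
    }


def aggregate(
    fits: list[FitResult], condition: str, dispersion: str = "sd"
) -> ReplicateSummary:
    """Summarize replicate fits of one condition as mean +/- dispersion.

    Censored colonization times enter at the window cap and are counted in
    ``n_censored_tc``.  A single replicate reports zero dispersion with a
    ``small_n`` flag.
    """
    if not fits:
        raise ValueError("aggregate needs at least one fit")
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    n = len(fits)
    values = {m: np.array([_metric_values(f)[m] for f in fits], dtype=float) for m in METRICS}
    stats_d = {}
    for m, v in values.items():
        mean = float(v.mean())
        if n == 1:
            disp = 0.0
        else:
            sd = float(v.std(ddof=1))
            disp = sd if dispersion == "sd" else sd / np.sqrt(n)
        stats_d[m] = (mean, disp)
    return ReplicateSummary(
        condition=condition,
        n=n,
        dispersion=dispersion,
        stats=stats_d,
        values=values,
        n_censored_tc=sum(f.tc_censored for f in fits),
        window_end=float(max(f.window_end for f in fits)),
        small_n=n == 1,
    )


@dataclass
class GroupComparison:
    """Compact-letter summary of all pairwise post hoc comparisons."""

    metric: str
    groups: tuple[str, ...]
    letters: dict  # condition -> letter string
    alpha: float
    method: str
    p_anova: float
    significant: np.ndarray  # boolean matrix, [i, j] True when i vs j differs
    p_values: np.ndarray
    warnings: tuple[str, ...] = ()


def compact_letter_display(groups, significant) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant[i, j]`` is True when groups i and j differ.  Returns one
    letter string per group such that two groups share a letter iff they are
    not significantly different.
    """
    k = len(groups)
    cols = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for c in [c for c in cols if i in c and j in c]:
                cols.remove(c)
                a, b = set(c), set(c)
                a.discard(j)
                b.discard(i)
                cols.extend([a, b])
            # absorb columns that became subsets of another
            cols = [c for c in cols if not any(c < d for d in cols if d is not c)]
            # drop exact duplicates
            uniq = []
            for c in cols:
                if c not in uniq:
                    uniq.append(c)
            cols = uniq
    cols.sort(key=lambda c: (min(c), -len(c)))
    alphabet = string.ascii_lowercase
    labels = [
        alphabet[i % 26] * (i // 26 + 1) for i in range(len(cols))
    ]  # a..z, then aa, bb, ...
    return {
        g: "".join(lab for lab, c in zip(labels, cols) if idx in c)
        for idx, g in enumerate(groups)
    }


def compare_conditions(data, metric: str = "value", alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA + Tukey HSD across conditions, with letter groups.

    ``data`` is a mapping {condition: per-replicate values}, a long-format
    DataFrame with ``condition`` and ``value`` columns, or a list of
    :class:`ReplicateSummary` (the stored raw values of ``metric`` are used).
    Each condition needs >= 2 replicates and there must be >= 2 conditions.
    """
    if isinstance(data, pd.DataFrame):
        groups = {c: g["value"].to_numpy(float) for c, g in data.groupby("condition", sort=False)}
    elif data and isinstance(data[0] if isinstance(data, list) else None, ReplicateSummary):
        groups = {s.condition: np.asarray(s.values[metric], float) for s in data}
    else:
        groups = {c: np.asarray(v, dtype=float) for c, v in dict(data).items()}

    names = tuple(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for c, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"condition {c!r} needs at least 2 replicates")

    k = len(names)
    notes: list[str] = []
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled.var(), 0.0):
        notes.append("degenerate: zero variance in all groups; no differences detectable")
        sig = np.zeros((k, k), dtype=bool)
        pvals = np.ones((k, k))
        p_anova = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_anova = float(sps.f_oneway(*groups.values()).pvalue)
        labels = np.concatenate([[c] * len(v) for c, v in groups.items()])
        tuk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
        sig = np.zeros((k, k), dtype=bool)
        pvals = np.ones((k, k))
        order = {c: i for i, c in enumerate(tuk.groupsunique)}
        res = np.asarray(tuk.summary().data[1:], dtype=object)
        for row, rej, p in zip(res, tuk.reject, tuk.pvalues):
            i, j = order[row[0]], order[row[1]]
            # map statsmodels' sorted group order back onto input order
            a = names.index(tuk.groupsunique[i])
            b = names.index(tuk.groupsunique[j])
            sig[a, b] = sig[b, a] = bool(rej)
            pvals[a, b] = pvals[b, a] = float(p)

    letters = compact_letter_display(names, sig)
    return GroupComparison(
        metric=metric,
        groups=names,
        letters=letters,
        alpha=alpha,
        method="one-way ANOVA + Tukey HSD",
        p_anova=float(p_anova),
        significant=sig,
        p_values=pvals,
        warnings=tuple(notes),
    )


def summary_table(summaries: list[ReplicateSummary], decimals: int = 1) -> pd.DataFrame:
    """Conditions-as-columns table of 'mean +/- dispersion' cells plus N."""
    rows = {m: {s.condition: s.cell(m, decimals) for s in summaries} for m in METRICS}
    rows["N"] = {s.condition: str(s.n) for s in summaries}
    return pd.DataFrame(rows).T
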