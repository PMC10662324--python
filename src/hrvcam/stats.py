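"""Group comparisons of cohort clinical variables.

One-way ANOVA in two equivalent routes — from raw per-subject values and
from printed summary statistics (mean, SD, n per group) — plus Tukey-Kramer
pairwise post-hoc comparisons.  The summary route exists because published
cohort tables report only mean +/- SD and n; with the classical identities

    SSB = sum n_i (xbar_i - xbar)^2,   SSW = sum (n_i - 1) s_i^2,
    F = (SSB / (g - 1)) / (SSW / (N - g)),

the printed F statistics of such a table can be reconstructed (to rounding
of the printed summaries) without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("groups must have n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    groups: tuple


#: Reference group summaries (mean, SD, n) for the three non-severe severity
#: groups of a 70-subject cue-reactivity cohort: the IAT severity score and
#: the Barratt impulsiveness scale.  Used by examples and validation checks;
#: the severe group (n = 2) is excluded from group comparisons because two
#: subjects carry no usable between-group variance.
REFERENCE_GROUP_SUMMARIES = {
    "iat": (
        GroupSummary("normal", 19.6, 8.5, 15),
        GroupSummary("mild", 38.7, 5.6, 30),
        GroupSummary("moderate", 61.1, 8.2, 23),
    ),
    "bis": (
        GroupSummary("normal", 47.2, 5.1, 15),
        GroupSummary("mild", 50.5, 6.6, 30),
        GroupSummary("moderate", 56.4, 8.1, 23),
    ),
}


def anova_from_summary(groups) -> AnovaResult:
    """One-way ANOVA from per-group (mean, sd, n)."""
    groups = tuple(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    N, g = n.sum(), len(groups)
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s ** 2).sum())
    dfb, dfw = g - 1, int(N - g)
    if ssw == 0.0:
        F = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return AnovaResult(F=F, df_between=dfb, df_within=dfw, p=p, groups=groups)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p, groups=groups)


def anova_oneway(raw_groups) -> AnovaResult:
    """One-way ANOVA from raw values, by the classical sum-of-squares
    decomposition (independent of the summary route, which it must match to
    numerical precision on exact summaries)."""
    arrays = [np.asarray(v, dtype=float) for v in raw_groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with n >= 2 each")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    g, N = len(arrays), allv.size
    dfb, dfw = g - 1, N - g
    summaries = tuple(GroupSummary(f"g{i}", float(a.mean()),
                                   float(a.std(ddof=1)), int(a.size))
                      for i, a in enumerate(arrays))
    if ssw == 0.0:
        F = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return AnovaResult(F=F, df_between=dfb, df_within=dfw, p=p,
                           groups=summaries)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw,
                       p=float(sps.f.sf(F, dfb, dfw)), groups=summaries)


def exact_summaries(raw_groups, labels=None):
    labels = labels or [f"g{i}" for i in range(len(raw_groups))]
    return tuple(GroupSummary(lab, float(np.mean(v)), float(np.std(v, ddof=1)),
                              int(len(v)))
                 for lab, v in zip(labels, raw_groups))


def tukey_from_summary(groups, alpha: float = 0.05) -> list[dict]:
    """Tukey-Kramer pairwise comparisons from group summaries.

    q_ij = |xbar_i - xbar_j| / sqrt( (MSW/2) (1/n_i + 1/n_j) ), compared to
    the studentized-range critical value at ``alpha``.
    """
    groups = tuple(groups)
    res = anova_from_summary(groups)
    n = np.array([g.n for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    msw = float(((n - 1) * s ** 2).sum() / res.df_within)
    crit = float(sps.studentized_range.ppf(1 - alpha, len(groups), res.df_within))
    table = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = groups[i].mean - groups[j].mean
            se = np.sqrt(msw / 2.0 * (1.0 / groups[i].n + 1.0 / groups[j].n))
            q = abs(diff) / se if se > 0 else np.inf
            table.append({
                "pair": (groups[i].label, groups[j].label),
                "difference": float(diff),
                "q": float(q),
                "q_critical": crit,
                "significant": bool(q > crit),
            })
    return table
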