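"""Validation statistics for media comparisons.

Continuous responses (shoot length, leaf area) are compared by one-way
ANOVA with Tukey's HSD at the study's strict alpha = 0.001; ordinal
scores use Kruskal-Wallis.  Published tables report only mean +/- SD per
medium, so a Welch t test from summary statistics is provided for
re-testing printed results without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groupings: dict[str, str] | None = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p must be in [0, 1]")


def welch_t_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch t test with Satterthwaite df from means, SDs and sizes."""
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0:
        # zero variance in both groups: equal means are trivially "equal"
        if a.mean == b.mean:
            return TestResult(0.0, a.n + b.n - 2, 1.0)
        return TestResult(np.inf, a.n + b.n - 2, 0.0)
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p)


def _compact_letters(labels, means, differs) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinct.

    ``differs[i][j]`` is True when labels i and j are significantly
    different.  Greedy insert-absorb on groups ordered by descending mean.
    """
    order = np.argsort(-np.asarray(means))
    letter_sets: list[set[int]] = []
    for i in order:
        placed = False
        for s in letter_sets:
            if all(not differs[i][j] for j in s):
                s.add(i)
                placed = True
        if not placed:
            letter_sets.append({i})
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for k, s in enumerate(letter_sets):
        for i in s:
            out[labels[i]] += letters[k]
    return {lab: "".join(sorted(v)) for lab, v in out.items()}


def anova_tukey(samples: dict[str, np.ndarray], alpha: float = 0.001) -> TestResult:
    """One-way ANOVA F plus Tukey HSD pairwise comparisons at ``alpha``."""
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(samples[g], float) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    F, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    group = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
    if np.ptp(values) == 0:
        differs = [[False] * len(labels) for _ in labels]
        F, p = 0.0, 1.0
    else:
        tk = pairwise_tukeyhsd(values, group, alpha=alpha)
        differs = [[False] * len(labels) for _ in labels]
        idx = {g: i for i, g in enumerate(tk.groupsunique)}
        k = 0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                gi = idx[tk.groupsunique[i]]
                reject = bool(tk.reject[k])
                a_, b_ = labels.index(tk.groupsunique[i]), labels.index(tk.groupsunique[j])
                differs[a_][b_] = differs[b_][a_] = reject
                k += 1
    means = [a.mean() for a in arrays]
    letters = _compact_letters(labels, means, differs)
    df = (len(labels) - 1, len(values) - len(labels))
    return TestResult(float(F), df, float(p), groupings=letters)


def kruskal_wallis(samples: dict[str, np.ndarray], alpha: float = 0.001) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value."""
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(samples[g], float) for g in labels]
    values = np.concatenate(arrays)
    if np.ptp(values) == 0:
        return TestResult(0.0, len(labels) - 1, 1.0)
    H, p = sps.kruskal(*arrays)
    return TestResult(float(H), len(labels) - 1, float(p))


def samples_from_summaries(summaries: list[GroupSummary],
                           seed: int = 0) -> dict[str, np.ndarray]:
    """Reconstruct plausible normal samples matching printed mean/SD/n.

    Draws are standardized within each group so the sample mean and SD hit
    the printed values exactly; used to re-run Tukey/Kruskal procedures
    from summary tables.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for s in summaries:
        z = rng.standard_normal(s.n)
        z = (z - z.mean()) / z.std(ddof=1)
        out[s.label] = s.mean + s.sd * z
    return out
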