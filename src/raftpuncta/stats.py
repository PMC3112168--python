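"""Group comparisons: Student's t-test and one-way ANOVA with
Student–Newman–Keuls (SNK) post-hoc pairwise decisions at 95% confidence.

SNK is implemented directly on scipy's studentized-range distribution: group
means are sorted, ranges are tested step-down from the widest span, and
pairs inside a non-significant span are not tested further (the defining
difference from Tukey's HSD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import GroupComparison, sem

__all__ = ["compare_groups", "SNKDecision"]


@dataclass(frozen=True)
class SNKDecision:
    group_a: str
    group_b: str
    q_statistic: float
    q_critical: float
    significant: bool


def _t_test(groups: dict[str, np.ndarray], alpha: float) -> GroupComparison:
    if len(groups) != 2:
        raise ValueError("t_test requires exactly two groups")
    (na, a), (nb, b) = groups.items()
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        test="t_test",
        means={na: float(np.mean(a)), nb: float(np.mean(b))},
        sems={na: sem(a), nb: sem(b)},
        ns={na: a.size, nb: b.size},
        statistic=float(t),
        pvalue=float(p),
        alpha=alpha,
    )


def _snk(groups: dict[str, np.ndarray], alpha: float) -> GroupComparison:
    names = list(groups)
    k = len(names)
    data = [groups[n] for n in names]
    f, p = sps.f_oneway(*data)

    n_total = sum(d.size for d in data)
    df_err = n_total - k
    mse = sum(((d - d.mean()) ** 2).sum() for d in data) / df_err

    # sort by mean; ties broken by group-label order (stable sort)
    order = sorted(range(k), key=lambda i: (float(data[i].mean()), names[i]))
    sorted_names = [names[i] for i in order]
    sorted_means = [float(data[i].mean()) for i in order]
    sorted_ns = [data[i].size for i in order]

    decisions: list[SNKDecision] = []
    blocked: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):  # step-down over range width
        q_crit = float(sps.studentized_range.ppf(1 - alpha, span, df_err))
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            pair_blocked = (lo, hi) in blocked
            # harmonic-mean n for unequal group sizes (Tukey–Kramer form)
            n_h = 2.0 / (1.0 / sorted_ns[lo] + 1.0 / sorted_ns[hi])
            q = abs(sorted_means[hi] - sorted_means[lo]) / np.sqrt(mse / n_h)
            significant = (not pair_blocked) and q > q_crit
            decisions.append(
                SNKDecision(
                    group_a=sorted_names[lo],
                    group_b=sorted_names[hi],
                    q_statistic=float(q),
                    q_critical=q_crit,
                    significant=significant,
                )
            )
            if pair_blocked or not significant:
                # no pair nested inside a non-significant span is tested
                for i in range(lo, hi + 1):
                    for j in range(i + 1, hi + 1):
                        blocked.add((i, j))

    return GroupComparison(
        test="anova_snk",
        means={n: float(groups[n].mean()) for n in names},
        sems={n: sem(groups[n]) for n in names},
        ns={n: groups[n].size for n in names},
        statistic=float(f),
        pvalue=float(p),
        alpha=alpha,
        pairwise=decisions,
    )


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    test: str = "t_test",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare sample groups with a two-sample t-test or one-way ANOVA
    followed by SNK pairwise decisions at ``alpha``.

    Each group needs n ≥ 2; ANOVA needs ≥ 2 groups.
    """
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size} < 2")
    if test == "t_test":
        return _t_test(arrays, alpha)
    if test == "anova_snk":
        if len(arrays) < 2:
            raise ValueError("ANOVA requires at least two groups")
        return _snk(arrays, alpha)
    raise ValueError(f"unknown test {test!r}")
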