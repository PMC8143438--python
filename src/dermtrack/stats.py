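"""Nonparametric group-comparison statistics.

The battery used for intravital motility data: two-group Mann-Whitney U
(exact by enumeration for small tie-free samples, normal approximation with
tie correction and continuity correction otherwise), Kruskal-Wallis H for
three or more groups with Dunn's pairwise post hoc, and the Holm-Šídák
step-down adjustment for families of comparisons (also applied to batteries
of Welch t tests, the parametric analogue used for quadrant panels).

Everything here is rank arithmetic implemented directly so that exactness
guarantees (enumeration cutoffs, correction terms) are explicit; the test
suite cross-checks against scipy and statsmodels implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ComputationError

#: Exact Mann-Whitney enumeration is used (in auto mode) when the smaller
#: sample has at most this many observations and the pooled data are
#: tie-free; C(16, 8) = 12870 splits is trivially enumerable.
EXACT_CUTOFF = 8


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    adjusted: bool = False
    comparison: str = ""


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates all C(n1+n2, n1) assignments of the pooled
    ranks (valid only without ties); ``"normal_approx"`` uses the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction; ``"auto"`` picks exact when min(n) ≤ 8 and the pooled data
    are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ComputationError("mann_whitney requires two non-empty samples")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_stat = min(u1, u2)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if np.all(pooled == pooled[0]):
        return TestResult(u_stat, 1.0, "mann_whitney_degenerate_all_tied",
                          (n1, n2))

    if mode == "auto":
        mode = "exact" if (min(n1, n2) <= EXACT_CUTOFF and not has_ties) \
            else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ComputationError("exact Mann-Whitney requires tie-free data")
        p = _exact_mw_p(ranks, n1, u_stat)
        return TestResult(u_stat, p, "mann_whitney_exact_enumeration", (n1, n2))
    if mode != "normal_approx":
        raise ValueError(f"unknown mode {mode!r}")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return TestResult(u_stat, 1.0, "mann_whitney_degenerate_all_tied", (n1, n2))
    # continuity correction shrinks |U − µ| by 0.5
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(u_stat, p, "mann_whitney_normal_approx_cc", (n1, n2))


def _exact_mw_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p: P(min(U₁, U₂) ≤ observed) by full enumeration.

    Counting splits in both tails via min(U₁, U₂) is equivalent, for the
    symmetric tie-free U distribution, to doubling one tail.
    """
    n = len(ranks)
    n1n2 = n1 * (n - n1)
    total = comb(n, n1)
    count = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u1 = ranks[list(idx)].sum() - offset
        if min(u1, n1n2 - u1) <= u_obs + 1e-9:
            count += 1
    return min(1.0, count / total)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from χ²(k − 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ComputationError("kruskal_wallis requires >= 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ComputationError("kruskal_wallis: empty group")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r = ranks[start:start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n ** 3 - n)
    if correction <= 0:
        # all observations identical: no separation whatsoever
        return TestResult(0.0, 1.0, "kruskal_wallis_degenerate_all_tied",
                          tuple(sizes))
    h /= correction
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult(h, p, "kruskal_wallis_tie_corrected", tuple(sizes))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    comparisons: str = "all_pairs",
    labels: Sequence[str] | None = None,
    adjustment: str = "holm_sidak",
) -> list[TestResult]:
    """Dunn's pairwise z tests on pooled mean ranks, after Kruskal-Wallis.

    ``comparisons`` is ``"all_pairs"`` or ``"vs_control"`` (the first group
    is the control).  Raw two-sided p-values are adjusted by Holm-Šídák
    (default) or Bonferroni over the comparisons actually made.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    kruskal_wallis(groups)  # validates the preconditions
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + len(g)].mean()))
        sizes.append(len(g))
        start += len(g)
    var_base = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))

    if comparisons == "all_pairs":
        pairs = list(combinations(range(len(groups)), 2))
    elif comparisons == "vs_control":
        pairs = [(0, j) for j in range(1, len(groups))]
    else:
        raise ValueError(f"unknown comparisons {comparisons!r}")

    raw = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        raw.append((z, p))

    p_raw = [p for _, p in raw]
    if adjustment == "holm_sidak":
        adj, _ = holm_sidak(p_raw)
    elif adjustment == "bonferroni":
        adj = [min(1.0, p * len(p_raw)) for p in p_raw]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    return [
        TestResult(z, float(pa), f"dunn_{adjustment}",
                   (sizes[i], sizes[j]), adjusted=True,
                   comparison=f"{labels[i]} vs {labels[j]}")
        for (i, j), (z, _), pa in zip(pairs, raw, adj)
    ]


def holm_sidak(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Holm-Šídák step-down adjustment.

    Sort the m raw p-values ascending; the i-th (1-based) adjusted value is
    max over j ≤ i of 1 − (1 − p₍ⱼ₎)^(m − j + 1), clipped to 1, which makes
    the adjusted sequence monotone.  Hypotheses are rejected while the
    adjusted p stays ≤ alpha.  Returns (adjusted p, reject flags) in the
    original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        # 1 - (1 - p)^k via expm1/log1p to stay exact for tiny p; the
        # max with the raw p guards the k=1 round-trip (one ulp low)
        with np.errstate(divide="ignore"):  # log1p(-1) = -inf for p = 1
            step = max(-np.expm1((m - i) * np.log1p(-p[idx])), p[idx])
        running = max(running, step)
        adjusted_sorted[i] = min(1.0, running)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    # step-down rejection: stop at the first adjusted p above alpha
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adjusted_sorted[i] <= alpha:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    return adjusted.tolist(), reject.tolist()


def welch_t_battery(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Welch t tests per comparison with Holm-Šídák family correction.

    The multiple-comparison t battery used for quadrant-percentage panels:
    one unpaired unequal-variance t test per quadrant, corrected across the
    family.
    """
    if labels is None:
        labels = [f"comparison{i}" for i in range(len(pairs))]
    raw = []
    for a, b in pairs:
        t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                             equal_var=False)
        raw.append((float(t), float(p) if np.isfinite(p) else 1.0))
    adj, _ = holm_sidak([p for _, p in raw], alpha=alpha)
    return [
        TestResult(t, float(pa), "welch_t_holm_sidak",
                   (len(a), len(b)), adjusted=True, comparison=lbl)
        for (a, b), (t, _), pa, lbl in zip(pairs, raw, adj, labels)
    ]


def results_to_dataframe(results: Sequence[TestResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "n_per_group": "/".join(str(n) for n in r.n_per_group),
                "adjusted": r.adjusted,
            }
            for r in results
        ]
    )
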