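"""Non-parametric comparison of identification tools.

Rubric scores are bounded, heavily tied and far from normal, so tool
comparison relies on rank-based tests:

* Kruskal-Wallis omnibus test (tie corrected) across k tools;
* Dunn-style pairwise z tests on mean pooled ranks with Bonferroni
  adjustment, summarized as a compact letter display (two tools share a
  letter iff their adjusted p >= alpha);
* the (n-1) chi-square test for comparing two proportions: the Pearson
  statistic on the 2x2 table scaled by (N-1)/N, recommended over the
  continuity-corrected test at small N;
* Kendall's coefficient of concordance W for agreement of m rankings of
  n objects, with the standard tie correction.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import ValidationError


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its chi-square approximation."""

    W: float
    m: int  # judges (rankings)
    n: int  # objects ranked
    chi2: float
    p: float


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus Kruskal-Wallis result with pairwise post-hoc letters."""

    H: float
    p: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # fully tied data carry no rank information
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def _pooled_ranks(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate(arrays)
    ranks = scipy.stats.rankdata(pooled)
    return pooled, ranks


def dunn_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Pairwise Dunn z tests on mean pooled ranks, Bonferroni adjusted.

    The z statistic for groups i, j uses the tie-corrected pooled-rank
    variance ``(N(N+1)/12 - T)(1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values are
    multiplied by the number of pairs k(k-1)/2 and capped at 1.
    """
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels must match the number of groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("groups must be non-empty")
    sizes = np.array([a.size for a in arrays], dtype=float)
    n_total = sizes.sum()
    pooled, ranks = _pooled_ranks(arrays)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = k * (k - 1) // 2
    out = pd.DataFrame(np.ones((k, k)), index=list(labels), columns=list(labels))
    for i, j in itertools.combinations(range(k), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            p = 1.0  # fully tied pooled sample
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * scipy.stats.norm.sf(abs(z))
            if adjust:
                p = min(1.0, p * n_pairs)
        out.iat[i, j] = out.iat[j, i] = p
    return out


def assign_letters(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from a symmetric adjusted-p matrix.

    Insert-and-absorb: start with every group in one letter; for each
    significant pair split any letter containing both; drop letters that
    are subsets of others.  The result shares a letter between two groups
    iff their adjusted p >= alpha.
    """
    groups = list(pairwise_p.index)
    letters: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if pairwise_p.loc[a, b] >= alpha:
            continue
        new_letters: list[set[str]] = []
        for member_set in letters:
            if a in member_set and b in member_set:
                new_letters.append(member_set - {a})
                new_letters.append(member_set - {b})
            else:
                new_letters.append(member_set)
        # absorb subsets (keeps the display minimal)
        new_letters = [s for s in new_letters if s]
        letters = [
            s
            for i, s in enumerate(new_letters)
            if not any(s < t or (s == t and i > j) for j, t in enumerate(new_letters))
        ]
    # stable ordering: letters sorted by best (earliest-listed) member
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda s: min(order[g] for g in s))
    alphabet = string.ascii_lowercase
    display = {g: "" for g in groups}
    for i, member_set in enumerate(letters):
        symbol = alphabet[i] if i < 26 else f"l{i}"
        for g in member_set:
            display[g] += symbol
    return display


def pairwise_letters(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Dunn/Bonferroni pairwise tests reduced to a letter display."""
    if len(groups) == 1:
        label = labels[0] if labels else "group1"
        return {label: "a"}
    return assign_letters(dunn_pairwise(groups, labels), alpha)


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Omnibus Kruskal-Wallis plus Dunn/Bonferroni letters in one shot."""
    h, p = kruskal_wallis(groups)
    pairwise = dunn_pairwise(groups, labels)
    return GroupComparison(h, p, pairwise, assign_letters(pairwise, alpha), alpha)


def n_minus_1_chi2(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """(n-1) chi-square test comparing proportions a/n1 and b/n2.

    The statistic is ``(N - 1)/N`` times the Pearson chi-square of the
    2x2 success/failure table, without continuity correction; p comes
    from chi-square with 1 df.  Degenerate margins give (0, 1).
    """
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValidationError("counts must satisfy 0 <= a <= n1 and 0 <= b <= n2")
    n_total = n1 + n2
    if n_total < 2 or n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty and N >= 2")
    successes = a + b
    failures = n_total - successes
    if successes == 0 or failures == 0:
        return 0.0, 1.0
    # Pearson chi-square for a 2x2 table: N (ad - bc)^2 / (r1 r2 c1 c2)
    d1, d2 = n1 - a, n2 - b
    pearson = n_total * (a * d2 - b * d1) ** 2 / (n1 * n2 * successes * failures)
    stat = (n_total - 1) / n_total * pearson
    return float(stat), float(scipy.stats.chi2.sf(stat, df=1))


def kendall_w(rank_matrix: np.ndarray | pd.DataFrame | Sequence[Sequence[float]]) -> ConcordanceResult:
    """Kendall's coefficient of concordance for m rankings of n objects.

    ``rank_matrix`` has one row per judge and one column per object; ties
    within a judge must be encoded as average ranks.  With the per-judge
    tie correction ``T_i = sum(t^3 - t)``::

        W = 12 S / (m^2 (n^3 - n) - m sum(T_i))

    where S is the sum of squared deviations of the object rank sums from
    their mean.  The chi-square approximation is ``chi2 = m (n - 1) W``
    with n - 1 df.
    """
    matrix = np.asarray(rank_matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("rank matrix must be 2-dimensional (judges x objects)")
    m, n = matrix.shape
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 judges and 2 objects")
    expected_sum = n * (n + 1) / 2.0
    for i, row in enumerate(matrix):
        if not np.isclose(row.sum(), expected_sum):
            raise ValidationError(
                f"row {i} does not look like a ranking of {n} objects "
                f"(sum {row.sum()}, expected {expected_sum})"
            )
    rank_sums = matrix.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_total = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_total += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * tie_total
    if denom <= 0:
        raise ValidationError("degenerate rankings: every judge ties all objects")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(scipy.stats.chi2.sf(chi2, df=n - 1))
    return ConcordanceResult(float(w), m, n, float(chi2), p)
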