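"""Vertical/quadrant neglect indices, per-position diagnostic screening, and
the nonparametric statistics around them.

Vertical neglect is probed by comparing omissions above the horizontal
midline (positions 1, 4, 8, 11) against those below it (positions 3, 6, 10,
13), by default with the directional hypothesis down > up (lower-left
quadrant deficits are the common clinical pattern). The comparison is a
Wilcoxon signed-rank test with a matched-pairs rank-biserial effect size.

Exact p-values are computed by enumeration on small samples (<= 12 non-zero
pairs for the signed-rank test; n1*n2 <= 400 for the Mann-Whitney test, both
using tie-corrected ranks) and by a tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .scoring import ScoreSheet

#: position sets above / below the horizontal midline
UP_POSITIONS = (1, 4, 8, 11)
DOWN_POSITIONS = (3, 6, 10, 13)

Alternative = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class VerticalCounts:
    """Summed omissions above vs below the midline, optionally per hemifield."""

    up: int
    down: int
    side_filter: Literal["all", "left_only", "right_only"] = "all"


@dataclass(frozen=True)
class TestResult:
    """A nonparametric test outcome with rank-biserial effect size."""

    statistic: float
    p_value: float
    effect_size_rrb: float
    alternative: Alternative
    n: int | tuple[int, int]
    method: str = ""


def vertical_counts(sheet: ScoreSheet,
                    side_filter: Literal["all", "left_only", "right_only"] = "all"
                    ) -> VerticalCounts:
    """Sum position omissions over the up/down sets, optionally side-restricted."""
    def keep(pid: int) -> bool:
        if side_filter == "left_only":
            return pid <= 7
        if side_filter == "right_only":
            return pid >= 8
        return True

    up = sum(sheet.position_omissions.get(pid, 0) for pid in UP_POSITIONS if keep(pid))
    down = sum(sheet.position_omissions.get(pid, 0) for pid in DOWN_POSITIONS if keep(pid))
    return VerticalCounts(up=up, down=down, side_filter=side_filter)


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float],
                         alternative: Alternative = "two_sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples (b vs a).

    Zero differences are dropped; ties among |differences| receive average
    ranks. W is the positive-rank sum of d = b - a, so ``alternative
    "greater"`` tests whether b tends to exceed a. The p-value comes from
    exhaustive sign enumeration when <= 12 non-zero pairs remain, else from a
    tie-corrected normal approximation. The effect size is the matched-pairs
    rank-biserial correlation (W+ - W-)/(W+ + W-).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: test is degenerate")
    if n < 5:
        warnings.warn("fewer than 5 non-zero differences; p-value is coarse")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = w_plus + w_minus
    rrb = (w_plus - w_minus) / total

    if n <= 12:
        # enumerate all 2^n sign assignments on the observed (tied) ranks
        count_ge = count_le = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count_ge += w >= w_plus - 1e-9
            count_le += w <= w_plus + 1e-9
        m = 2 ** n
        p_greater = count_ge / m
        p_less = count_le / m
        method = "exact enumeration"
    else:
        mean = total / 2.0
        # variance of W+ with average ranks: sum(ranks^2)/4
        sd = np.sqrt((ranks ** 2).sum() / 4.0)
        z_up = (w_plus - mean - 0.5) / sd
        z_dn = (w_plus - mean + 0.5) / sd
        p_greater = float(norm.sf(z_up))
        p_less = float(norm.cdf(z_dn))
        method = "normal approximation (tie-corrected)"

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return TestResult(statistic=w_plus, p_value=float(p), effect_size_rrb=rrb,
                      alternative=alternative, n=n,
                      method=f"Wilcoxon signed-rank, {method}")


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 alternative: Alternative = "two_sided",
                 exact_limit: int = 400) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    U is the statistic of group_a: over all (a, b) pairs, the number where a
    exceeds b, ties counting half. The rank-biserial effect size is
    r_rb = 1 - 2U/(n1*n2), so positive r_rb means group_b tends to exceed
    group_a. Exact p by enumeration of group assignments when
    n1*n2 <= exact_limit, else a tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)
    rrb = 1.0 - 2.0 * u / (n1 * n2)

    if n1 * n2 <= exact_limit:
        count_ge = count_le = total = 0
        idx = range(n1 + n2)
        for picked in itertools.combinations(idx, n1):
            ru = float(ranks[list(picked)].sum() - n1 * (n1 + 1) / 2.0)
            count_ge += ru >= u - 1e-9
            count_le += ru <= u + 1e-9
            total += 1
        p_greater = count_ge / total
        p_less = count_le / total
        method = "exact enumeration"
    else:
        n = n1 + n2
        mean = n1 * n2 / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        p_greater = float(norm.sf((u - mean - 0.5) / sd))
        p_less = float(norm.cdf((u - mean + 0.5) / sd))
        method = "normal approximation (tie-corrected)"

    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    return TestResult(statistic=u, p_value=float(p), effect_size_rrb=rrb,
                      alternative=alternative, n=(n1, n2),
                      method=f"Mann-Whitney U, {method}")


def holm_adjust(p_values: Sequence[float], alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and reject decisions at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


def phi_coefficient(table_2x2: Sequence[Sequence[float]]) -> float | None:
    """Guilford's phi for a 2x2 contingency table [[a, b], [c, d]].

    Equals the Pearson correlation of the two underlying binary variables.
    Returns None with a warning if any margin is zero.
    """
    (a, b), (c, d) = table_2x2
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        warnings.warn("phi undefined: a table margin is zero")
        return None
    return float((a * d - b * c) / np.sqrt(np.prod([float(m) for m in margins])))


def _lower_median(values: np.ndarray) -> float:
    """Median as a sample value: lower of the two middle order statistics."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def position_diagnostics(cohort_sheets: Sequence[ScoreSheet],
                         labels: Sequence[str]) -> pd.DataFrame:
    """Screen each target position as a standalone diagnostic marker.

    Per position the omission counts are binarized at the pooled-cohort
    median (>= median codes 1, i.e. "impaired"); sensitivity is the impaired
    share of the neglect group and specificity the unimpaired share of the
    no-neglect group. A position at which the whole cohort scores the median
    (e.g. all zeros) codes every subject 1 and yields sensitivity 1 /
    specificity 0, which is flagged.
    """
    labels = np.asarray(labels)
    if len(cohort_sheets) != len(labels):
        raise ValueError("sheets and labels must align")
    for cls in ("neglect", "no_neglect"):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need >= 2 subjects labelled {cls}")
    pids = sorted(cohort_sheets[0].position_omissions)
    rows = []
    is_neglect = labels == "neglect"
    for pid in pids:
        counts = np.array([s.position_omissions[pid] for s in cohort_sheets], dtype=float)
        med = _lower_median(counts)
        coded = counts >= med
        sens = coded[is_neglect].mean()
        spec = (~coded[~is_neglect]).mean()
        degenerate = bool(coded.all())
        if degenerate:
            warnings.warn(f"position {pid}: constant coding (all >= median); "
                          "specificity is 0 by construction")
        rows.append({"position": pid, "median": med, "sensitivity": sens,
                     "specificity": spec, "degenerate": degenerate})
    return pd.DataFrame(rows)
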