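"""Group statistics: Shapiro-Wilk normality gate, two-group tests, and the
significance-star convention.

Two groups are compared with the two-tailed t-test when both pass the
Shapiro-Wilk normality gate (p >= 0.05) and with the two-tailed
Mann-Whitney U test otherwise.  Stars follow the convention
*p < 0.01, **p < 0.001, ***p < 0.0001 (boundary values get the weaker
label).  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "NORMALITY_GATE_LEVEL",
    "shapiro_gate",
    "compare_groups",
    "significance_stars",
    "summarize",
]

#: Shapiro-Wilk gate level for choosing the parametric test.
NORMALITY_GATE_LEVEL = 0.05

#: Star thresholds, strictest first.
STAR_THRESHOLDS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


@dataclass
class GroupComparison:
    """Result of one two-group comparison."""

    test_name: str  # "t" or "mann-whitney"
    statistic: float
    p_value: float
    stars: str
    normality_p: tuple[float, float]
    n: tuple[int, int]

    def __str__(self) -> str:
        return (
            f"{self.test_name} test (n={self.n[0]}/{self.n[1]}): "
            f"p = {self.p_value:.3g} {self.stars or 'n.s.'}"
        )


def shapiro_gate(sample: np.ndarray, level: float = NORMALITY_GATE_LEVEL) -> tuple[float, bool]:
    """Shapiro-Wilk normality p-value and pass/fail at ``level``.

    A sample passes (is treated as normal) when p >= level.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: normality undefined")
    stat, p = sps.shapiro(x)
    return float(p), bool(p >= level)


def significance_stars(p: float) -> str:
    """Map a p-value to the star label; boundary values take the weaker one."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value must lie in [0, 1]")
    for thr, label in STAR_THRESHOLDS:
        if p < thr:
            return label
    return ""


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    welch: bool = True,
    gate_level: float = NORMALITY_GATE_LEVEL,
) -> GroupComparison:
    """Two-tailed two-group test with a normality gate.

    Both samples are gated with Shapiro-Wilk; if both pass, a two-tailed
    t-test is used (Welch's unequal-variance form by default,
    ``welch=False`` for the pooled-variance form), otherwise the two-tailed
    Mann-Whitney U test.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    p_a, pass_a = shapiro_gate(a, gate_level)
    p_b, pass_b = shapiro_gate(b, gate_level)
    if pass_a and pass_b:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        name = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    return GroupComparison(
        name, float(stat), float(p), significance_stars(float(p)), (p_a, p_b), (a.size, b.size)
    )


def summarize(sample: np.ndarray, normality_pass: bool = True) -> tuple[float, float | None, str]:
    """Mean, standard error, and a formatted summary string.

    The SE (= sd/sqrt(n)) is reported only for samples that passed the
    normality gate; otherwise the summary carries the mean alone.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    if normality_pass:
        return mean, se, f"{mean:.4g} ± {se:.2g}"
    return mean, None, f"{mean:.4g}"
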