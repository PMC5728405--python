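"""Condition-level statistics shared by all assays.

Mean +/- SEM summaries, two-tailed two-sample t-tests (Student pooled
variance by default, matching the figure-legend wording, with Welch as an
option), the star-annotation convention used throughout the figures
(* P < 0.05, ** P < 0.005, *** P < 0.0005), and clonogenic
surviving-fraction arithmetic normalized to plating efficiency.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .exceptions import ParameterError

__all__ = [
    "mean_sem",
    "two_tailed_t",
    "star_annotation",
    "plating_efficiency",
    "surviving_fraction",
    "DEFAULT_STAR_TIERS",
]

#: (threshold, label) tiers, strongest first.  The figures use the unusual
#: 0.005 middle tier (one panel prints ** P < 0.001; the majority
#: convention is the default and the tiers are configurable).
DEFAULT_STAR_TIERS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (sd with n-1 denominator / sqrt n).

    SEM is NaN for a single value (undefined, not zero).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("mean_sem needs at least one value")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return mean, sem


def two_tailed_t(a, b, variant: str = "student") -> float:
    """Two-sided two-sample t-test p-value.

    ``variant='student'`` pools the variance (the classical Student test the
    figure legends cite); ``'welch'`` drops the equal-variance assumption.
    Identical groups return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def star_annotation(p: float, tiers=DEFAULT_STAR_TIERS) -> str:
    """Figure-style significance label: 'ns', '*', '**' or '***'."""
    if not (0 <= p <= 1):
        raise ParameterError("p must lie in [0, 1]")
    for threshold, label in sorted(tiers):
        if p < threshold:
            return label
    return "ns"


def plating_efficiency(untreated_colonies: float, untreated_seeded: float) -> float:
    """Colonies per cell seeded in the untreated plate of one knockdown."""
    if untreated_seeded <= 0:
        raise ParameterError("seeded cell count must be > 0")
    if untreated_colonies < 0:
        raise ParameterError("colony count must be >= 0")
    return untreated_colonies / untreated_seeded


def surviving_fraction(colonies: float, seeded: float, plating_eff: float) -> float:
    """Clonogenic surviving fraction: (colonies/seeded) / plating efficiency.

    The untreated point of each knockdown defines its plating efficiency, so
    its own surviving fraction is exactly 1.
    """
    if seeded <= 0:
        raise ParameterError("seeded cell count must be > 0")
    if plating_eff <= 0:
        raise ParameterError("plating efficiency must be > 0")
    if colonies < 0:
        raise ParameterError("colony count must be >= 0")
    return (colonies / seeded) / plating_eff
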