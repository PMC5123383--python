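"""Fuzzy and punctual log2 fold change.

The fold change between two fuzzy read counts is itself fuzzy.  By the
extension principle it is approximated by a trapezoid over log2 fold-change
values whose endpoints divide opposite ends of the two count trapezoids:

``Tr[ log2(A'_case / D'_ctrl), log2(B_case / C_ctrl),
      log2(C_case / B_ctrl),  log2(D'_case / A'_ctrl) ]``

with ``A' = A - 1`` (clipped at 0) and ``D' = D + 1``.  A zero numerator or
denominator yields an infinite endpoint — a legal value, serialised as
"Inf"/"-Inf" — optionally avoided with a pseudocount.  The downstream DE
possibility engine never consumes the fuzzy fold change (it intersects the
two-dimensional count relation directly), so infinities affect reporting
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fuzzy_counts import TrapezoidalCount

__all__ = ["FuzzyFoldChange", "fuzzy_fc", "punctual_fc", "log2_ratio"]


def log2_ratio(num: float, den: float) -> float:
    """log2(num/den) on extended reals; 0/0 is 0 by the no-evidence convention."""
    if num == 0.0 and den == 0.0:
        return 0.0
    if num == 0.0:
        return -math.inf
    if den == 0.0:
        return math.inf
    return math.log2(num) - math.log2(den)  # no under/overflow of the ratio


@dataclass(frozen=True)
class FuzzyFoldChange:
    """Trapezoidal fuzzy set over log2(case/control); endpoints may be ±inf."""

    f1: float
    f2: float
    f3: float
    f4: float

    def __iter__(self):
        return iter((self.f1, self.f2, self.f3, self.f4))

    @property
    def core(self) -> tuple[float, float]:
        return (self.f2, self.f3)

    def negated(self) -> "FuzzyFoldChange":
        """Mirror around 0 (the fold change of the swapped comparison)."""
        return FuzzyFoldChange(-self.f4, -self.f3, -self.f2, -self.f1)


def fuzzy_fc(
    case: TrapezoidalCount, control: TrapezoidalCount, pseudo: float = 0.0
) -> FuzzyFoldChange:
    """Fuzzy log2 fold change of case over control.

    ``pseudo`` > 0 is added to every numerator and denominator, trading the
    infinite endpoints of zero counts for a conventional shrinkage.
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    a1 = max(case.a - 1.0, 0.0) + pseudo
    d1 = case.d + 1.0 + pseudo
    a2 = max(control.a - 1.0, 0.0) + pseudo
    d2 = control.d + 1.0 + pseudo
    return FuzzyFoldChange(
        log2_ratio(a1, d2),
        log2_ratio(case.b + pseudo, control.c + pseudo),
        log2_ratio(case.c + pseudo, control.b + pseudo),
        log2_ratio(d1, a2),
    )


def punctual_fc(
    case_centroid: float, control_centroid: float, pseudo: float = 0.0
) -> float:
    """Punctual log2 fold change of the two centroid counts.

    With ``pseudo`` 0 a single zero centroid gives ±inf; both zero gives 0
    (no evidence of change).
    """
    if case_centroid < 0 or control_centroid < 0:
        raise ValueError("centroids must be non-negative")
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    return log2_ratio(case_centroid + pseudo, control_centroid + pseudo)
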