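"""Inter-rater agreement statistics for nominal lesion ratings.

Two independent observers rate the same image sets with the decision
algorithm; reliability is summarized by the percent observed agreement and
Cohen's unweighted kappa,

    kappa = (p_o - p_e) / (1 - p_e),

with p_o the observed agreement proportion and p_e the chance agreement
expected from the raters' marginal label frequencies.  Only the unweighted
point estimate is computed (nominal categories, no partial credit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional, Sequence, Tuple

__all__ = ["RatingTable", "AgreementResult", "percent_agreement", "cohen_kappa", "evaluate_agreement"]


@dataclass(frozen=True)
class RatingTable:
    """Paired nominal ratings (rater A, rater B) over the same items.

    The category set defaults to the union of observed labels; unobserved
    categories change neither p_o nor p_e.
    """

    items: Tuple[Tuple[Hashable, Hashable], ...]
    categories: Optional[Tuple[Hashable, ...]] = None

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise ValueError("rating table must contain at least one item")
        observed = {r for pair in self.items for r in pair}
        if self.categories is None:
            object.__setattr__(self, "categories", tuple(sorted(observed, key=repr)))
        elif not observed <= set(self.categories):
            raise ValueError("ratings outside the declared category set")

    @classmethod
    def from_pairs(cls, a: Sequence[Hashable], b: Sequence[Hashable]) -> "RatingTable":
        if len(a) != len(b):
            raise ValueError("rating vectors must have equal length")
        return cls(tuple(zip(a, b)))


@dataclass(frozen=True)
class AgreementResult:
    n_items: int
    n_agree: int
    percent_agreement: float
    kappa: float


def percent_agreement(table: RatingTable) -> float:
    """100 x (number of concordant items) / (number of items)."""
    n = len(table.items)
    agree = sum(1 for a, b in table.items if a == b)
    return 100.0 * agree / n


def cohen_kappa(table: RatingTable) -> float:
    """Cohen's unweighted kappa for two raters on nominal categories.

    With degenerate marginals (p_e = 1: both raters constant on the same
    single category) perfect agreement is defined as kappa = 1.
    """
    n = len(table.items)
    p_o = sum(1 for a, b in table.items if a == b) / n
    marg_a: dict = {}
    marg_b: dict = {}
    for a, b in table.items:
        marg_a[a] = marg_a.get(a, 0) + 1
        marg_b[b] = marg_b.get(b, 0) + 1
    p_e = sum(marg_a.get(k, 0) * marg_b.get(k, 0) for k in table.categories) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise AssertionError("p_e = 1 with p_o < 1 is impossible for paired marginals")
    return (p_o - p_e) / (1.0 - p_e)


def evaluate_agreement(table: RatingTable) -> AgreementResult:
    n = len(table.items)
    agree = sum(1 for a, b in table.items if a == b)
    return AgreementResult(n, agree, percent_agreement(table), cohen_kappa(table))
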