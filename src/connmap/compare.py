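"""Cross-platform comparison of candidate-compound lists.

Two queries of the same biology — e.g. an RNA-seq-derived signature and a
microarray-derived one — each yield a list of stable significant compounds.
This module measures how compatible the two technologies are: the overlap of
the lists, its exact hypergeometric upper-tail significance on the compound
population, and the concordance of connection directions among shared hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .scoring import ConnectionResult

__all__ = ["OverlapResult", "overlap_significant", "sign_concordance", "stable_hits"]


@dataclass(frozen=True)
class OverlapResult:
    n_A: int
    n_B: int
    n_overlap: int
    population: int
    p_hyper: float
    overlap: tuple[str, ...]

    @property
    def expected_overlap(self) -> float:
        """Null expectation n_A * n_B / D."""
        return self.n_A * self.n_B / self.population


def overlap_significant(
    list_a: Sequence[str], list_b: Sequence[str], population: int
) -> OverlapResult:
    """Overlap of two duplicate-free compound lists and its exact
    hypergeometric upper-tail p-value P(X >= n_overlap), with
    X ~ Hypergeometric(population, n_A, n_B).

    The >=-tail (not >) is the standard enrichment convention; disjoint
    lists give P(X >= 0) = 1. Symmetric in the two lists.
    """
    a, b = list(list_a), list(list_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("compound lists must be duplicate-free")
    if len(a) > population or len(b) > population:
        raise ValueError(
            f"list sizes ({len(a)}, {len(b)}) exceed population {population}"
        )
    shared = tuple(sorted(set(a) & set(b)))
    k = len(shared)
    # upper tail P(X >= k) = sf(k - 1)
    p = float(stats.hypergeom.sf(k - 1, population, len(a), len(b)))
    p = min(max(p, 0.0), 1.0)
    return OverlapResult(
        n_A=len(a),
        n_B=len(b),
        n_overlap=k,
        population=population,
        p_hyper=p,
        overlap=shared,
    )


def stable_hits(results: Sequence[ConnectionResult]) -> list[str]:
    """Compounds with a significant connection of full perturbation
    stability — the population entering the cross-platform overlap."""
    return [
        r.compound
        for r in results
        if r.sig == 1 and r.perturbation_stability == 1.0
    ]


def sign_concordance(
    results_a: Sequence[ConnectionResult],
    results_b: Sequence[ConnectionResult],
    overlap: Sequence[str],
) -> float:
    """Fraction of shared compounds whose setscores agree in direction.

    Both result lists must contain every overlap compound with a nonzero
    setscore (a zero setscore has no direction). Empty overlap returns NaN.
    """
    if not overlap:
        return math.nan
    score_a = {r.compound: r.setscore for r in results_a}
    score_b = {r.compound: r.setscore for r in results_b}
    agree = 0
    for c in overlap:
        if c not in score_a or c not in score_b:
            raise ValueError(f"overlap compound {c!r} missing from a result list")
        sa, sb = score_a[c], score_b[c]
        if sa == 0 or sb == 0:
            raise ValueError(f"compound {c!r} has a zero setscore; direction undefined")
        agree += int(math.copysign(1, sa) == math.copysign(1, sb))
    return agree / len(overlap)
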