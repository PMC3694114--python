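"""Single-gene-omission perturbation and connection stability.

A discovered connection is only worth pursuing if it survives small
agitations of the query signature. Here each of the m probes is omitted in
turn (and restored before the next omission), the m perturbed signatures of
length m-1 are re-queried against the database at their own length's
Bonferroni threshold, and each significant compound receives a stability
score: the fraction of perturbed queries in which it stayed significant.
A stability of 1 means the connection withstood every omission.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .profiles import ReferenceDatabase
from .scoring import ConnectionResult, QueryConfig, query_database
from .signature import GeneSignature

__all__ = ["PerturbationReport", "perturb_signature", "stability", "attach_stability"]


@dataclass(frozen=True)
class PerturbationReport:
    compound: str
    n_perturbations: int
    n_surviving: int

    @property
    def stability(self) -> float:
        return self.n_surviving / self.n_perturbations


def perturb_signature(sig: GeneSignature) -> list[GeneSignature]:
    """The m leave-one-out variants of a signature, order preserved.

    Variant i omits entry i; the omitted entry is restored before the next
    omission, so every variant has length m-1 and their union recovers the
    original signature.
    """
    if sig.m < 2:
        raise ValueError("perturbation needs a signature of length >= 2")
    out = []
    for i in range(sig.m):
        probes = sig.probe_ids[:i] + sig.probe_ids[i + 1 :]
        signs = sig.signs[:i] + sig.signs[i + 1 :]
        out.append(GeneSignature(probes, signs, name=f"{sig.name}~omit{i}"))
    return out


def stability(
    sig: GeneSignature,
    db: ReferenceDatabase,
    cfg: QueryConfig,
    base: Sequence[ConnectionResult],
) -> list[PerturbationReport]:
    """Perturbation stability of every base-significant compound.

    ``base`` must be the query_database output for ``sig`` under the same
    cfg. Each perturbed signature is re-queried with cfg.seed offset by its
    perturbation index (1-based), drawing a fresh null stream for length
    m-1, and judged at the same alpha_family / D threshold. Compounds not
    significant in ``base`` carry no stability and are not reported.
    """
    significant = [r.compound for r in base if r.sig == 1]
    if not significant:
        return []
    survived = {c: 0 for c in significant}
    for i, psig in enumerate(perturb_signature(sig)):
        pres = query_database(psig, db, replace(cfg, seed=cfg.seed + 1 + i))
        sig_now = {r.compound for r in pres if r.sig == 1}
        for c in significant:
            if c in sig_now:
                survived[c] += 1
    return [
        PerturbationReport(
            compound=c, n_perturbations=sig.m, n_surviving=survived[c]
        )
        for c in significant
    ]


def attach_stability(
    base: Sequence[ConnectionResult], reports: Sequence[PerturbationReport]
) -> list[ConnectionResult]:
    """Merge stability scores into the significant rows of a result list."""
    by_compound = {rep.compound: rep.stability for rep in reports}
    out = []
    for r in base:
        if r.compound in by_compound:
            r = replace_result(r, by_compound[r.compound])
        out.append(r)
    return out


def replace_result(r: ConnectionResult, stab: float) -> ConnectionResult:
    from dataclasses import replace as _replace

    return _replace(r, perturbation_stability=stab)
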