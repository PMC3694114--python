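"""Connection scoring with randomization-based significance.

The connection strength of an m-probe signature against a reference profile
is c = sum_i s(g_i) * R(g_i), where s is the signature sign and R the
profile's signed rank of probe g_i. Normalising by the maximum attainable
strength c_max = sum_{i=1..m} (N - i + 1) gives the connection score
C = c / c_max in [-1, 1]: C = +1 exactly when the signature probes occupy
the top m rank magnitudes with matching signs, C = -1 for the perfectly
inverse arrangement.

A compound's *setscore* is the mean connection score over its replicate
profiles. Significance is gauged by randomization: random signatures of the
same length (distinct probes drawn uniformly from the universe, the query's
multiset of signs assigned in random order) are scored against each set with
the same combination rule, and the two-sided p-value is the add-one-smoothed
fraction of random |setscores| at least as extreme as the observed one.
A connection is declared significant when p <= alpha_family / D, the
family-wise (Bonferroni) threshold over the D compound sets; with the
default alpha_family = 1 the expected number of false positives over the
whole database is at most one, so the achieved FDR is estimated as
alpha_family / n_significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import ProbeUniverse, ReferenceDatabase, ReferenceProfile, ReferenceSet
from .signature import GeneSignature

__all__ = [
    "QueryConfig",
    "ConnectionResult",
    "connection_score",
    "score_from_ranks",
    "set_score",
    "scores_from_ranks",
    "estimate_pvalue",
    "query_database",
    "estimate_fdr",
    "rank_results",
    "results_to_frame",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class QueryConfig:
    """Settings for one database query.

    alpha_family is the family-wise expected-false-positive budget: each of
    the D reference sets is tested at alpha_family / D. n_random is the
    number of random signatures in the null stream; it must be large enough
    to resolve p-values at the Bonferroni threshold (n_random >= 10 D /
    alpha_family). One null stream is drawn per (query length, database) and
    shared across all sets of that query.
    """

    alpha_family: float = 1.0
    fdr_target: float = 0.01
    n_random: int = 1_000_000
    seed: int = 0
    perturb_mode: str = "omit"  # "omit" = leave-one-out with restoration

    def __post_init__(self) -> None:
        if not (0 < self.alpha_family <= 1):
            raise ScoringError("alpha_family must be in (0, 1]")
        if self.n_random < 1:
            raise ScoringError("n_random must be positive")
        if self.perturb_mode != "omit":
            raise ScoringError(f"unknown perturb_mode {self.perturb_mode!r}")

    def validate_for(self, D: int) -> None:
        need = 10 * D / self.alpha_family
        if self.n_random < need:
            raise ScoringError(
                f"n_random={self.n_random} cannot resolve the Bonferroni "
                f"threshold alpha/D={self.alpha_family / D:.3g} over D={D} "
                f"sets; need >= {math.ceil(need)}"
            )


@dataclass
class ConnectionResult:
    """Scored connection of one query signature to one compound set."""

    compound: str
    setsize: int
    query_name: str
    query_length: int
    setscore: float
    pvalue: float
    sig: int
    perturbation_stability: Optional[float] = None


def _c_max(N: int, m: int) -> float:
    if m > N:
        raise ScoringError(f"signature length m={m} exceeds universe size N={N}")
    # sum of the m largest magnitudes N, N-1, ..., N-m+1
    return m * N - m * (m - 1) / 2


def score_from_ranks(signs: Sequence[int], ranks: Sequence[float], N: int) -> float:
    """Connection score from signature signs and their signed ranks alone.

    Sufficient for scoring against published per-probe signed-rank excerpts,
    where the full profile is unavailable but N is known. ``ranks`` may be
    replicate-averaged (float), in which case this returns the setscore.
    """
    signs = np.asarray(signs, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if signs.shape != ranks.shape:
        raise ScoringError("signs and ranks differ in length")
    return float(np.dot(signs, ranks) / _c_max(N, len(signs)))


def scores_from_ranks(signs: Sequence[int], rank_matrix, N: int) -> tuple[float, np.ndarray]:
    """(setscore, per-replicate scores) from an m x K signed-rank matrix."""
    mat = np.asarray(rank_matrix, dtype=float)
    per = np.array([score_from_ranks(signs, mat[:, k], N) for k in range(mat.shape[1])])
    return float(per.mean()), per


def connection_score(sig: GeneSignature, profile: ReferenceProfile) -> float:
    """Normalised signed-rank connection score of a signature to one profile."""
    try:
        ranks = profile.ranks_for(sig.probe_ids)
    except KeyError as exc:
        raise ScoringError(str(exc)) from None
    return score_from_ranks(sig.signs, ranks, profile.universe.N)


def set_score(sig: GeneSignature, refset: ReferenceSet) -> float:
    """Mean connection score over the set's replicate profiles."""
    return float(
        np.mean([connection_score(sig, p) for p in refset.profiles])
    )


def _sample_distinct(rng: np.random.Generator, n: int, N: int, m: int) -> np.ndarray:
    """n rows of m distinct probe indices, uniform over m-subsets of 0..N-1.

    Rejection on rows with duplicates; for m << N almost all rows pass on
    the first draw.
    """
    if m >= N:
        raise ScoringError(
            f"m={m} >= N={N}: randomization null is degenerate"
        )
    idx = rng.integers(0, N, size=(n, m))
    while True:
        sorted_idx = np.sort(idx, axis=1)
        bad = (np.diff(sorted_idx, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, N, size=(int(bad.sum()), m))


class NullStream:
    """Shared stream of random signatures for one (query length, database).

    Holds an (n_random, m) matrix of probe indices and a matching matrix of
    signs (the query's sign multiset, independently shuffled per draw). The
    same stream scores every reference set of one query, mirroring a single
    randomization benchmark per signature size.
    """

    def __init__(
        self,
        universe: ProbeUniverse,
        signs: Sequence[int],
        n_random: int,
        rng: np.random.Generator,
    ):
        m = len(signs)
        N = universe.N
        self.c_max = _c_max(N, m)
        self.idx = _sample_distinct(rng, n_random, N, m)
        self.signs = rng.permuted(
            np.tile(np.asarray(signs, dtype=np.int8), (n_random, 1)), axis=1
        )
        self.n_random = n_random

    def abs_set_scores(self, mean_rank: np.ndarray) -> np.ndarray:
        """|setscore| of every random signature against one reference set,
        given the set's per-probe mean signed-rank vector."""
        raw = np.einsum("ij,ij->i", self.signs, mean_rank[self.idx])
        return np.abs(raw) / self.c_max

    def pvalue(self, mean_rank: np.ndarray, observed: float) -> float:
        b = int(np.count_nonzero(self.abs_set_scores(mean_rank) >= abs(observed) - 1e-12))
        return (b + 1) / (self.n_random + 1)


def _stream_seed(seed: int, m: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, m, salt])


def estimate_pvalue(
    sig: GeneSignature, refset: ReferenceSet, cfg: QueryConfig
) -> float:
    """Two-sided randomization p-value of a signature against one set.

    Draws cfg.n_random random signatures of the same length with the query's
    sign multiset and reports the add-one-smoothed fraction whose |setscore|
    is at least the observed |setscore|; never returns 0, so Bonferroni
    scaling stays valid. Deterministic given cfg.seed.
    """
    stream = NullStream(
        refset.universe, sig.signs, cfg.n_random, _stream_seed(cfg.seed, sig.m)
    )
    obs = set_score(sig, refset)
    return stream.pvalue(refset.mean_signed_rank(), obs)


def query_database(
    sig: GeneSignature, db: ReferenceDatabase, cfg: QueryConfig
) -> list[ConnectionResult]:
    """Score a signature against every compound set in the database.

    One null stream is drawn per query (seeded by (cfg.seed, m)) and reused
    across all D sets; each set's two-sided p-value is compared against the
    Bonferroni threshold alpha_family / D.
    """
    if sig.m == 0:
        raise ScoringError("empty query signature")
    cfg.validate_for(db.D)
    try:
        sig_idx = db.universe.index_of(sig.probe_ids)
    except KeyError as exc:
        raise ScoringError(str(exc)) from None
    stream = NullStream(
        db.universe, sig.signs, cfg.n_random, _stream_seed(cfg.seed, sig.m)
    )
    threshold = cfg.alpha_family / db.D
    sign_arr = sig.sign_array().astype(float)
    results = []
    for refset in db.sets:
        mean_rank = refset.mean_signed_rank()
        obs = float(np.dot(sign_arr, mean_rank[sig_idx]) / stream.c_max)
        p = stream.pvalue(mean_rank, obs)
        results.append(
            ConnectionResult(
                compound=refset.compound,
                setsize=refset.setsize,
                query_name=sig.name,
                query_length=sig.m,
                setscore=obs,
                pvalue=p,
                sig=int(p <= threshold),
            )
        )
    return results


def estimate_fdr(n_sig: int, cfg: QueryConfig) -> float:
    """Achieved-FDR estimate after Bonferroni selection.

    With each of D sets tested at alpha_family / D, the expected number of
    false positives is at most alpha_family, so FDR_est = alpha_family /
    n_significant; infinity when nothing was significant.
    """
    if n_sig < 0:
        raise ScoringError("n_sig must be >= 0")
    if n_sig == 0:
        return math.inf
    return cfg.alpha_family / n_sig


def rank_results(results: Sequence[ConnectionResult]) -> list[ConnectionResult]:
    """Prioritise significant connections.

    Keeps sig = 1 rows only and orders by perturbation stability (desc),
    then setsize (desc), then |setscore| (desc), ties broken by compound
    name. Stability must be populated on every significant row.
    """
    kept = [r for r in results if r.sig == 1]
    for r in kept:
        if r.perturbation_stability is None:
            raise ScoringError(
                f"significant result {r.compound!r} lacks perturbation stability"
            )
    return sorted(
        kept,
        key=lambda r: (
            -r.perturbation_stability,
            -r.setsize,
            -abs(r.setscore),
            r.compound,
        ),
    )


RESULT_COLUMNS = [
    "refsetname",
    "setsize",
    "queryName",
    "queryLength",
    "setscore",
    "pvalue",
    "sig",
    "Per",
]


def results_to_frame(results: Sequence[ConnectionResult]) -> pd.DataFrame:
    """Results as a table with the conventional column names
    (refsetname, setsize, queryName, queryLength, setscore, pvalue, sig, Per)."""
    return pd.DataFrame(
        [
            {
                "refsetname": r.compound,
                "setsize": r.setsize,
                "queryName": r.query_name,
                "queryLength": r.query_length,
                "setscore": r.setscore,
                "pvalue": r.pvalue,
                "sig": r.sig,
                "Per": (
                    "" if r.perturbation_stability is None else r.perturbation_stability
                ),
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )


def results_from_frame(df: pd.DataFrame, query_name: str = "query") -> list[ConnectionResult]:
    out = []
    for row in df.itertuples(index=False):
        per = getattr(row, "Per", "")
        out.append(
            ConnectionResult(
                compound=str(row.refsetname),
                setsize=int(row.setsize),
                query_name=str(getattr(row, "queryName", query_name)),
                query_length=int(getattr(row, "queryLength", 0)),
                setscore=float(row.setscore),
                pvalue=float(getattr(row, "pvalue", math.nan)),
                sig=int(row.sig),
                perturbation_stability=(
                    None if per in ("", None) or (isinstance(per, float) and math.isnan(per))
                    else float(per)
                ),
            )
        )
    return out
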