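import numpy as np
import pytest

from connmap import (
    GeneSignature,
    ProbeUniverse,
    ReferenceDatabase,
    ReferenceProfile,
    ReferenceSet,
)


@pytest.fixture
def abc_universe():
    return ProbeUniverse(("A", "B", "C"))


@pytest.fixture
def five_probe_profile():
    """N=5 profile with signed ranks {A:+5, B:-4, C:+3, D:-2, E:+1}."""
    uni = ProbeUniverse(("A", "B", "C", "D", "E"))
    return ReferenceProfile(
        profile_id="p1",
        compound="drugX",
        universe=uni,
        signed_rank=np.array([5, -4, 3, -2, 1]),
    )


@pytest.fixture
def four_probe_set():
    """K=1 reference set over N=4 with ranks {A:+4, B:-3, C:+2, D:-1}."""
    uni = ProbeUniverse(("A", "B", "C", "D"))
    profile = ReferenceProfile(
        profile_id="q1",
        compound="drugY",
        universe=uni,
        signed_rank=np.array([4, -3, 2, -1]),
    )
    return ReferenceSet("drugY", (profile,))


def make_profile(universe, signed_rank, profile_id="p", compound="c"):
    return ReferenceProfile(
        profile_id=profile_id,
        compound=compound,
        universe=universe,
        signed_rank=np.asarray(signed_rank),
    )


def random_database(N=50, D=8, K=2, seed=0, universe=None):
    """Small pure-null database of uniform signed permutations."""
    rng = np.random.default_rng(seed)
    universe = universe or ProbeUniverse(tuple(f"pr{i}" for i in range(N)))
    sets = []
    for j in range(D):
        profiles = tuple(
            make_profile(
                universe,
                rng.choice((-1, 1), size=N) * (rng.permutation(N) + 1),
                profile_id=f"c{j}_r{k}",
                compound=f"c{j}",
            )
            for k in range(K)
        )
        sets.append(ReferenceSet(f"c{j}", profiles))
    return ReferenceDatabase(universe=universe, sets=tuple(sets))


def exhaustive_pvalue(sig: GeneSignature, refset: ReferenceSet) -> float:
    """Exact two-sided null p-value by enumeration of every gene subset and
    every distinct assignment of the query's sign multiset.

    Independent oracle for the sampled randomization p-value: feasible for
    N <= 8, m <= 3. Works in exact integer arithmetic on the summed signed
    ranks (scaled by setsize to stay integral).
    """
    from fractions import Fraction
    from itertools import combinations, permutations

    uni = refset.universe
    N, m = uni.N, sig.m
    # integer rank sums across replicates (K * mean rank)
    rank_sum = np.sum([p.signed_rank for p in refset.profiles], axis=0)
    obs = abs(
        sum(
            s * int(rank_sum[uni.index_of([p])[0]])
            for p, s in zip(sig.probe_ids, sig.signs)
        )
    )
    sign_orders = sorted(set(permutations(sig.signs)))
    total = 0
    extreme = 0
    for subset in combinations(range(N), m):
        for signs in sign_orders:
            c = abs(sum(s * int(rank_sum[i]) for s, i in zip(signs, subset)))
            total += 1
            extreme += int(c >= obs)
    return Fraction(extreme, total)
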