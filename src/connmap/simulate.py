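"""Synthetic reference databases, DE tables and annotation maps.

The generator emulates the study conditions end-to-end so the whole
pipeline is testable without any downloads: a probe universe standing in
for a microarray platform, a population of compound reference sets with
1-32 replicate signed-rank profiles each, and a ranked DE table whose top
genes map (through a synthetic annotation with unmapped and multi-probe
genes) onto a signature that is planted into chosen compounds at a tunable
connection strength.

Null profiles are independent uniform signed permutations: the rank
magnitudes are a uniform permutation of 1..N and every sign is an
independent fair coin. A planted profile starts as a null profile, then the
planted signature's probes are moved to the top magnitudes N, N-1, ... with
matching signs (direction -1 flips them), and finally each planted probe is
independently swapped with a uniformly chosen probe with probability
1 - lambda. Swapping ranks (rather than adding rank noise) keeps every
profile an exact signed permutation at every strength; lambda = 1 forces a
connection score of exactly +/-1 on every replicate, lambda = 0 is
indistinguishable from null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    ProbeUniverse,
    ReferenceDatabase,
    ReferenceProfile,
    ReferenceSet,
)
from .signature import AnnotationMap, DETable, GeneSignature

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "gen_reference_db",
    "gen_de_table",
    "gen_pipeline_inputs",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape of a synthetic study.

    Desk-scale defaults (N = 2,000 probes, D = 200 compounds) keep a full
    pipeline run under a minute; :meth:`paper_scale` switches to the
    platform-scale universe (N = 22,283, the HG-U133A probe count) and the
    full compound population (D = 1,309) with setsizes up to 32.

    ``planted`` lists (compound, strength lambda in [0, 1], direction +/-1)
    triples; every other compound is pure null. ``n_signature`` is the
    length of the planted signature, drawn from the DE table's top mappable
    probes so that signature construction and planting agree.
    """

    N: int = 2_000
    D: int = 200
    K_range: tuple[int, int] = (1, 8)
    planted: tuple[tuple[str, float, int], ...] = ()
    n_genes: int = 500
    n_signal: int = 50
    n_signature: int = 10
    unmapped_frac: float = 0.3
    multiprobe_frac: float = 0.2
    signal_lfc_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.D < 1:
            raise ValueError("need N >= 2 and D >= 1")
        lo, hi = self.K_range
        if not (1 <= lo <= hi):
            raise ValueError("K_range must satisfy 1 <= lo <= hi")
        for compound, lam, direction in self.planted:
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"planted strength for {compound!r} outside [0, 1]")
            if direction not in (-1, 1):
                raise ValueError(f"planted direction for {compound!r} must be +/-1")
        if self.n_signal > self.n_genes:
            raise ValueError("n_signal cannot exceed n_genes")
        for frac in (self.unmapped_frac, self.multiprobe_frac):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticConfig":
        base = dict(N=22_283, D=1_309, K_range=(1, 32), n_genes=5_000, n_signal=200)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated database, for generator validation."""

    signature: GeneSignature
    planted: tuple[tuple[str, float, int], ...]

    def strength_of(self, compound: str) -> float:
        for c, lam, _ in self.planted:
            if c == compound:
                return lam
        return 0.0

    def direction_of(self, compound: str) -> int:
        for c, _, d in self.planted:
            if c == compound:
                return d
        return 0


def _default_universe(N: int) -> ProbeUniverse:
    width = len(str(N - 1))
    return ProbeUniverse(tuple(f"p{str(i).zfill(width)}_at" for i in range(N)))


def _null_signed_rank(rng: np.random.Generator, N: int) -> np.ndarray:
    mags = rng.permutation(N) + 1
    signs = rng.choice((-1, 1), size=N)
    return signs * mags


def _plant(
    rank: np.ndarray,
    sig_idx: np.ndarray,
    sig_signs: np.ndarray,
    lam: float,
    direction: int,
    rng: np.random.Generator,
    N: int,
) -> np.ndarray:
    """Place the signature at the top magnitudes, then corrupt with prob 1-lambda."""
    rank = rank.copy()
    for i, (pi, si) in enumerate(zip(sig_idx, sig_signs)):
        target_mag = N - i
        holder = int(np.flatnonzero(np.abs(rank) == target_mag)[0])
        # swap the signed values so magnitudes stay a permutation
        rank[holder], rank[pi] = rank[pi], rank[holder]
        rank[pi] = direction * si * target_mag
    # independent swap-corruption of each planted probe
    for pi in sig_idx:
        if rng.random() > lam:
            other = int(rng.integers(0, N))
            rank[pi], rank[other] = rank[other], rank[pi]
    return rank


def gen_reference_db(
    cfg: SyntheticConfig,
    signature: Optional[GeneSignature] = None,
    universe: Optional[ProbeUniverse] = None,
) -> tuple[ReferenceDatabase, SyntheticTruth]:
    """Generate a reference database with planted connections.

    If no planted ``signature`` is supplied, one of length cfg.n_signature
    is drawn uniformly from the universe with independent fair signs.
    Replicate counts per compound are uniform over cfg.K_range. Planted
    compounds get every replicate planted independently at their strength;
    all other profiles are independent uniform signed permutations. Fully
    reproducible from cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    if universe is None:
        universe = _default_universe(cfg.N)
    N = universe.N
    if signature is None:
        idx = rng.choice(N, size=cfg.n_signature, replace=False)
        signs = rng.choice((-1, 1), size=cfg.n_signature)
        signature = GeneSignature(
            tuple(universe.probe_ids[i] for i in idx),
            tuple(int(s) for s in signs),
            name="planted",
        )
    if signature.m > N:
        raise ValueError("planted signature larger than the probe universe")
    sig_idx = universe.index_of(signature.probe_ids)
    sig_signs = signature.sign_array()
    planted_by_name = {c: (lam, d) for c, lam, d in cfg.planted}
    unknown = set(planted_by_name) - {f"cmpd{i:04d}" for i in range(cfg.D)}

    sets = []
    lo, hi = cfg.K_range
    for j in range(cfg.D):
        compound = f"cmpd{j:04d}"
        K = int(rng.integers(lo, hi + 1))
        profiles = []
        for k in range(K):
            rank = _null_signed_rank(rng, N)
            if compound in planted_by_name:
                lam, direction = planted_by_name[compound]
                rank = _plant(rank, sig_idx, sig_signs, lam, direction, rng, N)
            profiles.append(
                ReferenceProfile(
                    profile_id=f"{compound}_r{k}",
                    compound=compound,
                    universe=universe,
                    signed_rank=rank,
                )
            )
        sets.append(ReferenceSet(compound, tuple(profiles)))
    db = ReferenceDatabase(universe=universe, sets=tuple(sets))
    if unknown:
        raise ValueError(f"planted compounds not in the database: {sorted(unknown)}")
    truth = SyntheticTruth(signature=signature, planted=cfg.planted)
    return db, truth


def gen_de_table(
    cfg: SyntheticConfig,
    universe: Optional[ProbeUniverse] = None,
) -> tuple[DETable, AnnotationMap]:
    """Generate a ranked DE table and a gene-to-probe annotation map.

    The first cfg.n_signal genes carry strong effects: |log2ratio| drawn
    lognormal around cfg.signal_lfc_mean with near-zero p-values; the rest
    are null (small |log2ratio|, p uniform away from zero). Rows are ordered
    by ascending p-value, sub-sorted by |log2ratio| descending at ties, and
    the position column records that order. Each gene is unmapped with
    probability unmapped_frac, maps to 2-3 probes with probability
    multiprobe_frac, else to one probe; probes are drawn without replacement
    from the universe. Deterministic from cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    if universe is None:
        universe = _default_universe(cfg.N)
    n = cfg.n_genes
    gene_ids = [f"G{str(i).zfill(len(str(n - 1)))}" for i in range(n)]

    is_signal = np.zeros(n, dtype=bool)
    is_signal[: cfg.n_signal] = True
    lfc = np.empty(n)
    pval = np.empty(n)
    # signal tier: large effects, astronomically small p spread over decades
    lfc[is_signal] = rng.lognormal(
        mean=np.log(cfg.signal_lfc_mean), sigma=0.3, size=cfg.n_signal
    ) * rng.choice((-1, 1), size=cfg.n_signal, p=(0.1, 0.9))
    pval[is_signal] = 10.0 ** rng.uniform(-300, -20, size=cfg.n_signal)
    n_null = n - cfg.n_signal
    lfc[~is_signal] = rng.normal(0, 0.4, size=n_null)
    pval[~is_signal] = rng.uniform(1e-4, 1, size=n_null)

    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [g.replace("G", "SYM") for g in gene_ids],
            "log2ratio": lfc,
            "pvalue": pval,
        }
    )
    df["adjusted_pvalue"] = np.minimum(
        df["pvalue"] * n / df["pvalue"].rank(method="min"), 1.0
    )
    df = df.sort_values(
        ["pvalue", "log2ratio"],
        key=lambda s: s if s.name == "pvalue" else -s.abs(),
        kind="stable",
    ).reset_index(drop=True)
    df["position"] = np.arange(1, n + 1)

    # annotation: decide mapping class per gene, then assign probes without
    # replacement in table order so top genes get reproducible probes
    n_probes_per_gene = np.ones(n, dtype=int)
    u = rng.random(n)
    n_probes_per_gene[u < cfg.unmapped_frac] = 0
    multi = (u >= cfg.unmapped_frac) & (u < cfg.unmapped_frac + cfg.multiprobe_frac)
    n_probes_per_gene[multi] = rng.integers(2, 4, size=int(multi.sum()))
    demand = int(n_probes_per_gene.sum())
    if demand > universe.N:
        raise ValueError(
            f"annotation needs {demand} distinct probes but universe has {universe.N}"
        )
    pool = rng.permutation(universe.N)
    ann = AnnotationMap()
    cursor = 0
    for gi in range(n):
        gene = df["gene_id"].iloc[gi]
        k = n_probes_per_gene[gi]
        ann[gene] = [universe.probe_ids[pool[cursor + j]] for j in range(k)]
        cursor += k
    return DETable(df), ann


def gen_pipeline_inputs(
    cfg: SyntheticConfig,
) -> tuple[ReferenceDatabase, SyntheticTruth, DETable, AnnotationMap]:
    """Jointly generate DE table, annotation and database.

    The planted signature is exactly the top cfg.n_signature mappable probes
    of the generated DE table (with the genes' regulation signs), so running
    signature construction on the synthetic DE table recovers the planted
    signature and the planted compounds are genuinely connected to it.
    """
    from .signature import map_genes_to_probes

    universe = _default_universe(cfg.N)
    de, ann = gen_de_table(cfg, universe)
    signature = map_genes_to_probes(de, ann, universe, cfg.n_signature, name="planted")
    db, truth = gen_reference_db(cfg, signature=signature, universe=universe)
    return db, truth, de, ann
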