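"""Signed-rank reference profiles and compound reference sets.

A reference profile encodes one compound-treatment experiment as a signed
ranking of every probe on the platform: the magnitude of the rank is the
strength of differential expression (N = most extreme, 1 = least), and the
sign is the direction of regulation. A reference *set* collects the
replicate profiles for one compound; a reference *database* collects all
sets over a fixed probe universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeUniverse",
    "ReferenceProfile",
    "ReferenceSet",
    "ReferenceDatabase",
    "build_profile",
    "load_database",
    "save_database",
]


class ProfileError(ValueError):
    """Raised when profile data violate the signed-rank permutation model."""


@dataclass(frozen=True)
class ProbeUniverse:
    """Ordered collection of unique probe identifiers.

    The order is fixed per database: it defines the deterministic tie-break
    used when building profiles from differential statistics and the row
    order of every profile matrix written to disk.
    """

    probe_ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(self.probe_ids)
        if len(ids) < 2:
            raise ProfileError("probe universe needs at least 2 probes")
        index = {p: i for i, p in enumerate(ids)}
        if len(index) != len(ids):
            seen: set[str] = set()
            dups = sorted({p for p in ids if p in seen or seen.add(p)})
            raise ProfileError(f"duplicate probe ids in universe: {dups}")
        object.__setattr__(self, "probe_ids", ids)
        object.__setattr__(self, "_index", index)

    @property
    def N(self) -> int:
        return len(self.probe_ids)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._index

    def index_of(self, probe_ids: Iterable[str]) -> np.ndarray:
        """Positions of ``probe_ids`` in universe order; KeyError if absent."""
        try:
            return np.array([self._index[p] for p in probe_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"probe {exc.args[0]!r} not in universe") from None


@dataclass(frozen=True, eq=False)
class ReferenceProfile:
    """One treatment instance: a signed rank for every universe probe.

    ``signed_rank[i]`` belongs to ``universe.probe_ids[i]``; the multiset of
    magnitudes is exactly {1..N}.
    """

    profile_id: str
    compound: str
    universe: ProbeUniverse
    signed_rank: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.signed_rank, dtype=np.int64)
        object.__setattr__(self, "signed_rank", r)
        self.validate()

    def validate(self) -> None:
        N = self.universe.N
        r = self.signed_rank
        if r.shape != (N,):
            raise ProfileError(
                f"profile {self.profile_id!r}: expected {N} ranks, got {r.shape}"
            )
        mags = np.sort(np.abs(r))
        if not np.array_equal(mags, np.arange(1, N + 1)):
            raise ProfileError(
                f"profile {self.profile_id!r}: rank magnitudes are not a "
                f"permutation of 1..{N}"
            )

    def ranks_for(self, probe_ids: Sequence[str]) -> np.ndarray:
        return self.signed_rank[self.universe.index_of(probe_ids)]


@dataclass(frozen=True, eq=False)
class ReferenceSet:
    """All replicate profiles for one compound (cardinality = setsize K)."""

    compound: str
    profiles: tuple[ReferenceProfile, ...]

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        if not profiles:
            raise ProfileError(f"reference set {self.compound!r} is empty")
        uni = profiles[0].universe
        for p in profiles:
            if p.universe is not uni and p.universe != uni:
                raise ProfileError(
                    f"reference set {self.compound!r}: profiles span "
                    f"different universes"
                )
        object.__setattr__(self, "profiles", profiles)

    @property
    def setsize(self) -> int:
        return len(self.profiles)

    @property
    def universe(self) -> ProbeUniverse:
        return self.profiles[0].universe

    def mean_signed_rank(self) -> np.ndarray:
        """Per-probe mean of signed ranks across replicates (float)."""
        return np.mean([p.signed_rank for p in self.profiles], axis=0)


@dataclass(frozen=True, eq=False)
class ReferenceDatabase:
    universe: ProbeUniverse
    sets: tuple[ReferenceSet, ...]

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        if not sets:
            raise ProfileError("reference database has no sets")
        names = [s.compound for s in sets]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dups = sorted({n for n in names if n in seen or seen.add(n)})
            raise ProfileError(f"duplicate compound names in database: {dups}")
        object.__setattr__(self, "sets", sets)

    @property
    def D(self) -> int:
        """Number of compound reference sets (the Bonferroni divisor)."""
        return len(self.sets)

    def __getitem__(self, compound: str) -> ReferenceSet:
        for s in self.sets:
            if s.compound == compound:
                return s
        raise KeyError(compound)

    def compounds(self) -> list[str]:
        return [s.compound for s in self.sets]


def build_profile(
    diff_stats: Mapping[str, float],
    universe: ProbeUniverse,
    profile_id: str = "profile",
    compound: str = "unknown",
) -> ReferenceProfile:
    """Convert per-probe signed differential statistics into a signed-rank profile.

    The most extreme statistic receives magnitude N (so a perfectly matching
    m-probe signature occupies magnitudes N..N-m+1 and the normalised
    connection score attains exactly +/-1). Ties in |statistic| are broken by
    universe order, the earlier probe taking the larger magnitude. The sign of
    the rank is the sign of the statistic; a zero statistic counts as
    up-regulated (+1) by convention, since a signed rank must be nonzero.

    Raises :class:`ProfileError` if ``diff_stats`` does not cover the universe
    exactly (missing and extra probe ids are both reported).
    """
    missing = [p for p in universe.probe_ids if p not in diff_stats]
    extra = sorted(set(diff_stats) - set(universe.probe_ids))
    if missing or extra:
        raise ProfileError(
            f"diff_stats must cover the universe exactly; "
            f"missing={missing[:10]} extra={extra[:10]}"
        )
    stats = np.array([float(diff_stats[p]) for p in universe.probe_ids])
    N = universe.N
    # stable argsort on -|stat|: ties keep universe order, earlier probe
    # comes first and therefore gets the larger magnitude
    order = np.argsort(-np.abs(stats), kind="stable")
    magnitude = np.empty(N, dtype=np.int64)
    magnitude[order] = np.arange(N, 0, -1)
    signs = np.where(stats < 0, -1, 1)  # sign(0) == +1 by convention
    return ReferenceProfile(
        profile_id=profile_id,
        compound=compound,
        universe=universe,
        signed_rank=signs * magnitude,
    )


def save_database(db: ReferenceDatabase, profiles_path, metadata_path) -> None:
    """Write a database as two TSVs: probe x profile signed-rank matrix and
    profile metadata (``profile_id``, ``compound``)."""
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in db.sets:
        for p in s.profiles:
            if p.profile_id in cols:
                raise ProfileError(f"duplicate profile_id {p.profile_id!r}")
            cols[p.profile_id] = p.signed_rank
            meta_rows.append({"profile_id": p.profile_id, "compound": p.compound})
    mat = pd.DataFrame(cols, index=pd.Index(db.universe.probe_ids, name="probe_id"))
    mat.to_csv(profiles_path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


def load_database(profiles_path, metadata_path) -> ReferenceDatabase:
    """Load a database written by :func:`save_database`.

    Every profile column is validated as a signed permutation; metadata and
    matrix profile ids must agree exactly. Round-trips ``save_database``
    bit-exactly (tab-delimited, header row, UTF-8).
    """
    mat = pd.read_csv(profiles_path, sep="\t", index_col="probe_id")
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("profile_id", "compound"):
        if col not in meta.columns:
            raise ProfileError(f"metadata file {metadata_path} lacks column {col!r}")
    meta["profile_id"] = meta["profile_id"].astype(str)
    matrix_ids = set(map(str, mat.columns))
    meta_ids = set(meta["profile_id"])
    if matrix_ids != meta_ids:
        raise ProfileError(
            f"profile id mismatch between matrix and metadata: "
            f"matrix-only={sorted(matrix_ids - meta_ids)[:10]} "
            f"metadata-only={sorted(meta_ids - matrix_ids)[:10]}"
        )
    universe = ProbeUniverse(tuple(map(str, mat.index)))
    by_compound: dict[str, list[ReferenceProfile]] = {}
    order: list[str] = []
    for _, row in meta.iterrows():
        pid, compound = row["profile_id"], str(row["compound"])
        profile = ReferenceProfile(
            profile_id=pid,
            compound=compound,
            universe=universe,
            signed_rank=mat[pid].to_numpy(dtype=np.int64),
        )
        if compound not in by_compound:
            by_compound[compound] = []
            order.append(compound)
        by_compound[compound].append(profile)
    sets = tuple(ReferenceSet(c, tuple(by_compound[c])) for c in order)
    return ReferenceDatabase(universe=universe, sets=sets)


def database_from_profiles(profiles: Iterable[ReferenceProfile]) -> ReferenceDatabase:
    """Group loose profiles by compound into a database (insertion order)."""
    by_compound: dict[str, list[ReferenceProfile]] = {}
    for p in profiles:
        by_compound.setdefault(p.compound, []).append(p)
    sets = tuple(ReferenceSet(c, tuple(ps)) for c, ps in by_compound.items())
    return ReferenceDatabase(universe=sets[0].universe, sets=sets)
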