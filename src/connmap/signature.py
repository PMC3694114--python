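"""Gene signatures from ranked differential-expression tables.

A gene signature is an ordered list of platform probe ids with up/down signs,
built by walking a DE table in rank order and expanding each gene into its
annotated probes. The signature length m that first meets the FDR target with
at least one significant connection is the "optimal" size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import ProbeUniverse, ReferenceDatabase

__all__ = [
    "DETable",
    "AnnotationMap",
    "GeneSignature",
    "SignatureError",
    "map_genes_to_probes",
    "filter_to_platform",
    "optimize_signature_size",
]

DE_COLUMNS = ("gene_id", "symbol", "log2ratio", "pvalue", "adjusted_pvalue", "position")


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class DETable:
    """Ranked differential-expression table.

    Rows are (gene_id, symbol, log2ratio, pvalue, adjusted_pvalue, position).
    The ``position`` column is the ranking authority — it carries the source
    tool's own ordering, including its tie-handling (e.g. sub-sorting equal
    p-values by |log2ratio|) — so the table is never re-sorted by p here.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in DE_COLUMNS if c not in df.columns]
        if missing:
            raise SignatureError(f"DE table lacks columns {missing}")
        df = df.loc[:, list(DE_COLUMNS)].copy()
        df["position"] = df["position"].astype(int)
        df = df.sort_values("position", kind="stable").reset_index(drop=True)
        n = len(df)
        if n == 0:
            raise SignatureError("DE table is empty")
        if not np.array_equal(df["position"].to_numpy(), np.arange(1, n + 1)):
            raise SignatureError("positions must be 1..n without gaps")
        pv = df["pvalue"].to_numpy(dtype=float)
        if np.any(pv < 0) or np.any(pv > 1):
            raise SignatureError("p-values must lie in [0, 1]")
        if np.any(np.diff(pv) < -1e-12):
            raise SignatureError("position order inconsistent with ascending p-value")
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def read_tsv(cls, path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class AnnotationMap(dict):
    """gene_id -> list of probe_ids (order-preserving; empty list = unmapped).

    TSV dialect: two columns ``gene_id`` and ``probe_id``, one row per pair;
    genes absent from the file are unmapped.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        super().__init__()
        if mapping:
            for gene, probes in mapping.items():
                self[gene] = list(probes)
                if len(set(self[gene])) != len(self[gene]):
                    raise SignatureError(f"duplicate probes for gene {gene!r}")

    @classmethod
    def read_tsv(cls, path) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "probe_id"):
            if col not in df.columns:
                raise SignatureError(f"annotation file lacks column {col!r}")
        out = cls()
        for gene, probe in zip(df["gene_id"].astype(str), df["probe_id"].astype(str)):
            out.setdefault(gene, [])
            if probe in out[gene]:
                raise SignatureError(f"duplicate probe {probe!r} for gene {gene!r}")
            out[gene].append(probe)
        return out

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_id": g, "probe_id": p} for g, probes in self.items() for p in probes
        ]
        pd.DataFrame(rows, columns=["gene_id", "probe_id"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class GeneSignature:
    """Ordered (probe_id, sign) pairs; sign +1 = up-regulated in the query
    phenotype, -1 = down-regulated."""

    probe_ids: tuple[str, ...]
    signs: tuple[int, ...]
    name: str = "query"

    def __post_init__(self) -> None:
        probes = tuple(self.probe_ids)
        signs = tuple(int(s) for s in self.signs)
        if len(probes) != len(signs):
            raise SignatureError("probe_ids and signs differ in length")
        if len(probes) == 0:
            raise SignatureError("empty signature")
        if len(set(probes)) != len(probes):
            raise SignatureError("duplicate probe ids in signature")
        if any(s not in (-1, 1) for s in signs):
            raise SignatureError("signs must be +1 or -1")
        object.__setattr__(self, "probe_ids", probes)
        object.__setattr__(self, "signs", signs)

    @property
    def m(self) -> int:
        return len(self.probe_ids)

    def sign_array(self) -> np.ndarray:
        return np.array(self.signs, dtype=np.int64)

    def flipped(self) -> "GeneSignature":
        return GeneSignature(self.probe_ids, tuple(-s for s in self.signs), self.name)

    @classmethod
    def read_tsv(cls, path, name: str | None = None) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        return cls(
            tuple(df["probe_id"].astype(str)),
            tuple(df["sign"].astype(int)),
            name or "query",
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"probe_id": self.probe_ids, "sign": self.signs}).to_csv(
            path, sep="\t", index=False
        )


def filter_to_platform(
    probes: Sequence[str], universe: ProbeUniverse
) -> list[str]:
    """Restrict a probe list to platform members, preserving order.

    Mirrors dropping probeset ids that are not part of the reference
    platform before querying; idempotent; may return an empty list.
    """
    return [p for p in probes if p in universe]


def map_genes_to_probes(
    de: DETable,
    ann: AnnotationMap,
    universe: ProbeUniverse,
    m: int,
    name: str = "query",
) -> GeneSignature:
    """Build the top-m platform-mapped signature from a ranked DE table.

    Walks the table in position order; each gene contributes all its annotated
    probes (in annotation order) that are on the platform, every probe
    carrying the gene-level regulation sign (sign of log2ratio). Unmapped
    genes are skipped. Collection stops as soon as m probes are gathered, so
    the cut may fall mid-gene, truncating a multi-probe gene.
    """
    if m < 1:
        raise SignatureError("signature size m must be >= 1")
    probes: list[str] = []
    signs: list[int] = []
    seen: set[str] = set()
    for row in de.frame.itertuples(index=False):
        gene_probes = filter_to_platform(ann.get(row.gene_id, []), universe)
        sign = -1 if row.log2ratio < 0 else 1
        for p in gene_probes:
            if p in seen:
                continue
            probes.append(p)
            signs.append(sign)
            seen.add(p)
            if len(probes) == m:
                return GeneSignature(tuple(probes), tuple(signs), name)
    raise SignatureError(
        f"only {len(probes)} mappable probes available, need m={m} "
        f"(shortfall {m - len(probes)})"
    )


@dataclass(frozen=True)
class SizeScan:
    """Per-size audit record from the optimal-size search."""

    m: int
    n_significant: int
    fdr_estimate: float
    results: list = field(repr=False, default_factory=list)


class NoOptimalSizeError(SignatureError):
    """No size in the grid met the FDR target; carries the per-m scan."""

    def __init__(self, scans: list[SizeScan], fdr_target: float):
        self.scans = scans
        super().__init__(
            f"no signature size met FDR <= {fdr_target}: "
            + "; ".join(f"m={s.m}: FDR={s.fdr_estimate:.4g}" for s in scans)
        )


DEFAULT_M_GRID = tuple(range(5, 101, 5))


def optimize_signature_size(
    de: DETable,
    ann: AnnotationMap,
    db: ReferenceDatabase,
    cfg,
    m_grid: Sequence[int] = DEFAULT_M_GRID,
    name: str = "query",
):
    """Find the smallest signature size meeting the FDR target.

    For each m in the ascending grid the top-m signature is built and queried
    against the whole database; the FDR estimate is alpha_family divided by
    the number of Bonferroni-significant connections. The optimum m* is the
    smallest m with >= 1 significant connection and FDR <= cfg.fdr_target.
    Returns ``(m_star, scans)`` with one :class:`SizeScan` per grid value for
    audit; raises :class:`NoOptimalSizeError` (carrying the scans) if the grid
    is exhausted.
    """
    from .scoring import estimate_fdr, query_database

    grid = list(m_grid)
    if grid != sorted(grid) or len(set(grid)) != len(grid):
        raise SignatureError("m_grid must be strictly ascending")
    scans: list[SizeScan] = []
    m_star = None
    for m in grid:
        sig = map_genes_to_probes(de, ann, db.universe, m, name=f"{name}_m{m}")
        results = query_database(sig, db, cfg)
        n_sig = sum(r.sig for r in results)
        fdr = estimate_fdr(n_sig, cfg)
        scans.append(SizeScan(m=m, n_significant=n_sig, fdr_estimate=fdr, results=results))
        if m_star is None and n_sig >= 1 and fdr <= cfg.fdr_target:
            m_star = m
            break
    if m_star is None:
        raise NoOptimalSizeError(scans, cfg.fdr_target)
    return m_star, scans
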