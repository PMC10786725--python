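"""Hypergeometric gene-set over-representation.

Tests whether gene sets (GMT collections, e.g. MSigDB HALLMARK) are
over-represented among promoters gained with treatment, against the
background of unchanged plus decreased promoters.  The universe is
foreground ∪ background; each set is first intersected with the universe,
the upper-tail hypergeometric p-value is computed in log-space, and BH
FDR is applied across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .differential import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper",
    "enrich",
]


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for sname, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {sname}")


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int  # overlap with foreground
    K: int  # set size within universe
    n: int  # foreground size
    N: int  # universe size
    p: float
    q: float
    significant: bool


def read_gmt(path: str, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, member genes...).

    Duplicate genes within a set are removed (logged); lines with fewer
    than three fields are an error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            sname = fields[0]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    continue
                seen.add(g)
                genes.append(g)
            if len(genes) < len([g for g in fields[2:] if g.strip()]):
                logger.info("%s: deduplicated genes in set %s", path, sname)
            sets[sname] = genes
    return GeneSetCollection(name or path, sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for sname, genes in collection.sets.items():
            fh.write("\t".join([sname, collection.name, *genes]) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("need K <= N and n <= N")
    if k == 0:
        return 1.0
    # scipy's sf is computed from log-pmf terms; stable for the sizes here
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of each set in the foreground vs the universe.

    Universe = foreground ∪ background (disjoint inputs required).  Gene
    identifiers are matched case-sensitively after whitespace trimming.
    Sets with no member in the universe are skipped (logged) and excluded
    from the BH family.  Records are returned sorted by p.
    """
    fg = {g.strip() for g in foreground}
    bg = {g.strip() for g in background}
    if fg & bg:
        raise ValueError("foreground and background must be disjoint")
    universe = fg | bg
    if not universe:
        raise ValueError("empty universe")

    names, ks, Ks = [], [], []
    for sname in collection.sets:
        members = {g.strip() for g in collection.sets[sname]}
        K = len(members & universe)
        if K == 0:
            logger.info("set %s has no members in universe; skipped", sname)
            continue
        names.append(sname)
        Ks.append(K)
        ks.append(len(members & fg))
    n, N = len(fg), len(universe)
    ps = [hypergeom_upper(k, K, n, N) for k, K in zip(ks, Ks)]
    qs = bh_fdr(ps) if ps else []
    records = [
        EnrichmentRecord(sname, k, K, n, N, p, q, bool(q < alpha))
        for sname, k, K, p, q in zip(names, ks, Ks, ps, qs)
    ]
    return sorted(records, key=lambda r: (r.p, r.set_name))


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.k, r.K, r.n, r.N, r.p, r.q, r.significant)
            for r in records
        ],
        columns=["set", "k", "K", "n", "N", "p", "q", "significant"],
    )
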