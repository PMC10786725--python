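"""Per-gene pausing indices and paired condition comparison.

The pausing index (PI) of a gene is the log2 ratio of promoter per-bp
fragment density to gene-body per-bp density:

    PI = log2((n_prom + eps) / L_prom) - log2((n_body + eps) / L_body)

A small pseudocount eps (default 0.5) keeps the PI finite at zero counts.
Genes with PI > 1 carry >2-fold more promoter-proximal than elongating
polymerase and are classified "paused".  Conditions are compared with a
two-sided paired Wilcoxon signed-rank test on per-gene PIs: exact null
distribution (midranks; dynamic programming over rank sums) for n <= 25,
normal approximation with tie and continuity corrections above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import WindowPair
from .signal_io import CountVector

logger = logging.getLogger(__name__)

__all__ = [
    "PausingRecord",
    "WilcoxonResult",
    "PausingSummary",
    "pausing_index",
    "condition_pi",
    "classify_paused",
    "paired_wilcoxon",
    "ecdf",
]


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    condition: str
    promoter_count: float
    body_count: float
    promoter_density: float
    body_density: float
    pi: float


@dataclass(frozen=True)
class WilcoxonResult:
    W: float  # sum of ranks of positive differences
    n: int  # non-zero paired differences
    p: float  # two-sided
    method: str  # exact | normal_approx


@dataclass(frozen=True)
class PausingSummary:
    n_genes: int
    fraction_paused: float
    threshold_log2: float


def pausing_index(
    promoter_count: float,
    body_count: float,
    promoter_length: float,
    body_length: float,
    pseudocount: float = 0.5,
) -> float:
    """log2 promoter density over body density, pseudocounted."""
    if promoter_length <= 0 or body_length <= 0:
        raise ValueError("window lengths must be positive")
    if promoter_count < 0 or body_count < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and (body_count == 0 or promoter_count == 0):
        raise ValueError("zero counts with zero pseudocount: PI undefined")
    prom_d = (promoter_count + pseudocount) / promoter_length
    body_d = (body_count + pseudocount) / body_length
    return float(np.log2(prom_d) - np.log2(body_d))


def condition_pi(
    replicate_counts: Sequence[tuple[CountVector, CountVector]],
    windows: Sequence[WindowPair],
    condition: str,
    pseudocount: float = 0.5,
) -> list[PausingRecord]:
    """Average replicate densities per gene, then compute the PI.

    ``replicate_counts`` holds one (promoter CountVector, body CountVector)
    pair per replicate, on the same gene universe.  Counts are averaged
    across replicates (window lengths are shared, so averaging counts and
    averaging densities are the same operation) and the pseudocount is
    applied to the averaged counts.  Genes missing from any replicate are
    dropped with a log entry.
    """
    if not replicate_counts:
        raise ValueError("need at least one replicate")
    wmap = {w.gene_id: w for w in windows}
    prom_tabs = [pc.counts for pc, _ in replicate_counts]
    body_tabs = [bc.counts for _, bc in replicate_counts]

    common = set(wmap)
    for t in prom_tabs + body_tabs:
        common &= set(t.index)
    n_dropped = len(wmap) - len(common)
    if n_dropped:
        logger.info("condition %s: dropped %d genes missing in a replicate",
                    condition, n_dropped)

    records = []
    for gid in sorted(common):
        w = wmap[gid]
        pc = float(np.mean([t[gid] for t in prom_tabs]))
        bc = float(np.mean([t[gid] for t in body_tabs]))
        pi = pausing_index(pc, bc, w.promoter_length, w.body_length, pseudocount)
        records.append(
            PausingRecord(
                gene_id=gid,
                condition=condition,
                promoter_count=pc,
                body_count=bc,
                promoter_density=pc / w.promoter_length,
                body_density=bc / w.body_length,
                pi=pi,
            )
        )
    return records


def classify_paused(
    records: Iterable[PausingRecord] | Sequence[float],
    threshold_log2: float = 1.0,
) -> PausingSummary:
    """Fraction of genes with PI strictly above the log2 threshold."""
    pis = np.asarray(
        [r.pi if isinstance(r, PausingRecord) else float(r) for r in records]
    )
    if pis.size == 0:
        raise ValueError("no pausing records")
    frac = float(np.mean(pis > threshold_log2))
    return PausingSummary(n_genes=int(pis.size), fraction_paused=frac,
                          threshold_log2=threshold_log2)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    # DP over doubled midranks (integers); null assigns each rank +/-
    # with probability 1/2.  Two-sided p doubles the smaller tail.
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(w_plus * 2))
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def paired_wilcoxon(
    pi_a: Sequence[float] | pd.Series,
    pi_b: Sequence[float] | pd.Series,
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of b vs a.

    Pairs are matched by index when both inputs are pandas Series,
    positionally otherwise.  Zero differences are dropped (standard
    signed-rank convention); W is the sum of midranks of positive
    differences d = b - a.
    """
    if isinstance(pi_a, pd.Series) and isinstance(pi_b, pd.Series):
        common = pi_a.index.intersection(pi_b.index)
        d = (pi_b.loc[common] - pi_a.loc[common]).to_numpy(dtype=float)
    else:
        a = np.asarray(pi_a, dtype=float)
        b = np.asarray(pi_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired inputs must have equal length")
        d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return WilcoxonResult(W=0.0, n=0, p=1.0, method="exact")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = float(np.sum(ranks**2)) / 4.0  # midranks absorb tie correction
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal_approx"
    return WilcoxonResult(W=w_plus, n=n, p=p, method=method)


def ecdf(values: Sequence[float]) -> pd.DataFrame:
    """Right-continuous ECDF as a (value, F) table; F(max) == 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    from statsmodels.distributions.empirical_distribution import ECDF

    f = ECDF(v)
    xs = np.unique(v)
    return pd.DataFrame({"value": xs, "F": f(xs)})
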