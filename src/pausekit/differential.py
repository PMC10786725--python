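"""Differential RNAPII promoter enrichment between two conditions.

The comparison design follows the ChIP-seq analysis it re-implements:
peaks called in both replicates of a condition are merged into consensus
peaks; promoters (±300 bp of a TSS) carrying a consensus peak in at least
one condition form the tested universe; fragment counts over those
promoters are compared 2 vs 2 between conditions and promoters are
classified increased / decreased / no_change at BH FDR < 0.05.

The count test itself is an explicit, documented replacement for a
differential-binding package: median-of-ratios size factors, a common
negative-binomial dispersion pooled across promoters by the method of
moments, and an exact conditional NB test per promoter (the distribution
of one condition's summed count given the total, with two-sided p from
doubling the smaller tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signal_io import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusPeakSet",
    "PromoterCountMatrix",
    "DifferentialRecord",
    "consensus_peaks",
    "promoter_universe",
    "size_factors",
    "estimate_dispersion",
    "differential_test",
    "bh_fdr",
]


@dataclass
class ConsensusPeakSet:
    """Merged intervals supported by peak calls in both replicates."""

    condition: str
    peaks: pd.DataFrame  # columns chrom, start, end


@dataclass
class PromoterCountMatrix:
    """Promoters × samples count matrix with condition labels.

    ``size_factors`` may be supplied externally (e.g. derived from full
    library sizes).  When a treatment shifts the majority of promoters —
    the global-pausing regime — median-of-ratios factors computed on the
    promoter matrix itself absorb the effect, so library-size factors are
    the right choice there; ``None`` means estimate median-of-ratios from
    the matrix.
    """

    counts: pd.DataFrame  # index promoter ids, columns sample ids
    conditions: dict[str, str]  # sample id -> condition label
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = pd.Series(self.size_factors).reindex(
                self.counts.columns
            )
            if (self.size_factors <= 0).any() or self.size_factors.isna().any():
                raise ValueError("size factors must be positive for every sample")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class DifferentialRecord:
    region_id: str
    log2fc: float
    p: float
    q: float
    classification: str  # increased | decreased | no_change


def consensus_peaks(rep1: PeakSet, rep2: PeakSet, condition: str = "") -> ConsensusPeakSet:
    """Merge peaks supported by both replicates.

    Overlapping intervals (≥1 bp) across the two replicates are clustered;
    clusters containing at least one peak from each replicate are emitted
    as the union interval of the cluster.
    """
    if rep1.peaks.empty or rep2.peaks.empty:
        logger.warning("empty replicate peak set; consensus is empty")
        return ConsensusPeakSet(condition, pd.DataFrame(columns=["chrom", "start", "end"]))
    p1 = rep1.peaks.assign(rep=1)
    p2 = rep2.peaks.assign(rep=2)
    allp = pd.concat([p1, p2]).sort_values(["chrom", "start", "end"])
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=False):
        cur_start = cur_end = None
        reps: set[int] = set()
        for _, r in grp.iterrows():
            if cur_start is None or r["start"] >= cur_end:
                if cur_start is not None and reps == {1, 2}:
                    rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end, reps = r["start"], r["end"], {r["rep"]}
            else:
                cur_end = max(cur_end, r["end"])
                reps.add(r["rep"])
        if cur_start is not None and reps == {1, 2}:
            rows.append((chrom, cur_start, cur_end))
    return ConsensusPeakSet(
        condition, pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )


def promoter_universe(
    consensus: list[ConsensusPeakSet],
    diff_promoters: pd.DataFrame,
) -> list[str]:
    """Promoter ids overlapping (≥1 bp) a consensus peak in ≥1 condition."""
    kept = []
    peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cs in consensus:
        for _, r in cs.peaks.iterrows():
            peak_by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"]))
    for chrom in peak_by_chrom:
        peak_by_chrom[chrom].sort()
    for _, row in diff_promoters.iterrows():
        ivs = peak_by_chrom.get(row["chrom"], [])
        s, e = row["start"], row["end"]
        # sorted scan; promoter lists are short enough that bisection is moot
        if any(ps < e and s < pe for ps, pe in ivs):
            kept.append(row["region_id"])
    return kept


def size_factors(matrix: PromoterCountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    Reference is the per-promoter geometric mean over samples, computed on
    promoters with all-positive counts; each sample's factor is the median
    ratio of its counts to the reference.  Falls back to library-size
    ratios (scaled to geometric mean 1) when no promoter is all-positive.
    """
    c = matrix.counts
    allpos = c[(c > 0).all(axis=1)]
    if allpos.empty:
        logger.warning("no promoter with all-positive counts; using library-size ratios")
        lib = c.sum(axis=0).astype(float)
        return lib / stats.gmean(lib)
    logc = np.log(allpos.to_numpy(dtype=float))
    ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - ref, axis=0))
    return pd.Series(factors, index=c.columns)


def estimate_dispersion(matrix: PromoterCountMatrix, factors: pd.Series) -> float:
    """Common NB dispersion pooled across promoters (method of moments).

    On size-factor-normalized counts, within-condition sample mean m and
    variance s² satisfy E[s²] ≈ m + α m²; α is estimated by the pooled
    ratio Σ(s² − m) / Σ m², clipped to [0, 10].
    """
    norm = matrix.counts / factors
    num = 0.0
    den = 0.0
    for cond in sorted(set(matrix.conditions.values())):
        cols = matrix.samples_for(cond)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 10.0))


def _group_sum_logpmf(x: np.ndarray, mean: float, disp: float, r: int) -> np.ndarray:
    # sum of r iid NB(mu, alpha) is NB(r*mu, alpha/r)
    total_mean = r * mean
    if disp <= 1e-12:
        return stats.poisson.logpmf(x, total_mean)
    size = r / disp
    p = size / (size + total_mean)
    return stats.nbinom.logpmf(x, size, p)


def exact_nb_test(a: int, b: int, r_a: int, r_b: int, dispersion: float) -> float:
    """Two-sided exact conditional NB test for summed group counts.

    Given group sums a, b from r_a and r_b replicates at common per-sample
    mean and dispersion, computes P(A = x | A + B = a + b) over the
    conditional support and doubles the smaller inclusive tail.
    """
    t = a + b
    if t == 0:
        return 1.0
    mu = t / (r_a + r_b)
    x = np.arange(t + 1)
    lp = _group_sum_logpmf(x, mu, dispersion, r_a) + _group_sum_logpmf(
        t - x, mu, dispersion, r_b
    )
    lp -= np.max(lp)
    pr = np.exp(lp)
    pr /= pr.sum()
    lo = pr[: a + 1].sum()
    hi = pr[a:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def differential_test(
    matrix: PromoterCountMatrix,
    treatment: str = "treated",
    control: str = "vehicle",
    alpha: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-promoter differential enrichment, treatment vs control.

    Returns a DataFrame indexed by promoter id with columns
    mean_control, mean_treatment (normalized), log2fc, p, q, class.
    Promoters with zero counts in every sample are dropped (logged).
    """
    t_cols = matrix.samples_for(treatment)
    c_cols = matrix.samples_for(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >=2 replicates per condition for dispersion estimation")

    counts = matrix.counts
    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropped %d all-zero promoters", n_dropped)
    counts = counts[nonzero]
    sub = PromoterCountMatrix(counts, matrix.conditions)

    factors = matrix.size_factors if matrix.size_factors is not None else size_factors(sub)
    if dispersion is None:
        dispersion = estimate_dispersion(sub, factors)
    norm = counts / factors

    mean_c = norm[c_cols].mean(axis=1)
    mean_t = norm[t_cols].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))

    a = np.rint(norm[t_cols].sum(axis=1)).astype(int)
    b = np.rint(norm[c_cols].sum(axis=1)).astype(int)
    pvals = np.array(
        [
            exact_nb_test(ai, bi, len(t_cols), len(c_cols), dispersion)
            for ai, bi in zip(a, b)
        ]
    )
    qvals = bh_fdr(pvals)
    cls = np.where(
        qvals < alpha, np.where(log2fc > 0, "increased", "decreased"), "no_change"
    )
    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treatment": mean_t,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "class": cls,
        },
        index=counts.index,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
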