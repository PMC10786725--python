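"""Seeded synthetic inputs with ground truth for every pipeline stage.

The ChIP generator emulates the statistical structure of RNAPII occupancy:
per-gene fragment counts are Poisson with mean λ (sequencing depth per
gene); each fragment is promoter-proximal with probability φ_g (the
gene's promoter signal fraction) or falls uniformly on the gene body;
promoter-proximal fragment midpoints concentrate in a Gaussian pause site
just downstream of the TSS; a uniform genome-wide background is added.
Treatment multiplies the promoter rate of an "affected" gene subset by δ
(the promoter fraction is renormalized, so the true pausing-index gain of
an affected gene is exactly log2 δ), which is the signature of a CDK9
inhibitor blocking pause release.

φ_g is parametrized through a baseline pausing index: given a gene's
window lengths, baseline_pi (log2, drawn per gene from a normal
distribution) fixes φ_g via PI = log2(φ/L_prom) − log2((1−φ)/L_body).

Dose-response tables are 4PL curves plus Gaussian noise; count matrices
for differential-test calibration are negative binomial with per-promoter
log-normal baseline means.  All generators are pure functions of the
config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GeneRecord, WindowPair, make_pausing_windows
from .signal_io import FragmentSet, PeakSet
from .differential import PromoterCountMatrix
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "simulate_annotation",
    "write_gtf",
    "assign_truth",
    "simulate_fragments",
    "simulate_peaks",
    "simulate_gene_sets",
    "simulate_dose_response",
    "simulate_count_matrix",
]

_CONDITION_CODE = {"vehicle": 0, "treated": 1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate a deep RNAPII ChIP-seq experiment on one synthetic
    chromosome: ~1,000 fragments per gene (the desk-scale analogue of
    ≥60M-read-pair libraries over ~20k genes), a mildly promoter-enriched
    baseline (PI ≈ 0.25 log2, as unperturbed cells already show moderate
    promoter-proximal RNAPII), and a strong treatment effect (δ = 6, true
    PI gain log2 6 ≈ 2.6) hitting 60% of genes.
    """

    seed: int = 0
    # annotation
    n_genes: int = 300
    chrom: str = "chrS"
    gene_length_range_bp: tuple[int, int] = (4000, 20000)
    gap_range_bp: tuple[int, int] = (5000, 40000)
    n_short_genes: int = 0  # deliberate <1 kb filter violations
    n_close_pairs: int = 0  # deliberate <3 kb gap violations
    chrom_length_bp: int | None = None  # computed from placement if None
    # ChIP signal
    depth_per_gene: float = 1000.0  # λ, expected fragments per gene
    baseline_pi_mean: float = 0.25  # log2, vehicle
    baseline_pi_sd: float = 0.2
    treated_effect: float = 6.0  # δ, promoter-rate multiplier
    affected_fraction: float = 0.6  # f
    background_rate: float = 5e-4  # fragments per bp, genome-wide
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 50.0
    pause_site_offset_bp: float = 40.0  # downstream of TSS
    pause_site_sd_bp: float = 50.0
    # peaks
    peak_occupancy_threshold: float = 5.0  # expected promoter fragments
    peak_jitter_bp: int = 20
    # dose-response
    doses_nM: tuple[float, ...] = (62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)
    n_dose_replicates: int = 5
    noise_sd_percent: float = 5.0
    fourpl_truth: tuple[float, float, float, float] = (100.0, 0.0, 500.0, 1.5)

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


def simulate_annotation(config: SyntheticConfig) -> list[GeneRecord]:
    """Place genes left-to-right on one chromosome, alternating strands.

    ``n_short_genes`` genes get lengths of 300–900 bp and
    ``n_close_pairs`` gene pairs get intergenic gaps of 1,000–2,900 bp so
    the exclusion filters have deliberate targets; all other lengths and
    gaps come from the configured ranges (which keep genes > 3 kb apart).
    """
    rng = config.rng(10)
    n = config.n_genes
    if n == 0:
        return []
    if config.n_short_genes + 2 * config.n_close_pairs > n:
        raise ValueError("more requested violations than genes")

    lengths = rng.integers(*config.gene_length_range_bp, size=n)
    short_idx = rng.choice(n, size=config.n_short_genes, replace=False)
    lengths[short_idx] = rng.integers(300, 900, size=config.n_short_genes,
                                      endpoint=True)
    gaps = rng.integers(*config.gap_range_bp, size=n)  # gap before each gene
    # close pairs: shrink the gap *after* chosen genes, avoiding short genes
    normal_idx = np.setdiff1d(np.arange(n - 1), short_idx)
    normal_idx = np.setdiff1d(normal_idx, short_idx - 1)
    pair_lead = rng.choice(normal_idx[:: 2], size=config.n_close_pairs, replace=False) \
        if config.n_close_pairs else np.array([], dtype=int)
    for i in pair_lead:
        gaps[i + 1] = rng.integers(1000, 2900, endpoint=True)

    genes = []
    pos = 0
    width = len(str(n))
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        pos = end
        genes.append(
            GeneRecord(
                gene_id=f"G{i:0{width}d}",
                transcript_id=f"G{i:0{width}d}.t1",
                chrom=config.chrom,
                strand="+" if i % 2 == 0 else "-",
                start=start,
                end=end,
            )
        )
    if config.chrom_length_bp is not None and pos + 5000 > config.chrom_length_bp:
        raise ValueError("genes do not fit on the configured chromosome length")
    return genes


def chrom_length(config: SyntheticConfig, genes: list[GeneRecord]) -> int:
    if config.chrom_length_bp is not None:
        return config.chrom_length_bp
    return (max(g.end for g in genes) + 5000) if genes else 10000


def write_gtf(genes: list[GeneRecord], path: str, source: str = "pausekit") -> None:
    """Write one transcript + one exon feature per gene (1-based GTF)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            for feature in ("transcript", "exon"):
                fh.write(
                    "\t".join(
                        [
                            g.chrom, source, feature,
                            str(g.start + 1), str(g.end),
                            ".", g.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )


def _phi_from_pi(pi: np.ndarray, prom_len: np.ndarray, body_len: np.ndarray
                 ) -> np.ndarray:
    q = (2.0**pi) * prom_len / body_len
    return q / (1.0 + q)


def assign_truth(
    genes: list[GeneRecord],
    config: SyntheticConfig,
    windows: list[WindowPair] | None = None,
) -> pd.DataFrame:
    """Per-gene ground truth: φ (vehicle/treated), affected flag, true PIs."""
    if windows is None:
        sizes = {config.chrom: chrom_length(config, genes)}
        windows = make_pausing_windows(genes, chrom_sizes=sizes)
    wmap = {w.gene_id: w for w in windows}
    genes = [g for g in genes if g.gene_id in wmap]

    rng = config.rng(20)
    n = len(genes)
    pi0 = rng.normal(config.baseline_pi_mean, config.baseline_pi_sd, size=n)
    # exactly round(f*n) genes receive the effect, sampled without replacement
    affected = np.zeros(n, dtype=bool)
    affected[rng.choice(n, size=round(config.affected_fraction * n), replace=False)] = True

    prom_len = np.array([wmap[g.gene_id].promoter_length for g in genes], float)
    body_len = np.array([wmap[g.gene_id].body_length for g in genes], float)
    phi_v = _phi_from_pi(pi0, prom_len, body_len)
    delta = np.where(affected, config.treated_effect, 1.0)
    # promoter rate scaled by δ, then renormalized: odds scale exactly by δ
    phi_t = delta * phi_v / (delta * phi_v + (1.0 - phi_v))
    pi_t = pi0 + np.log2(delta)

    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "affected": affected,
            "phi_vehicle": phi_v,
            "phi_treated": phi_t,
            "true_pi_vehicle": pi0,
            "true_pi_treated": pi_t,
            "true_pi_gain": np.log2(delta),
            "true_promoter_fc": delta,
            "expected_promoter_fragments_vehicle": config.depth_per_gene * phi_v,
            "expected_promoter_fragments_treated": config.depth_per_gene * phi_t,
        }
    ).set_index("gene_id")


def _truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_fragments(
    genes: list[GeneRecord],
    truth: pd.DataFrame,
    config: SyntheticConfig,
    condition: str = "vehicle",
    replicate: int = 1,
) -> FragmentSet:
    """Sample one replicate's fragments for one condition (BED-ready).

    Per gene: N ~ Poisson(λ); promoter-proximal fragments are Binomial(N,
    φ′) with midpoints truncated-normal around the pause site; the rest
    have midpoints uniform on the gene-body window.  Background fragment
    midpoints are uniform genome-wide at ``background_rate`` per bp.
    Fragment lengths are normal (truncated ≥ 50 bp).
    """
    if condition not in _CONDITION_CODE:
        raise ValueError(f"unknown condition {condition!r}")
    rng = config.rng(30, _CONDITION_CODE[condition], replicate)
    clen = chrom_length(config, genes)
    sizes = {config.chrom: clen}
    windows = {w.gene_id: w for w in make_pausing_windows(genes, chrom_sizes=sizes)}
    phi_col = f"phi_{condition}"

    mids: list[np.ndarray] = []
    for g in genes:
        w = windows.get(g.gene_id)
        if w is None or g.gene_id not in truth.index:
            continue
        phi = float(truth.loc[g.gene_id, phi_col])
        n = rng.poisson(config.depth_per_gene)
        if n == 0:
            continue
        n_prom = rng.binomial(n, phi)
        n_body = n - n_prom
        if n_prom:
            if g.strand == "+":
                site = g.tss + config.pause_site_offset_bp
            else:
                site = g.tss - config.pause_site_offset_bp
            mids.append(
                _truncnorm(rng, site, config.pause_site_sd_bp,
                           w.promoter[0], w.promoter[1] - 1, n_prom)
            )
        if n_body:
            mids.append(rng.uniform(w.body[0], w.body[1], size=n_body))
    n_bg = rng.poisson(config.background_rate * clen)
    if n_bg:
        mids.append(rng.uniform(0, clen, size=n_bg))

    if mids:
        mid = np.concatenate(mids)
    else:
        mid = np.array([])
    lengths = _truncnorm(
        rng, config.fragment_length_mean, config.fragment_length_sd,
        50.0, np.inf, mid.size,
    )
    start = np.maximum(0, np.rint(mid - lengths / 2)).astype(np.int64)
    end = np.minimum(clen, np.rint(mid + lengths / 2)).astype(np.int64)
    ok = end > start
    df = pd.DataFrame({"chrom": config.chrom, "start": start[ok], "end": end[ok]})
    df = df.sort_values(["start", "end"]).reset_index(drop=True)
    return FragmentSet(f"{condition}_rep{replicate}", df)


def simulate_peaks(
    truth: pd.DataFrame,
    genes: list[GeneRecord],
    config: SyntheticConfig,
    condition: str = "vehicle",
    n_replicates: int = 2,
) -> list[PeakSet]:
    """Per-replicate promoter peak calls derived from true occupancy.

    A peak is emitted over the ±300 bp promoter of every gene whose
    expected promoter fragment count under ``condition`` exceeds the
    configured threshold, with edges jittered ±peak_jitter_bp per
    replicate.
    """
    col = f"expected_promoter_fragments_{condition}"
    out = []
    for rep in range(1, n_replicates + 1):
        rng = config.rng(40, _CONDITION_CODE[condition], rep)
        rows = []
        for g in genes:
            if g.gene_id not in truth.index:
                continue
            if float(truth.loc[g.gene_id, col]) <= config.peak_occupancy_threshold:
                continue
            c = g.tss_boundary
            j = config.peak_jitter_bp
            jit_lo = int(rng.integers(-j, j, endpoint=True)) if j else 0
            jit_hi = int(rng.integers(-j, j, endpoint=True)) if j else 0
            rows.append((g.chrom, max(0, c - 300 + jit_lo), c + 300 + jit_hi))
        out.append(
            PeakSet(
                f"{condition}_rep{rep}",
                pd.DataFrame(rows, columns=["chrom", "start", "end"]),
            )
        )
    return out


def simulate_gene_sets(
    truth: pd.DataFrame,
    config: SyntheticConfig,
    n_sets: int = 10,
    set_size: int = 40,
    target_affected_fraction: float = 0.9,
) -> GeneSetCollection:
    """Decoy sets drawn uniformly plus one TARGET_SET biased to affected genes."""
    rng = config.rng(50)
    genes = np.array(truth.index)
    affected = np.array(truth.index[truth["affected"]])
    unaffected = np.array(truth.index[~truth["affected"]])
    sets = {}
    n_aff = min(int(round(set_size * target_affected_fraction)), affected.size)
    target = list(rng.choice(affected, size=n_aff, replace=False))
    n_rest = min(set_size - n_aff, unaffected.size)
    target += list(rng.choice(unaffected, size=n_rest, replace=False))
    sets["TARGET_SET"] = target
    for i in range(n_sets - 1):
        sets[f"DECOY_{i:02d}"] = list(
            rng.choice(genes, size=min(set_size, genes.size), replace=False)
        )
    return GeneSetCollection("synthetic", sets)


def simulate_dose_response(
    config: SyntheticConfig,
    n_experiments: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """4PL responses with Gaussian noise; vehicle rows at 100% + noise."""
    from .dose_response import four_pl

    top, bottom, ic50, hill = config.fourpl_truth
    if not (0 <= bottom <= top <= 100):
        raise ValueError("fourpl_truth must satisfy 0 <= bottom <= top <= 100")
    rng = config.rng(60)
    rows = []
    for exp in range(1, n_experiments + 1):
        for dose in (0.0, *config.doses_nM):
            mu = 100.0 if dose == 0 else float(four_pl(dose, top, bottom, ic50, hill))
            for rep in range(1, config.n_dose_replicates + 1):
                noise = rng.normal(0.0, config.noise_sd_percent)
                rows.append((f"E{exp}", dose, rep, mu + noise))
    table = pd.DataFrame(rows, columns=["experiment", "dose_nM", "replicate",
                                        "response_pct"])
    truth = {"top": top, "bottom": bottom, "ic50": ic50, "hill": hill}
    return table, truth


def simulate_count_matrix(
    n_promoters: int = 2000,
    n_replicates: int = 2,
    mean_log: float = np.log(300.0),
    mean_sd: float = 0.5,
    dispersion: float = 0.05,
    log2fc: float | np.ndarray = 0.0,
    affected_fraction: float = 0.0,
    sample_scales: tuple[float, ...] | None = None,
    seed: int = 0,
) -> tuple[PromoterCountMatrix, pd.DataFrame]:
    """NB count matrix (2 conditions × replicates) with known effects.

    Baseline per-promoter means are log-normal; the treated mean is
    baseline × 2^log2fc for an ``affected_fraction`` subset (or per-
    promoter log2fc array).  ``sample_scales`` multiplies each sample's
    means (library-size differences); defaults to slightly unequal
    scales so size-factor estimation is exercised.
    """
    rng = np.random.default_rng([seed, 70])
    mu0 = rng.lognormal(mean_log, mean_sd, size=n_promoters)
    if np.isscalar(log2fc):
        affected = rng.random(n_promoters) < affected_fraction
        lfc = np.where(affected, float(log2fc), 0.0)
    else:
        lfc = np.asarray(log2fc, dtype=float)
        affected = lfc != 0
    mu_t = mu0 * 2.0**lfc

    if sample_scales is None:
        sample_scales = tuple(
            [1.0 + 0.1 * ((i % 3) - 1) for i in range(2 * n_replicates)]
        )
    samples = [f"vehicle_rep{r+1}" for r in range(n_replicates)] + [
        f"treated_rep{r+1}" for r in range(n_replicates)
    ]
    conditions = {s: ("vehicle" if s.startswith("vehicle") else "treated")
                  for s in samples}
    cols = {}
    for j, s in enumerate(samples):
        mu = (mu0 if conditions[s] == "vehicle" else mu_t) * sample_scales[j]
        if dispersion <= 1e-12:
            cols[s] = rng.poisson(mu)
        else:
            size = 1.0 / dispersion
            p = size / (size + mu)
            cols[s] = rng.negative_binomial(size, p)
    idx = [f"P{i:05d}" for i in range(n_promoters)]
    counts = pd.DataFrame(cols, index=idx)
    truth = pd.DataFrame(
        {"baseline_mean": mu0, "log2fc": lfc, "affected": affected}, index=idx
    )
    # library-scale factors are known by construction (geometric mean 1)
    scales = np.asarray(sample_scales, dtype=float)
    factors = pd.Series(scales / np.exp(np.log(scales).mean()), index=samples)
    return PromoterCountMatrix(counts, conditions, size_factors=factors), truth
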