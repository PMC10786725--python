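"""End-to-end synthetic ChIP pipeline: generate, count, test, enrich.

Convenience orchestration used by the CLI, the test suite and the
acceptance script: runs the full pausing/differential/enrichment analysis
on data from the synthetic generator and returns every intermediate
alongside the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential, enrichment, gene_model, pausing, signal_io
from .synthetic_data import (
    SyntheticConfig,
    assign_truth,
    chrom_length,
    simulate_annotation,
    simulate_fragments,
    simulate_gene_sets,
    simulate_peaks,
)

__all__ = ["ChipPipelineResult", "run_chip_pipeline"]

CONDITIONS = ("vehicle", "treated")


@dataclass
class ChipPipelineResult:
    genes: list
    filter_report: gene_model.FilterReport
    windows: list
    truth: pd.DataFrame
    universe: list[str]
    pausing_records: dict[str, list[pausing.PausingRecord]]
    pi: pd.DataFrame  # per-gene PI per condition (universe genes)
    wilcoxon: pausing.WilcoxonResult
    summary_treated: pausing.PausingSummary
    diff_table: pd.DataFrame
    enrichment_records: list[enrichment.EnrichmentRecord]

    @property
    def fraction_increased(self) -> float:
        return float((self.diff_table["class"] == "increased").mean())


def run_chip_pipeline(
    config: SyntheticConfig,
    n_replicates: int = 2,
    pseudocount: float = 0.5,
    paused_threshold: float = 1.0,
    alpha: float = 0.05,
    universe_mode: str = "consensus_peaks",
) -> ChipPipelineResult:
    """Generate synthetic ChIP data and run the full analysis.

    ``universe_mode``: "consensus_peaks" restricts the pausing and
    differential universe to filtered genes whose ±300 bp promoter
    carries a consensus peak in at least one condition; "all_filtered"
    uses every gene surviving the filters.
    """
    genes_all = simulate_annotation(config)
    genes, report = gene_model.filter_genes(genes_all)
    sizes = {config.chrom: chrom_length(config, genes_all)}
    windows = gene_model.make_pausing_windows(genes, chrom_sizes=sizes)
    diff_promoters = gene_model.make_diff_promoters(genes, chrom_sizes=sizes)
    truth = assign_truth(genes, config, windows=windows)

    frags = {
        (cond, rep): simulate_fragments(genes, truth, config, cond, rep)
        for cond in CONDITIONS
        for rep in range(1, n_replicates + 1)
    }

    # promoter universe from per-replicate peak calls
    if universe_mode == "consensus_peaks":
        consensus = []
        for cond in CONDITIONS:
            reps = simulate_peaks(truth, genes, config, cond, n_replicates)
            consensus.append(differential.consensus_peaks(reps[0], reps[1], cond))
        universe = differential.promoter_universe(consensus, diff_promoters)
    elif universe_mode == "all_filtered":
        universe = list(diff_promoters["region_id"])
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")

    uwindows = [w for w in windows if w.gene_id in set(universe)]
    prom_regions = gene_model.promoter_regions(uwindows)
    body_regions = gene_model.body_regions(uwindows)

    pausing_records = {}
    for cond in CONDITIONS:
        rep_counts = [
            (
                signal_io.count_fragments(frags[(cond, rep)], prom_regions),
                signal_io.count_fragments(frags[(cond, rep)], body_regions),
            )
            for rep in range(1, n_replicates + 1)
        ]
        pausing_records[cond] = pausing.condition_pi(
            rep_counts, uwindows, cond, pseudocount
        )

    pi = pd.DataFrame(
        {
            cond: pd.Series({r.gene_id: r.pi for r in recs})
            for cond, recs in pausing_records.items()
        }
    ).dropna()
    wres = pausing.paired_wilcoxon(pi["vehicle"], pi["treated"])
    summary = pausing.classify_paused(pausing_records["treated"], paused_threshold)

    # differential enrichment over ±300 bp promoters in the universe
    uprom = diff_promoters[diff_promoters["region_id"].isin(set(universe))]
    counts = {}
    conditions = {}
    libsizes = {}
    for (cond, rep), fs in frags.items():
        cv = signal_io.count_fragments(fs, uprom)
        counts[fs.sample_id] = cv.counts
        conditions[fs.sample_id] = cond
        libsizes[fs.sample_id] = fs.library_size
    # library-size factors: a CDK9 inhibitor shifts most promoters, so
    # matrix-internal normalization would absorb the global effect
    lib = pd.Series(libsizes, dtype=float)
    factors = lib / float(np.exp(np.log(lib).mean()))
    matrix = differential.PromoterCountMatrix(pd.DataFrame(counts), conditions,
                                              size_factors=factors)
    diff_table = differential.differential_test(matrix, alpha=alpha)

    foreground = list(diff_table.index[diff_table["class"] == "increased"])
    background = list(diff_table.index[diff_table["class"] != "increased"])
    if foreground and background:
        collection = simulate_gene_sets(truth, config)
        enr = enrichment.enrich(foreground, background, collection, alpha)
    else:
        enr = []

    return ChipPipelineResult(
        genes=genes,
        filter_report=report,
        windows=windows,
        truth=truth,
        universe=universe,
        pausing_records=pausing_records,
        pi=pi,
        wilcoxon=wres,
        summary_treated=summary,
        diff_table=diff_table,
        enrichment_records=enr,
    )
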