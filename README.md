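# pausekit

Quantifying RNA polymerase II (RNAPII) promoter-proximal pausing from
ChIP-seq, and the cell-based drug-response readouts that accompany a
transcriptional-inhibitor study. The package is aimed at genomics analysts
who have aligned ChIP fragments and peak calls in hand (alignment and peak
calling are upstream, out of scope) and want a tested, scriptable route
from those files to pausing indices, differential promoter enrichment,
gene-set over-representation, and IC50 / growth-rate / qPCR summaries —
plus a seeded synthetic-data generator with ground truth so the whole
pipeline can be exercised and validated without any external data.

## What it computes

**Pausing index.** For each gene (longest isoform; genes < 1 kb or < 3 kb
from a neighbour excluded) two windows are built: a proximal-promoter
window from 50 bp upstream to 300 bp downstream of the TSS, and a gene-body
window from 300 bp downstream of the TSS to 3 kb past the TES. With
fragment counts *n*<sub>p</sub>, *n*<sub>b</sub> and window lengths
*L*<sub>p</sub>, *L*<sub>b</sub>,

    PI = log2[(n_p + ε)/L_p] − log2[(n_b + ε)/L_b],   ε = 0.5

A gene with PI > 1 carries more than 2-fold more paused than elongating
polymerase. Conditions are compared with a two-sided paired Wilcoxon
signed-rank test on per-gene PIs (exact null for n ≤ 25, tie- and
continuity-corrected normal approximation above) and an ECDF shift.

**Differential promoter enrichment.** Peaks called in both replicates of
a condition are merged into consensus peaks; ±300 bp TSS promoters with a
consensus peak in ≥ 1 condition are tested 2 vs 2 between conditions with
an exact conditional negative-binomial count test (common method-of-moments
dispersion, median-of-ratios or library-size normalization) and classified
increased / decreased / no change at Benjamini–Hochberg FDR < 0.05.

**Gene-set over-representation.** Upper-tail hypergeometric test of GMT
gene sets among promoters gained with treatment, against the background of
unchanged + decreased promoters, BH-corrected.

**Dose-response and friends.** Four-parameter logistic fits
y = bottom + (top − bottom)/(1 + (x/IC50)^hill) with plateaus restrained to
0–100 %, IC50 optimized in log-space from a multi-start grid, and
per-experiment IC50s averaged with a t-based 95 % CI; caspase/live death
ratios; exponential growth rates from OLS on log signal; and 2^−ΔΔCt
relative expression.

## Worked example

```python
from pausekit import SyntheticConfig, run_chip_pipeline

res = run_chip_pipeline(SyntheticConfig(seed=1))
print(f"genes analysed: {res.summary_treated.n_genes}")
print(f"fraction paused after treatment: {res.summary_treated.fraction_paused:.2f}")
w = res.wilcoxon
print(f"paired Wilcoxon: W={w.W:.0f}, n={w.n}, p={w.p:.3g}")
print(f"fraction of promoters increased: {res.fraction_increased:.2f}")
print(res.enrichment_records[0].set_name, f"q={res.enrichment_records[0].q:.2e}")
```

prints

```
genes analysed: 300
fraction paused after treatment: 0.60
paired Wilcoxon: W=41043, n=300, p=1.15e-34
fraction of promoters increased: 0.62
TARGET_SET q=2.38e-04
```

Here the generator planted a promoter-rate increase (δ = 6) in 60 % of the
300 synthetic genes: the pipeline recovers that fraction both as genes with
PI > 1 after treatment (0.60) and as promoters with significantly increased
RNAPII (0.62), the paired Wilcoxon test rejects equality of the PI
distributions, and the planted gene set is flagged by the over-representation
test. The same stages run from files via the CLI
(`pausekit simulate | windows | count | pi | diff | enrich | ic50 | growth | ddct`).

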