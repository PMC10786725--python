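# Methods

## Coordinate and window conventions

All coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read. The TSS of a minus-strand gene
is `end − 1`. One transcript per gene is kept — the longest, with ties
broken by the lexicographically smallest transcript id. Gene spans are
genomic (no exon-aware splicing).

Pausing windows: plus strand, promoter `[TSS−50, TSS+300)` and body
`[TSS+300, TES+3000)`; minus strand mirrored in the transcription
direction, so the promoter is always 350 bp and the body abuts it. The
±300 bp differential promoters are centred on the half-open TSS boundary
(`start` on +, `end` on −) so both strands get 600 bp. Windows are clipped
to `[0, chrom_size)` and the clipped lengths are used for densities; a
gene whose body vanishes after clipping is dropped.

Gene filters: length < 1,000 bp excludes a gene (strict `<`; exactly
1 kb is kept). The "< 3 kb from each other" rule is read as intergenic
gap between gene *spans* on the same chromosome, strand-agnostic, with
both members of a violating pair removed; overlap counts as gap ≤ 0.
Proximity is assessed among genes that passed the length filter, since
short genes are already out of the analysis. Each excluded gene carries
exactly one reason, so the filter report balances.

## Counting

Fragments are assigned to windows by their midpoint `floor((start+end)/2)`
so a fragment straddling the promoter/body boundary is never counted
twice; with disjoint windows, counting a partition conserves the library
size exactly. Any-overlap counting is available as an option. Duplicates
are kept (no dedup stage), and single-end reads — if fragments come from
the BAM adapter — are extended to 200 bp in read orientation; paired
records are collapsed to template spans.

## Pausing index and condition comparison

PI = log2((n_p+ε)/L_p) − log2((n_b+ε)/L_b) with ε = 0.5 added to both
counts, which keeps the PI finite at zero counts and biases large counts
negligibly. Replicates are averaged *before* the log: per-gene counts are
averaged across replicates per condition (equivalently densities, as
window lengths are shared) and the PI is computed on the average. The
pausing gene universe defaults to filtered genes whose ±300 bp promoter
carries a consensus peak in ≥ 1 condition; `universe_mode="all_filtered"`
uses every filtered gene.

The paired Wilcoxon signed-rank test drops zero differences, midranks
ties, and reports W = sum of ranks of positive differences (treated −
vehicle). For n ≤ 25 the null distribution is computed exactly by dynamic
programming over doubled midranks (two-sided p doubles the smaller
inclusive tail); above that, a normal approximation with the midrank
variance Σr²/4 (which absorbs the tie correction) and a 0.5 continuity
correction. Against brute-force enumeration of all sign assignments the
exact path agrees to machine precision; the approximation tracks exact
tail p-values within ~30 % at n ≈ 40, which is ample for the n ≈ 10²–10⁴
regimes it serves.

## Differential promoter enrichment

The comparison design (consensus peaks → ±300 bp promoter universe → 2 vs
2 count test → BH FDR < 0.05 → increased/decreased/no change) is preserved
while the count test is an explicit, documented construction (equivalence
with any particular differential-binding package is not claimed):

1. **Normalization.** Median-of-ratios size factors (DESeq-style) are
   implemented and used by default. When the treatment genuinely shifts
   the majority of promoters — exactly the global-pausing regime this
   package targets — factors computed on the promoter matrix absorb the
   effect, so `PromoterCountMatrix.size_factors` accepts externally
   derived factors and the pipeline supplies full-library-size factors
   (geometric mean 1).
2. **Dispersion.** A single NB dispersion α pooled across promoters by
   the method of moments on normalized within-condition mean/variance
   pairs: α̂ = Σ(s² − m)/Σm², clipped to [0, 10]. With thousands of
   promoters this is precise even at 2 replicates per condition.
3. **Test.** An exact conditional NB test per promoter: group sums of
   normalized counts (sum of r NB(μ, α) variables is NB(rμ, α/r)), the
   conditional distribution of one group's sum given the total, and a
   two-sided p from doubling the smaller inclusive tail. The exact
   conditional form was chosen over a Wald test for finite-sample
   calibration at 2 + 2 samples: on a 2,000-promoter NB null the raw
   p < 0.05 rate is ~0.046–0.058 across seeds.

log2 fold changes are log2 of (mean normalized treated + 0.5) over (mean
normalized vehicle + 0.5). BH adjustment uses the standard step-up
procedure with monotonicity enforcement.

## Gene-set over-representation

Plain upper-tail hypergeometric P(X ≥ k) per set, universe = foreground ∪
background only (matching the gained-vs-unchanged/decreased design), sets
first intersected with the universe, K = 0 sets skipped and excluded from
the BH family. Identifiers are matched case-sensitively after whitespace
trimming. No length-bias weighting is applied; if the original analysis
used length-aware weights the q-values would differ — a known divergence
risk.

## Dose-response, growth, qPCR

4PL fits run on the nonzero doses (vehicle anchors the 100 % scale but is
not a point on the curve, since the 4PL is undefined at x = 0 except as a
limit). Parameters are (top, bottom, log IC50, hill) with box constraints
0 ≤ plateaus ≤ 100; bottom ≤ top is enforced by the exact symmetry
(top, bottom, hill) → (bottom, top, −hill). The optimizer is bounded
least-squares started from a 10-point log-spaced IC50 grid spanning the
dose range crossed with hill ∈ {+1, −1}; the lowest RSS wins. Constant
responses yield `converged=False` rather than an exception. Noiseless
data are recovered to ≪ 4 significant figures; at 5 % Gaussian noise the
median IC50 error is ~5 % over 100 seeds.

Per-experiment IC50s are summarized as the arithmetic mean with a t-based
95 % CI (n − 1 df). With 3 experiments and 5 % response noise this CI
covers the true IC50 in ~90 % of simulations — slightly below nominal
because the IC50 sampling distribution is right-skewed at n = 3.

Growth curves are fit by OLS of ln(signal) on time; k is the slope and R²
is reported on the log scale. Relative expression is
2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_vehicle.

## Synthetic data: what it emulates, and what it does not

Per gene, fragment counts are Poisson(λ) and each fragment is
promoter-proximal with probability φ_g, else uniform on the gene body;
promoter-proximal midpoints are truncated-normal around a pause site
40 bp downstream of the TSS (sd 50 bp, a typical promoter-proximal pause
position); a uniform genome-wide background is added and fragment lengths
are truncated-normal (mean 200 bp, sd 50 bp, ≥ 50 bp). Treatment
multiplies the promoter rate of an affected subset by δ with φ
renormalized, so a gene's true PI gain is exactly log2 δ.

φ_g is parametrized through the baseline PI: given the gene's window
lengths, PI₀ ~ Normal(0.25, 0.2) in log2 fixes φ_g. The +0.25 baseline
reflects that unperturbed cells already show moderate promoter-proximal
RNAPII enrichment, and it puts per-promoter coverage in a range where a
4-fold promoter gain is recoverable at λ = 200 while unaffected genes
stay well below the paused threshold of PI > 1. Defaults λ = 1,000
fragments/gene (the desk-scale analogue of ≥ 60M-read-pair libraries over
~20k genes), δ = 6 (PI gain ≈ 2.58), affected fraction 0.60 applied to
exactly round(0.6·n) genes, 300 genes on one synthetic chromosome with
4–20 kb lengths and 5–40 kb gaps (deliberate short genes and close pairs
can be injected for filter testing). Peak calls are emitted per replicate
over promoters whose expected occupancy exceeds a threshold (default 5
expected fragments), edges jittered ±20 bp, so the consensus/universe
logic is exercised.

Not emulated: read-level sequence (FASTQ), mappability and GC bias,
duplicate structure, spike-ins, multi-chromosome genomes (optional),
inter-gene contamination and enhancer signal. Passing recovery tests on
this generator demonstrates the *pipeline arithmetic* — windows, counting,
normalization, tests — under known truth; it does not certify performance
on real chromatin, where fragment placement is far less regular.

Determinism: every generator draws from `default_rng([seed, stream,
condition, replicate])`, so outputs are pure functions of the config, and
distinct stages consume independent streams.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at 100–300 genes,
λ = 200–1,000, 2 replicates, and the count-test calibrations at 2,000
promoters — sizes chosen so the full suite completes in about a minute
while keeping Monte-Carlo standard errors well inside the asserted
tolerances. Degenerate inputs are handled explicitly: empty gene sets and
all-zero promoters are dropped with log entries, all-zero paired
differences return p = 1 with a warning, constant dose-response data are
flagged non-converged, and bound violations raise errors naming the
offending quantity or line.
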