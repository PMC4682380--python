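# Methods

## Model overview

`dmrhmm` compares two bisulfite-seq samples at CpG resolution. The observed
data at site *i* are count pairs (m_si, u_si) for samples s = 1, 2; the
hidden variable is the differential state of the site: Up (hypermethylated
in sample 1), Down, or NoCh. The model has three parts: per-sample
methylation-level priors, per-site emission functions built from them, and
a hidden Markov chain that couples neighbouring sites through learned
distance distributions.

### Level priors

Methylation levels pooled over a genome are bimodal. Each sample's level
distribution is modeled as

    p(θ) = w_H Beta(θ | α_H, 1) + w_L Beta(θ | 1, β_L) + w_unif · 1

with α_H ≥ 1 and β_L ≥ 1. The fixed unit shapes serve two purposes: each
beta component is then monotone, so it owns exactly one mode (high or low),
and the NoCh integral below stays in closed form. The parameters are
estimated by EM on the beta-binomial marginals of read counts — not on the
ratios m/n — at `n_sites = 10000` randomly chosen covered sites, so
sequencing depth shapes the posterior sharpness automatically. The E-step
computes component responsibilities from the closed-form marginals; the
M-step updates weights by responsibility means and each component's single
free shape by damped Newton ascent of the EM Q-objective with backtracking
and projection onto [1, 10^6]. Backtracking makes this a generalized EM:
the data log-likelihood is non-decreasing (asserted in tests to 1e-10
slack). Initialization is moment-based: sites are split at level 1/2, the
split proportions (times 0.95) initialize w_H and w_L with w_unif = 0.05,
and each component's shape is matched to its group mean. Convergence:
relative log-likelihood change < 1e-6, at most 500 iterations.

Both samples are fitted on the *same* site subsample (sites covered in both
samples) by default. This choice, beyond halving selection noise, makes the
fit exactly symmetric under exchanging the samples; per-sample subsampling
of each sample's own covered sites is available.

### Emissions

For each site the three states' emissions integrate the two binomial
likelihoods against state-dependent level priors: Up pairs sample 1's high
component with sample 2's low component; Down mirrors it; NoCh forces a
single common level drawn from the normalized product of the two full
mixtures. All three reduce to beta functions; NoCh expands over the 3 × 3
component pairs with normalizer Z = Σ_{s,t} w_s w_t
B(α_s+α_t−1, β_s+β_t−1) / (B(α_s,β_s) B(α_t,β_t)), the exact integral of
the mixture product. The shape constraints guarantee α_s + α_t − 1 ≥ 1, so
every beta function is defined (asserted at construction). Everything is
computed in log space via log-gamma; for fixed coverages each emission is a
proper distribution over count outcomes (tested by exhaustive summation).

A site with no reads in either sample emits probability 1 in every state:
it stays in the chain, so inter-CpG distances remain correct, without
influencing state inference.

The legacy pseudocount emissions are retained behind
`emission_mode="legacy"`: plug-in binomials with levels tilted by an
empirical pseudocount (toward 1 for the sample expected high, toward 0 for
the other; pooled level for NoCh, clamped to [1e-12, 1−1e-12] before the
log). With pseudocount 0 the Up and Down levels coincide and direction is
unidentifiable; the optimal pseudocount depends on depth, which is the
weakness the mixture emissions remove.

### The chain

State space {CpG, gap} × {Up, Down, NoCh} × {basic, second}. CpG states are
visited exactly at CpG positions and carry the emissions (shared between
units); gap states are silent and fill the d = pos_{i+1} − pos_i − 1
interval positions between consecutive CpGs. Topology: each CpG state
enters its own gap state deterministically; gap states self-loop
(probability a per state) or exit to any CpG state, so direction changes
and unit switches happen at gap→CpG boundaries. Dwell in a gap state is
geometric, and the duplicated unit gives each differential state a
two-geometric mixture of distance distributions — differential cytosines
cluster at much shorter distances than unchanged ones, and this is where
that signal lives.

Because gap runs are silent self-loops, they collapse exactly: the
CpG-to-CpG kernel at distance d is a^{d−1} (1−a) q per source state,
evaluated in log space (no underflow at any d; distances are capped at
10^6, far beyond any real chromosome gap's information content). The
kernels are deliberately substochastic — the model assigns probability to
the observed distances themselves, which is what lets EM fit the distance
distributions. A consequence worth noting: with all-equal emissions the
chain log-likelihood equals the log-probability of the observed gap-length
pattern (negative), not zero.

Transition and initial probabilities are learned by Baum–Welch with
emissions fixed. The expected gap self-loop count per traversal is
analytic (d − 1 self-loops and one exit), so the M-step is the exact EM
update and the likelihood is monotone. Chromosomes are independent chains
sharing parameters and initial distribution. Starting values are
near-uniform exit targets with a small unit asymmetry (the second unit
starts with longer dwell and stronger direction persistence) so EM can
differentiate the units; the asymmetry, including its seeded jitter, is
replicated across the three directions, keeping the starting point exactly
invariant under relabeling Up↔Down. Convergence: absolute log-likelihood
change < 1e-4, at most 100 iterations. The initial state distribution puts
0.9 on NoCh.

### Scoring and extraction

A region [s, e] with direction dir is scored as the log ratio between the
best constrained path (dir on sites s..e, NoCh elsewhere) and the best
all-NoCh path. Units are collapsed Viterbi-style before scoring: each
per-distance kernel is reduced to a 3 × 3 per-direction matrix by taking
the most probable unit pair, and the initial distribution by the most
probable unit. This makes the score an exact sum of per-site increments
(emission log ratios plus transition log ratios against the NoCh→NoCh
baseline), at the price of letting the unit choice vary per step rather
than tracing one consistent unit path — the practical difference is
negligible because the kernel maxima are dominated by the persistent unit
inside regions.

Extraction maximizes the total score of a set of disjoint segments, each
individually above the score threshold (default 0), with a linear dynamic
program over three macro states (outside / inside-Up / inside-Down) and
exact traceback; adjacent segments are allowed under the additive
semantics. On small instances the result provably matches exhaustive
search over all disjoint (start, end, direction) combinations (tested up
to 8 sites). Overlap between Up and Down candidates is resolved by the
same maximization. Output is ranked by descending score, ties broken by
(chrom, start); intervals span first to last CpG dinucleotide
(end = last position + 2).

### Numerical symmetry under sample exchange

Swapping the two samples should turn every Up call into an identical Down
call with an identical score. The package makes this exact in floating
point, not just to rounding: emission terms are grouped per sample so sums
commute, the NoCh component-pair reduction is transpose-symmetric, and
every reduction over the 6-state axis in forward/backward and Baum–Welch
uses a fixed tree (units within direction first, then (Up + Down) + NoCh)
that is invariant under the direction relabeling. The end-to-end test
asserts bit-exact interval and score agreement.

## Synthetic data

The generator emulates a planted-DMR benchmark at the count level; it does
not model reads, qualities or alignment. Defaults define the study
conditions and are not tuned per experiment:

- 20000 CpG sites; spacing a mixture of two geometrics (25% "island"
  spacing, mean 15 bp; 75% background, mean 120 bp; floor 2 bp), ~94 bp
  mean — a desk-scale stand-in for CpG islands in a CpG-poor sea.
- baseline levels per site from the bimodal mixture (w_H = 0.5,
  w_L = 0.45, w_unif = 0.05, α_H = 8, β_L = 8), shared by both samples.
- 50 planted non-overlapping regions of 5000 bp (~50 CpGs each), direction
  Up/Down with probability 1/2 each.
- counts n ~ Poisson(10) per site and sample, m ~ Binomial(n, θ′) with
  θ′ = θ(1−ε) + (1−θ)ε and conversion/sequencing error ε = 0.005.

Inside planted regions the level *switches fully* by default
(`switch_mode="both"`): sample 1 to the maximum and sample 2 to the minimum
for Up, mirrored for Down, so the planted direction is true at every CpG of
the region. The alternative `switch_mode="sample2"` changes only sample 2
and leaves sample 1 at its baseline; with bimodal baselines that makes
planted regions mosaics in which roughly the low-mode fraction of sites is
not differential at all, and any scorer that honestly penalizes
non-differential sites fragments such regions into their differential
sub-segments. The default was chosen because it is the only reading under
which the planted direction labels are correct site-wise and whole-region
recovery is a meaningful target; the one-sided mode remains available to
study the mosaic regime deliberately.

What passing benchmarks does and does not show: the simulator draws levels
independently per site, plants rectangular regions with extreme levels, and
uses Poisson coverage with a single error rate. Real data have correlated
levels along the genome, partial-magnitude DMRs, coverage that varies with
mappability and GC, and strand- and context-dependent error — so recovery
rates here bound the idealized regime only.

## Benchmark metric

A planted region is recovered if some top-k call overlaps it reciprocally
in at least the criterion fraction (0.5 / 0.9 / 0.99) of *both* lengths and
(by default) matches direction. Predictions are consumed in rank order and
each may match at most one truth region (best overlap among unmatched).
The reported rate divides by k; benchmarks plant as many regions as they
rank (k = n_dmr), so the rate is precision and recall at once.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 10000 | sites subsampled for each mixture fit |
| mixture `tol`, `max_iter` | 1e-6 (relative), 500 | EM stopping rule |
| HMM `tol`, `max_iter` | 1e-4 (absolute), 100 | Baum–Welch stopping rule |
| `threshold` (`--min-score`) | 0 | minimum segment log-likelihood ratio |
| `pseudo` | none (required in legacy mode) | legacy level tilt |
| simulator | see above | study conditions |

## Known limitations

- Two samples only; no replicates or covariates.
- No FDR calibration of scores; the ranked list is the interface.
- The unit-collapsed score is a Viterbi-style approximation of the
  constrained path probability, chosen for exact linear-time extraction.
- The mixture constraints (β_H = α_L = 1) assume clean bimodality; datasets
  with a dominant intermediate mode would be served poorly by design.
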