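# dmrhmm

De novo detection of differentially methylated regions (DMRs) from
two-sample whole-genome bisulfite sequencing, directly from per-CpG read
counts.

## The problem

Bisulfite sequencing reads out cytosine methylation: at each CpG site a
sample yields `m` reads supporting methylation and `u` reads against it
(coverage `n = m + u`). Comparing two samples — tumour vs. normal, stem vs.
differentiated — the task is to find *regions* where methylation changed,
including their boundaries, not just isolated differential cytosines. Window
methods need a window size, but real DMRs range from hundreds of bases to
megabases, so `dmrhmm` uses a hidden Markov model whose transition
probabilities are learned from each dataset and whose emission functions
exploit the genome-wide distribution of methylation levels.

## The model

Each CpG site *i* is in one of three differential states: **Up**
(hypermethylated in sample 1), **Down**, or **NoCh** (no change). Emissions
integrate binomial read-count likelihoods against state-dependent level
priors:

    e_i^Up   = ∫∫ Binom(m1|n1, θ1) Binom(m2|n2, θ2) p_H(θ1) p_L(θ2) dθ1 dθ2
    e_i^Down = the mirror image
    e_i^NoCh = (1/Z) ∫ Binom(m1|n1, θ) Binom(m2|n2, θ) p1(θ) p2(θ) dθ

where each sample's level prior is a constrained beta mixture
`p(θ) = w_H Beta(θ|α_H, 1) + w_L Beta(θ|1, β_L) + w_unif`, fitted by
maximum likelihood (EM on beta-binomial marginals) to counts at 10000
randomly chosen covered sites — matching the bimodal shape of genome-wide
methylation levels. All integrals reduce to beta-function closed forms.

The chain itself has a CpG state and a silent *gap* state per differential
state, duplicated into two units, 12 states in all. Gap states occupy the
interval positions between CpGs; their self-transition probabilities encode
per-state geometric distance distributions (a two-component mixture thanks
to the duplicated unit), and Baum–Welch adjusts all transition
probabilities to each dataset with emissions held fixed. Gap runs collapse
analytically, so chromosomes with megabase CpG deserts cost nothing extra.

DMRs are the disjoint segments maximizing the log-likelihood-ratio score
log P(region, dir) / P(region, NoCh), extracted by a linear-time dynamic
program and ranked by score.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

simulates 4000 CpG sites with 8 planted DMRs (full methylation switch,
mean coverage 10×), runs the whole pipeline — mixture fit, emissions,
Baum–Welch, extraction — and prints:

```
detected 9 DMRs (Baum-Welch ran 68 iterations)

rank direction      start        end  n_cpg   score
   1      Down     121071     123590     38   618.8
   2      Down      13438      16236     38   610.5
   ...
top-8 accuracy at 50% reciprocal overlap: 1.00
top-8 accuracy at 90% reciprocal overlap: 1.00
top-8 accuracy at 99% reciprocal overlap: 1.00
```

The score is the log-likelihood ratio in nats (larger = stronger evidence);
a planted region counts as recovered when a top-k call reciprocally
overlaps it in at least the stated fraction of both lengths with the right
direction. The other examples fit the level mixture on its own
(`02_fit_level_mixture.py`), show per-site emissions and region scores
(`03_emissions_and_region_scores.py`), and compare the fitted-mixture
emissions against the legacy pseudocount emissions
(`04_legacy_vs_mixture_emissions.py`).

## Command line

```sh
dmrhmm simulate --n-cpg 20000 --n-dmr 50 --seed 1 -o data/
dmrhmm fit -i data/counts.tsv -o data/params.txt
dmrhmm detect -i data/counts.tsv --params data/params.txt -o data/dmrs.bed
dmrhmm evaluate --pred data/dmrs.bed --truth data/truth.bed -k 50
dmrhmm run-all --seed 1 -o run/          # all of the above in one go
```

Input is a TAB-separated table `chrom pos m1 u1 m2 u2` (0-based positions;
`--one-based` converts), or a pair of bedGraph-style per-sample count
files. Output is a ranked BED with the direction in the strand column
(`+` = Up) and the full-precision score in column 7.

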