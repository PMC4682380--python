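"""Fit the genome-wide methylation-level prior from read counts.

Pooled methylation levels m/n are bimodal: a high mode near 1, a low mode
near 0, plus a thin uniform background.  The prior is a constrained
three-component beta mixture fitted by maximum likelihood on the counts
themselves (not the ratios), so sequencing depth informs the fit.
"""

import numpy as np

from dmrhmm import BetaMixture, fit_beta_mixture

truth = BetaMixture(w_h=0.5, w_l=0.45, w_unif=0.05, alpha_h=8.0, beta_l=8.0)
rng = np.random.default_rng(0)

n_sites, depth = 10000, 10
comp = rng.choice(3, size=n_sites, p=truth.weights)
theta = np.where(comp == 0, rng.beta(truth.alpha_h, 1, n_sites),
                 np.where(comp == 1, rng.beta(1, truth.beta_l, n_sites),
                          rng.random(n_sites)))
n = np.maximum(rng.poisson(depth, n_sites), 1)
m = rng.binomial(n, theta)

mix, history = fit_beta_mixture(np.column_stack([m, n - m]))
print(f"EM converged in {len(history)} iterations "
      f"(final log-likelihood {history[-1]:.1f})\n")
print(f"{'parameter':>12} {'truth':>8} {'fitted':>8}")
for name, t, f in [("w_high", truth.w_h, mix.w_h),
                   ("w_low", truth.w_l, mix.w_l),
                   ("w_unif", truth.w_unif, mix.w_unif),
                   ("alpha_high", truth.alpha_h, mix.alpha_h),
                   ("beta_low", truth.beta_l, mix.beta_l)]:
    print(f"{name:>12} {t:>8.3f} {f:>8.3f}")
print("\nalpha_high/beta_low control how sharply the two modes peak at 1/0;"
      "\nthe weights are the genome-wide fractions of each mode")
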