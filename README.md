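# coalabc

Joint estimation of the population-scaled recombination rate **ρ = 4Nrl**,
the population-scaled codon substitution rate **θ = 4NµL** and the
nonsynonymous/synonymous rate ratio **ω = dN/dS** from a single
protein-coding multiple sequence alignment, by approximate Bayesian
computation (ABC).

Recombination biases phylogeny-based dN/dS estimation, and substitution and
recombination rates are rarely estimated jointly. `coalabc` sidesteps the
intractable likelihood of a recombining coding alignment by simulation:

1. **Simulate** alignments under a neutral constant-size coalescent with
   recombination (including intracodon breakpoints) and GY94 codon
   substitution (κ transition/transversion ratio or GTR exchangeabilities,
   arbitrary sense-codon frequencies, gamma rate variation, invariable
   sites), with (ρ, θ, ω) and the nuisance parameters drawn from priors.
2. **Summarise** each simulated alignment and the observed one with the same
   26 statistics: three fast recombination tests (PHI, NSS, MaxChi); four
   moments of pairwise diversity and of per-site heterozygosity at codon and
   amino-acid levels; segregating sites at nucleotide, codon and amino-acid
   levels; and four joint codon/amino-acid statistics.
3. **Estimate** (ρ, θ, ω) by rejection — keep the fraction `tolerance` of
   simulations closest to the observed summaries — optionally followed by
   weighted local-linear regression adjustment on none/log/logit scales
   with an optional heteroscedasticity correction. Posterior
   modes come from a weighted kernel density; intervals are weighted
   2.5%/97.5% quantiles.

The target audience is molecular evolutionary biologists analysing
recombining protein-coding genes (the method was motivated by data such as
HIV-1, where recombination and substitution rates are both high).
See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Estimate parameters for a pseudo-observed alignment simulated at known
values (ρ=10, θ=100, ω=0.5; 15 sequences × 300 codons):

```python
import numpy as np
from coalabc import (CoalescentConfig, SubstitutionParams, simulate_arg,
                     evolve_alignment, write_fasta)
from coalabc.pipeline import PriorSpec, RunConfig, run_estimation

rng = np.random.default_rng(1)
gen = simulate_arg(CoalescentConfig(n_samples=15, l_nt=900, rho=10.0), rng)
params = SubstitutionParams(theta=100.0, omega=0.5, kappa=0.5, n_codons=300)
observed = evolve_alignment(gen, params, rng)

spec = PriorSpec(rho=(0, 50), theta=(0, 300), omega=(0, 2), kappa=0.5)
config = RunConfig(n_simulations=3000, n_samples=15, n_codons=300,
                   tolerance=100 / 3000, method="loclinear",
                   transform="logit", seed=7)
result = run_estimation(observed, spec, config)
for name in ("rho", "theta", "omega"):
    lo, hi = result.intervals[name]
    print(f"{name}: mode {result.modes[name]:.3g}  95% CI [{lo:.3g}, {hi:.3g}]")
```

Output from this exact script (about a minute of simulation; a logged
warning notes that a few of the 26 summaries are linearly dependent and are
dropped from the regression design):

```
rho: mode 7.34  95% CI [1.82, 25.9]
theta: mode 81  95% CI [53.8, 118]
omega: mode 0.56  95% CI [0.376, 0.749]
```

All three generating values fall inside their 95% intervals; ω and θ are
comparatively sharp while ρ, as expected for a single alignment, carries a
wide interval. The same analysis from the shell:

```sh
coalabc estimate --observed obs.fasta --n-simulations 3000 \
    --n-accept 100 --method loclinear --transform logit \
    --seed 7 --out run/
coalabc sumstats obs.fasta          # the 26-statistic summary vector
coalabc validate --cell 0 --seed 0  # recovery benchmark at one design cell
```

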