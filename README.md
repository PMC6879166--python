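# rhosmc

Inference of recombination landscapes — and jointly, demographic history —
from a **single pair of genomes**, using a Markov-modulated pairwise
sequentially Markovian coalescent (SMC') hidden Markov model.

## The problem

The population recombination rate ρ = 4·Ne·r varies along genomes over
orders of magnitude.  LD-based methods estimate its landscape from dozens
of sampled haplotypes; for most species no such sample exists.  A single
diploid individual, however, already carries a record of past
recombination: along the genome, the time to the most recent common
ancestor (TMRCA) of its two haplotypes changes wherever an ancestral
cross-over occurred, and the local density of heterozygous sites tracks the
local TMRCA.  `rhosmc` exploits this by modelling, per site:

- a hidden TMRCA interval (the genealogy), transitioning between sites
  according to the SMC' coalescent with local rate ρ_i, under
  piecewise-constant coalescence rates λ(τ) (the demography, parameterised
  by cubic splines); and
- a hidden recombination-rate category, ρ_i = ρ0·r_l with multipliers r_l
  from a discretised mean-one Gamma(α) prior, switching between sites with
  autocorrelation parameter δ.

The composite chain over (category, interval) pairs is an HMM with
n = t·k hidden states whose transition matrix is assembled from the k
genealogy kernels Q_SMC(ρ0·r_l) and the k×k category-switch matrix
(diagonal 1−δ, off-diagonals δ/(k−1)).  Fitting maximises the forward
likelihood over (ρ0, δ, α, spline knots) with Powell's method; AIC decides
between this model and the constant-ρ null (k = 1).  Posterior decoding
then yields a per-site posterior-mean map ρ̄_i = ρ0·Σ_l r_l·P_i(l), which
is binned into windowed maps, compared with other maps by Pearson/Spearman
correlation, and optionally restricted to recent TMRCA intervals to focus
on recent recombination.  See `docs/methods.md` for the full model.

## A worked example

```python
import rhosmc as r

# a 1 Mb pair on a heterogeneous landscape: Gamma(0.5) segment rates,
# 100 kb mean segment length, rho0 = 0.0012, theta = 0.003
land  = r.gen_rho_landscape(0.5, 100_000, 1_000_000, 0.0012, seed=1)
truth = r.simulate_sequential_smc(land, None, None, 0.003, seed=2)

hom = r.fit(truth.obs, t=10, k=1, maxiter=10)                 # null model
het = r.fit(truth.obs, t=10, k=5, init=hom, maxiter=10,
            refit_demography=False)                           # full model
print(round(r.select_model(hom, het).delta_aic, 1))           # 12.5

field = r.decode(truth.obs, het)
rmap  = r.posterior_mean_rho(field, het.prior)
res   = r.compare_r2(r.bin_map(rmap, 50_000),
                     r.bin_values(land.per_site(), 50_000), seed=0)
print(round(res.r2, 2))                                       # 0.84
```

The ΔAIC of 12.5 (positive: the heterogeneous model wins clearly) says
the pair carries a real signal of rate variation; the R² of 0.84 means the
inferred 50 kb map explains 84% of the variance of the true landscape at
that scale (this replicate is a lucky one; typical 1–2 Mb replicates spread
over roughly 0.4–0.9).  The scripts in `examples/` walk through this
pipeline, the fixed-prior protocol for heavily gapped (e.g. ancient)
samples, and UPGMA clustering of maps from several samples.

A command-line interface mirrors the library:

```
rhosmc simulate -L 1000000 --seed 5 -o sim
rhosmc fit sim_1.fa sim_2.fa --t 10 --k 5 -o fit
rhosmc decode sim_1.fa sim_2.fa --fit fit_k5.fit.json --width 50000 -o map
rhosmc bin sim_truth.tsv --width 50000 -o truth.bedgraph
rhosmc compare map_50000.bedgraph truth.bedgraph
```

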