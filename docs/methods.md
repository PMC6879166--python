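# Methods

## Model

`rhosmc` infers the spatial variation of the population recombination rate
ρ = 4·Ne·r along a genome, together with demographic history, from a single
pair of haploid genome sequences (equivalently one unphased diploid).  It is
a pairwise sequentially Markovian coalescent (SMC') hidden Markov model in
which the transition rates of the genealogy process are themselves modulated
by a second, hidden Markov chain of recombination-rate categories — a
Markov-modulated HMM.

**Time scale.** All times are scaled in units of 2·Ne generations, so the
pairwise TMRCA under a constant population has density λ·e^(−λτ) with λ = 1,
and the compound per-site rates θ = 4·Ne·μ and ρ = 4·Ne·r act on a tree of
height s through 1 − e^(−θs) (probability the site is heterozygous) and
1 − e^(−ρs) (probability of at least one recombination between adjacent
sites).  Only the compound rates are identifiable: Ne and r cannot be
separated, and a global rescaling of (time, λ, θ, ρ) leaves the likelihood
essentially unchanged — inferred *landscapes* are therefore meaningful up to
scale even when the absolute rates are not.

**Hidden states.** The TMRCA prior is discretised into `t` equal-probability
intervals (boundaries at prior quantiles; the representative time of an
interval is its conditional prior mean, with the infinite last interval
capped at five times the penultimate boundary).  Local recombination rates
are ρ0·r_l where the multipliers r_l are the means of the `k`
equal-probability slices of a mean-one Gamma(α, rate = α) prior, computed
from the closed-form Gamma partial expectation.  The composite chain has
n = t·k states; n ≤ 200 by default.

**Transitions.** The genealogy kernel follows SMC': on a tree of height s,
recombination events arrive at rate ρ·s per site; the break point is uniform
on the tree; the detached lineage re-coalesces at the local coalescence
rate, with two partner lineages below s — one of which restores the old
height (back-coalescence) — and one above.  The t×t matrix is computed as
the matrix exponential of the discretised jump generator, with the source
height integrated over its interval under the conditional prior
(Gauss–Legendre in prior-CDF space; within-interval re-coalescence integrals
in closed form on the piecewise-constant hazard).  Two consequences we rely
on: ρ = 0 gives the identity exactly, and the discretised prior is the
stationary law of the kernel to quadrature accuracy (~1e−8), because the
continuous SMC' process is stationary for the coalescent prior.  A
single-jump Bernoulli construction was rejected: its O((ρs)²) stationarity
bias is visible at model-regime ρ.

The category chain switches with a single autocorrelation parameter δ:
diagonal 1 − δ, off-diagonals δ/(k − 1).  The composite n×n matrix places
block (l, m) = P_lm · Q_SMC(ρ0·r_l): the genealogy transition uses the
*source* category's rate (the destination-rate reading of the block layout
is mathematically possible but not used).  Its stationary distribution is
exactly uniform-over-categories ⊗ discretised-prior, which is what the
forward recursion starts from at every contig.

**Emissions.** P(het | interval j) = 1 − e^(−θ·τ_j) at the representative
time τ_j; missing sites emit with probability one from every state.  θ is
fixed before optimisation from global heterozygosity ĥ as θ̂ = −ln(1 − ĥ),
which is exact to first order under the stationary constant-rate coalescent.
Under strongly non-constant demography θ̂ absorbs the mean tree height; by
the rescaling invariance above this shifts the *scale* of fitted rates but
not the shape of the inferred landscape.

**Demography.** Coalescence rates follow a natural cubic spline through
five control points in (log time, log rate) — two endpoints plus three
internal knots on a fixed geometric grid spanning scaled times 0.005–5 —
evaluated at interval boundaries and held constant within intervals.  The
parameter count (five log-rates) is independent of `t`.

## Likelihood, fitting, and decoding

The forward recursion runs over run-length-compressed observations: within
a run of m identical symbols the forward vector advances with cached binary
powers of the emission-weighted transition matrix (O(log m) matrix–vector
products), with per-site scaling in probability space.  Contigs restart at
the stationary distribution.  Posterior decoding is forward–backward with
windowed memory (O(n·window)): a backward sweep stores checkpoints at
window boundaries only, and a second sweep reconstructs backward vectors
one window at a time.  Per site we keep the category marginal, the MAP
TMRCA interval (marginalised over categories), the category posterior
conditioned on that interval, and a flag for sites whose MAP interval has
numerically vanishing mass (those fall back to the plain marginal).

Parameters (log ρ0; logit-bounded δ; log α; the five knot log-rates) are
optimised by Powell's derivative-free method; box constraints ρ0 ∈ [1e−6,
0.1], δ ∈ [1e−8, 0.5], α ∈ [0.05, 20] are enforced by the transforms.
Defaults: xtol 1e−3, ftol 1e−4, at most 200 iterations; optimisation is
deterministic given data and start.  The k = 1 model (6 parameters) is
fitted first and warm-starts the heterogeneous model (8 parameters); with
`refit_demography=False` the k > 1 stage optimises only (ρ0, δ, α) on top
of the stage-one demography — the staged scheme used for the desk-scale
benchmarks below.  Model choice is by AIC = 2p − 2·logL; ties go to the
null.  For heavily gapped samples the two-step fixed-prior protocol
assembles a heterogeneous model from the sample's own k = 1 demography fit
plus externally supplied (ρ0, α, δ), without re-optimisation.

**Maps.** The per-site map is the posterior mean ρ̄_i = ρ0·Σ_l r_l·P_i(l),
a convex combination of category rates and hence bounded by them.
Time-restricted maps use the category posterior conditioned on the MAP
TMRCA interval and, when binned, average only sites whose MAP interval
index is below the chosen cutoff — discarding recombination signal carried
by old, potentially shared, genealogies.  Binning uses non-overlapping
fixed-width windows (50 kb default; a trailing partial window is kept only
if it covers at least half a width); windows with more than 50% missing
data are masked.  Map agreement is the squared Pearson correlation over
jointly unmasked windows with a 100-replicate window bootstrap CI; a map
with zero variance is assigned R² = 0 (correlation is undefined, and a flat
map explains nothing).  Map clustering uses 1 − Spearman (average ranks for
ties) distances, UPGMA, bootstrap clade support by window resampling, and
collapses clades below 60% support in the Newick output.

## Synthetic data

The generator reproduces the benchmark conditions: piecewise-constant ρ
landscapes with Gamma(α, rate α) segment scales and geometric segment
lengths (mean g; minimum length 1); θ landscapes with Uniform(0.1, 10)
scales (mean 5.05, so θ0 = 0.003 gives an expected genome-wide θ = 0.01515)
and geometric lengths of mean f.  Sequences come from a *continuous-TMRCA*
sequential SMC' simulator (first height from the demography's prior; per
site, recombination with probability 1 − e^(−ρ_i·s), uniform break point,
re-coalescence with back-coalescence under the piecewise-constant hazard;
heterozygote emission with 1 − e^(−θ_i·s)), so the data-generating process
is not the discretised inference model.  Demographic scenarios: constant; a
20-fold expansion 0.01 time units ago; a 20-fold bottleneck 0.5 units ago.
Both are scaled to the smaller epoch's population size (expansion: recent
rate 1/20, ancient 1; bottleneck: recent 1, ancient 1/20), so that
sequence diversity stays at the benchmark level — scaling the expansion to
the present-day size instead would shrink mean tree height ~17-fold and
leave a few hundred SNPs per megabase, a regime in which no method can
recover the reference accuracy (verified with true-parameter decoding).
Two-population
introgression scenarios (split 2.0; 10% pulse at 0.125 or 0.25) are
generated with msprime's structured coalescent, since pairwise sequential
simulation does not cover population structure.  An exact generative twin
of the fitted HMM (`simulate_hmm_path`) exists for parameter-recovery
checks.  Clumped missing data (geometric tracts) emulates low-coverage
samples.

What the generator does *not* emulate: sequencing/genotyping error,
selection, gene conversion, trapped non-ancestral material, and landscape
evolution between samples.  Passing benchmarks therefore bound performance
under the model's own assumptions, not on real data.

## Benchmark problem sizes

The reference study uses 10 replicates of 30 Mb with 200 hidden states
(40×5 or 20×10).  The desk-scale replication in `scripts/acceptance.py` and
the acceptance tests uses 10×5 states, 50 kb windows, and replicate
lengths that are information-matched rather than uniform: 2 Mb for the
100 kb-segment designs, the null, the demographic and the introgression
scenarios; 4 Mb for the 1 Mb-segment designs so a replicate contains
several landscape segments (at 2 Mb they degenerate to near-constant
truths); and 6 Mb for the α = 5, g = 1 Mb design, the smallest length at
which its AIC signal — an order of magnitude weaker than at α = 0.5 — is
reliably detected.  The AIC tally uses 3 replicates per scenario; the map-
accuracy medians pool 4–5 decoded replicates per scenario.  The
demographic-scenario models are fitted on a 1.2 Mb prefix and decoded on
the full replicate: the bottleneck's ~8-fold SNP density makes full-length
fitting dominate runtime without changing the optimum appreciably.  Staged
fitting (`refit_demography=False`, maxiter 10, bounded function
evaluations) is used throughout.  At this scale the scatter of
per-replicate R² is a few tens of percentage points, which is why the
benchmarks report pooled medians and are compared with the reference
values at ±15 percentage points.

## Numerical choices and edge cases

- Row-stochasticity is exact by construction (generator rows sum to zero;
  expm output is clipped at 0 and row-normalised, a ~1e−15 correction).
- Gauss–Legendre with 8 nodes per dimension; the source-height integral is
  taken in prior-CDF space which handles the infinite last interval.
- Zero likelihood at a site raises an error naming the site and contig
  (e.g. an impossible emission), rather than returning −inf.
- Degenerate time-restricted sites (MAP interval mass ≤ 1e−12) fall back
  to the unrestricted posterior mean and are flagged.
- UPGMA ties are resolved by scipy's deterministic lowest-index merge;
  all bootstrap RNGs take explicit seeds and are recorded in outputs.
- The trailing-window rule (≥ half width) and the 0-based half-open
  coordinate convention apply everywhere, including BedGraph output.

## Known limitations

- Single pairs only; no multi-pair or phased extensions.
- θ is homogeneous in the inference model even when data were generated
  with a θ landscape; strong local mutation-rate variation is partly
  absorbed by the TMRCA posterior.
- Absolute rate levels inherit the θ̂ scale; cross-sample comparisons
  should rely on landscape shape (rank correlations), as the clustering
  machinery does.
- The spline demography has five fixed-knot parameters: adequate for the
  single-change histories benchmarked here, coarse for oscillatory
  histories.
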