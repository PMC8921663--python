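# Methods

## The model

A source community is a set of variants with proportions `p = (p₁ … p_k)`
on the simplex; its alpha diversity is the Shannon index
`S(p) = -Σ pᵢ ln pᵢ` in nats, with the continuity convention
`0·ln 0 = 0`. A library of N reads is modeled as
`x ~ Multinomial(N, p)`: reads generated independently with probabilities
equal to the source proportions. The plug-in estimate `S(x/N)` is biased
low for `S(p)` and the bias shrinks as N grows, which is why raw Shannon
values from libraries of different sizes are not comparable.

### When the multinomial holds, and when it does not

The multinomial is valid only under assumptions about the chain from
source to library, and `ampdiv.error_models` provides one generative
operator per link so each assumption can be probed by simulation:

- **Dispersion.** Randomly dispersed organisms give independent Poisson
  counts per variant (mean = concentration × volume). Independent Poisson
  counts conditioned on their total are *exactly* multinomial — for two
  variants with means in ratio 2:1 conditioned on N, variant-1 is
  `Binomial(N, 2/3)` — so pure sampling error is compatible. Clustering
  (including multiple gene copies per organism) is modeled by the
  negative binomial with mean μ and size k (variance `μ + μ²/k`); its
  conditional law is not binomial, so overdispersion breaks the model.
- **Loss / analytical recovery.** Binomial thinning
  `yᵢ ~ Binomial(xᵢ, rᵢ)`. Constant recovery across variants rescales
  every proportion equally and the conditioned composition is unchanged;
  differential recovery biases it.
- **Clustering operator.** The simplest mechanism — every organism
  contributes a fixed number of gene copies — multiplies counts, so
  conditioned totals live on multiples of the copy number, immediately
  outside binomial support.
- **Amplification.** Default is a Pólya urn: copies are added one at a
  time, each duplicating a molecule drawn with probability proportional
  to current counts, until the target total. A mechanistic alternative,
  `cycle_doubling`, duplicates each molecule independently with
  probability equal to the per-cycle efficiency and reports the final
  (possibly overshooting) total. Both preserve zeros — amplification
  inflates the library only at the diversity already present — and both
  distort the conditional count law: amplifying a 2:1 mixture from four
  to six reads yields a variant-1 distribution measurably different from
  `Binomial(6, 2/3)` (the exact urn pmf is obtained by enumeration in the
  test suite and has chi-square noncentrality ≈ 0.41 per replicate
  against the binomial).

Compatibility is decided by `binomial_compat_test`: a Pearson chi-square
goodness-of-fit of conditioned variant-1 counts against `Binomial(n, p)`
over the support `{0 … n}`, pooling cells with expected frequency below 5
from the tails inward, df = cells − 1, α = 0.05 by default. Conditioning
is by rejection (simulate, keep replicates whose total equals N), keeping
the simulate-then-condition structure of the experiments; the analytic
binomial is used only as the reference law.

## Bayesian inference of the source Shannon index

With a conjugate `Dirichlet(α)` prior over the k *modeled* variants
(default `α = 1` for every variant, equal prior weight), the posterior is
`Dirichlet(x + α)` in closed form. Each posterior draw of `p` yields one
draw of `S(p)`; the draw set is summarized by mean, median, quartiles,
Tukey whiskers (most extreme draws within 1.5×IQR of the quartiles — a
disclosed convention, since box-plot whisker rules vary) and a central
95% credible interval. Both mean and median are reported because point
summaries of a skewed posterior differ. The useful closed form
`E[S] = ψ(α₀+1) − Σ (αᵢ/α₀) ψ(αᵢ+1)` (digamma ψ, `α₀ = Σ αᵢ`, posterior
concentrations substituted) serves as an exact oracle in the tests.

Because inference conditions on the raw counts, libraries of different
sizes enter directly — no rarefying, scaling or pseudo-counts — and
posterior width automatically reflects N.

### Zero policies

The number of modeled variants k is the one quantity the data cannot
supply: zeros may be non-detects (present, missed), structural (truly
absent) or missing entirely (no row in the table). The choice is made
explicit:

- `observed_only` — model only detected variants. Treats every zero as
  structural; underestimates source diversity, badly so at small N. An
  all-zero sample is an error here (nothing left to model).
- `pad_to_richness(k)` — keep zeros up to richness k. With the true k
  this is the consistent analysis: the posterior concentrates on the
  source index as N grows. Padding beyond the true richness
  (extraneous zeros) overestimates, because never-observed variants keep
  positive posterior mass `αᵢ/(N+α₀)`.
- `table_zeros` — model one variant per row of a supplied ASV table,
  the situation of a multi-sample table whose rows include variants
  detected only in other samples.

The exact posterior mean is monotone non-decreasing in the padded
richness for fixed data (property-tested), which is the formal version of
"more modeled zeros, more estimated diversity". The default sampler draws
exact independent Dirichlet variates. A Gibbs mode (systematic sweeps of
pairwise conditional updates: for adjacent coordinates i, j the split of
`pᵢ+pⱼ` is redrawn from its exact Beta conditional; 10,000 draws after
1,000 burn-in sweeps by default, randomized initialization) is retained
for parity with general-purpose MCMC workflows; both modes target the
same posterior and are required to agree in distribution.

## Repeated rarefaction

Rarefying draws m reads without replacement from the N observed — an
exact multivariate hypergeometric sample (numpy's marginal-by-marginal
conditional implementation), so every repetition sums to m, no variant
exceeds its original count and zeros stay zero. Repetitions are
independent re-subsamples of the *original* vector, never chained, and
the per-repetition plug-in Shannon values form the sample's rarefied
diversity distribution. Defaults: 1,000 repetitions; depth m = the
smallest library size among the samples compared (`normalize_table`),
with shallower samples skipped with a warning rather than upsampled —
rarefying up is refused. Rarefaction estimates *sample-level* diversity
at a normalized depth; it does not estimate the source index (its mean at
m = 25 from the Scrabble source is ≈ 2.5, below the source's 3.03).

## Synthetic ground truth

`scrabble_population()` encodes the standard 100-tile English Scrabble
distribution — 27 variants: E×12; A,I×9; O×8; N,R,T×6; D,L,S,U×4; G×3;
B,C,F,H,M,P,V,W,Y,blank×2; J,K,Q,X,Z×1 — with source Shannon index
3.0292 (3.03 to 2 dp). It emulates compositional count data with modest
richness and strong unevenness and supports exact reasoning; it does not
emulate real amplicon features such as thousands of rare variants,
sequencing artifacts, or compositional correlation between samples, so
passing tests demonstrate correctness of the inferential machinery under
the multinomial model, not robustness to real-data violations of it
(which the error-model suite instead makes testable). Multinomial
sampling (with replacement) treats the bag as an effectively infinite
source; the finite-population hypergeometric alternative is deliberately
out of scope. Every sampler takes an explicit seed and fixed seeds give
bit-identical output.

## Numerical and design choices

- Natural log only; no log2 variant.
- Simplex validation tolerance 1e-12 (scaled mildly with length for long
  vectors); Shannon values clipped at 0 to absorb roundoff.
- Simulation scales: experiment sweeps use 5 replicate samples per
  library size with 10,000 posterior draws; compatibility experiments
  use 10,000 conditioned replicates (≈150,000 raw simulations for the
  negative binomial at total 6) and 200 repetitions for type-I-rate
  estimation — sizes chosen so Monte-Carlo error is well below the
  effects being demonstrated while the full suite runs in seconds.
- Chi-square pooling threshold of 5 expected counts and α = 0.05 follow
  conventional goodness-of-fit practice.
- Degenerate inputs: N = 0 has no proportion simplex (error);
  `observed_only` on an all-zero sample is an error; a single-variant
  model has S ≡ 0; `condition_on_library` retaining nothing warns and
  returns an empty matrix rather than raising.
- I/O is plain TSV/CSV with IDs rejected (not quoted) if they contain
  whitespace; both table orientations are readable via a transpose flag;
  BIOM/HDF5 are out of scope.

## Known limitations

- The Pólya-urn and cycle-doubling amplifiers are deliberately simple
  mechanisms; neither models primer bias, chimera formation or per-base
  error, and real PCR need not match either in distribution (both
  nevertheless exhibit the qualitative incompatibility that matters).
- Source richness is not estimable from a sample; `pad_to_richness` is
  only as good as the supplied k, and no unseen-richness estimator is
  provided on purpose.
- No hierarchical model links samples to a shared meta-community; each
  sample is analyzed alone.
- The Gibbs sampler is provided for workflow parity, not performance;
  the conjugate sampler is exact and should be preferred.
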