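# Methods

This note records the models implemented, the parameter and design choices
that were genuinely open, and what the synthetic-data experiments do and do
not demonstrate.

## Data model and diversity conventions

OTU tables are non-negative integer count matrices (taxa × samples) with
unique identifiers; all community statistics operate on a table rarefied to
a common depth. Conventions where the literature is not uniform:

- **Shannon** is reported in natural-log units (nats) so that Pielou's
  evenness is exactly H/ln S; Pielou is defined as 0 for single-taxon
  samples.
- **Simpson** is the Gini-Simpson index 1 − Σp² (the vegan-toolchain
  convention).
- **Rarefaction** is a single exact without-replacement draw per sample
  (multivariate hypergeometric), not an average over draws; the seed is part
  of the pipeline config, keeping downstream results deterministic. The
  default depth is the minimum sample depth — a convention, since no single
  depth is canonical.
- **Bray-Curtis** is computed on counts, **Jaccard** on presence/absence.
- **PCoA** is classical Gower scaling; negative eigenvalues are dropped and
  counted, and explained fractions are taken over the positive eigenvalue
  mass.
- **PERMANOVA** is one-way only, from the distance matrix directly
  (Anderson's among/within decomposition); p = (#{F* ≥ F} + 1)/(B + 1) with
  a seeded permutation stream. Factorial designs are handled as separate
  one-way runs per factor (site, depth), which answers the marginal
  "which factor separates communities more" question.

## Sloan neutral community model

Local relative abundances under neutral assembly follow
q ~ Beta(Nm·p̄, Nm·(1−p̄)). The occurrence frequency of a taxon is the
probability that it is *detected* in a sample sequenced to depth N.

- **Detection model.** The classical fitting scripts approximate detection
  as P(q > d) with a continuous detection limit d = 1/N. On data actually
  sampled at finite depth (including this package's own generator) that
  approximation undershoots the true detection probability of rare taxa and
  biases the fitted Nm upward by ~30%. The default here is therefore the
  exact zero-truncated beta-binomial form,
  P(detect) = 1 − B(a, b+N)/B(a, b), which recovers the generator's m with
  a 2–3% median error (N = 1000, 200 samples); the continuous approximation
  remains available as `fit_ncm(..., detection="beta_cdf")` for comparison
  with legacy fits.
- **Optimisation.** Nm is fitted by least squares on occurrence vs mean
  relative abundance, over a 200-point log grid on [0.1, 10N] refined by
  bounded scalar minimisation inside the best grid cell; the returned
  objective is verified (and unit-tested) to beat the whole grid.
- **Partitioning.** The 95% band is a Wilson score interval around the
  predicted frequency at n = number of samples, with a 1e-9 tolerance at
  the saturated ends (predicted frequency ≈ 1 makes the upper bound 1 only
  up to float round-off). Because many taxa are rare and occurrence counts
  are small and discrete, the band's effective coverage on neutral
  simulations is 84–90% rather than the nominal 95%; this is a property of
  per-taxon interval coverage, not a defect of the fit.
- Both m and Nm are reported, since published values are ambiguous about
  which is meant.

## Modified stochasticity ratio

For each within-group pair, MST = D/E when D ≤ E and (1−D)/(1−E) otherwise,
where D is the observed Jaccard dissimilarity and E the mean Jaccard
dissimilarity over null communities. The index is 1 exactly when D = E and
falls to 0 at either deterministic extreme; group means are reported in
percent with 50% as the determinism/stochasticity boundary.

- **Null model** (the cited methodology names none explicitly): per-sample
  richness is preserved; taxa are drawn without replacement with probability
  proportional to their occurrence frequency across the *whole* table;
  incidence only, 1000 randomizations by default. The whole-table pool is
  essential: a per-group pool would make strongly selected groups match
  their own null (MST → 100%), inverting the index's semantics.
- **Determinism and invariance.** Weighted sampling uses the
  exponential-race construction with randomness keyed to each sample's ID
  and to frequency-sorted taxon slots, which makes the result bit-identical
  under taxon relabeling and sample reordering, and fully determined by the
  seed.
- Pairs with degenerate null expectation (E = 0 or 1) are excluded and
  counted in the result.
- The reference implementation of the cited index was not available for a
  toy-matrix comparison, so the formula is validated through its fixed
  points (D = E → 100%, D ∈ {0,1} → 0) and the regime-discrimination
  experiment below.

## Levins niche breadth

B_j = 1/Σ_i P_ij² with P_ij the share of taxon j's reads in sample i;
1 ≤ B ≤ n_samples. The community value is the arithmetic mean over taxa
occurring in at least `min_occurrence` samples (default 1) — an
aggregation convention, documented because abundance-weighted alternatives
exist. Zero-count taxa are dropped and logged.

## Co-occurrence networks

Taxa above an overall relative-abundance floor (strictly greater than
0.1% of the grand total by default) are pairwise Spearman-correlated on
per-sample relative abundances; edges require |r| > 0.7 *and* p < 0.01
(t-approximation, raw p-values — no multiple-testing correction, matching
the stated thresholds). Zero-variance taxa are excluded (exact max−min
test) and isolated nodes dropped.

Topology record: average path length and diameter are computed over
reachable pairs only, aggregated across components; clustering is the mean
local coefficient with degree-<2 nodes contributing 0; density is
2E/(N(N−1)); with an empty edge set the path metrics and modularity are
reported as NaN markers.

**Modularity** is Newman modularity of a deterministic, seed-free
partition: exact maximum by complete set-partition enumeration for networks
of ≤ 10 nodes (Bell(10) ≈ 1.2e5 partitions, ~1 s), and
Clauset-Newman-Moore greedy agglomeration with deterministic single-node
move and community-merge refinement passes above that. Greedy CNM alone
misses the optimum on a noticeable fraction of small dense graphs, which is
why the exact branch exists; for large networks the reported value is a
deterministic lower bound, as for any heuristic. Published peatland-network
tables include modularity values above 1, which is impossible for Newman
modularity; whatever that quantity was, this package reports standard
Newman modularity only.

## Gas kinetics

- **Chamber flux**: F = (dc/dt)·(M/V₀)·(P/P₀)·(T₀/T)·H with
  M = 16.04 g/mol, V₀ = 22.414 L/mol, T₀ = 273.15 K, P₀ = 101.325 kPa;
  dc/dt is the OLS slope of ppm vs hours over all points (a configurable
  closure dead-band trim exists but defaults to 0). R² < 0.9 sets a QC flag
  without suppressing the value. Hand check: 1 ppm/h at H = 0.2 m and
  standard conditions is 0.2 m³/m² ÷ 22.414 L/mol = 8.923 mol m⁻² of air,
  hence 0.1431 mg CH₄ m⁻² h⁻¹.
- **Incubations**: each sampling removes an aliquot v and back-fills with
  N₂, scaling the carried-forward concentration by (V−v)/V. The correction
  adds all previously removed aliquots back
  (amount_k = C_k·V + Σ_{j<k} C_j·v), which restores an exactly linear
  series in noiseless simulations and conserves mass. Rates convert ppm to
  µg via the ideal gas law at the incubation temperature (20 °C default,
  the stated incubation condition) and are normalised per g dry peat
  (fresh mass × (1 − water content)) per day. Headspace volume defaults to
  90 mL (100-mL bottle minus ~10 g peat) but is an explicit, required
  config field, as are the sampled volume and units — none of these are
  standardised in the field literature.
- **qPCR**: efficiency = 10^(−1/slope) − 1 from the Cq vs log10(copies)
  fit; QC passes iff 0.90 ≤ efficiency ≤ 1.10 (inclusive, with a 1e-9
  float guard) and R² > 0.99. Quantification scales reaction copies by the
  eluate/template volume ratio per g fresh peat and flags Cq values outside
  the fitted standard range as extrapolation.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the estimators assume:

- **Neutral tables** use the stationary beta-binomial form of the neutral
  model (per-sample Beta draws at known m, multinomial counts at fixed
  depth) rather than explicit birth–death dynamics — identical stationary
  occurrence structure, orders of magnitude faster, and analytically
  checkable. Metacommunity abundances default to a deterministic Fisher
  log-series (quantile construction, mean abundance 200), matching typical
  amplicon rank-abundance shape.
- **Niche tables** weight taxa by exp(−(env−optimum)²/2σ²) times the same
  base abundances; σ sets selection strength. σ → ∞ recovers
  environment-independent sampling.
- **Gas series** are linear with additive Gaussian analyzer noise —
  unbiased for least-squares recovery; chamber slopes invert the flux
  formula exactly, and incubation series apply the dilution recursion
  event by event.
- **qPCR curves** follow Cq = intercept − log10(Q)/log10(1+E) on 10-fold
  dilutions.

Default experiment sizes mirror the motivating study design (48 samples =
4 sites × 4 depths × 3 replicates; two markers; recovery experiments use
100–300 taxa at 1000–2000 reads — about an order of magnitude below real
OTU richness, chosen to keep the full validation suite fast while leaving
every estimator's behaviour regime unchanged).

Passing these tests shows the estimators are correct *under their own
model assumptions with known truth*. Real amplicon data add PCR and primer
bias, chimeras, compositional closure at much higher diversity, spatial
autocorrelation and environmental covariation that no generator here
emulates — recovery on synthetic data bounds implementation error, not
field inference error.

## Pipeline determinism

Every stochastic stage (rarefaction, PERMANOVA permutations, MST nulls)
requires an explicit seed in the config; validation fails before any
computation if one is missing. The run manifest records the config hash,
package version, seeds and relative output paths; no stage reads the clock
or global random state, so re-running a config is byte-identical — and the
validation suite asserts exactly that.

## Known limitations

- The NCM fit assumes a single metacommunity and equal depth; it refuses
  unrarefied input rather than silently normalising.
- MST group means are sensitive to the null-model choice; only the
  frequency-weighted fixed-richness incidence null is implemented.
- Greedy modularity above 10 nodes is a lower bound; exact computation is
  exponential and deliberately capped.
- PERMANOVA is one-way; no strata/blocked permutations.
- Spearman p-values use the t-approximation, slightly anti-conservative
  below ~16 samples; with the |r| > 0.7 co-threshold the realised false-edge
  rate stays below the p threshold at the study's sample sizes.
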