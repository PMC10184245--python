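# Methods

This note documents the statistical methods implemented in `morphorates`,
the conventions they follow, and how each is validated. All validation
numbers quoted here were computed by this package (see
`scripts/acceptance.py` and `tests/test_acceptance.py`); no empirical
claim below is asserted without having been computed.

## 1. Landmark handling

A **template** describes the landmark scheme: fixed landmarks, curve
semilandmarks and surface semilandmarks, grouped into named regions, each
region tagged with its embryonic origin (cranial neural crest, CNC, or
paraxial mesoderm, PM). Only one body side plus the midline is digitized;
`mirror_set` reflects paired points across the midline plane (fit by least
squares to the midline landmarks, or supplied explicitly) to produce full
bilateral configurations.

**Curve resampling** places a fixed number of semilandmarks at equal
arc-length intervals along each digitized curve by piecewise-linear
interpolation of the cumulative chord length.

**Missing landmarks** are estimated by thin-plate-spline (TPS)
interpolation: for each incomplete specimen, the TPS that maps the
observed landmarks of a complete donor configuration (the mean of
complete specimens) onto the specimen's observed landmarks is applied to
the donor's coordinates of the missing points. Estimated points are
flagged with a distinct status code so downstream analyses can trace
them. Validation: with 5 % of landmarks deleted at random per specimen
(one third of specimens kept complete as donors), recovered positions
have RMSE below 5 % of mean centroid size.

**Absent elements** (regions genuinely missing in a specimen, not just
undigitized) are collapsed to the region's sample mean shape after
alignment bookkeeping, so they contribute no variance while keeping the
data matrix complete.

## 2. Superimposition

**Generalized Procrustes analysis (GPA)** removes position, scale and
orientation: configurations are centered, scaled to unit centroid size,
and iteratively rotated to the evolving consensus by the Kabsch
singular-value-decomposition solution until the consensus converges.
Optionally the aligned shapes are orthogonally projected into the tangent
space at the consensus. The consensus orientation is canonicalized
(principal axes with a deterministic sign convention) so the result is
independent of input orientation. Validation: after applying random
rotations, scalings and translations per specimen, the GPA solution
(including sliding) changes by less than 1e-8; the analytic optimal
rotation for a toy planar triangle matches a brute-force grid over
rotation angle at 1e-6.

**Semilandmark sliding** lets curve semilandmarks slide along their local
tangent directions to minimize thin-plate-spline bending energy against
the consensus, solving the standard linear system per specimen, with
re-superimposition between passes. Sliding never increases bending
energy (asserted per specimen in the tests); bending energy is zero for
affine deformations of the reference.

**Disparity** is Procrustes variance: the mean squared Procrustes
distance of aligned shapes from their mean.

**Phylogenetically aligned PCA** uses the inverse phylogenetic covariance
to weight the mean and covariance, yielding components aligned with the
non-phylogenetic residual structure; on a star tree it reduces exactly to
ordinary PCA.

## 3. Phylogenetic signal, rates and group contrasts

**K_mult** generalizes Blomberg's K to high-dimensional shape data: the
ratio of observed mean squared deviation from the phylogenetic mean,
under the tree-implied covariance, to its Brownian-motion expectation,
computed trace-wise over coordinates. Significance is by permuting
species across tips. Validation: on 128-tip Brownian data with 20 trait
dimensions, mean K over 200 replicates is 1.003 (within [0.9, 1.1]); on a
star tree K equals 1 to machine precision. The permutation test's type-I
error is measured on exchangeable (signal-free, i.i.d.) data — the null
hypothesis that permutation actually tests — and is 0.065 with 199
permutations at α = 0.05 (within [0.03, 0.07]). Brownian data, by
contrast, should be and is rejected essentially always.

**σ²_mult**, the multivariate Brownian rate, is the REML estimate pooled
over coordinates: mean squared phylogenetically independent contrast per
unit branch length, summed over dimensions (reported per point for region
data). Validation: relative error of the mean estimate over 100
replicates at 128 tips is below 1 % against the generating rate.

**Rate-ratio test**: the observed ratio of σ²_mult between two groups is
compared to its distribution under simulation from the fitted common-rate
model. Validation: empirical size 0.047 at nominal 0.05 (400 null
replicates); power 1.0 at a true 3× ratio (100 replicates).

**Covariance transforms**: Pagel λ (scaling internal covariance), κ
(raising branch lengths to a power) and δ (node-depth power) are
implemented both as covariance transforms and as branch-length maps;
identity parameters reproduce the original covariance to machine
precision. Maximum-likelihood λ estimated by the penalized GLS fit
recovers generating values 0, 0.5 and 1 with mean absolute error
0.008, 0.14 and 0.0004 over 100 univariate replicates at 128 tips (all
within the 0.15 tolerance; λ = 0.5 is intrinsically the hardest because
the likelihood surface is flattest mid-range).

**Group contrasts** use the exact Mann–Whitney U with midrank ties and a
tie-corrected, continuity-corrected normal approximation for p-values.
Applied to the packaged 17-region reference table the CNC-vs-PM contrasts
give p = 0.0234 (rates), 0.2457 (disparity) and 0.1256 (disparity
excluding the pterygoid), reproducing the published-scale values 0.0232,
0.246 and 0.126 within 0.001.

## 4. Ecology models

**Penalized multivariate GLS** whitens the response by the inverse
Cholesky factor of the (optionally λ-transformed) phylogenetic
covariance, fits ordinary least squares, and shrinks the residual
covariance toward its diagonal (Ledoit–Wolf style) so the fit remains
well-defined when trait dimension exceeds the number of species.

**Procrustes PGLS** tests allometry and other continuous predictors on
full shape data by permuting reduced-model residuals; effect sizes are
reported as standard-normal Z from the permutation distribution of the
trace statistic.

**Type-II phylogenetic MANOVA** tests each term after all others using
the pseudo-trace statistic under residual permutation.

**State-specific rates** estimate one Brownian rate per discrete
ecological state by distributing each branch's squared contrast over
states in proportion to time spent, averaged over stochastic character
maps. With a single state this collapses exactly to σ²_mult.

## 5. Discrete traits

The **Mk model** likelihood uses Felsenstein pruning with per-branch
matrix exponentials; it matches brute-force enumeration over all interior
state assignments on small trees to 1e-8. The all-rates-different **Q**
matrix is estimated by L-BFGS-B from multiple restarts with a
Nelder–Mead polish. **Stochastic character maps** are drawn by sampling
node states from conditional distributions and rejection-sampling
endpoint-conditioned substitution histories per branch; state durations
sum exactly to tree length, node-state frequencies over 800 maps agree
with the marginal posteriors within three Monte-Carlo standard errors.

## 6. Variable-rates model

The variable-rates model places an unknown number of rate-shift events on
branches; each shift multiplies the rates of all descendant branches by
its scalar. The likelihood is the multivariate Brownian REML likelihood
of the phylogenetically independent contrasts under the rescaled tree.
Priors: truncated Poisson on the number of shifts, uniform placement over
branches, log-normal scalars, and a reference prior on the base rate that
is integrated analytically.

**Reversible-jump MCMC** proposes birth, death, move and rescale moves
with standard Green acceptance ratios. Validation:

- *Prior preservation*: sampling with the likelihood switched off
  recovers the truncated-Poisson prior on shift count (total variation
  distance 0.02–0.04).
- *Planted shift*: a 5× clade of 20 tips in a 100-tip tree is recovered
  with posterior mean clade rate more than 2× (observed ≈ 4.6×) the
  background median and log Bayes factor ≈ 29–40 for the variable-rates
  model over single-rate.
- *Null calibration*: on single-rate data the variable-rates model is
  not preferred (log-BF < 2) in at least 90 % of replicates (observed
  0.95–1.0 over 20 and 10 replicates).

**Marginal likelihoods** are estimated by stepping-stone sampling along a
power posterior path with Beta-spaced temperatures. On a conjugate
normal–normal toy with a closed-form evidence the estimate is accurate to
well under 0.1 nats (observed ≈ 0.001–0.005). The single-rate Brownian
model's evidence has a closed form (`bm_single_logml_exact`), used as the
comparison baseline. **Bayes factors** are reported as 2 × Δ log marginal
likelihood, with the conventional reading that values above ~10 are
strong support and values around 3–5 positive but weaker support.

Convergence diagnostics (Gelman–Rubin across chains, effective sample
size) and summaries (posterior branch rates, rate-through-time bins,
terminal rates grouped by clade) are provided.

## 7. Synthetic generator

`simulate_tree` draws a birth–death tree conditioned on the tip count and
rescales it to the requested root age (defaults: 322 tips, 80.3 Myr).
`build_template` constructs a bilateral 17-region skull-like template (12
CNC regions, 5 PM regions) with fixed landmarks and curve semilandmarks
and a true midline at x = 0. `simulate_shapes` evolves per-region shape
deviations by Brownian motion at per-region rates (defaults ordered to
make facial CNC regions fastest), plus allometric size variation.
`inject_missing` applies element-wise missingness with realistic
proportions, distinguishing missing landmarks from genuinely absent
elements. Every ground-truth quantity (tree, rates, states, deviations)
is recorded in a `SyntheticTruth` object that serializes to JSON and
regenerates bit-identically from the same seed.

## 8. Pipeline determinism

The pipeline derives every random stream from the single configured seed
via a fixed hierarchical scheme; stage outputs are cached keyed by a hash
of the configuration subset they depend on. Running the full pipeline
twice with one seed produces byte-identical CSV tables (asserted by
SHA-256 in the tests and the acceptance script).

## Limitations

- The rejection sampler for endpoint-conditioned substitution histories
  can be slow for strongly disfavored endpoint pairs on long branches;
  the branch lengths used here are well inside its comfortable range.
- The penalized MANOVA and PGLS report permutation p-values, so their
  resolution is limited by the permutation count (minimum p = 1/(n+1)).
- λ estimation near 0.5 has the largest sampling error (MAE ≈ 0.14 at
  N = 128); this is a property of the likelihood surface, not the
  optimizer.
- The variable-rates sampler assumes an ultrametric tree for the
  rate-through-time summaries; non-ultrametric trees are accepted for the
  likelihood itself.
- Stochastic mapping assumes the fitted Q is the truth; uncertainty in Q
  is not propagated into the state-specific rate estimates.
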