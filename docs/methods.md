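# Methods

## Model

For cell `i` from sample `j` in QC cell type `k` (unobserved), the vector of
D transformed QC metrics is modelled as

    x_i ~ N(alpha_0 + alpha_j + beta_k, Sigma_k),
    P(Z_i = k | s_i = j) = p_jk,

within one *sample group* — a set of samples whose QC distributions roughly
agree. `alpha_0` is the grand center, `alpha_j` a uniform per-sample shift,
`(beta_k, Sigma_k)` the shared component geometry, `p_jk` per-sample mixing
proportions. Because only the sums `alpha_0 + alpha_j + beta_k` enter the
likelihood, the decomposition is fixed by two centering constraints:
`sum_j n_j alpha_j = 0` (cell-count weighted) and `sum_k w_k beta_k = 0`
(`w_k` = overall component weights). Any other convention is an equivalent
re-parameterization; all comparisons of fitted to reference parameters must
first map both to one convention. Components are labelled in ascending
order of the first coordinate of `beta_k` for reproducible output.

Key consequence of sharing `beta_k, Sigma_k` across a group: a cell type
that is rare in one sample but common elsewhere in the group is still
modelled by its own component, so its cells are not mistaken for outliers —
the central claim the validation experiments test.

## Transforms

Metrics enter the model after Gaussianizing transforms: `log10` for library
size and feature counts, `log2((s + c)/(u + c))` for the spliced:unspliced
ratio, and a smoothed logit for the mitochondrial fraction,
`logit((m + c)/(n + 2c))` with `c = 0.5` (counts `n`, mito counts `m`).
Additive smoothing keeps every transform finite and strictly monotone on
the closed domain including `m = 0` and `m = n`; clamping would instead
create point masses at the boundaries. The fitted model is invariant to the
choice of log base up to a linear rescaling of the metric axes.

## Sample grouping

Pairwise distances between samples are unbiased U-statistic estimates of
the squared maximum mean discrepancy under a Gaussian RBF kernel
`k(x, y) = exp(-||x - y||^2 / (2 h^2))`; the matrix stores the square root
of the estimate clamped at zero. Choices:

- **Standardization.** Metrics are robustly standardized experiment-wide
  (median / 1.4826-scaled MAD) before the kernel so no metric dominates.
  The distances are then invariant to affine rescaling of any one metric.
  Per-sample centering was considered and rejected: it removes the
  between-group location signal along with the nuisance shifts and
  measurably degrades group recovery.
- **Bandwidth.** Median heuristic: the median pairwise distance over a
  pooled seeded subsample (capped at 1000 cells). Parameter-free and, in
  our scans, group recovery was flat across a 4x bandwidth range.
- **Subsampling.** Each sample is subsampled without replacement to at most
  500 cells (kernel cost is quadratic); seeded per sample so results do not
  depend on sample order.
- **Graph and clustering.** Unweighted union-symmetrized kNN graph with
  `k = min(5, J-1)`, Louvain at resolution 1.0 with a fixed seed, labels
  relabelled by decreasing group size. Louvain comes from networkx
  (seedable and deterministic). Edge-weighted variants changed recovery by
  at most one sample in our scans.
- **Embeddings.** Classical (Torgerson) MDS with negative eigenvalues
  clamped, and optionally UMAP on the precomputed distance matrix with a
  fixed random state.

## Robust fitting

Fitting alternates an exact E-step (log-sum-exp stabilized
responsibilities) with robust M-steps:

1. **Components.** Cells are hard-assigned to their max-responsibility
   component (ties to the lowest index). Per component, the `(1 - eps)`
   fraction nearest the current center in Mahalanobis distance is kept
   (`eps = 0.1` by default) and the trimmed covariance is rescaled by the
   consistency factor `c(eps) = (1 - eps) / F_{chi2,D+2}(q_{1-eps})`, with
   `q_{1-eps}` the chi-square(D) quantile — without it the estimate would
   shrink by ~22% at `eps = 0.1`, `D = 3`, destroying the chi-square
   calibration of the outlier statistic. A one-step reweighting follows
   (reweighted-MCD style): mean and covariance are re-estimated from all
   assigned cells inside the chi-square(0.975) radius of the trimmed
   estimate, with the analogous consistency factor. The reweighting matters
   when contamination occupies the trim budget: fixed-fraction trimming then
   keeps exactly the clean population, and `c(eps)` alone would over-inflate
   the covariance by ~29%.
2. **Sample shifts.** `alpha_j` is the coordinate-wise median of per-cell
   residuals `x_i - alpha_0 - beta_{k(i)}` over the sample's cells inside
   the same chi-square radius (at ~10% one-sided gross contamination a raw
   median is biased by ~0.14 sigma), then re-centered into `alpha_0`.
3. **Proportions.** Per-sample responsibility means over cells inside the
   chi-square(1 - eps) radius of their nearest component, floored at 1e-6
   and renormalized. The radius gate (rather than the fixed-fraction trim
   set) is used because it removes the *same* `eps` fraction of genuine
   cells from every component — leaving proportions unbiased — while
   excluding arbitrarily much contamination.

Initialization: seeded k-means++ on globally centered metrics first
(`alpha_j = 0`), then `alpha_j` from component-aware residual medians. A
raw per-sample median would conflate a true shift with a difference in
composition and can start EM in a basin where a one-component-dominated
sample is explained by a shifted wrong component; the component-aware order
avoids this (and coincides with the simple recipe at K = 1).

Convergence: relative change of the objective (observed-data log-likelihood
over non-trimmed cells; all cells in MLE mode) below `tol = 1e-6`, or a
relative parameter fixed point below 1e-9 — hard-assignment updates can
leave the objective oscillating in the last digit while the parameters have
stopped moving. Best of `n_restarts = 5` seeded restarts is returned. In
MLE mode (`robust=False`) the M-steps are exact weighted MLE / GLS updates,
so the objective is monotone non-decreasing (generalized EM); in robust
mode monotonicity is not guaranteed and not asserted. Covariances carry a
ridge of `1e-6 * trace(Sigma)/D`; components that keep fewer than `D + 2`
cells are flagged degenerate and ridge-inflated. Components whose overall
weight falls below 1% trigger a warning — in practice the typical symptom
of requesting too many components, which is also why K selection is left to
the user with the diagnostic report (no automatic model selection).

## Outlier criteria

The outlier statistic is the *minimum* squared Mahalanobis distance over
components, under the cell's sample shift. For a genuine member this is
chi-square(D) distributed, so cells above the `1 - alpha` quantile are
flagged (`alpha = 0.01` default); p-values are clamped into `(0, 1]`.
Component-level rules (`metric comparator threshold`) evaluate the
group-level component means `alpha_0 + beta_k`; cells nearest an excluded
component are flagged with reason `excluded_component`, which takes
precedence over (and is independent of) the distance criterion. Sample
flagging: each coordinate of `alpha_j` is z-scored against the
across-sample median/scaled-MAD; any |z| > 3 marks the sample for review.
No automatic sample exclusion is performed.

A subtlety used throughout validation: cells *kept* at level `alpha` are by
construction those below the cutoff, so their distances follow chi-square
*truncated* at that cutoff. Goodness-of-fit tests of kept cells must use
the truncated CDF; against the full chi-square a sample of 50k kept cells
would reject purely because of the missing `alpha` tail (KS statistic
`>= alpha/(1-alpha) ~ 0.0101` vs a 1% critical value of 0.0073).

## Simulator

The generator draws, hierarchically:

- **Experiment:** component offsets `beta_k` with pairwise separations in
  [1, 3] transformed units (rejection sampling; a jittered, randomly
  rotated center+octahedron lattice when K is too large for rejection),
  labelled low-to-high counts; covariances from a Wishart with
  `df = D + 4` scaled so `E[Sigma] = 0.05 * I` (marginal SD ~0.22, matching
  within-component spreads of real log-scale QC metrics; the df keeps
  anisotropy moderate); group means `mu_g ~ N(base, 0.2^2 I)` around
  `base = (3.3, 3.0, -3.0)` — about 2000 counts, 1000 features, ~4.7% mito.
- **Groups:** multinomial cell split; a non-empty component subset per
  group, all subsets pairwise distinct and jointly covering every component
  (a lone group gets the full set); outlier regime `p_out_0 ~ U[0.02,0.15]`,
  beta concentration `theta_0 ~ U[20,100]`, read-loss center
  `p_loss_0 ~ U[0.4, 0.8]`, logit-normal spread `sigma_loss ~ U[0.3, 0.7]`.
- **Samples:** shift `alpha_j ~ N(0, 0.15^2 I)`; proportions
  `p_jk ~ Dirichlet(5)` over the group's subset (a concentration vector is
  accepted, e.g. to plant a rare cell type); outlier fraction
  `p_out_j ~ Beta(p_out_0 theta_0, (1-p_out_0) theta_0)`; loss
  `p_loss_j = expit(N(logit(p_loss_0), sigma_loss^2))`; per-sample
  component wobble `delta_jk ~ N(0, 0.05^2 I)`.
- **Cells:** component from `p_jk`, metrics from
  `N(mu_g + alpha_j + beta_k + delta_jk, Sigma_k)` (or multivariate-t with
  configurable df for the heavy-tailed variant); outlier flag
  `Bernoulli(p_out_j)`; per-cell loss from a Beta centered at `p_loss_j`
  with concentration 50.

Degradation reconstructs counts from the metrics (`n = round(10^lc)` etc.),
thins the non-mitochondrial reads and the feature count binomially with
keep probability `1 - loss`, and re-applies the standard transforms. Counts
and features can only fall and the mitochondrial fraction can only rise —
the signature of dying/lysed cells; `loss = 0` reproduces the input
exactly. Every drawn parameter is retained (`SimTruth`) and serializable
for exact replay.

**What the simulator does not emulate:** gene-level expression (metrics are
drawn directly, not computed from a count matrix), doublets and empty
droplets (assumed handled upstream), correlations between a sample's shift
and its outlier burden, and batch structure beyond the group level. Passing
tests therefore demonstrate correct inference *under the model's own
assumptions* plus the planted degradations — not that flagged cells in a
real experiment are biologically bad.

## Validation experiment designs

All experiments live in `sampleqc.validation`, seeded and recomputed from
scratch by `scripts/acceptance.py` and `tests/test_acceptance.py`.

- **Calibration:** 50k cells, 3 components, 10 samples, no outliers; fit
  with the correct K; the flagged fraction at `alpha = 0.01` should fall in
  [0.5%, 2%] and kept distances pass a KS test against the truncated
  chi-square in >= 4 of 5 seeds.
- **Recovery:** 10 samples x 2000 cells, K = 3, 5% outliers; after mapping
  to a common centering convention and optimal component matching,
  `max|beta_hat - beta| < 0.1`, `max|alpha_hat - alpha| < 0.05`,
  `max|p_hat - p| < 0.05`. The fitted shift is compared against
  `alpha_j + sum_k p_jk delta_jk`: the generator's wobble is not in the
  model, and its composition-weighted mean is what the shift identifies.
  Good-cell precision and recall exceed 0.95 at the default alpha.
- **Bias:** K = 2 with Dirichlet concentration (1.5, 10) — a rare QC cell
  type at low counts; the pipeline's bias index (spread of per-cell-type
  exclusion fractions among good cells) must undercut both baselines at
  their defaults (2.5 MADs; 0.75 posterior) in every seed; on all-unimodal
  data the pipeline's and the MAD filter's recall agree within 0.02.
- **Grouping:** 3 groups x 8 samples with pairwise *disjoint* two-component
  subsets, outlier-free; ARI > 0.9 in every seed. Disjoint subsets are the
  regime in which the generative group labels are identifiable: with
  nested subsets a sample of the superset group whose rare-component weight
  happens to be small is a bona fide member of the subset group, and with
  single-component groups identification rests on location alone, which an
  extreme (~1%-tail) sample shift can defeat. Either mechanism occasionally
  costs one sample (ARI 0.87 with 24 samples) — a limitation of the
  generative conditions, not of the clustering.
- **Estimator checks:** the vectorized MMD U-statistic agrees with a
  brute-force double loop to 1e-10 over 50 random instances; the robust fit
  under 10% gross contamination at distance 100 recovers the mean within
  0.1 and the covariance within 0.15 (max element) while plain EM is
  displaced by the contamination; the MLE-mode objective is monotone; the
  degradation worked example (1000 counts, 100 mito, 500 features, 50%
  loss) lands within 3 binomial SEs of (550 counts, 250 features, 18.2%
  mito).

Problem sizes follow the experiment designs above (50k cells for
calibration, 20-24k elsewhere); the full validation run takes a few minutes
on one CPU.

## Known limitations

- Robust-mode EM has no monotonicity or global-optimum guarantee; restarts
  plus the diagnostic report are the practical safeguard.
- The number of components per group is user-specified; badly misspecified
  K usually shows up as non-convergence or a sub-1% component (warned), but
  silently plausible wrong fits are possible.
- Sample grouping degrades when within-group heterogeneity (composition
  spread, extreme shifts, heterogeneous outlier burden) rivals the
  between-group signal; the embeddings exist precisely so users can audit
  the partition.
- The mixture-of-regressions baseline is a behavioral stand-in for the
  published tool (same model family, same 0.75 default), not a port.
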