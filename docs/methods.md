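# Methods

This note documents the models, defaults and design choices behind
`nirselect`, and what the synthetic-data tests do and do not demonstrate.

## Data model and instrument grid

Spectra are absorbance matrices on a uniform, descending wavenumber grid.
The emulated instrument scans 10000→4000 cm⁻¹; the working window selected
by spectrum standard deviation is 7501.74–4088.35 cm⁻¹. The grid spacing is
fixed at (7501.74 − 4088.35)/885 = 3.8569379 cm⁻¹ (3.857 at two decimals):
this is the unique spacing for which the window holds exactly 886 points
with both edges on-grid, and every characteristic wavenumber the workflow
reports (4092.21, 4439.33, 5866.40 cm⁻¹, …) lies on the lattice anchored at
4088.35 cm⁻¹. Grid uniformity is enforced to 10⁻⁶ cm⁻¹; all variable
bookkeeping is by wavenumber value, never column position, so results
survive cropping and selection.

## Pretreatment chain

Default order: Norris filter → mean centering → standardization
(autoscaling, unit sample variance per variable) → Savitzky–Golay second
derivative. Defaults: Norris segment 5 / gap 5 (common instrument-software
defaults; the smoothing stage uses the segment, the gap drives the optional
Norris gap derivative); Savitzky–Golay window 11, polynomial order 2,
derivative with respect to grid index. Whether the original workflow's
"Norris" step was smoothing-only or a gap derivative is ambiguous; both are
implemented and the default chain uses smoothing in the quoted order.
"Standardization" is read as per-variable autoscaling, the conventional
meaning in TQ-style software. All steps are stateless; a chain is exactly
reproducible.

Two consequences of this chain matter for interpretation:

* a *multiplicative* (scale) artifact becomes a constant offset after
  autoscaling and is annihilated by the second derivative — so scale
  outliers must be screened on raw spectra (see QC);
* after autoscaling, i.i.d. noise variables carry as much variance as
  signal variables, and the second derivative then *amplifies* jagged noise
  relative to smooth structure — so unsupervised variance/geometry-based
  filters (SDD on pretreated data, LPG) are weaker on this representation
  than on raw spectra.

SDD band selection: per-variable SD across samples, threshold at a quantile
of the SD distribution (default 0.25), longest contiguous run of at least
`min_run` (default 50) variables wins. The study's fixed window
[4088.35, 7501.74] is the pipeline default (`band_mode="window"`).

## Quality control

* Replicate stability: Hotelling T² with limit
  `k(n−1)/(n−k)·F⁻¹(α; k, n−k)`. For 25 parallel collections and one score
  dimension this gives 4.26 (95%) and 7.82 (99%), the published stability
  coefficients.
* Outlier screening: iterative PCA (k = 5 components, α = 0.99). Each pass
  computes every surviving sample's T² and squared reconstruction residual
  Q (Jackson–Mudholkar limit), removes the single worst exceeder (T² takes
  precedence; ties by larger T², then lexicographic sample id), refits, and
  stops when nobody exceeds. Because each pass screens the *maximum* of n
  statistics, the per-sample level is Bonferroni-adjusted to
  1 − (1 − α)/n; without this the Q limit false-alarms on roughly a fifth
  of clean datasets. Screening aborts if more than 20% of samples would be
  removed. The procedure is invariant to sample order.

## Kennard–Stone partition

Classic greedy maximin on Euclidean distance: seed with the most distant
pair, repeatedly add the candidate farthest from the selected set.
Validation size = round(n/3) (the 2:1 convention; the workflow's own counts
imply inconsistent rounding, so one convention is fixed and logged). A
deterministic repair pass swaps nearest cross-set pairs until both sets
contain all five region classes. Note the greedy algorithm is a maximin
2-approximation, not an exact optimizer; on small instances it often, but
not always, matches the exhaustive optimum.

## PLS-DA and the Galtier rule

Origin classes are coded 1…5 in a single numeric response (the printed
prediction tables span that range, which rules out one-hot coding) and
regressed by PLS1 (NIPALS), default 5 latent variables, 10-fold
cross-validation stratified by class. RMSECV uses held-out predictions; R²
is the full-data fit; RMSEP uses the validation set. Rank deficiency below
the requested dimension raises an error naming the achievable rank; inside
Monte-Carlo selectors a rank-deficient subset simply scores +∞.

For each validation sample the candidate class is the code nearest the
prediction `Y_pre`; the deviation `Y_dev` is the half-width of the spread
of the 10 fold-submodels' predictions (the original software's definition
of Y_dev is opaque, so the verdict machinery accepts (Y_pre, Y_dev) from
any source, enabling exact replay of printed tables). The decision rule —
reconstructed minimally from the printed flags, whose prose description is
internally garbled — is:

* **uncredited** if `Y_pre < min(codes) − 0.55` and `Y_dev < 0.45`;
* **suspicious** if `Y_dev ≥ 0.45`;
* **ok** otherwise.

The 0.45/0.55 limits (10% error brackets around the 0.5 threshold) are
config-exposed. Replayed against the published tables, this rule reproduces
183 of 185 printed flags; the two exceptions carry (Y_pre, Y_dev) values
that are provably inconsistent with the other 183 under *any* rule monotone
in the deviation and the distance to the nearest code, and are most likely
misprints. Set accuracy is `100·#{ok ∧ candidate = actual}/n`, two
decimals.

## Wavelength selection

All Monte-Carlo selectors take an explicit seed; there is no global random
state, and results are bit-for-bit reproducible.

**CARS** (defaults: 100 runs, 50 iterations, 80% subsampling, 10 folds,
A = 5). The retained-ratio schedule `r_i = a·e^{−k i}` is pinned to
`r₁·p = p` and `r₅₀·p = 2`. Per iteration: fit PLS on a random 80% sample
subset, rank active variables by |b|, apply the enforced cut to `r_i·p`
variables, then adaptive reweighted sampling (a weighted bootstrap of the
same size; unique survivors continue). One fold assignment, derived from
the seed, scores every iteration of every run, so RMSECV values are
directly comparable and the winning subset (minimum RMSECV; ties toward
fewer variables, then lower run index) is not fold-lottery noise. The
per-variable selection frequency across runs is reported alongside.

**MC-UVE** (defaults: 500 Monte-Carlo draws, 80% subsets, forward cap 150).
`RI_j = mean(b_j)/sd(b_j)` over the resampled coefficient draws; variables
are ranked by |RI| and added one at a time; the prefix at the global RMSECV
minimum is kept and the |RI| of its last member is the reported threshold.
RI measures the *stability of the in-sample coefficient*: it is large for
variables whose fixed-sample association is reproducible across subsamples,
which is not a null-calibrated significance score.

**SPA** (defaults: N = 1000 submodels, R = 0.8, Q = 10, COSS cut 2).
Submodels draw ⌈R·n⌉ samples and Q variables; the out-of-sample error of
every submodel is recorded. Variables are allocated to submodels by
chaining random permutations cut into Q-sized windows, so every variable is
included ⌊NQ/p⌋ or ⌈NQ/p⌉ times and the importance score is defined for all
of them. Importance is the one-sided Wilcoxon rank-sum P that submodels
containing the variable predict better; `COSS = −log₁₀ P`, selected when
COSS > 2 (P < 0.01).

**LPG** (defaults: 2 components, turning angle 15°). PCA of the
standardized training matrix places each variable at its singular-value-
weighted (correlation) loading coordinates; walking the variables in
wavenumber order traces a polyline; a variable is non-collinear when its
turning angle exceeds the threshold or it lies on the convex hull of the
cloud. On derivative-pretreated data with substantial uncorrelated noise
this rule keeps most of the grid (noise loadings are jagged at every
scale), so LPG here acts as a weak filter: it reliably *contains* the
informative variables but, unlike the three supervised methods, does not
produce a subset whose cross-validation error beats the full spectrum.
Threshold scans (15–150°) and loading-magnitude gates do not change this on
the synthetic data; the favourable LPG behaviour reported for real spectra
rests on smooth inter-variable correlation structure that the generator
deliberately does not emulate.

**Consensus**: wavenumbers selected by at least `min_votes` methods
(default 2 — "more than twice" is read inclusively as ≥ 2 of 4, and the
threshold is config-exposed).

## Stepwise screening and Fisher functions

Stepwise Wilks-Λ discriminant screening: at each step the candidate with
the largest partial F (`F = ((n−g−q)/(g−1))·(1−L)/L`, `L` the ratio of
successive Λ = det(W)/det(T)) enters if it clears `f_enter` (default 3.84),
then retained variables with partial F below `f_remove` (default 2.71)
leave. Λ never increases at an entry. With n = 40 training samples and
~100–140 candidate common variables, the liberal default thresholds admit
a few chance-separating variables besides the planted ones; the
resubstitution and leave-one-out accuracies (computed on variables chosen
using the full training set) are therefore optimistic relative to the
independent validation set, whose accuracy the pipeline also reports.
Tighter thresholds trade retained-set size against that optimism and are
config-exposed.

Fisher classification functions use equal priors (the printed function
form carries no prior term, despite unbalanced classes):
`coef_c = W⁻¹μ_c`, `const_c = −½μ_cᵀW⁻¹μ_c + ln π_c` with W the pooled
within-class covariance; a singular W receives a logged ridge of
`10⁻⁸·tr(W)/p`. The argmax class equals the nearest centroid in
Mahalanobis distance; ties resolve to the lowest class code. Leave-one-out
validation refits the functions for every held-out case.

## Synthetic data generator

Per tissue: 60 samples in five region classes (19/12/5/10/14) on the full
instrument grid. Each spectrum is a per-sample random quadratic baseline
(coefficients jittered with sd 0.02 around 0.5/0.3/−0.2 absorbance units),
ten broad shared Gaussian bands (σ 90–250 cm⁻¹, amplitudes 0.05–0.30,
different between BFL and FLP so pooled PCA separates the tissues), six
narrow informative bands, twelve nuisance bands, and i.i.d. noise
(sd 0.005 absorbance).

* Informative bands: σ = 6 cm⁻¹ (~1.6 grid steps), centers at six of the
  characteristic wavenumbers (disjoint between tissues), peak amplitudes
  0.04–0.12 following six distinct monotone/step class profiles. Two design
  constraints fix these choices: each band must be *individually* class-
  correlated (SPA scores marginal utility), and the per-band amplitude
  jitter (10%) must be large enough that no small subset of bands saturates
  prediction of the class code — otherwise RMSECV-minimizing selectors
  legitimately discard the redundant bands.
* Nuisance bands: σ 30–60 cm⁻¹ at twelve fixed centers ≥ ~80 cm⁻¹ from all
  informative centers, with class-independent per-sample amplitudes
  (sd 0.03–0.04). They create the correlated uninformative background that
  survives derivative pretreatment and handicaps full-spectrum models,
  which is what makes variable selection worthwhile in the first place.
* Ground truth: the centers of the non-shared bands, snapped to the grid; a
  selected variable "hits" a band within ±2 grid steps.

What the generator does *not* emulate: multiplicative scatter, wavelength-
dependent noise, instrument line shapes, or the smooth inter-variable
correlation of real NIR spectra. Passing tests therefore demonstrate that
the algorithms recover isolated class-informative bands from structured
backgrounds, not that they reproduce any particular real-data figure; the
LPG cross-validation caveat above is the clearest instance of the gap.

## Determinism, problem sizes and numerics

Every stochastic stage derives its seed from the master seed and the stage
name (BLAKE2 hash, < 2³¹), so stages can be rerun in isolation and full
pipeline reruns are byte-identical (no timestamps anywhere; JSON keys
sorted; floats written with round-trip precision). The twenty-seed study
sweeps in the test suite and the acceptance script run CARS with 15 runs,
MC-UVE with 200 draws (forward cap 100) and SPA with 1000 submodels — the
library defaults keep the full published counts (100/500/1000), and the
scaled sweep sizes are the package's own choice of test-scale problem.
Degenerate inputs are handled explicitly: zero-variance columns are left
centered (warning), rank-deficient Monte-Carlo subsets score +∞, zero-
spread MC-UVE coefficients get an ∞ sentinel, degenerate LPG loadings give
an empty selection with a warning, and an empty consensus aborts the
pipeline at the stepwise stage with a clear message.
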