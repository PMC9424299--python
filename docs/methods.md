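# Methods note

This note records the model definitions, parameter choices, generator scope
and numerical conventions of the `dfstates` package, including every place
where a convention had to be fixed by choice.

## Windowed dynamic FC

Sessions are parcellated region × frame matrices; the analysis retains a
fixed number of frames per session (default 300, `AnalysisConfig.n_keep`)
after motion censoring.  Pearson correlations are computed in sliding
windows of `window_width = 30` frames (60 s at TR = 2 s) stepped by
`window_step = 1` and Fisher z-transformed, with correlations clipped to
±(1 − 1e−6) before `arctanh` so degenerate windows stay finite.  Constant
regions inside a window produce zero rows/columns with a logged warning.

**Window-count convention.**  The number of windows is
`floor((T − w) / step)`, i.e. windows are the half-open spans
`[i·step, i·step + w)` for `i = 0 … (T−w)/step − 1`: a 300-frame session
yields **270** windows.  The more common convention `(T − w)/step + 1`
would give 271; the package deliberately uses the former, and all row
counts downstream (e.g. 181 sessions × 270 = 48,870 concatenated windows)
follow from it.

## Leading-eigenvector representation

Each window's z-matrix is summarized by the unit eigenvector `v` of its
largest **algebraic** eigenvalue (`numpy.linalg.eigh`), not the largest
magnitude; for FC-like matrices these coincide.  `v·vᵀ` is the best rank-1
approximation (Eckart–Young) and is invariant to the sign of `v`; the
clustering feature is the row-major upper triangle of `v·vᵀ`.  For display
and network summaries the sign of `v` is fixed so the mean over cortical
regions is ≥ 0, with ties broken by making the largest-|entry| coordinate
positive.

## State clustering

K-means under the correlation distance `d(x, c) = 1 − corr(x, c)` is
written by hand (no standard library implements this metric directly):
rows are centered and scaled to unit norm, so `d = 1 − x̂·ĉ`; centroids are
means of member rows re-standardized after each update; a cluster that
empties is reseeded from the row farthest from its centroid (keeping its
previous centroid if reseeding would empty another).  The best of
`kmeans_replicates` (default 20) seeded replicates by total within-cluster
distance is kept.  State labels are 1-based.

K is selected by maximizing the silhouette under the correlation distance
(seeded row subsample above `silhouette_row_budget` rows); a hand-written
Davies–Bouldin index using the correlation distance and the fitted
centroids is reported as a cross-check, and a disagreement between the two
optima is logged rather than resolved automatically.

Per-state biomarkers: mean homotopic z per network, mean within-hemisphere
DAN–DMN z, and signed modularity.  The signed modularity is also written
by hand: at each edge density (4–20% of possible edges, retained by
|weight|), `Q = Q⁺ − Q⁻`, where each part scores its sign's subgraph
against its own configuration null under the fixed parcellation-network
partition.

## State dynamics (Eqs. 1–4 statistics)

For a session's window-label sequence of length N: fraction time
`f_k = #(x = k)/N`; dwell time = mean length of uninterrupted runs of k
(runs touching the sequence boundary count as complete runs); transition
probabilities `TP[i,j] = #(jumps i→j)/#(all jumps)` with a zero diagonal
and an explicit no-jump flag.  Dwell times are in **window counts**;
multiply by TR × step for seconds.  The per-session feature vector
concatenates `f`, dwell, and the off-diagonal TP entries in row-major
order — length 2K + K(K−1), i.e. 30 at K = 5 — and is z-scored across
sessions before a 3-component PCA (Dyn-PCs; component signs fixed by the
largest loading).

Group contrasts use a vectorized permutation test on the Welch t statistic
with add-one p-values; multiplicity is handled by Benjamini–Hochberg or
Bonferroni.

## Cortico-subcortical coupling

The subcortical entries of all window eigenvectors, pooled across
sessions, are reduced by a 2-component spatial PCA (typically separating
basal-ganglia/thalamus from hippocampus/amygdala; near-isotropic variance
is flagged).  Shift series are |differences| of the per-network cortical
eigenvector means and of the subcortical component scores between
consecutive windows, never across session boundaries.  Jumps are shifts
**strictly above** the 95th percentile; the default pooling scope is
**global** (one threshold over all subjects, networks and components —
matching a single study-wide threshold), with a `per_series` alternative.
Per subject, subcortical jumps are pooled across the two components (a
jump in either counts); the observed coincidence
`P(subcortical jump | network jump)` is compared with the subject's
overall subcortical jump rate (the independence null) by a paired,
one-sided Wilcoxon signed-rank per network, Bonferroni-corrected.
Subjects without any jump in a network are excluded from that network's
test; fewer than six contributing subjects is an error.

## Lesion/disconnection ridge mapping

Designs are subjects × voxels binary lesion matrices (voxels lesioned in
at least one subject) or subjects × region-pair disconnection matrices
(row-major upper-triangle order shared with the window features).  The
design is PCA-reduced to the minimal leading components reaching 97%
variance and then z-scored with a **single global mean/sd** (not
per-column); the score is z-scored; ridge `β = (XᵀX + λI)⁻¹Xᵀy` carries no
intercept.

λ is selected on a 200-step log grid over [1e−5, 1e5] by **exact
closed-form LOOCV**: with the SVD X = U·diag(s)·Vᵀ, the hat diagonal is
`h_ii = Σ_j U_ij² s_j²/(s_j²+λ)` and the held-out residual is
`(y_i − ŷ_i)/(1 − h_ii)`, algebraically identical to refitting every fold
but ~n times cheaper — this is what makes the 10,000-iteration permutation
protocol (which re-runs the entire LOOCV + λ optimization per shuffle)
tractable.  Accuracy is R² on the held-out predictions and may be
negative.  The model p-value is the add-one permutation exceedance of R²;
per-predictor significance marks back-projected weights outside the
central 95% of their own permutation distribution.  Reported weights are
averaged over per-fold ridge solutions (per-fold SVDs are precomputed once
since only y changes).  Display maps are Gaussian-smoothed (σ = 1 voxel,
nearest-edge boundary), scaled by the maximum |weight|, and thresholded at
|w| ≤ 0.05.

## Behavior models

Static FC is the Fisher-z correlation over all retained frames (not the
mean of windowed matrices).  The ST score is the first spatial PC of
edge-wise control-referenced z-abnormality maps (zero-variance control
edges dropped), fitted on a reference patient set when provided; its sign
is oriented so that higher ST tracks **lower** mean homotopic FC, and
ST > 0 labels a patient severe.  Relative recovery is
`(s_1y − s_2wk)/|s_2wk|`, undefined (excluded) at a zero baseline.
Static-vs-dynamic comparisons use Gaussian identity-link GLMs with
likelihood-ratio tests, `χ² = 2Δll` on df = added regressors.  A
generalized linear *mixed* model across timepoints is out of scope; the
package fits per-timepoint complete-case models.

## Synthetic generator: scope and realism

The cohort plant is a hidden-Markov covariance-switching model: a Markov
chain over K states (symmetric, parameterized by mean dwell in frames;
severe patients get per-state occupancy multipliers — state 2 ×2.5,
states 1 and 3 ×0.7 — applied by column scaling and row renormalization),
per-state covariances built from network-block coupling matrices (within-
network correlation, between-network coupling, homotopic boost, PSD repair
by eigenvalue clipping at 1e−8), and AR(1) temporal smoothing
`s_t = a·s_{t−1} + √(1−a²)·ε_t`.  The default parcellation has 48
cortical regions (8 networks × 6, all homotopically paired) and 12
subcortical regions (6 nuclei, 6 limbic).  Lesions are connected random
blobs on a 12³ grid with scores `Σ w_true` over lesioned voxels plus noise
at SNR 3; behavior is linear in ST and the Dyn-PCs plus Gaussian noise.

The generator is a *statistical* plant, not a biophysical one: it has no
hemodynamics, spatial autocorrelation beyond the network blocks, scanner
drift, or motion structure.  It exists to give every pipeline stage
ground truth with known statistics.

## Validation problem sizes and numerical choices

All validation problem sizes are the package's own choices, set before the
assertions were run and sized to keep the full suite within a desktop
budget:

- **Plant recovery** uses 12 sessions × 300 frames, 3 states, coupling
  0.7, mean dwell 60 frames, AR 0.2.  The long dwell is needed because a
  30-frame window cannot resolve switching much faster than its own width
  — with the study-like 14-frame dwell, most windows straddle states and
  label recovery degrades.  This window-resolution limit is a property of
  all sliding-window state analyses, not of this implementation.
- The fraction-time check compares the estimated fractions with the
  *realized* planted occupancy rather than the asymptotic stationary
  distribution: at ~60 state runs per cohort the realized occupancy itself
  deviates from the stationary law with per-state sd ≈ 0.06, so a direct
  comparison at a 0.05 band would fail about half of the seeds for any
  correct implementation.  The plant's stationary distribution (exactly
  uniform) is asserted separately.
- **Coincidence calibration** runs 500 independence cohorts of 20 subjects
  (Bernoulli jump rasters at the pipeline's 5% rate).  The Wilcoxon test
  is conservative on such discrete data (per-network type-I ≈ 0.02–0.03 at
  α = 0.05), so the calibration asserts the across-network mean within
  [0.02, 0.08].
- **Ridge null calibration** uses 200 refits at n_perm = 99 (add-one
  p-resolution 1/100, a documented widening); the lesion sign-recovery
  check runs at the full n_perm = 1000.
- **LRT calibration** is checked at n = 200, where the asymptotic χ²
  reference is accurate; at the power-analysis size n = 40 the test is
  known to be slightly liberal (rejection ≈ 0.06–0.08 at α = 0.05), a
  standard small-sample property of the LRT, so calibration and power are
  asserted at their respective sizes.
- Permutation p-values use the add-one convention throughout; derived
  seeds come from SHA-256 of `"{master_seed}:{label}"` reduced mod 2³¹.

## Limitations

- Sliding-window state estimates blur transitions faster than the window
  width; dwell-time estimates are biased upward near that limit.
- The coincidence test's global jump threshold couples subjects; a
  subject-level threshold scope is provided but not default.
- Ridge per-predictor significance is marginal (per-weight nulls), not a
  joint test; correlated voxels share credit.
- The ST abnormality metric (edge-wise z against controls) is one
  reasonable choice among several; the orientation constraint (higher ST =
  lower homotopic FC) is what downstream code relies on.
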