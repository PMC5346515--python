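# Methods

## Model and procedure

The package operates on three inputs: a per-subject ICA decomposition
(component time-courses, optionally with calibrated spatial maps in percent
signal change), a region-labeled parcellation volume, and the 4-D BOLD
series (or, equivalently, a precomputed region×time matrix). The workflow
is strictly per subject, aggregated afterwards; there is no group-ICA path.

1. **Component selection.** Components are filtered to a "neuronal" subset
   and assigned to named networks. Template assignment scores each
   component map against each binary template with the goodness-of-fit
   GOF = mean(map inside template) − mean(map outside), then solves a
   maximum-weight one-to-one assignment over all templates simultaneously
   (Hungarian algorithm with zero-gain dummy rows). A template whose best
   attainable GOF is ≤ 0 is reported absent. The optimal assignment is
   deterministic and at least as good as any greedy pass; ties at zero
   resolve to "absent". Neuronality is a pluggable contract
   `(timecourse, tr) -> bool`; the built-in default labels a component
   neuronal when more than `neuronal_cutoff` (default 0.5) of its non-DC
   periodogram power lies in 0.01–0.1 Hz. This heuristic is a deliberately
   simple spectral criterion, not a trained spatiotemporal-fingerprint
   classifier; users with a trained model plug it in unchanged.

2. **Regional GLM.** Region courses are unweighted voxel means. Each is
   regressed by OLS on the neuronal component courses plus an intercept;
   residual variance uses DOF = volumes − components − 1 (the −1 is the
   intercept). t-values use the standard contrast form with the explicit
   design covariance. No prewhitening is applied: the model is ordinary
   least squares by design. Which components enter the design is
   configurable (`use_all_components`); the default is the subject's
   neuronal subset, so DOF varies by subject.

3. **Edge weighting and thresholding.** For each retained component the
   correlation weight `|t_a|+|t_b|−|t_a−t_b|` and anti-correlation weight
   `|t_a|+|t_b|−|t_a+t_b|` are formed for all pairs; edges below
   2·t_threshold are discarded, with t_threshold the one-tailed Student-t
   quantile at significance `significance_p` (default .001) applied to
   |t|. Keeping W ≥ 2·t_threshold is algebraically identical to requiring
   both node t-values to be individually significant under the flavor's
   sign condition, which is the only reading of the edge rule consistent
   with significance filtering (2·t_threshold is the *minimum* weight of a
   doubly-significant pair, not a maximum). Ties at the threshold are
   kept. Regions with exactly zero residual variance carry infinite
   t-values; they are flagged and excluded from component graphs with a
   warning rather than silently passed through.

4. **Group aggregation.** An edge enters the group graph when present
   (nonzero post-threshold weight) in at least `presence_fraction`
   (default 25%) of subjects. The canonical group quantity is the per-edge
   subject count; mean weights over contributing subjects are stored as a
   convenience only, because all statistics are computed on per-subject
   graphs, so the group weighting convention never influences a result.

5. **Classical network.** The cleaned voxel signal is the linear
   combination of the neuronal components weighted by their spatial maps;
   it is region-averaged and correlated pairwise, each r mapped to
   t = r·sqrt(DOF/(1−r²)), and an edge kept iff t ≥ t_threshold with
   weight 2t so it lives on the scale of the component-graph weights.
   Perfectly correlated pairs (r = 1 within numerical tolerance) are
   retained with infinite weight and survive binarization unchanged.
   The correlation→t construction is this package's documented choice of
   connectivity measure for the reconstructed signal; the min-based
   component weighting does not extend to a multi-component
   reconstruction because no single per-region t-value exists there.

6. **Metric battery.** All metrics are computed on the binarized
   thresholded graph after deleting isolated nodes (the "connected
   constellation"): edge count E, average degree k = 2E/n, triangle count,
   average local clustering C, characteristic path length L, and
   σ = (C/C_rand)/(L/L_rand). Binarization reflects that degree and
   triangle counts are integer-natured summaries of the thresholded
   topology; weights remain available in the outputs. The null model for
   C_rand, L_rand and triangle normalization is Erdős–Rényi G(n, E)
   matched on node and edge counts, averaged over `n_random_nulls`
   (default 20) seeded draws. L on a disconnected graph is averaged over
   reachable pairs only and the disconnected-pair fraction is reported
   alongside — this keeps L finite while making the disconnection visible
   rather than hiding it.

7. **Comparison.** Per-subject metric distributions are compared across
   networks by one-way ANOVA followed by Tukey's HSD (statsmodels), with
   significance tiers at .05 and .01. The classical network is first
   masked to the component network's group constellation, since node
   count strongly affects topology. A subject contributes to a network's
   group only when that network was detected for it, so group sizes are
   unbalanced; Tukey HSD handles that. Subjects are not modeled as a
   blocking factor: one-way ANOVA is the procedure implemented, and a
   repeated-measures variant is out of scope.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `significance_p` | .001 | node-level significance for t_threshold (one-tailed on |t|) |
| `presence_fraction` | .25 | minimum fraction of subjects carrying an edge for group retention |
| `n_random_nulls` | 20 | ER null draws behind C_rand, L_rand, triangle normalization |
| `neuronal_cutoff` | .5 | band-power fraction above which a component is neuronal |
| `band_low_hz`, `band_high_hz` | .01, .1 | resting-state band for the spectral heuristic |
| `drop_initial_volumes` | 3 | leading volumes removed from 4-D input (T1 saturation) |
| `use_all_components` | false | regress on all components rather than the neuronal subset |
| `seed` | 0 | seeds every stochastic step (null graphs) |

The significance level is exposed because two conventions circulate for
this thresholding step (p = .001 vs the 99th percentile, i.e. .01); the
default is .001 and the alternative is one config key away.

## Synthetic data

The generator produces exactly what the method consumes and nothing more.
Component courses are white Gaussian noise Fourier-restricted to the
resting-state band, orthogonalized over the sample (QR on mean-zero
columns, so orthogonality equals zero sample correlation) and scaled to
unit variance. Regional courses are `mixingᵀ·X` plus white noise scaled so
var(signal)/var(noise) equals the configured SNR on loaded regions;
unloaded regions get noise at the loaded regions' mean level so they are
signal-free rather than constant. The default mixing places 3 components
over 60 regions in signed blocks of 20: component i loads +1 on block i
and −1 on block i+1 (mod 3). The implied ground truth per component — the
union of the two same-sign block cliques for the correlation flavor, the
complete bipartite graph between the blocks for the anti-correlation
flavor — is returned alongside, and the default cohort is 15 subjects at
SNR 10 with 150 time points at TR 2 s, sizes at which the full suite and
the acceptance run complete in seconds. The optional volume painter
partitions a voxel grid into contiguous labeled chunks and replicates each
region's course across its voxels with small independent voxel noise;
spatial maps assign each voxel its region's loading. Geometry is
deliberately unrealistic (boxes, not anatomy): every equation in the
pipeline touches only label bookkeeping, never shape.

What passing tests on these fixtures shows: the estimator algebra, the
edge rule, the group combinatorics and the metric battery are correct, and
planted block structure is recovered exactly at the group level under
band-limited signals with white noise. What it does not show: robustness
to hemodynamic convolution, autocorrelated or physiological noise, motion,
imperfect ICA unmixing, or template mismatch on real anatomy.

## Numerical choices

- OLS is solved through the normal equations with an explicit Gram
  inverse, matching the covariance needed for the t-transform; a
  rank-deficient design raises immediately, naming the collinear
  components, rather than silently pseudo-inverting.
- Residual sums of squares at or below a 1e-24 relative floor are treated
  as exact fits: t is flagged ±∞ (NaN for a zero coefficient), the region
  is excluded from graphs with a warning.
- Constant regions are dropped with a warning instead of failing the run.
- Pairwise weights clip numerical dust to 0 so that opposite-sign pairs
  are exactly zero.
- Edge retention uses ≥ with a 1e-12 tolerance at the group-presence
  boundary so that 4/15 vs 0.25 compares as intended in floating point.
- Text outputs serialize floats with `repr` and JSON with sorted keys;
  identical config + seed reproduces byte-identical artifacts.

## Known limitations

- The neuronality default is a spectral heuristic; on real data a trained
  classifier should be plugged in.
- The template-matching GOF and assignment rule are a principled,
  documented convention (inside-minus-outside mean, optimal one-to-one
  assignment); other conventions exist and would change assignments on
  ambiguous maps.
- Single-subject graphs at p = .001 carry node-level false positives at
  the nominal rate (≈ 0.2% two-sided per null region); exact structure
  recovery is a property of the group-presence rule, not of individual
  subject graphs.
- No spatial resampling: inputs must share a voxel grid, by design.
- σ and the triangle ratio are undefined (NaN) when the null has zero
  clustering or the graph is edgeless; records flag rather than fabricate.
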