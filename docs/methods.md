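# Methods

## Model

Objects are points in a k-dimensional perceptual space estimated from
behavior. Three assumptions carry the whole account:

1. **Dissimilarity from search.** The reciprocal of the mean oddball-search
   time for a pair of images (1/RT, units s⁻¹) measures their perceptual
   dissimilarity. Trials are pooled across participants and across which
   item played target before averaging ("mean first, then reciprocal");
   a per-participant-first average is available as an option but is not the
   default.
2. **Multiple-object averaging.** The response to a display of several items
   is the (weighted) average of the single-item responses. A homogeneous
   display therefore responds exactly like its single item, and an oddball
   array lies on the segment between target and distractor responses. Only
   two-identity arrays are modeled; spatial layout, set size and eccentricity
   are out of scope.
3. **Distance-to-center read-out.** Visual homogeneity VH_i = ‖r_i − c‖ for
   a center c. If decisions threshold VH at a boundary b and RTs fall with
   distance from the boundary, RT correlates positively with VH below b
   (heterogeneous displays) and negatively above it, with a near-zero pooled
   correlation when the two groups mirror each other.

The center c is the model's only free parameter vector. It is fitted by
maximizing `objective(c) = r_A(VH, RT) − r_B(VH, RT)` (Pearson by default;
Spearman optional). The objective is bounded in [−2, 2] and attains 2 only
when VH orders both groups' RTs perfectly and oppositely.

## Fitting

* **Optimizer.** Nelder–Mead within box bounds, from the response centroid
  plus `n_restarts` (default 20) uniform draws inside the bounds. The
  objective is piecewise-smooth (non-differentiable where a center
  coincides with a response), so a derivative-free local search is used.
  All restart optima are reported so stability is auditable; among
  numerically tied optima the smallest-norm center is returned.
* **Bounds.** The responses' bounding box expanded by 50% per side. The
  fitted optimum has always been interior on well-conditioned data; the
  bounds mainly guard the random restarts.
* **Degenerate geometry.** When the responses span fewer than k dimensions
  the out-of-span component of the center is weakly identified. A projection
  onto the response span is available (`project_center=True`) but off by
  default: an out-of-span offset h maps in-span distances d to
  √(d²+h²), which is a nonlinear transform of VH, so unconditional
  projection could report a center that does not attain the reported
  objective.
* **LOOCV.** For each object, every display involving it is held out, the
  center refit on the remainder (warm-started from the full-data center),
  and the held-out displays' VH computed under the refit center; group
  correlations are taken over the assembled out-of-fold predictions.
  Degenerate folds (fewer than 3 displays per group remaining) are skipped
  with a warning and reported.
* **Dimension selection.** `dimension_sweep` scores each k by
  |r_A| + |r_B| under LOOCV and returns the smallest k within a plateau
  tolerance (default 0.05) of the sweep maximum. The embedding's match to
  the split-half noise ceiling is reported as a diagnostic only; the sweep
  is the operative criterion.
* **MDS.** SMACOF (scikit-learn), metric stress by default with Kruskal
  nonmetric stress-1 as an option, best of `n_init` runs initialized from
  classical (Torgerson) scaling plus Gaussian perturbations (classical
  scaling is exact for Euclidean inputs, which makes noiseless round trips
  machine-precision). Coordinates are centered; orientation is arbitrary,
  and every downstream quantity is invariant to orthogonal transforms.
  Reported stress is stress-1 = √(Σ(d̂−d)²/Σd²).

## Trial filtering

Search trials outside 0.3–3 s and incorrect trials are removed before
averaging. For the symmetry-task decision data, RTs under 100 ms are
removed and all of a participant's trials involving an object are dropped
when that participant's accuracy on the object (computed on the unfiltered
trials) is below 80%. The fraction removed by each rule is reported; an
empty result is an error naming the dominant filter.

## Searchlight procedures

Per voxel, the 3×3×3 neighborhood is clipped to the mask (27 voxels in the
interior, fewer at edges; the per-voxel dimensionality is recorded for the
RDM maps). Mean-activation maps z-score the neighborhood means and the
behavioral predictor *within* display groups (sample SD, ddof = 1) to
remove overall activation-level differences between groups, then correlate
across conditions; undefined correlations become NaN and are counted.
RT maps use the same group-wise z-scoring by default (a documented flag,
since comparability with the VH maps is the goal). RDM maps correlate each
voxel's pairwise-distance vector (Euclidean distances between neighborhood
patterns across all object pairs) with the behavioral dissimilarities.
Regions are 26-connected suprathreshold clusters above a user threshold and
minimum size (no canonical thresholding rule is assumed); region summaries
bootstrap participants with replacement (default 10,000 draws) for the SD
and a one-sided violation-fraction p.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:
search RTs are 1/distance plus Gaussian trial noise truncated at a 0.05 s
floor; decision RTs follow `t_max − β·|VH − b|` plus truncated noise;
accuracy is Bernoulli (0.98 for search, mirroring ~99% in practiced
observers; 0.95 for decisions) with incorrect trials flagged, not removed,
so filtering is exercised; voxel volumes carry planted linear VH- and
RT-codes in disjoint cuboid regions plus i.i.d. Gaussian noise. Random
streams are split per operation, so enlarging one table never perturbs
another's draws, and everything is bit-reproducible under a seed.

Study-scale defaults: 32 objects, 5 latent dimensions (3 for the symmetry
design), 16 participants, 2 search repetitions per pair (992 correct trials
per participant over the 496 pairs), decision-noise SD = 10% of the
noiseless RT range. Latent coordinates are isotropic Gaussian with spread
0.55, placed sequentially so pairwise distances stay in [0.4, 3.0] s⁻¹ —
emulating stimulus-set curation, since real stimuli are chosen to be
neither indistinguishable nor trivially different, which is what keeps
search RTs almost entirely inside the 0.3–3 s window. The mirrored
("symmetric") design places singleton objects at radii b∓δ with matched δ
so the pooled VH–RT correlation is exactly zero by construction.

Not emulated: spatial array geometry and eye movements, RT distributional
shape (the Gaussian trial noise is a configurable stand-in; real RTs are
right-skewed), attentional and practice effects, spatially correlated
fMRI noise, and hemodynamics. Passing tests therefore show that the
*analysis* recovers what it assumes, not that real cortex implements it.

## Numerical choices

* Pearson correlations computed on centered dot products; zero variance
  raises a typed error naming the offending group rather than returning NaN
  silently (maps are the exception: NaN, counted).
* Nelder–Mead tolerances default to xatol 1e-6 / fatol 1e-10; repeated-
  simulation studies and LOOCV folds use the looser 1e-4 / 1e-8 with warm
  starts, which changes correlations by < 1e-3 at study scale.
* Rank-sum test: exact null when the pooled sample is tie-free, otherwise
  the tie-corrected normal approximation; two identical groups give p = 1.
* Display labels map to correlation groups as: group A = present or
  asymmetric (expected r > 0), group B = absent or symmetric (expected
  r < 0); the symmetry chain is the same code path.
* The decision boundary of the generator sits at the midpoint of the two
  groups' mean VH; with structural (non-boundary) labels the group VH
  ranges overlap, as in real data, and the noiseless objective is then
  strictly below 2 — the boundary-rule labeling is what makes perfect
  recovery checks well-posed.
* Problem sizes in the repeated-simulation tests (200 fits, 200 LOOCV
  runs, 100 searchlight volumes at 20×20×20 with 64 conditions) were chosen
  to give tight rate estimates while keeping a full test run in the
  low minutes on one CPU.

## Known limitations

* The optimizer guarantees only local optima; the grid-search oracle check
  covers 2-D problems, and restart agreement is the practical stability
  diagnostic in higher dimensions.
* With structural labels and heavy group overlap the fitted center can
  exploit the overlap and exceed the true-center objective; interpret the
  fitted center geometrically, not mechanistically.
* Bootstrap SDs are slightly downward-biased at small participant counts,
  as usual for resampling with replacement.
* World/MNI coordinates require a caller-supplied affine; no template
  registration, smoothing, or GLM estimation is performed.
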