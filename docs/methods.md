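# Methods

`tonguetopo` implements a geometry–topology–machine-learning pipeline for
studying papillae on micro-scale 3D tongue-surface meshes, together with a
synthetic data generator that emulates the statistical structure of such
scans.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## The pipeline

A surface is a triangulated mesh with vertex coordinates in micrometres.
The analysis proceeds in four stages:

1. **Segment extraction.**  From a seed point P, the candidate set B is
   every vertex within the closed Euclidean ball of radius r + δ of P
   (r = max(r_fungiform, r_filiform) = 439 µm with r_fungiform = 439,
   r_filiform = 177.5; δ = 100 µm).  Components of B not edge-connected to
   P are discarded.  A base plane is fitted to the component by RANSAC
   (1000 three-point hypotheses, 20 µm inlier threshold, least-squares
   refit on the final inlier set), oriented along the component's mean
   outward normal.  The local maximum M is the component vertex with the
   largest signed height above that plane, and the segment is M's connected
   component of the vertices within r of M.

2. **Baseline and curvature features.**  The segment radius is found
   iteratively: start at 100 µm and grow in 10 µm steps until the closed
   ball around M holds ≥ 90 % of the segment's points.  The height is the
   unsigned distance from M to a RANSAC base plane of the radius-r region
   around M.  Discrete curvature uses the mixed finite-element/finite-
   volume discretization: Gaussian curvature is the angle deficit
   2π − Σθ divided by the mixed Voronoi area (obtuse triangles contribute
   area/2 at the obtuse corner and area/4 elsewhere), and mean curvature is
   half the norm of the cotangent Laplace vector over the same area.
   Boundary vertices are excluded from every statistic.  The summary
   features are the extremes of both curvatures plus the sign-count ratios
   k_ratio = min(x, y)/max(x, y) and k_positive_ratio = x/(x + y), where x
   and y count interior vertices of positive and negative Gaussian
   curvature (zeros count in neither).

3. **Topological features.**  Each segment's vertex cloud is subsampled to
   1000 points and its Vietoris–Rips persistence computed with the edge
   filtration value equal to Euclidean length.  H0 deaths are the
   single-linkage merge heights, obtained from the minimum spanning tree.
   H1 is computed by column reduction of the triangle boundary matrix over
   F2.  Twelve one-number summaries are taken per segment: short-bar
   counts (bars of length in (0, 10] µm) in H0/H1; persistent entropy
   −Σ pᵢ ln pᵢ with pᵢ = (dᵢ − bᵢ)/L_D over finite bars; the L2 amplitude
   of the first persistence landscape layer sampled on a uniform grid
   (trapezoid norm); the L2 norm of a Gaussian persistence image raster
   (100 × 100, bandwidth 0.1 × the filtration range, linear persistence
   weighting, unnormalized kernel so the amplitude scales linearly with
   the coordinates); the Wasserstein amplitude (√2/2)(Σ lᵢᵖ)^{1/p} with
   p = 2; and the bottleneck amplitude (√2/2) max lᵢ.  Essential classes
   are excluded from all summaries; an empty H1 diagram contributes zeros.

4. **Classification study.**  Features join ground-truth labels (papilla
   type, participant, gender, age group; age group is young iff age ≤ 28)
   in a tidy table.  Features with pairwise |Pearson r| > 0.65 are pruned
   greedily in canonical column order (the later column of an offending
   pair is dropped).  Two models are evaluated at library-default
   hyperparameters behind a train-split-fit z-score standardizer: an
   RBF-kernel SVM (C = 1, γ = scale) and multinomial logistic regression
   (C = 1).  Evaluation is balanced accuracy (unweighted mean of per-class
   recall) over 50 stratified 80/20 random splits, or leave-one-group-out
   folds where each fold's test set is one whole participant.  Permutation
   feature importance permutes one test column at a time (30 independent
   shuffles) on the best-balanced-accuracy random split and records the
   mean and sd of the accuracy drop, plus a normalized per-family
   aggregate.

## Numerical choices

* **Closed balls.**  All radius queries use ≤; results are checked against
  exhaustive scans and do not depend on the KD-tree.
* **Enclosing-radius truncation.**  The Rips filtration is cut at
  R = minᵢ maxⱼ d(i, j).  At any scale t ≥ R the complex is a cone over
  the minimising vertex, hence connected and H1-trivial, so the H0/H1
  diagram equals the complete filtration's while the triangle count drops
  sharply.  An explicit `max_filtration` below R truncates genuinely:
  classes alive at the cap become essential and are excluded from the
  summaries.
* **Desk-scale H1.**  The triangle-reduction cost grows as the cube of the
  cloud size, so the default feature configuration computes H0 on the full
  1000-point subsample but H1 on a further 150-point subsample with the
  filtration capped at 250 µm — the scale of the crown-ring loops the H1
  features are meant to see.  Both knobs are exposed (`TopoConfig`);
  `h1_subsample=None, h1_max_filtration=None` gives the exact diagram.
* **Entropy sign.**  The Shannon form −Σ pᵢ ln pᵢ is returned (the signed
  sum is available via `shannon=False`), so the entropy of k equal bars is
  ln k and grows with k.
* **Landscape norm scaling.**  Because the landscape amplitude integrates
  over the filtration axis, scaling coordinates by c scales it by c^{3/2};
  the distance-type amplitudes (Wasserstein, bottleneck, image) scale by c
  and entropy is scale-invariant.  All twelve features are invariant to
  rigid motions.
* **Sweep strategy.**  The whole-surface sweep harvests candidate maxima
  from random unvisited seeds, refining each candidate to a fixed point by
  re-cutting centred on M (a far-away seed otherwise only sees a papilla's
  flank at the edge of its ball).  Candidates are then accepted greedily
  in order of decreasing height above their base plane, each accepted
  maximum suppressing later candidates within distance r.  Prominence
  ordering prevents low-relief maxima from permanently shadowing nearby
  papillae, while preserving the invariant that accepted maxima are
  pairwise ≥ r apart.  The sweep ends when the seed pool is exhausted or
  after 60 consecutive fruitless draws.
* **Degenerate inputs.**  Plane fits require ≥ 3 non-collinear points;
  persistence requires ≥ 2 points; curvature requires an interior vertex;
  the sign-count ratios require at least one non-zero-curvature vertex.
  Violations raise typed errors, and the sweep skips degenerate seeds with
  a logged warning.

## The synthetic generator

Real scan data of this kind (silicone tongue impressions, optically
scanned and surface-reconstructed) is not publicly available, so the
package ships a generator whose output mimics its structure:

* a gently undulating base sheet (three plane waves, 30 µm total
  amplitude, ~4 mm wavelength) on a regular 15 µm grid;
* mid-frequency micro-relief between papillae (random plane waves,
  sd 8 µm, wavelengths 0.4–1 mm) — real non-papillated tongue is not
  smooth;
* sparse sharp non-papillar micro-features (folds, filament tips; by
  default 250 per cm², 30–60 µm radius, 15–35 µm height), kept off papilla
  base disks.  These poison extreme-value curvature statistics in every
  class, the way real tissue irregularities do;
* fungiform papillae: smooth domes, 878 µm nominal diameter, 140 µm
  nominal height, concentrated profile (1 − u²)^k with k = 1 + sharpness
  and default sharpness 2.5, so the dome sits inside its footprint with a
  flat skirt and a gently curved apex;
* filiform papillae: crowns of 355 µm nominal diameter and 170 µm height —
  a broad pedestal, a central spike and a ring of (by default) six
  sub-spikes whose sharpness far exceeds the fungiform dome's;
* per-papilla biological variability: lognormal jitter on height
  (sd 0.40), footprint radius (sd 0.12) and profile sharpness (sd 0.10),
  plus a ±2 spread on the crown spike count.  The large height jitter is
  what makes the baseline (height/radius) features genuinely weak, as they
  are on real tongues;
* spatially correlated measurement noise along vertex normals (sd 2.5 µm,
  correlation length 60 µm).  Reconstruction noise is smooth at the vertex
  scale; uncorrelated per-vertex noise would dominate discrete curvature;
* cohort structure: participants draw gender (P(F) = 9/15) and integer
  ages ~ N(29.1, 3.7²) clipped to 22–37, with guaranteed presence of both
  genders and age groups.  Female and young participants receive a
  relative sharpness boost (+20 % each by default), and each participant
  carries small lognormal idiosyncratic size and sharpness multipliers
  (sd 0.08) plus a crown-spike-count offset — the signal that makes a
  participant identifiable from a single segment.

"None" training segments are sampled from papilla-free regions of the same
surfaces (a reserved strip guarantees such regions exist at cohort scale),
never from separate flat meshes.

Generator parameters were chosen once so that the class-conditional
feature structure mirrors the qualitative behaviour reported for real
papillae — heights overlapping heavily across types, filiform far sharper
than fungiform, fungiform otherwise gently curving like non-papillated
tissue, and extreme-value curvature statistics brittle where aggregate
topological summaries are stable.  They are defaults of the generator, not
fitted quantities.

### What the synthetic experiments show — and what they do not

Passing the study-level checks shows that the pipeline recovers planted
geometry accurately, that its feature families rank the way the analogous
real-data study ranks them (all combined > topological > curvature >
baseline for papilla-type classification under both random splits and
leave-one-participant-out), that injected participant effects are
detectable and their absence collapses participant identification to
chance, and that the permutation-importance machinery behaves.  It does
not show that real tongue scans would yield the same absolute accuracies:
the generator's papillae are idealized radial bumps without the full
richness of real microanatomy, its noise model is stationary, and its
cohort is small (six participants at desk scale).

## Study problem sizes

The default study configuration (`StudyConfig`) runs 6 participants × 60
segments (12 fungiform : 43 filiform : 5 none, following the real class
ratio 414 : 1489 : 190), 50 random splits, 30 permutations, a 1000-point
subsample per segment with the H1 stage at 150 points, and a 0.5 cm²
recovery surface bearing 40 well-separated papillae.  A full run of
`scripts/acceptance.py` takes roughly a quarter of an hour on one CPU.

## Known limitations

* The printed height algorithm measures height inside the 3D ball of the
  computed containment radius around M; for papillae tall enough that the
  ball excludes the base entirely, the estimate degrades.  At the default
  geometry the mean error on planted papillae is ~4 %.
* H1 features at the desk-scale defaults are computed on a 150-point
  sub-subsample; loops smaller than the resulting point spacing are
  invisible.
* The RBF-SVM at default hyperparameters under-serves the 9 % minority
  "none" class at small n; the logistic-regression results are the more
  faithful view of family-level information content at desk scale, and
  both are reported.
* Correlation pruning is order-dependent by design (canonical column
  order) and documented in the removal log.
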