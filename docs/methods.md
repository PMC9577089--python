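# Methods

This note documents the models and procedures implemented in `cbparc`, the
assumptions behind them, the parameters that matter, and the choices made
where the procedure was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Connectivity-based parcellation (CBP) assumes that voxels belonging to the
same cortical subregion share a long-range connectivity profile. The
pipeline consumes, per subject, a seed-voxel × target matrix of
probabilistic-tractography streamline counts (rows indexed in a fixed scan
order: x fastest, then y, then z), on a voxel grid shared by all subjects.
All registration happens upstream: any operation comparing two volumes
requires identical grids (equal shape, affines within 1e-4 mm) and raises
rather than resampling.

## Similarity and clustering

The clustered quantity is the Pearson correlation between the connectivity
profiles of voxel pairs. Raw inner products of count rows are
scale-dependent (a voxel with twice the streamline count would dominate),
so profiles are standardized per row; the result is a symmetric matrix in
[−1, 1] with unit diagonal. Voxels with zero-variance profiles (no
streamlines) keep their place with similarity 0 to all others, so label
volumes retain the seed geometry; a warning is logged.

Spectral clustering is deliberately pinned down, since "spectral
clustering" names a family:

* affinity = similarity with negative entries clipped to 0, unit diagonal;
* embedding = top-K eigenvectors of D^{−1/2} A D^{−1/2} (symmetric
  normalized), rows normalized to unit length;
* assignment = k-means with 10 restarts and a fixed seed.

Negative correlations carry no affinity information for a random-walk
embedding and are clipped; this can disconnect the affinity graph (it
regularly does when cluster profiles anticorrelate). A disconnected graph
is handled per component: the K clusters are shared out to components
proportionally to size (each major component gets at least one), each
component is embedded and clustered separately, and components too small to
receive a cluster are merged into the cluster with the highest mean
affinity. All of this is logged.

## Group maps, tie-breaks, filtering

Subject labels are arbitrary, so each subject is aligned to the first by
the label permutation maximizing total voxel overlap (Hungarian assignment
on the K × K overlap matrix). Aligned subjects yield per-cluster probability
maps (labeling frequency per voxel); the maximum probability map (MPM)
takes the per-voxel argmax. Exact probability ties are broken by the higher
mean probability over the 26-neighborhood (the 3×3×3 cube minus the center,
clipped at grid borders, in-grid neighbors only in the denominator); a
residual exact tie goes to the lower cluster index and is logged. Voxels
with zero probability for every cluster stay background; no minimum
group-probability threshold is applied.

"Median filtering" of categorical labels is implemented as the only
order-free reading: each in-mask voxel takes the modal label of its in-mask
26-neighbors in a single pass, with modal ties keeping the original label.
The filter can be applied per subject or to the MPM; the pipeline default
is MPM-level (`median_filter="mpm"` in `fit()`), which smooths single-voxel
islands without touching the per-subject evidence the probability maps are
built from.

## Choosing the number of subregions

Reproducibility per K is scored by split-half resampling: each repetition
splits the subjects into two equal halves (sizes differing by one for odd
cohorts), builds an MPM per half, and compares the two half-cohort maps.
Four indices are computed from the contingency table over voxels labeled in
both maps (background excluded, so partial support cannot inflate
agreement):

* Cramér's V = √(χ² / (N·(min(r,c)−1))), in [0,1]; degenerate marginals
  (a single nonzero row or column) return 0 with a warning.
* NMI = 2·I(X;Y)/(H(X)+H(Y)). Among the normalization variants in use
  (min, max, sqrt, arithmetic), the arithmetic form is fixed here: it is
  symmetric, bounded, and the most common convention.
* VI = H(X)+H(Y)−2·I(X;Y). Entropies use natural logarithms, so VI is in
  nats; the choice only rescales VI and is fixed for comparability.
* Dice: per-label 2|A∩B|/(|A|+|B|) after alignment, averaged over labels
  present in either map.

The same split-half protocol is applied to all four indices for uniformity
(the resampling scheme is only explicit for CV in the source procedure; the
alternatives — all-pairs subject comparisons, subject-vs-MPM — would give
one number per index per K just as well but are not what the package
computes). The default repetition count in the CLI is 1,000; the model
object's `fit()` default is 100 and the acceptance checks use 200, which is
where the mean stabilizes to ~2 decimal places at cohort sizes of a dozen
subjects.

The optimal K minimizes the total rank across the four indices (CV, Dice,
NMI ranked higher-is-better; VI lower-is-better; average ranks for ties);
an exact tie in the total goes to the smaller K, logged. On the published
per-hemisphere evaluation tables this rule selects K = 2 for both
hemispheres, which the acceptance script recomputes.

## Connectivity fingerprints

A fingerprint is one region's vector of connection values over an ordered
target set; the canonical set is 19 homologous regions spanning motor,
somatosensory, language, memory, and higher-cognitive cortex. Structural
values are connection probabilities: streamlines from the seed region
reaching the target, divided by (region size × streamlines seeded per
voxel). This denominator is a definitional choice (the standard
streamlines-reaching / streamlines-seeded reading); it cancels under the
min-max normalization anyway. Streamlines per voxel is a configuration
value, default 20,000 (published protocols vary between 5,000 and 50,000
per voxel depending on species and image quality).

Min-max normalization maps each fingerprint's strongest target to 1 and
weakest to 0: p′ = (p − min)/(max − min). The normalization is stated in
the source once with the numerator inverted (p − max), which would yield
range [−1, 0] and contradict the accompanying stated contract (max→1,
min→0); the contract is implemented. Constant fingerprints are rejected as
degenerate rather than silently mapped.

Comparison uses cosine similarity (primary criterion) and Manhattan
distance (corroborative). `match_homologs` reports full CS and MD matrices,
proposes the CS-argmax per region, flags CS ties and any CS/MD
disagreement, and resolves neither. Group-level fingerprints average
per-subject structural fingerprints after normalization, and functional
ones on the Fisher-z scale — the variance-stabilizing defaults, exposed as
the only behavior of `group_fingerprint`.

Functional fingerprints are Pearson correlations between region time
series; target selection for display uses a strict threshold (r > 0.4 for
region charts, r > 0.5 for fingerprint wheels), descending order.

## The synthetic cohort

`generate_cohort` emulates the product of probabilistic tractography, not
the physics upstream of it:

* The seed box (default 10×10×3 = 300 voxels, the scale of a small cortical
  area at ~1.4 mm resolution) is partitioned into `k_true` spatially
  contiguous slabs along its longest axis — real parcels are contiguous,
  and contiguity makes the MPM and modal-filter stages meaningful.
* Cluster c's target-propensity vector is
  θ_c = (1−separation)·base + separation·δ_c with a shared positive simplex
  `base` and cluster-specific simplex vectors δ_c with disjoint support, so
  `separation` interpolates from identical profiles (0) to disjoint
  high-mass targets (1).
* Subject s perturbs θ multiplicatively with log-normal factors
  (σ = `subject_jitter`, default 0.1) and renormalizes — inter-subject
  variability of connection strength.
* Voxel v draws Multinomial(`n_streamlines`,
  (1−`noise_floor`)·θ_sc + `noise_floor`·uniform). The multinomial
  preserves the fixed per-voxel streamline total real tractography output
  has; the noise floor (default 0.05) mimics spurious streamlines.

Defaults: 12 subjects, k_true = 2, 19 targets, 2,000 streamlines per voxel,
separation 0.5, seed 42. These are the package's study conditions: a
moderately separated bipartition a dozen subjects can pin down, with the
streamline count scaled to the desk-size seed box (2,000 × 300 voxels per
subject). Everything is bit-identical under a fixed seed.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: spatial autocorrelation of tractography error,
distance-dependent streamline attrition, registration misalignment between
subjects, gyral-crown seeding bias, and partial-volume mixing at parcel
borders. Recovery at Dice 1.0 on the default cohort certifies the pipeline
machinery, not expected performance on diffusion MRI, where published CBP
split-half indices are far below 1.

`generate_timeseries` draws i.i.d. multivariate-normal time points whose
population correlation equals the requested matrix (eigen-factorization, so
exactly singular targets such as r = 1 are allowed); no hemodynamics are
simulated because the functional stage only consumes Pearson r.
`generate_fingerprint_sets` plants homolog pairs as a shared base profile
plus independent noise.

## Numerical choices and degenerate inputs

* Similarity matrices are symmetrized ((R+Rᵀ)/2) and clipped to [−1, 1]
  after the standardized product; symmetry is enforced at 1e-10.
* Label I/O accepts float-typed NIfTI labels within 1e-6 of integers
  (files written by tools that store labels as float32) and rejects
  anything else.
* Matrix tables are TSV, UTF-8, '.' decimal, written at full precision
  (%.17g), so fixture round-trips are exact to 1e-12 or better.
* Cosine similarity returns exactly 1.0 for bit-identical profiles,
  avoiding sqrt round-trip error on the natural "self-match" check.
* Zero-variance time series, all-zero fingerprints, constant fingerprints,
  empty joint support, and sub-minimum cohort sizes all raise with the
  offending region/voxel named; nothing is silently dropped.
* VI is clipped at 0 and NMI to [0, 1] against −1e-17-scale negative
  rounding in the entropy sums.

## Known limitations

* Spectral clustering details (clipping, normalization, restarts) are one
  reasonable fixing of an under-specified procedure; other choices yield
  other partitions on weakly separated data.
* The optimal-K rank rule treats the four indices as equally weighted;
  published VI values quoted alongside CV/Dice/NMI tables are sometimes on
  a different scale than definitional nats, and the rule only uses ranks
  partly for this reason.
* Hemisphere handling is the caller's: the seed mask passed in defines the
  unit of analysis; nothing splits left/right automatically.
* `match_homologs` is a per-region argmax, not a global assignment; two
  regions may propose the same partner, and flags are the only arbitration.
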