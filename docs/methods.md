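# Methods

`scalemorph` quantifies the silhouette shape of teleost elasmoid scales with
two complementary geometric-morphometric pipelines and tests whether shape
separates species, body areas, or rearing groups. This note records the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Coordinate and unit conventions

All internal geometry uses mathematical axes: x rightward, y upward. Image
pixels are flipped from row-major order on load, so a scale photographed in
the standard orientation (anterior margin leftward, dorsal margin upward)
reads the same way internally. Coordinates are divided by each scale's
`pixels_per_mm` calibration at load; centroid sizes are therefore in
millimetres and comparable across magnifications. TPS files do not declare a
y-axis convention, so the loader exposes a `flip_y` flag rather than
guessing.

## Landmark route

Each scale contributes five fixed landmarks on the margin — the four
junctions between the anterior, dorsal, posterior and ventral margins plus
the middle of the posterior margin — and 80 semilandmarks: 40 along the
anterior margin (the most variable trait) and 10 along each of the four
other inter-landmark margins, 85 points in total. The focus (growth centre)
is deliberately excluded: it is invisible in regenerated scales, which are
common in farmed fish, and a focus-free scheme stays applicable to them.

Digitized landmarks are snapped to the nearest point of the traced outline;
two landmarks snapping within 1% of the perimeter of each other, or labels
in no cyclic order along the outline, abort with an error (implausible
digitization). If the labels run clockwise around the counterclockwise
outline — a digitizer y-axis mismatch — the traversal direction is flipped
and analysis proceeds; the geometry itself is untouched. Semilandmarks are
placed at equal arc spacing along the traced outline between consecutive
snapped landmarks (margin length / (count + 1)); arc length is the only
self-consistent parameterization for "equidistant" placement on a polyline.

Superimposition is partial generalized Procrustes: each configuration is
centered and scaled to unit centroid size once, then iteratively rotated
onto the running consensus (pointwise mean) until the RMS consensus change
falls below 1e-8 (max 100 iterations; non-convergence returns a flagged
result rather than an error). Reflections are disallowed by default because
scales are imaged in a standard orientation; a flag exists for mirrored
inputs. The rotational indeterminacy left by superimposition is removed by a
deterministic gauge: the consensus landmark-1 → landmark-4 chord (anterior
tip to mid-posterior) is made horizontal, or, for unlabeled configurations,
the consensus principal axis is aligned with x.

Semilandmark sliding is available (`slide="bending_energy"`): during the
first five alignment rounds each semilandmark may move along its local
tangent to minimize thin-plate-spline bending energy against the consensus,
then is re-projected onto its own outline polyline; fixed landmarks never
move. Sliding is *off* by default — equidistant placement is itself a
well-defined treatment, and both modes are first-class and recorded in the
output metadata. Capping sliding at five rounds prevents the
align–slide–reproject loop from cycling below the convergence tolerance;
in practice positions stabilize within two or three rounds.

## Outline route

The silhouette boundary is traced at the 0.5 iso-level of the binary mask
(marching squares), giving a sub-pixel polygon that encloses every
foreground pixel centre. The polygon is resampled to 360 equidistant points
(configurable; 360 resolves the default dentate margin comfortably and
keeps the Nyquist bound far above the 32-harmonic cap), centered on its
vertex mean, and scaled to unit centroid size. Orientation is *not*
normalized by default: acquisition orientation is standardized upstream, and
preserving it keeps the coefficients anatomically interpretable. First-
ellipse orientation (`orient="first_ellipse"`) is available for unoriented
collections.

**Starting point.** Elliptic Fourier coefficients depend on where t = 0
sits on the outline. An extremal rule (e.g. the minimum-x vertex) wanders
along flat or wavy anterior margins under digitization noise, scrambling the
cosine/sine split of every harmonic — measured on synthetic data, the
induced within-group coefficient scatter was as large as the between-species
signal. The pipeline instead anchors the start where the outline crosses the
anterior ray (the −x direction from the centroid): an angular anchor is
invariant under radial shape noise, deterministic, and respects the
acquisition orientation. The classical first-ellipse phase normalization is
also provided (`normalize_phase`) but is not used by the pipeline: it is
unstable when the first-harmonic ellipse is nearly circular, which several
scale shapes are.

**Transform.** The curve parameter advances one unit per vertex and the
Fourier projections are integrated exactly over the piecewise-linear chain.
On equidistantly resampled outlines — which is all the pipeline ever feeds
the transform — this is precisely the classical arc-length (chain-code)
formulation; a curve supplied with its own parameterization keeps that
parameterization's coefficients (so a densely sampled trigonometric ellipse
is exactly one harmonic). Harmonic power is (a² + b² + c² + d²)/2; the
analysis keeps the smallest harmonic count whose cumulative power reaches
99% for every outline in the dataset (one shared count, capped at 32).
Because size and position are removed geometrically before the transform,
all four first-harmonic coefficients are retained in the descriptor matrix
and DC terms are dropped.

## Inference

PERMANOVA follows Anderson's one-way decomposition on squared Euclidean
distances: SS_total = (1/N) Σ_{i<j} d²ᵢⱼ, SS_within = Σ_g (1/n_g) Σ_{i<j∈g}
d²ᵢⱼ, pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)), R² =
SS_between/SS_total. Whole labels are permuted; the observed statistic is
included in both numerator and denominator of the p-value, so p ≥
1/(n_permutations+1). When the distinct label arrangements number at most
10 000 the exact distribution is enumerated instead of sampled. The test
runs on the full coordinate/coefficient matrix; because Euclidean distances
are invariant under the orthonormal change of basis, running it on all PCA
scores gives identical statistics (verified by test), which reconciles
"testing on the PCA" with testing the raw matrix. Pairwise tests are
Bonferroni-adjusted over the number of pairs in the run by default (Holm and
no adjustment available); at 999 permutations and six pairs the smallest
attainable adjusted p is 6 × 0.001 = 0.006. Every permutation routine takes
an explicit seed and identical seeds give identical p-values.

Centroid-size group differences use pairwise two-sided Welch (unequal
variance) t-tests, reported unadjusted with effect direction. Allometry is
the multivariate regression of aligned coordinates on log centroid size;
R² = SS_model/SS_total over the whole coordinate matrix and significance
comes from permuting sizes across specimens.

PCA is the eigendecomposition of the feature covariance (divisor n−1) via
SVD, with a deterministic sign convention (largest-magnitude loading
positive). PC shape vectors back-project an axis into shape space at
mean ± magnitude·√λ·v, rendered as a coordinate displacement field
(landmark context) or a reconstructed outline (Fourier context).

## Synthetic scale generator

Templates are rounded quadrilaterals (superellipses of exponent ~3–5,
semi-axes aspect_ratio × radius and radius), anterior margin at −x, with the
anterior margin modulated by the species-diagnostic oscillation style:
smooth (none), striated (24 shallow ripples, amplitude 1.2% of local
radius), waved (6 sinusoidal lobes, 5%), dentate (8 triangular teeth, 7%).
Amplitudes are fractions of the local radius; a window vanishing at the
margin ends keeps the landmark junctions fixed. True landmarks sit at the
four margin junctions and mid-posterior by construction. The five default
species templates differ in margin style, aspect ratio, squareness and
radius (0.45–2 mm), mirroring the study system's gross size ordering
(mullet-like largest, zebrafish-like smallest) and its four margin styles.

Per-specimen variation is a low-order random radial Fourier field (6 orders,
coefficients ~ N(0, noise_sd²), default noise_sd = 0.015, i.e. pointwise
radial scatter of ≈ 3.7%) plus small rotation (sd 0.02 rad) and log-scale
(sd 0.03) jitter that downstream normalization removes. Radial fields
cannot self-intersect a star-shaped outline, and they span the same
descriptor space as the Fourier pipeline, which makes power studies
interpretable. Group-level effects perturb the template by a fixed random
radial direction scaled by an effect size δ, so δ = 0 is an exact null and
R² grows monotonically with δ (verified). Everything is deterministic under
a seed, and the recorded truth block regenerates a dataset bit-identically.
Datasets can be written to disk as PNG silhouettes (rasterized at a stated
pixels/mm), TPS landmarks and CSV metadata — exactly the formats the loaders
read — so synthetic runs exercise the full I/O path.

What the generator does *not* emulate: surface texture (circuli, radii,
cteni), the focus, damaged or partially digested scales, operator-dependent
silhouette thresholding, and correlated within-specimen effects beyond the
shared template. Passing tests therefore demonstrate the correctness and
calibration of the machinery on scale-like geometry, not field performance
on real images.

## Problem sizes and checks

The validation suite uses: exactness checks on transformed copies (100
shapes × 85 points); a hand-enumerable PERMANOVA instance and classical
one-way ANOVA as oracles; 1000 null simulations (24 specimens, 200 features,
199 permutations) for type-I calibration of PERMANOVA and the Welch test;
20 replicate five-species datasets at the study's group sizes (35, 29, 11,
81, 28) with 999 permutations for the discrimination power check; and a
rasterize-at-371 px/mm → trace round trip required to recover the
generating outline within one pixel (Hausdorff distance). The acceptance
script repeats the main computations from scratch, including one full
disk-pipeline pass (write silhouettes → reload → both analyses).

## Known limitations

* 2-D only; no missing-landmark estimation — damaged scales must be
  excluded upstream.
* No automatic landmark detection; landmarks are inputs (TPS or synthetic
  ground truth).
* Outlines must be simply connected; 1-pixel-wide necks in a mask produce a
  cleanup error rather than a repaired contour.
* The anterior-ray start anchor assumes the standard acquisition
  orientation; for unoriented collections combine `orient="first_ellipse"`
  with `normalize_phase` and inspect stability.
* Whether the original workflows slid semilandmarks or fixed them, and
  their exact outline-normalization options, are not recoverable; both
  sliding modes are provided and reported, and the outline dialect here is
  this package's defined behavior.
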