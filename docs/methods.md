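# Methods

This note documents the models, parameter choices and numerical
conventions behind `sphereseg`, and what its synthetic tests do and do
not establish.

## Spherical slice deformation

The deformation is a gnomonic projection onto a sphere of radius R
tangent to the image plane at the projection origin, unrolled
equidistantly: an output pixel at radial distance ρ from the origin
samples the source at s(ρ) = R·tan(ρ/R) along the same direction, with
inverse ρ(s) = R·arctan(s/R).  Properties that motivated this choice:

* it is exactly invertible, so ensemble predictions can be pulled back
  to the original grid before aggregation;
* the local scale ds/dρ = sec²(ρ/R) is 1 at the origin and strictly
  increasing, i.e. the origin's neighbourhood is relatively magnified
  and the periphery compressed, while the field of view is preserved up
  to the horizon ρ = πR/2;
* it converges to the identity as R → ∞ (analytically |s−ρ| ≤ ρ³/3R²),
  which the tests verify.

The literature on fisheye-style deformations for segmentation ensembles
admits several radial laws; the exact transform is a configurable
strategy here, not a fidelity claim about any particular prior work.

Parameters: R defaults to 64 px for 256×256 slices, placing the horizon
(≈ 100.5 px) near the slice half-diagonal so peripheral compression is
visible but non-degenerate.  Interpolation is bilinear with fill 0 (MR
background after skull stripping); nearest-neighbour is available and
preserves binary value sets.  Resampling uses scipy's
`map_coordinates` with `grid-constant` boundary handling so border
pixels blend with the fill value instead of being hard-clipped.

Origin grids start at ⌊interval/2⌋ and step by `interval` in each
dimension — 32² = 1024 origins at the full-scale 8-pixel interval.
Desk-scale defaults use interval 16 (16 origins per 64×64 slice); all
entropy and aggregation properties are ensemble-size agnostic.

## Entropy uncertainty

Ensemble probabilities are discretised into B = 100 uniform bins on
[0,1], the last bin right-closed so 1.0 is counted.  Entropy is the
natural-log Shannon entropy of the nonzero bin frequencies, bounded by
ln 100 ≈ 4.605.  Only predictions whose back-projection landed inside
the deformed grid are counted; pixels with no valid prediction get
entropy 0 and are flagged (`UncertaintyVolume.no_valid`).  Aggregation
happens in original-grid coordinates — back-project first, then
average/bin — the only geometrically consistent ordering when every
ensemble member lives on a differently deformed grid.

## Kernel localisation

Window scores are exact d³ sums computed with a zero-padded 3D
summed-area table (O(1) per window), candidates at stride 1 by default.
Greedy selection sorts candidates by descending score, breaking ties by
lexicographic corner order for determinism, accepts a candidate iff its
volumetric overlap with *every* accepted kernel is ≤ `max_overlap`
(default 0.40), and halts when the best remaining score falls below
`stop_fraction` (default 0.10) of the first accepted score.  The
relative stopping rule was chosen because it is scale-free across
uncertainty magnitudes; an absolute floor (`min_score`) is also
available.  Scores are *not* recomputed after acceptance; a compact
blob can therefore legitimately be covered by several equal-score,
low-overlap kernels — the refinement stage is insensitive to this
redundancy because composite averaging is idempotent for agreeing
local predictions.  Kernels are clamped inside the volume (no padding),
so every crop contains real image content; when the configured edge
exceeds the smallest volume dimension it is reduced to the largest
fitting power of two with a warning.

## Fusion

Composite 3D probabilities are plain voxel-wise means of the local
predictions covering each voxel (no border feathering).  Fusion applies
the logistic squash only where coverage ≥ 1; uncovered voxels keep P2D
bit-identical.  The bias b is defined by the fusion rule but the swarm
canonically searches only (w2D, w3D); by default b = −(w2D + w3D)/2,
which maps P2D = P3D = 0.5 to 0.5 — without such centering, a sigmoid
of non-negatively weighted probabilities is systematically biased above
0.5.  b may instead be fixed or added as a third search dimension
(`b_policy="optimize"`, bounds [−5, 5]).

## PSO

Standard global-best PSO: inertia 0.72, cognitive = social = 1.49
(constriction-like defaults), box [0, 5] per weight (the logistic
saturates far beyond), velocity clamped to half the box width,
positions clipped to the box (which enforces w ≥ 0), population 20, 50
iterations, seeded `numpy` Generator throughout.  NaN objective values
are demoted to −∞ with a warning.  The DSC objective freezes P2D and
the composite per case, so each particle evaluation costs only a fused
sigmoid, a binarisation and a Dice ratio.

## Metrics

* Dice: 2|A∩B|/(|A|+|B|); both-empty → 1.0 by convention (flagged
  contexts; ET can be genuinely absent).
* HD95: surfaces are 6-connectivity erosion differences; directed
  distances come from spacing-aware Euclidean distance transforms; the
  reported value is the maximum of the two directed 95th percentiles —
  the convention most common in medical-segmentation tooling (pooling
  conventions differ across packages; this one is symmetric by
  construction).  Either mask empty → NaN, excluded from aggregates.
* Wilcoxon signed-rank: zero differences excluded, exact distribution
  for ≤ 25 nonzero pairs (no ties), normal approximation with
  continuity correction otherwise; two-sided; fewer than 5 pairs warns.
  Bonferroni threshold is exactly alpha / number-of-comparisons.

## Synthetic phantom

The phantom emulates the structure of preprocessed BraTS-style cases:
a 4-channel volume on a 1 mm isotropic grid, nested ellipsoidal tumor
subregions (ET inside NCR/NET inside ED, giving ET ⊆ TC ⊆ WT), an
intracranial ellipsoid as brain ROI, per-tissue channel means
(normalised [0,1] scale: edema hyperintense on FLAIR 0.80 / T2 0.75;
enhancing tumor hyperintense on T1ce 0.90; necrotic core T1-hypo 0.30)
and additive Gaussian noise (sd 0.05 by default).  The default grid is
64×64×48 for desk-scale runtime; 256×256×160 is supported.  Contrast
values are conventions chosen to give the right ordinal relations
between tissues — real BraTS intensity distributions are not published
as parametric tables and no realism beyond ordering is claimed.  What
a green phantom test establishes: the geometry, aggregation, selection
and fusion machinery behave as specified.  What it does not establish:
segmentation accuracy on real MRI, which depends on trained backbones;
consequently published real-data DSC/HD95 values and learned fusion
weights are out of scope, and the weight-ordering scenarios assert only
the *direction* of dominance, which is construction-determined.

## Numerical and degenerate-input conventions

* Binarisation is strictly greater than 0.5 everywhere (0.5 → 0).
* All-zero uncertainty → empty kernel selection → fused ≡ P2D (no-op).
* Duplicate kernels in a composite are counted twice, with a warning.
* Probabilities are clamped to [0,1] after interpolation; stacks with
  fewer than 2 members warn (entropy degenerate).
* Mock logistic backends use `scipy.special.expit` (no overflow).
* All randomness flows through `numpy.random.default_rng(seed)`; reruns
  with equal seeds are bit-identical end to end.

## Known limitations

* The entropy is a test-time-ensemble surrogate; it does not separate
  epistemic from aleatoric uncertainty.
* Kernel size, overlap cap and stopping fraction are empirical
  hyperparameters; no adaptive selection is attempted.
* The slice ensemble is 2D-only; no volumetric spherical deformation.
* The bundled backends are deliberately trivial; scientific conclusions
  about real images require plugging in trained networks through the
  predictor contracts.
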