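# Methods

## Decoding model

Decoders are multi-output ridge regressions from vertex beta values to a
stimulus embedding space,

    min_W ||Y − XW − b||² + α ||W||²,

with an unpenalized intercept fitted by centering both sides. The solver
uses the primal normal equations when vertices ≤ trials and the dual
(kernel) form otherwise; at α = 0 a rank-deficient design falls back to
the pseudoinverse with a warning. Inputs are column-standardized with
training-split statistics (sample sd, ddof 1; constant columns pass
through centered), and the identical transform is applied at prediction
time — this keeps a single shared α meaningful across vertices and
feature dimensions.

Training regimes differ only in row selection: a *modality-specific*
decoder uses the training trials of one modality; a *modality-agnostic*
decoder concatenates the image-trial and caption-trial rows, each row
targeting its own stimulus's features. The target provider is
independent of the training modality (an image-trained decoder may
predict language-model features of the corresponding captions).

α defaults to a fixed 10.0 for the synthetic studies; `alpha="cv"`
selects from a logarithmic grid (1e-2 … 1e6) by k-fold cross-validated
pairwise accuracy on the training split, ties resolving to the smallest
value (stronger shrinkage is never preferred without evidence). The
regularization path is deliberately configurable because no single
convention dominates practice.

## Identification metric

Predictions for an evaluated stimulus set are standardized per feature
dimension (mean 0, sample sd 1; constant dimensions set to 0 — this is
the only axis convention that leaves cosine geometry informative) and
compared to every candidate's features by cosine similarity. A query's
score is the fraction of distractors whose similarity falls strictly
below the true candidate's; ties count ½, which is unbiased under
exchangeability. Chance is exactly 0.5 for any candidate-set size. For
cross-modal evaluation the true candidate is the matched stimulus of the
other modality. Implementation is rank-based (average ranks), verified
exactly against an all-pairs counting oracle.

Imagery trials are evaluated with the perception-trained agnostic
decoder; their predictions are standardized separately over the imagery
rows only (three rows in `three_only` mode), never pooled with
perceptual predictions. The extended candidate set adds the full test
set (3 + 70 = 73 candidates by default). Standardizing three predictions
over themselves sharpens within-imagery contrasts but does not
generalize — the accuracy drop from `three_only` to `extended` is an
expected property, not a bug.

Decoder-type comparisons grouped by subject are fitted as a
fixed-effects linear model, `accuracy ~ C(subject) + C(decoder_type)`,
reporting the contrast coefficient, its standard error and a two-sided
p — the β/SE/p form of a two-level repeated-measures comparison. With a
single subject the subject term is absorbed (with a warning).
Uncertainty on mean accuracies uses percentile bootstrap intervals of
the mean.

## Searchlight conjunction

Neighborhoods are the k nearest vertices by Euclidean coordinate
distance, center included, ties broken by vertex id (k = 750 is the
field convention on a full-resolution surface; desk-scale runs use
k ≈ 25 on a 900-vertex grid). Per vertex, three decoders are fitted on
the neighborhood columns and scored on four conditions — agnostic
decoding of images and of captions, caption-trained decoding of images,
image-trained decoding of captions. All four must exceed chance for a
region to count as modality-invariant, so per-condition one-tailed
one-sample t-maps against 0.5 (across subjects) are combined by their
pointwise minimum.

Computationally the per-vertex fits are exact but share one Gram matrix
per decoder and subject: a neighborhood's normal equations are a
submatrix slice of the full-vertex Gram, solved in LAPACK batches. A
chunk-invariance test guarantees results do not depend on evaluation
order, so per-vertex work may be parallelized freely.

Zero-variance t statistics (all subjects identical) map to a signed
sentinel of magnitude 1e6 rather than ±∞ so that minima and TFCE stay
finite; |t| is capped there as well.

## TFCE and permutation inference

Graph TFCE integrates, per vertex, extent^E · height^H over thresholds
h = dh, 2dh, … up to the map maximum, where extent is the size of the
vertex's connected component among vertices ≥ h (components via sparse
connected-components on the positive-support subgraph). Defaults H = 2,
E = 1 follow the surface convention; dh defaults to max/100 (floored at
1e-6) and is configurable — note TFCE is only guaranteed monotone under
pointwise map increases at *fixed* dh. Negative conjunction values are
clamped to zero first (one-tailed hypothesis; TFCE is defined for
positive excursions). The isolated-vertex closed form (∫h² dh = h³/3)
and the two-vertex cluster (2h³/3) validate the implementation to the
Riemann-sum error of dh.

The null distribution is built in two stages. Per subject, the decoders
are fitted once and evaluated under shuffled labels: each shuffle draws
one permutation of the test-stimulus pairing (identity excluded),
applied at evaluation time across all vertices and conditions so null
maps keep their spatial correlation. Group-level, unique subject-shuffle
combinations are drawn (enumeration when the combinatorial space is
small, rejection sampling otherwise; an error states the bound when the
request is infeasible), and for each the full statistic — four t-maps,
min-t, TFCE — is recomputed and its spatial maximum recorded. Vertexwise
p-values are the literal proportion of null maxima exceeding the
observed TFCE (which can be exactly 0); a Phipson–Smyth (b+1)/(m+1)
variant is available. Comparing every vertex to the distribution of the
spatial maximum is what delivers family-wise error control.

Shuffling the evaluation pairing rather than retraining on shuffled
targets reflects the fixed-decoder reading of label permutation and
keeps the null computationally honest (the alternative retrains decoders
per shuffle at ~100x cost; it is not implemented).

## Synthetic study generator

The generator emulates the study design the analyses assume: per
subject, disjoint training stimuli per modality, a shared test set whose
stimuli appear once as an image trial and once as a caption trial
(matched pairs), and three imagery conditions on stimuli never shown
perceptually. Stimulus content is an i.i.d. standard-normal latent
vector. Feature providers are random linear maps of the latents plus
independent modality-private Gaussian components scaled by
`modality_specific_weight` (multimodal providers get a 4x smaller
private part), mimicking vision/language/multimodal embedding spaces
with shared semantics but modality-specific detail.

Vertex responses are linear-Gaussian on a graph surface (lattice or
random sphere mesh). Three spatially contiguous regions are planted by
farthest-point center placement and coordinate-ball growth: *invariant*
vertices respond to the stimulus latent identically in both modalities,
*image_only* vertices respond to vision features on image trials only,
*caption_only* symmetrically, and the rest are pure noise. Mixing-map
entries are N(0, 1/in_dim) so signal vertices have unit response
variance and `noise_sd` directly sets the SNR. Region labels are shared
across subjects (group analyses assume spatial correspondence); mixing
maps and noise draws are per subject. Imagery trials reuse the invariant
pathway with noise inflated by `imagery_noise_factor` (default 2 —
imagery is reliably harder than perception; the factor is a tunable
default, as no quantitative anchor exists for it).

Default desk-scale conditions: 6 subjects, a 30x30-vertex grid, 400
training trials per modality, 70 matched test pairs, latent dimension
16, 64-dimensional feature spaces, regions of 60 vertices,
`noise_sd = 1.0`. The relative variance of modality-dependent versus
invariant signal within a region has no published anchor; the defaults
(unit signal variance per region pathway) are explicit config.

What the generator deliberately omits — hemodynamics and temporal
structure, GLM estimation, realistic cortical geometry and geodesic
distances, head motion, repeated presentations and trial averaging,
behavioral tasks — bounds what passing tests show: they validate the
statistical machinery (identification, conjunction, TFCE, FWER control)
under the linear-Gaussian assumptions, not robustness to real fMRI
artifacts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full default study
(6 subjects, 900 vertices) for planted-region recovery with searchlight
k = 25, 20 per-subject shuffles and 200 group permutations; family-wise
error calibration uses a 144-vertex global-null study (4 subjects, 20
shuffles, 200 unique permutations, 20 repetitions, α = 0.2);
directional effects average 20–40 single-subject studies at 100–144
vertices. These sizes were chosen as the smallest that keep the planted
effects and Monte-Carlo error bars well separated; all of them are
config, not constants.

## Known limitations

- Neighborhoods use Euclidean coordinate distance, not geodesic mesh
  distance; on a convoluted real surface these differ.
- The per-subject null shares one pairing permutation across vertices
  per shuffle — faithful to the fixed-decoder reading, but it means the
  number of independent per-subject nulls is `n_per_subject_nulls`, not
  vertices x shuffles.
- The literal-proportion p-value can be exactly zero; use the
  `add_one` method when calibrated nonzero p-values are needed.
- `build_neighborhoods` materializes the full distance matrix (O(n²));
  fine at desk scale, not at 160k-vertex scale.
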