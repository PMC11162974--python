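# Methods

## Model

Every pixel spectrum is modeled as a convex combination of a small set of
pure endmember spectra plus additive sensor noise (the linear mixing model).
For seed trays the endmembers are one or more seed-coat spectra, a hilum
spectrum, the backing cloth and shadow. The assumptions that matter:

- **Linearity.** No multiple scattering between seeds; adequate for matte
  seed coats at close range, wrong for specular highlights.
- **Spatial coherence.** Noise is estimated from horizontal/vertical pixel
  differences, which assumes the *signal* varies slowly between neighbouring
  pixels. Cubes whose composition changes pixel-to-pixel (no spatial
  structure) will leak signal into the noise estimate and degrade both the
  MNF rotation and the source-count test.
- **Non-negative, sum-to-one abundances.** The default solver is fully
  constrained least squares (FCLS) via the classic augmented-row NNLS with a
  heavy sum-to-one weight, renormalized so the simplex constraint holds
  exactly; `constraint="none"/"nonneg"` are available for diagnostics.

## Source counting (NWHFC)

The number of spectrally distinct sources is estimated by noise-whitening the
cube (Cholesky factor of the shift-difference noise covariance) and comparing
the sorted eigenvalues of the sample correlation matrix against those of the
covariance matrix: a source with non-zero mean energy inflates a correlation
eigenvalue above its covariance partner. Each pair is tested one-sided at a
false-alarm probability `pfa` (default 10⁻³).

The detector's variance is evaluated **under the null hypothesis**: after
whitening, an H0 eigenvalue pair sits at the unit noise floor, so the
difference has asymptotic variance 4/N (N = pixels). Evaluating the variance
at the observed eigenvalues instead — a common shortcut — makes the threshold
scale with the signal and removes all power at positions where both pair
members are signal-sized; in our validation that shortcut systematically
undercounted cubes with four or more sources, while the null-floor form
recovers K ∈ {2, 3, 5, 6} on 50/50 seeded mixtures at SNR 40 dB and reports
0 (zero-mean) or 1 (non-zero mean) on pure-noise cubes.

## Endmember extraction and consolidation

PPI projects MNF-reduced pixels onto random unit skewers (default 10,000,
processed in memory-capped blocks) and counts how often each pixel is a
projection extreme. Candidates above the 99th-percentile hit count are
consolidated by k-means into `p` groups; each group is represented by its
**highest-hit-count member** — a cluster centroid or nearest-to-centroid
pixel is dragged inward by partially mixed candidates (switching to the
purest member improved worst-case endmember angle across 30 seeded mixtures
from 0.078 to 0.025 rad). All stochastic steps take an explicit seed.

Endmembers pooled across extractions are merged by single-linkage over the
strict MSE graph (`0 < MSE < 5×10⁻⁵` by default, the cutoff used for seed
libraries); connected groups are averaged and returned largest-group first.
Identical duplicates (MSE = 0) merge trivially; the strict upper bound means
a pair sitting exactly at the cutoff stays separate.

## Spectral similarity

SID is computed on raw reflectance with natural logarithms, exactly as the
symmetric sum of the two directed divergences; this is *not* scale-invariant
unless `normalize=True` first divides each spectrum by its sum (the standard
probabilistic SID). NS3 combines Euclidean-RMS amplitude distance with the
SAM angle: `NS3 = sqrt(EuclidRMS² + (1 − cos SAM)²)`. Note the Euclidean term
here is the root *mean* square difference (divided by the number of bands),
so NS3 for the orthogonal pair `[1,0]`,`[0,1]` is `sqrt(1 + 1) = √2`.
Hierarchical clustering uses average linkage by default on the full pairwise
distance matrix; the cluster count is a user choice, not a model output.

## Segmentation

Pixels are associated with their most-abundant endmember. Endmember roles can
be set explicitly or by the `auto` heuristic: an endmember is
foreground-like when its association mask forms compact blobs (mean
isoperimetric compactness of its components) — the score is zeroed when the
mask covers more than half the frame or runs along more than 10% of the frame
border, because seeds are imaged away from the edge while background always
reaches it.

The binarization pipeline follows grayscale → Sobel gradient → Otsu →
3×3 opening, applied to the foreground-masked grayscale lifted onto a unit
pedestal: the Otsu threshold then separates abundance evidence rather than
coat brightness (a black seed coat is darker than a lit cloth background and
would otherwise fall below the threshold). The Sobel magnitude is divided by
8 before subtraction — a straight unit step drives the 3×3 kernel to ≈4, so
this suppresses the foreground/background pedestal edge by about half its
height while leaving interior coat/hilum contrast (steps ≪ 1) intact.
Components are filtered to [0.5, 1.5]× the median area; no watershed is used
(non-overlapping trays don't need it, and striped or multi-colour coats are
out of scope). The coat/hilum split assigns each foreground-dominant pixel
its argmax foreground endmember (ties to the lower index); pixels matching
the region's modal endmember form the coat, the rest the hilum.

## Traits

Band trimming removes `floor(0.05·n)` bands per end by default (204 → 184);
the counts are overridable (`n_trim_start=10, n_trim_end=11` retains 183,
matching workflows that quote 183 bands, spanning ≈426–970 nm). The
first-derivative spectrum uses the printed two-band-gap form
`dR_i = (r_{i+2} − r_i)/Δλ` — divisor Δλ, not the conventional 2Δλ
(`central=True` gives the conventional value); logR defaults to base 10.
UPOV shape rules as published leave a gap (W/L between 0.89 and 0.90, T/W
between 0.84 and 0.85) and state "spherical-flattened" with T/W > 0.84, which
contradicts the flattened definition (T/W ≤ 0.84); the implementation closes
the gaps with ≤/> boundaries and treats the flattened rule as ≤ — the four
classes exactly partition the positive quadrant (property-tested). Index
wavelengths use nearest-band lookup (≈ exact at 2.9 nm sampling). Automatic
coat-colour naming by nearest RGB centroid is a convenience; the reference
workflow is majority vote of human raters, and the default centroid table is
synthetic except for the two published brown-class means.

## Classification

LDA standardizes predictors on training statistics, pools the within-class
covariance and adds a ridge of `regularization · trace/d` (default 10⁻⁶) so
the fit stays defined when predictors outnumber per-class samples.
Per-predictor importance is the largest absolute coefficient over all
pairwise discriminant directions. Accuracy is micro (trace/total); precision,
recall and F1 are macro one-vs-rest by default, with a `binary` mode for
two-class positive-class reporting. An optional random-subspace LDA ensemble
(B=30 members, d=⌈√p⌉ predictors, majority vote) is provided. OSP band
selection greedily grows the band set from the maximal-variance band, each
step adding the band whose residual after projection onto the selected span
is largest, computed on a seeded 10% pixel subsample; residual norms are
non-increasing by construction and selection stops early when the span is
exhausted.

## Synthetic data: what it emulates and what it does not

The scene generator draws smooth endmember spectra (2–4 Gaussian bumps on a
linear baseline; pigmented coats add a red-edge sigmoid at 690–740 nm; shadow
spectra are capped at 0.15 reflectance; rejection sampling keeps pairwise SAM
≥ 0.1 rad). Scenes place non-overlapping ellipses (semi-axes 8.5–10 px,
aspect 0.8–0.95 — within-accession seeds are uniform, area CV ≈ 10%) with an
interior hilum patch (8% of seed area), 50/50 coat-background mixing along
each rim, a left-to-right shadow gradient up to 0.4 over the cloth, and
additive Gaussian noise (default sd 0.01–0.02 reflectance) clipped at zero.
Mixture cubes for unmixing tests use softmax-normalized smooth random fields
with geometrically spread contrasts, so the K sources carry well-separated
energies, plus a forced pure patch per endmember.

Not emulated: specular highlights, coat texture (stripes, mottling), seed
overlap, physically based shading, wavelength-dependent sensor response.
Passing tests therefore demonstrate the algorithms' correctness under the
linear mixing model with well-separated sources — not performance on
collections whose coats are textured or whose seeds touch.

## Problem sizes and numerical choices

Validation runs use 64×64×50 mixture cubes (20 replicates, 3–6 sources),
160–220 px scenes with 12–32 seeds, and 10-accession × 20-seed cohorts with
60-band spectra — sizes chosen so the full suite completes in a couple of
minutes while every property is exercised at realistic conditions; the code
paths are identical at camera resolution (PPI projections are chunked to a
~160 MB buffer). Reconstruction on synthetic data is scored against the
noise-free scene, which ground truth makes available; on real cubes the
reference is the acquired cube itself and the rRMSE floor is the sensor
noise. Degenerate inputs are defined errors: constant cubes (MNF, Otsu,
rRMSE), zero-norm spectra (SAM), non-positive values (SID, logR), empty
masks, rank-deficient endmember matrices. Ties: coat/hilum argmax breaks to
the lower endmember index; NWHFC regularizes the noise covariance by
10⁻¹²·trace/n before factorization.

## Known limitations

- NWHFC undercounts sources that occupy very few pixels (a hilum covering
  ~1% of a scene): rare sources contribute little eigen-energy. The pipeline
  accepts an explicit endmember count for such scenes.
- SID on raw (unnormalized) spectra mixes brightness into the divergence;
  use `normalize=True` for pure shape comparison.
- The auto role heuristic presumes seeds are imaged away from the frame
  border; crop ROIs accordingly.
- FCLS renormalization trades a strictly optimal least-squares solution for
  an exact simplex constraint; the discrepancy is ≪ the noise level in all
  tested conditions.
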