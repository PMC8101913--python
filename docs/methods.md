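# Methods

## Measurement model

The package quantifies how thoroughly a two-colour gum bolus has been
kneaded, from a photograph of the flattened specimen. Two readouts are
computed on the segmented specimen region only:

**Texture.** The image is converted to grey (Rec. 601 luma,
0.299 R + 0.587 G + 0.114 B — the default of the common conversion tools;
configurable), quantized to G grey levels by `floor(value · G)` clamped to
G − 1, and the grey-level co-occurrence matrix (GLCM) is accumulated over
all pixel pairs at the configured offset **with both pixels inside the
mask** — the background never contributes. In symmetric mode (default)
each ordered pair is counted in both directions, making the matrix exactly
symmetric. Uniformity, contrast, homogeneity and entropy are computed per
angle and averaged over the configured angles (averaging features, not
matrices, so a single-angle run equals the individual feature functions).

Defaults: G = 256, distance 1, angle 0°, symmetric, entropy in bits.
These mirror the widely used texture-plugin conventions; with coarser
quantization the floor of uniformity, 1/G², could not fall in the
10⁻³ range that chewed-gum images produce. Homogeneity uses the inverse
difference moment 1/(1+(i−j)²); 1/(1+|i−j|) is available as a config
option. Grey-level pair counting is validated against a literal pair loop
and against `skimage.feature.graycomatrix` on full rectangular masks
(scikit-image cannot restrict counting to an arbitrary mask, which is why
the masked accumulation is implemented here).

**Colour mixing.** RGB is converted to HSI with the geometric (arccos)
hue: I = (R+G+B)/3, S = 1 − min/I, and hue the polar angle of the pixel's
projection onto the plane orthogonal to the grey axis, reflected into
(π, 2π) when B > G. Pixels with saturation at or below a threshold
(default 0.05 at conversion; the variance-of-hue step uses the
segmentation threshold 0.15 so one knob controls chromaticity) are flagged
as having undefined hue. The variance of hue (VOH) is by default the
circular variance 1 − R̄ over the defined in-mask hues — hue is an angle,
so linear variance would depend on where the 0/2π cut falls. VOH is 0 iff
all hues coincide, 1 when the mean hue vector vanishes, and an unmixed
equal-area two-colour specimen with hue gap Δ scores exactly 1 − cos(Δ/2).
A linear mode (sample variance of hue as a fraction of a turn) is provided
for comparability with tools that treat hue as a plain number; published
VOH scales in the 0.05–0.13 range are consistent with more than one
estimator convention, so neither mode claims numeric equivalence to any
specific closed-source tool.

**Segmentation** thresholds HSI saturation (default 0.15), keeps the
largest connected candidate component (4-connectivity by default, to avoid
diagonal leakage through JPEG artefacts) and fills interior holes. It
fails explicitly if no component reaches a minimum area fraction (default
5% of the image). An optional border erosion radius (default 0) trims
specimen edges before feature extraction. The procedure is deterministic
and monotone in the threshold at the candidate-set level.

## Specimen simulator

No public image set exists for this test, so validation rests on a seeded
simulator with known ground truth.

*Unchewed specimen*: a rounded-rectangle slab (30 × 18 mm, corner radius
2 mm, rendered at `px_per_mm`) of two equal colour layers joined
lengthwise on a white background. The layer colours are chosen with three
exact properties:

1. hues exactly 120° (green) and 330° (pink), 150° apart;
2. equal chroma radius (distance from the grey axis), so any convex blend
   of the two keeps the circular mean hue on their bisector — mixing
   tightens the hue distribution without rotating it;
3. equal Rec. 601 luma, so grey-level texture reflects surface relief
   rather than a brightness difference between the colours.

The surface is given a multiplicative intensity mottle (smooth Gaussian
field, sd 0.06, correlation length 1 mm), standing in for the embossed,
granular surface of real gum. Because the mottle scales all three channels
equally it perturbs brightness but leaves hue and saturation exactly
unchanged: the unchewed specimen contains exactly two hues and its VOH
equals the closed form 1 − cos(75°) ≈ 0.741.

*Chewing*: each cycle performs 4 feathered swaps of random in-specimen
patches (35% of the short axis; Hann-windowed alpha blending, which
conserves colour mass exactly and never touches the background) followed
by one masked Gaussian diffusion pass (σ = 0.15 mm, normalized
convolution confined to the mask). Sensor noise (sd 0.005 per channel,
clipped) is added once at the end. Diffusion monotonically erodes both the
mottle and the colour boundary, so in expectation contrast falls,
homogeneity and uniformity rise, entropy and VOH fall as cycles increase —
the directions the clinical readouts are designed to detect. With the
defaults, 20 cycles reduce the specimen to a nearly single-colour bolus.

Cycle counts are "effective kneading strokes": the clinical protocol
prescribes 20 chew cycles, and a subject's efficiency determines how many
of them actually mix. The bundled improving profile draws cycles per
specimen as N(µ_t + a_s, σ_t) (rounded, floored at 0) with visit means
4 / 12 / 20 at T0 / T1 / T2, per-visit sd 2–4, and a per-subject ability
a_s ~ N(0, 2) shared across visits; the null profile uses mean 8 at every
visit. The two photographed sides of a specimen are two independent mixing
realizations of the same cycle count; their true correlation structure in
real chewing is unknown, so none is imposed beyond the shared count.

What the simulator does **not** emulate: specular gloss and saliva,
occlusal imprint morphology, perspective and lighting variation, camera
colour response, and subtractive pigment mixing (blending is linear in
RGB). Passing tests therefore establish that the pipeline recovers known
mixing structure under controlled conditions, not that any particular
absolute feature value will be reproduced on clinical photographs —
absolute GLCM values also depend on quantization, offset and angle
conventions that vary between tools.

## Statistics

Descriptives are mean, sample SD (n−1), median, and IQR (Q3−Q1 with
linear-interpolation quantiles). The tests are rank-based throughout:

* **Friedman** across follow-up times on complete subject × time blocks,
  mid-ranks for ties, tie-corrected chi-square with k−1 df. Fully tied
  blocks carry no information; if all blocks are tied the statistic is 0
  and p = 1 (the chi-square form is 0/0 there). An exact mode enumerates
  the permutation null by dynamic programming over column rank-sum vectors
  (feasible for k ≤ 4, n ≤ 30); the chi-square approximation can differ
  from the exact p by ~0.05–0.10 at n ≤ 24, so the exact mode is the
  reference for small samples, while the default chi-square matches the
  convention of standard statistics packages.
* **Wilcoxon signed-rank** between time pairs on per-subject differences:
  zeros dropped, mid-ranks on |d|. For n ≤ 25 the two-sided p is exact —
  the full sign-flip distribution of W⁺ is built by convolution over
  doubled mid-ranks (integers), which handles ties exactly, something
  off-the-shelf exact routines do not; above that, a normal approximation
  with tie-corrected variance Σr²/4 and no continuity correction.
* **Mann–Whitney U** between the upper and lower specimen side at each
  time, delegated to `scipy.stats.mannwhitneyu`: exact for small tie-free
  samples, otherwise the tie-corrected normal approximation. The sides
  come from the same specimen, so an unpaired test is conservative in
  spirit; it is kept because it matches the convention of the clinical
  analyses this mirrors.

Replicate handling: a subject's replicate samples enter descriptives as
separate rows but are averaged per subject/time/side for the tests, which
need one value per subject; `replicate_policy="rows"` keeps them separate.
No multiple-testing correction is applied by default, matching the
per-comparison p < 0.05 convention of the mirrored analyses.

All exact-mode p-values are tested against brute-force enumeration
(2ⁿ sign patterns, all group assignments, all within-block orderings), and
the full pipeline's type-I error under the null simulator profile is
checked to sit near the nominal 0.05.

## Numerical and design notes

* Pixel values are floats in [0, 1] regardless of source bit depth; grey
  levels enter only at explicit quantization.
* `quantize` maps 1.0 into the top bin (clamp, not floor overflow).
* GLCM probabilities normalize by the realized pair count, so thin or
  heavily masked regions remain proper distributions; an offset with no
  valid pair raises rather than returning zeros.
* The simulator's diffusion scale is specified in mm and converted to
  pixels at rendering time, so mixing dynamics are resolution-independent;
  simulations in the test suite run at 2–4 px/mm, the default for
  generated studies is 10 px/mm.
* Determinism: every stochastic component takes a seed;
  `numpy.random.SeedSequence` spawning derives independent per-subject and
  per-image streams, and identical seeds give byte-identical manifests and
  feature CSVs.
* Problem sizes in the validation scripts (18-subject studies at reduced
  resolution, 5 × 20 mixing sweeps, 100-replicate null calibration) were
  chosen to exercise the full design at interactive runtimes.

## Known limitations

* Absolute feature values are convention-dependent (grey weights, G,
  offset, angle, log base); only within-study comparisons are meaningful.
* The HSI hue is undefined on achromatic pixels; specimens photographed
  over chromatic backgrounds, or gum colours with saturation below the
  threshold, will fail segmentation or hue collection by design.
* The Mann–Whitney side comparison treats paired-looking data as
  unpaired (see above).
* The simulator's mixing model is phenomenological: monotone and
  mass-conserving, but not a mechanical model of mastication.
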