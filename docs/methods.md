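# Methods

`agesal` studies how the spatial distribution of gaze over natural scenes
differs between observer age groups, and how a bottom-up saliency model can
be adapted to a group. This note describes the models, the measurement
conventions, the synthetic-cohort generator, and the numerical and design
choices a user should know before trusting (or extending) the results.

## Gaze representation

Fixations are `(x, y)` pixel coordinates, 0-based, x = column, y = row,
origin top-left, valid on the half-open raster `[0, w) × [0, h)`.
Fractional coordinates are assigned to pixels by rounding half away from
zero. The **human fixation map** of a group on one image is the binary
raster of all fixated pixels, pooled over the group's observers (repeat
fixations of a pixel collapse). The **human saliency map** is that raster
convolved with an isotropic Gaussian and min-max normalized to [0, 1].

The smoothing bandwidth defaults to `25 · width / 1024` pixels, roughly one
degree of visual angle for a 1024-px display viewed at 60 cm; it is a free
parameter everywhere. The blur is zero-padded, so fixations within about
four sigma of a border lose mass; the mass-conservation property holds only
for interior fixations, which is the case tested.

## Analysis metrics

**Explorativeness.** For a min-max normalized saliency map `U` with `L`
pixels and a `B = 256`-bin intensity histogram `h(l)`,

    H(U) = Σ_{l : h(l)>0} h(l) · log(L / h(l))        (natural log)

which equals `L` times the Shannon entropy of the normalized histogram.
Scattered gaze occupies many intensity levels and scores high; gaze
concentrated on few hotspots scores low. A constant map scores 0 and is
flagged degenerate. `B` and the log base are configurable; entropy values
are therefore comparable only within a fixed `(B, base, L)` convention.

**Agreement.** A source saliency map is thresholded at T coverage levels of
its most salient area (default 5%, 10%, …, 100%; ties at the cut broken in
raster order). Each mask yields one ROC point against a target fixation
map: TPR = fixated pixels inside the mask / all fixated pixels, and FPR =
non-fixated pixels inside the mask / all non-fixated pixels. The curve is
anchored at (0,0) and (1,1) and integrated by the trapezoid rule. With one
level per pixel count this converges to the Mann–Whitney rank AUC (tested
to 0.02). The group-level agreement matrix averages, over images, the AUC
of the source group's *human saliency map* predicting the target group's
*pooled* fixation pixels; pooling over observers (rather than per-observer
scoring) follows the map-construction convention and is the cheaper,
lower-variance choice.

**Center bias.** The center map of a group is the pixel-wise mean of its
per-image saliency maps, min-max normalized. Two statistics are reported:
the Euclidean distance from the map's intensity centroid to the geometric
center `((w−1)/2, (h−1)/2)` (small = centrally biased), and the AUC of the
center map itself used as a fixation predictor. The centroid distance is
only informative when the underlying scene-driven attention is not itself
centered on average: near-uniform gaze also has a central centroid. Under
the default benchmark (few images, uniformly placed scene content) the
distance is weakly identified and the AUC measure is the one whose group
ordering is asserted; the distance ordering is exercised in the dedicated
center-bias recovery experiment, where only the central-mixture weight
varies.

## Multi-scale center-surround model ("S")

A 9-level dyadic Gaussian pyramid (smooth with σ = 1, decimate by 2) is
built for intensity `(r+g+b)/3`, four broadly-tuned color channels and
Gabor orientation energy. Color channels are computed from `r, g, b`
normalized by intensity where intensity exceeds 10% of its image maximum
(zero elsewhere): `R = r−(g+b)/2`, `G = g−(r+b)/2`, `B = b−(r+g)/2`,
`Y = (r+g)/2−|r−g|/2−b`, rectified at zero. Orientation uses an even/odd
Gabor quadrature pair (frequency 0.25 cycles/px at every level, σ =
0.56/frequency, DC-free even kernel) at 0°, 45°, 90°, 135°, where θ is the
bar orientation (90° = vertical).

Center-surround feature maps are `|center − upsampled(surround)|` for
center levels c ∈ {2,3,4} and surrounds c+3, c+4 — six maps per channel,
indexed i = 1 (finest pair, (2,3)) to 6 (coarsest, (4,4)); color maps use
the double-opponent form `|(R(c)−G(c)) − (G(s)−R(s))|` and the B/Y
analogue. Each map's borders are linearly attenuated over a 10% ramp:
without this, convolution artifacts at coarse levels form spurious unique
peaks that the normalization operator then promotes.

The normalization operator `N` scales a map to [0,1] and multiplies it by
`(M − m̄)²`, where M is the global maximum and m̄ the mean of the other
local maxima (3×3 neighborhood, above 0.05). One dominant peak keeps full
weight; many comparable peaks drive the factor toward zero. Maps whose raw
dynamic range is below 1e-9 are treated as silent and zeroed — min-max
scaling would otherwise amplify float-rounding noise of an inactive channel
(e.g. B−Y on a red/green display) to full scale.

Conspicuity maps sum the normalized feature maps over scales i = s..6 at
the common raster of pyramid level 4, and the final map is
`S = (N(Ī) + N(C̄) + N(Ō)) / 3`, upsampled bilinearly to image resolution
and min-max normalized. The subset start `s` is the age-adaptation knob:
s = 1 uses all levels of detail, s = 6 only the coarsest.
`scan_scale_subsets` evaluates the mean agreement AUC for every s and
reports the argmax `s*` (first on ties).

## Learned combination ("S+I+C")

Per pixel, the feature vector is the three conspicuity planes (Ī, C̄, Ō)
upsampled to image resolution and min-max normalized each. For each
training image, P = 10 strongly salient and P strongly non-salient pixels
are picked greedily from the group's human saliency map in value order
under a pairwise separation constraint (default: the smoothing sigma;
halved with a warning if P samples do not fit). A linear max-margin
classifier (L2-regularized hinge loss, C = 1, liblinear, fixed random
state) fit on the pooled samples gives `(w_g, b_g)`; the predicted map is
`w_g·X + b_g`, min-max normalized. More than 10 samples per class mostly
adds redundant near-duplicate pixels from the same peaks. The score is used
as a graded map — AUC evaluation needs a ranking, not a binary label.

## Center weighting

`C(i) = 1 − d(c, p_i)/D` falls linearly from 1 at the geometric center to 0
at the farthest corner. A group's strength `w_k ∈ [0, 1]` enters as the
convex blend `out = (1 − w_k)·map + w_k·C`, re-normalized. The blend —
rather than multiplicative modulation `map·(1 − w_k + w_k·C)` — is a
deliberate choice: under the multiplicative form full strength never ranks
central background above strong off-center peaks, so training AUC is
monotone in `w_k` for any moderately central cohort and a fitted strength
saturates at the boundary, making groups indistinguishable. The convex
blend over-centers when pushed too far, giving an interior AUC optimum that
tracks the cohort's true central tendency (and matches the additive
learned-center-feature convention in the saliency literature). `w_k` can be
set per group (defaults 0.6 / 0.5 / 0.35 / 0.3 youngest→adult, ordering
only), or fitted by a grid search over {0, 0.1, …, 1} maximizing training
agreement AUC.

## Patch-dissimilarity model ("P")

The image is tiled into non-overlapping t×t patches, t ∈ {64, 32, 16, 8}
(scale index 1 = 64 px, coarsest), trailing remainders cropped. Each patch
vector concatenates the flattened CIELAB planes and the horizontal and
vertical intensity gradients — 5t² values (the per-channel flattening is
the only reading under which the patch content is fully used). Vectors are
centered per dimension and reduced by PCA to the smallest d whose
eigenvalue share reaches 95% (exact thin-SVD; centering is required or the
first component confounds the mean with variance). Patch saliency is

    S(R_i) = ω(i) · Σ_{j≠i} ‖x_i − x_j‖₁ / (1 + dist(p_i, p_j))

with patch-center distances normalized by the image diagonal (so the
denominator is scale-free), neighbours defaulting to all patches
(configurable K-nearest), and ω(i) = 1 − w_k·d(c, p_i)/D. Scores are
min-max normalized, painted back on the tiling, and Gaussian-smoothed with
σ = t/2 of the *finest* size used. Multi-size maps are averaged after
per-size normalization and re-normalized. A vectorized implementation is
verified against a literal double loop to 1e-9.

## Synthetic cohorts

The generator stands in for non-public eye-tracking data. Per group it
exposes three orthogonal knobs:

- `tau` (exploration temperature): fixations are sampled i.i.d. from the
  attention density raised to 1/τ. Low τ concentrates gaze on the
  density's peaks (child-like), high τ spreads it (adult-like). τ ≥ ~1 on
  the diffuse conspicuity densities degenerates toward uniform sampling,
  which no free-viewing cohort shows and which confounds both the entropy
  and the centroid statistics — default profiles stay below 1.
- `lambda_cb`: weight of a central Gaussian mixture component
  (σ = width/6).
- `source_mode`: the attention density — full conspicuity (s = 1), coarse
  conspicuity (a true subset start `s_true`), an explicit map, or uniform.

Default cohort: 20 observers × 30 fixations per image per group, profiles
("4y", τ=0.35, λ=0.55), ("6y", 0.5, 0.45), ("8y", 0.7, 0.32),
("adult", 0.85, 0.25). Everything regenerates bit-identically from
(profiles, stimuli, seed); per-observer streams are keyed by seed, group
label, image id and observer index.

Stimuli: pop-out bar arrays (one bar odd in color or orientation, ±2 px
jitter, 1 px antialiasing; the color singleton is saturated red among
*muted* green — with equally saturated distractors the R−G opponent channel
responds symmetrically to target and distractors and no model of this
family can find the singleton), and layered scenes mixing broad colored
Gaussian blobs (coarse structure) with small high-contrast crosses (fine
structure), used to separate coarse-scale from fine-scale attention.

What the generator does *not* emulate: saccade dynamics and temporal order,
fixation durations, oculomotor noise, top-down/semantic attraction, and
photographer bias in scene composition. Passing the recovery experiments
shows the estimators detect the constructs they target under i.i.d.
location sampling; it does not certify performance on real developmental
eye-tracking data.

## Problem sizes and numerics

Synthetic stimuli default to 256×256 (the smallest size at which the
9-level pyramid stays non-degenerate; smaller inputs are upscaled with a
warning). The benchmark uses 4 scenes; the scale-recovery experiments use
5 scenes × 10 seeds per condition; pop-out uses 20 displays per feature.
Tie-breaks are deterministic (raster order) everywhere; training fixes the
liblinear random state; the full benchmark is byte-reproducible from its
seed. Degenerate inputs (constant maps, zero-variance patch sets) are
flagged rather than raised wherever a neutral result exists.

## Known limitations

- AUC comparisons across groups inherit the usual center-bias sensitivity
  of non-shuffled AUC; shuffled-AUC variants are out of scope.
- The centroid-distance center-bias statistic is weakly identified on small
  uniformly-composed stimulus sets (see above).
- Entropy values depend on the histogram convention and image size; only
  within-convention comparisons are meaningful.
- The learned combination uses three global features (Ī, C̄, Ō); it cannot
  express spatially varying feature preferences.
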