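# Methods

## The screening model

The package treats laryngopharyngeal-cancer screening as semantic
segmentation followed by two thresholded decision layers.

**Segmentation.** A fixed-depth U-Net: four encoder blocks (two 3×3
convolutions + ReLU, then 2×2 max-pool stride 2), a two-convolution
bottleneck, four decoder blocks (2× nearest-neighbour upsampling + 3×3
convolution, concatenation with the same-level encoder features, two 3×3
convolutions + ReLU), and a 1×1 convolution to a single
cancer-vs-background logit per pixel. All 3×3 convolutions use *same*
padding, so the output mask has the input's spatial size and skip
connections concatenate without cropping — the natural choice when
masks and annotations are compared at full frame size. Channel widths
double per level from `base_channels`; input sides must be divisible by
16 (four pooling halvings). Nearest-upsample + convolution is used
instead of transposed convolution to avoid checkerboard artefacts; both
the upsampling style and everything below are configurable.

**Frame rule.** The predicted mask (probability > 0.5 by default) is
cleaned by morphological closing then opening with one 5×5 square
structuring element — closing fills interior voids, opening removes
speckle; the operators are standard, the order and element size are this
package's defaults since only the operator pair is canonical. Connected
components are labelled with 8-connectivity (diagonally touching tumour
pixels are one region; 4-connectivity is a flag). The frame is called
cancer iff the largest single component's area **strictly exceeds** the
area threshold: "exceeding" is read literally, and the boundary case
(area exactly 1024 px at threshold 32×32) is unit-tested as non-cancer.
Largest-component rather than summed area is the default because lesion
regions are anatomically connected; a summed mode exists behind a flag.
The 32×32 threshold is defined at the 512×512 working resolution;
masks at other sizes use the area scaled by the pixel-count ratio
(e.g. 64 px at 128×128).

**Video rule.** Per-frame calls are streamed in order; the clip is
diagnosed cancer iff the longest run of consecutive positive frames
spans strictly more than the duration threshold, with run duration
`run_length / fps`. A single negative frame breaks a run — the rule is
about *consecutive* evidence — but an optional `gap_tolerance` can merge
runs across short dropouts (default 0). The strict boundary (50 frames
at 25 fps vs a 2 s threshold → non-cancer; 51 frames → cancer) is
unit-tested.

**Threshold selection.** Both thresholds are chosen by exhaustive
evaluation of their candidate grids — areas {8², …, 256²} px and
durations {0.5, …, 3} s — on a verification split, maximising accuracy.
Ties break toward the *smaller* threshold: in a screening context the
more sensitive operating point is preferred. The selection metric and
tie-break are this package's choices; the full metric-vs-threshold table
is always returned so other operating points can be read off. As the
continuous ROC score the package uses the largest-component area (frame
level) and the longest-run duration (video level) — the natural
generalisations of the two discrete rules.

**Multimodal variants.** Three models are supported: a white-light-only
model (train/test on WLI), a narrow-band-only model (NBI), and the
pooled model trained on both modalities. The pooled single-network form
is the default. An optional modality-conditioned variant adds a learned
per-modality embedding, merged into the bottleneck through a linear
layer — a lightweight way to give the shared network an explicit
modality cue; neither variant is claimed to be canonical, and both are
selectable in `UNetSpec`.

## Statistics

* **Proportion CIs.** Clopper–Pearson in beta-quantile form
  (`Beta(α/2; k, n−k+1)` / `Beta(1−α/2; k+1, n−k)`, exact at k = 0 and
  k = n) is the default, verified in tests against brute-force inversion
  of the binomial tails and by a simulated coverage property. The Wald
  interval `p̂ ± z√(p̂(1−p̂)/n)` is also provided because screening
  literature frequently prints Wald-style intervals even when naming the
  exact method; reports take a `ci_method` flag.
* **ROC/AUC** by midrank Mann–Whitney (pairwise concordance with ½ for
  ties), which equals trapezoidal integration of the empirical curve —
  asserted exactly in tests, and cross-checked against scikit-learn.
* **IoU** defines empty∪empty as 1.0 (two raters agreeing there is no
  lesion agree); median IoU is computed over truth-positive images only,
  since segmentation quality is meaningful where a lesion exists.
* **McNemar** (two-sided): exact binomial (doubled smaller tail of
  Bin(b+c, ½), capped at 1) when b+c < 25, continuity-corrected χ²
  otherwise; b = c = 0 returns p = 1 by convention. Verified against
  exhaustive enumeration of all 2^(b+c) discordant outcomes and against
  statsmodels.
* **Cohen's κ** from the marginal-product chance agreement; undefined
  (None, not 0) when both raters are constant and identical.
* Metrics with zero denominators are reported as undefined, never as 0.
* Display rounding is 3 decimals; all internal values keep full
  precision.

## Synthetic data: what it emulates, what it does not

The generator emulates the *statistical structure* the pipeline depends
on, not endoscopic photorealism:

* **Frames** (default 128×128): smooth mucosa-like background with a
  radial vignette; WLI uses a broad pink/red palette, NBI a darker
  green/brown palette with curvilinear vessel-like strokes. A cancer
  frame carries one irregular star-convex lesion (radial perturbation of
  an ellipse — irregular like carcinoma margins yet exactly traceable to
  a polygon annotation) whose mask area falls in a configured range
  (default 600–3000 px ≈ 4–18 % of the frame, the scale of lesions that
  dominate a clinical frame). Both classes may carry small bright
  distractor blobs (8–60 px, specular-reflection-like) that are *not* in
  the truth mask.
* **Datasets**: patients with one pathology each (cancer / benign /
  normal; benign and normal are both diagnosis-negative), at most 10
  frames per patient, patient-disjoint train/verification/test splits,
  labelme-style polygon annotations traced from lesion contours, and a
  manifest CSV. Quality-control exclusions are a manifest flag supplied
  by the user (clinical QC is human review, not auto-detected).
* **Videos**: 8–25 s per lesion at 25 fps (typical clip lengths and
  hardware frame rate); a cancer clip shows its lesion in one contiguous
  run of ~60 % of frames by default, jittered in position and scale.
  Per-frame truth labels follow lesion visibility.

Because lesion areas sit far above distractor areas, thresholding the
true-mask largest component separates the classes perfectly — the
designed fixture for the threshold-selection tests. What passing tests
therefore show is that the *pipeline machinery* (segmentation training,
morphology, both decision rules, both grid selections, all statistics)
is correct and recoverable under controlled conditions; they do not show
clinical performance. Real laryngoscopy involves blur, specularity,
occlusion, camera motion and subtle early lesions that this generator
deliberately does not model.

## Problem sizes and numerical choices

* The bundled desk-scale experiment uses 300 frames (60 patients × 5) at
  128×128, `base_channels = 8`, 6 epochs of Adam (lr 1e-3, batch 8,
  pixel-wise BCE), horizontal-flip augmentation, model selection on the
  verification split, and 20 fresh clips for the video stage — a
  configuration chosen so the whole pipeline trains and evaluates in
  minutes on a single CPU while leaving a comfortable margin over the
  pass thresholds (it reaches held-out frame accuracy ≈ 1.0 and median
  IoU ≈ 0.9 on the synthetic test split).
* Training is float32 throughout; backprop was verified against float64
  central differences parameter-by-parameter.
* BCE uses the numerically stable log1p/softplus form; the optional Dice
  term (off by default) follows the soft-Dice gradient.
* All randomness flows through `numpy.random.Generator` seeded from the
  config: same config + seed ⇒ bit-identical frames, label sequences,
  and loss histories.
* Degenerate inputs: zero-area polygons rasterize to nothing (with a
  warning); polygons outside the raster are clipped, not errors;
  single-class verification sets, empty decision sequences, fps ≤ 0 and
  non-divisible-by-16 input sizes raise immediately.
* Video I/O writes uncompressed 24-bit RIFF/AVI (codec-free, readable by
  any player); other containers are delegated to imageio where a plugin
  is available. Missing frame-rate metadata is an error that names the
  explicit `fps` override.

## Known limitations

* The NumPy U-Net targets reduced CPU configurations; 512×512 training
  works but is slow without a GPU framework behind it.
* The synthetic generator's class separability is tunable but its
  default is easy by design; it cannot calibrate clinical operating
  points.
* MP4 reading requires an imageio ffmpeg plugin at runtime; the bundled
  reader handles uncompressed AVI only.
* The exact continuous score behind clinical ROC curves for this kind of
  three-stage system is not standardised; this package's choices
  (largest-component area, longest-run duration) are stated above.
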