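# Methods

This note records the models, conventions and design choices behind
`cyclereg`, in the spirit of a package reference manual: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

Given a 2-D cardiac CT slice, a TEE slice of the same anatomy, and labels
drawn in the CT domain, estimate the dense deformation relating the two
domains and propagate the labels into the TEE view. The obstacle is the
appearance gap: no intensity-based similarity aligns raw CT against raw
B-mode ultrasound reliably. The package's approach is
translate-then-register: map each modality into the other's appearance with
a cycle-consistent adversarial network, solve the two resulting mono-modal
registrations, and average the two fields.

## Coordinate and field conventions

* Arrays are row-major `(row, col)`, 0-based, pixel-centered; physical
  coordinate of index `(r, c)` is `origin + (r, c) * spacing` (mm).
* Deformation fields are **backward maps** sampled on the fixed grid with
  displacements in pixels of that grid: `output(p) = moving(p + u(p))`.
  Label propagation is then a single nearest-neighbour interpolation.
* Out-of-domain samples use edge-value extension: the TEE fan has hard
  zeros, and constant extension avoids ringing artifacts there.
* Fields serialize as 2-channel NIfTI; PNG inputs are assigned 1.0 mm/px,
  so downstream distances are then in pixel units.
* Resampling defaults to 0.45 mm isotropic, the mid-range of typical CT
  slice spacings; anti-aliasing (Gaussian prefilter at ratio/2) is applied
  when downsampling. The common crop/pad size default is 256×256.

## Synthetic phantom model

`PhantomParams` → `PhantomCase` is a pure function of its seed.

* **Anatomy.** An elliptical "heart" (myocardium, label 1) with 2–4
  elliptical chambers (labels 2+) carved into it, placed on an elliptical
  ring at half the heart axes with per-seed jitter. Geometry is rejected
  and regenerated (up to 10 perturbed attempts) if chambers overlap, break
  the myocardial ring, or any structure falls below 1 % of the pixels —
  closed boundaries keep HD95/ASD well defined.
* **CT render.** Per-label constant intensities (chambers contrast-bright,
  myocardium mid-gray), Gaussian blur (σ = 1 px), additive Gaussian noise
  (σ = 0.03 by default), clipped to [0, 1].
* **TEE render.** Fan-shaped field of view from a transducer at top-center
  (default aperture 75°); inside the fan, per-label echogenicity (chambers
  anechoic, myocardium echogenic) × exp(−attenuation·depth_mm) ×
  unit-mean Rayleigh speckle, then log compression
  `log(1+30·I)/log(31)` and min-max rescale over the fan; exactly 0
  outside. This is the standard B-mode amplitude model; the multiplicative
  Rayleigh speckle has coefficient of variation ≈ 0.52 before compression.
* **Noise streams.** Each render's noise realization is keyed on the seed
  *and* on a checksum of the anatomy being rendered. Rendering the same
  anatomy twice is bit-identical, but the CT-domain and TEE-domain renders
  of one case carry independent realizations — as in real acquisitions,
  where noise is not shared across modalities. (Sharing one realization
  would let registration lock onto the speckle pattern instead of the
  anatomy.)
* **Ground-truth deformation.** Gaussian-smoothed white noise
  (σ = 16 px) plus a random constant offset (half the displacement
  budget — emulating the global probe/scanner geometry difference), jointly
  rescaled so the peak magnitude equals `max_disp` exactly (default 8 px at
  256²). The finite-difference Jacobian determinant of `p + u(p)` must be
  positive at every pixel; otherwise the magnitude is halved (≤ 5 times).
  The TEE anatomy is the CT anatomy warped by this field with
  nearest-neighbour interpolation, so the correspondence is exact by
  construction.

The default `max_disp = 8 px` is large enough that direct cross-modality
registration visibly fails and small enough for Demons to recover.

What the phantom does **not** emulate: real cardiac geometry and texture,
shadowing and reverberation artifacts, probe-angle-dependent appearance,
cardiac motion, 3-D effects. Passing tests demonstrate the pipeline's
mechanics and the translate-then-register advantage under a controlled
appearance gap — not clinical performance.

## Adversarial translation

* **Generators** (7 conv-BatchNorm-ReLU stages, tanh output): encoder of 3
  stages with a single stride-2 downsampling, one residual stage, decoder
  with one nearest-neighbour ×2 upsampling, channels (32, 64, 64). A single
  down/up pair is used because the cycle reconstruction must reproduce
  fine speckle texture; a deeper bottleneck discards it and slows
  convergence markedly at the small training scales this package targets.
* **Discriminators** (5 stages): a shared 4-stage trunk (stride 2, 2, 2, 1)
  and two parallel 1-channel conv heads returning score maps — D₁ for
  real-vs-generated, D₂ for the modality. Scores are least-squares
  regressed to 1 (real/correct) and 0 (fake). D₂ is trained on real and
  generated images with equal weight; α (default 1.0, symmetric weighting)
  balances the two heads. λ_cyc defaults to the canonical 10.0.
* **Loss-form note.** As printed in the source formulation, all four
  expectations of the discriminative loss range over the target domain
  `y ~ P_Y`, which leaves the `G(x)` terms unbound. The implementation
  takes real terms over real target-domain samples and fake terms over
  translated source-domain samples — the only internally consistent
  reading; flagged here rather than silently resolved.
* **Training.** Alternating generator/discriminator Adam updates
  (lr 2·10⁻⁴, batch 2; β₁ = 0.5, β₂ = 0.9 — momentum settings chosen for
  short small-batch adversarial runs). No identity loss. Training state is
  float64 numpy; a fixed seed reproduces the loss history bit-exactly, and
  checkpoints (npz + json) round-trip bit-exactly. Inference uses running
  BatchNorm statistics, so `translate` is deterministic.
* **Scale.** The package's training fixture is 32×32 patches for a few
  hundred iterations — enough for the cycle loss to fall well below half
  its initial level and for translated histograms to move measurably
  toward the target modality (Bhattacharyya coefficient), which is what
  the tests assert. It is not a substitute for a full-scale training run.

## Registration

* **Affine (grid) stage.** Powell's derivative-free method over
  translation (mm), rotation, two log-scales and shear about the fixed
  image's center, coarse-to-fine over a 3-level pyramid; NCC metric for
  mono-modal (translated) pairs, mutual information (32-bin histogram) for
  the raw cross-modality baseline; `ftol = 1e-6`. On hitting the
  evaluation budget the best transform found is returned with a warning
  flag.
* **Demons (nongrid).** Per-pixel update
  `u += (f − m∘u)·∇f / (‖∇f‖² + (f − m∘u)²)` (the intensity-difference
  direction that decreases SSD), step capped at 2 px, field smoothed with a
  Gaussian of σ = 2 px every iteration, up to 100 iterations per pyramid
  level over 3 levels. Both images are prefiltered with a σ = 1 px
  Gaussian, which stabilizes the update on speckled inputs. Ten
  consecutive non-improving iterations trigger an early stop; the
  best-so-far field is kept, and the returned field is never worse (in
  SSD on the input images) than the initialization.
* **FFD / "Powell" (nongrid).** Cubic B-spline control lattice (default
  spacing 32 px); control displacements optimized by Powell on the chosen
  metric; the dense field is the direct B-spline series of the fitted
  coefficients, hence C²-smooth by construction.
* **Pipeline.** Both directions run affine-then-nongrid by default, the
  affine initializing the deformable stage. `field_1` registers TEE-like
  (moving) to TEE (fixed); `field_2` registers CT (moving) to CT-like
  (fixed). Because the TEE-like image carries CT morphology and the
  CT-like image carries TEE morphology, both fields map TEE-domain
  coordinates into the CT domain and can be averaged componentwise — the
  only typing under which the bidirectional average is well-defined.
* **Oracle translator.** For isolating registration behaviour from
  adversarial-training variance, the phantom's own renderers can stand in
  for a trained model: the "TEE-like" image is the TEE render of the CT
  anatomy, and vice versa. With zero planted deformation this makes the
  end-to-end flow exactly the identity, which the tests assert bit-wise.

## Evaluation metrics

* Dice ratio `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 (agreement
  convention), one empty mask 0.0.
* Boundaries are 4-connectivity inner boundaries (mask pixels with a
  4-neighbour outside; image-edge pixels count missing neighbours as
  outside), converted to physical mm.
* HD95 is the max over both directions of the 95th-percentile
  nearest-boundary distance; percentiles use linear interpolation on the
  sorted distances. ASD is the mean nearest-boundary distance over both
  boundary sets. Both are pinned explicitly because the percentile method
  and boundary definition change HD95 at the sub-millimetre level.
* Mean endpoint error (px) against the ground-truth field is reported for
  synthetic cases only.
* Reports carry explicit distance units (mm, or px for PNG inputs).

## Problem sizes used by the test and acceptance runs

Chosen so the full suite runs in about ten minutes on one CPU: metric
oracles on 64² masks (200 pairs); transform recovery on 256² phantoms
(20 seeds in the tests, 10 in the acceptance script); the OI-vs-GI
comparison on 10 seeded 256² cases; adversarial training on 32² patches
for 300 iterations; determinism and identity checks at 96–128².

## Known limitations

* 2-D only; no DICOM ingestion; no wrapping of external registration
  binaries; no GPU path.
* Demons is a local optimizer: it recovers smooth fields within its
  capture range (helped by the affine stage) but can fail under large
  shape differences — visible in the OI arm, where that failure is the
  expected outcome.
* The directional OI-vs-GI result on phantoms mirrors the qualitative
  claim of the translate-then-register approach; absolute metric values on
  clinical data are not reproducible here and are out of scope.
* The leave-one-out protocol of clinical evaluations is replaced by
  independent seeded cases, which phantom construction makes i.i.d.
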