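# Methods

## The experiment being modeled

A glass probe (tip radius ~25 µm) is inserted into a soft polyacrylamide
gel 13 µm away from the edge of an adherent cell (~125 µm diameter) that
expresses an ECFP/YPet calcium biosensor. A spring-mass mechanism vibrates
the probe (~140 Hz, ~70 µm tip excursion), deforming the gel locally; the
cell's calcium response is read out as the YPet/ECFP emission ratio, which
rises with calcium because FRET efficiency increases (acceptor emission up,
donor emission down). Substrate deformation is measured separately from
1 µm fluorescent beads embedded at the gel surface, imaged by a fast camera
with the probe still vs. displaced.

## Response pipeline

1. **Background**: the per-frame mean intensity over a cell-free ROI is
   subtracted from each channel; negative results are clipped at zero.
   Clipping (plus a donor floor, default 1 count) keeps ratios stable for
   dim pixels; both choices only matter outside the cell interior.
2. **Partition**: mask pixels are projected onto the unit vector from the
   probe to the mask centroid and the projected extent is cut into three
   equal intervals (*closer*/*middle*/*farther*). Ties at a cut go to the
   band nearer the probe. When the probe sits directly below the cell this
   reduces to three horizontal bands of equal height; the axis formulation
   makes the partition well defined for any probe placement.
3. **Region ratio**: a band's ratio is mean(acceptor)/mean(donor) over the
   band per frame (ratio of means). Pixel-wise ratio maps are also
   available for display; for a band with constant donor the two
   definitions coincide, and the classifier consumes the ratio-of-means
   version, which is robust to low-signal pixels.
4. **Quantification**: baseline = pre-stimulus mean of the band ratio
   (at least 3 pre-stimulus frames required); the stimulated increase is
   the baseline-normalized **peak** within a post-stimulus window (default
   60 s). Peak rather than plateau is used because the response is a
   transient; the window default comfortably contains the peak of the
   synthetic kinetics (rise 3 s, recovery 30 s) and is configurable.
5. **Classification** (rule order matters): *none* if no band's relative
   increase exceeds `threshold_none` = 0.10 — a cell with no band above
   threshold has nothing to localize, so this rule fires first using the
   maximum band delta; otherwise *global* if the farther-band increase is
   at least `global_fraction` = 0.5 of the closer-band increase (exact
   equality counts as global); otherwise *local*. All comparisons use
   relative (fractional) increases, consistent with the relative 10%
   threshold.

## Mechanics pipeline

Bead tracking is a two-pass predictor–corrector block matcher: beads are
detected as local maxima in the reference frame, matched by normalized
cross-correlation of a 15 px template over a 31 px search region, and
filtered by a neighborhood-consistency rule (displacement within 3 px of
the median of the 5 nearest matches). A displacement predictor is built
from those inliers, and every bead is re-matched in a tight search window
centered on its predicted position. Sub-pixel positions come from a
3-point parabolic fit on the spot **log-intensities** (exact for Gaussian
spots) with an intensity-weighted-centroid fallback for blended spots. The
refinement acts on the spot rather than the correlation surface because
near the probe the substrate strain reaches ~30–40%: the rigid-template
correlation peak is biased by differential motion inside the window, while
the spot center is not.

Scattered displacements are interpolated onto a regular grid (default
spacing 2 µm) by piecewise-linear interpolation — exact on affine fields,
which provides a clean oracle; nodes outside the convex hull are NaN and
propagate through the stencils. Strains use the 2-point/3-point finite
difference scheme; the total strain is E = √(E_x²+E_y²) with normal
components only (no shear or large-deformation terms).

**Noise floor.** Linear interpolation of scattered data amplifies
sub-pixel localization noise over short Delaunay edges. On image pairs with
zero true displacement and Poisson noise, individual bead errors are
~0.01–0.1 px, but the **maximum** node strain over a ~10⁴-node map can
reach ~0.1–0.4 through sliver triangles, while the median node strain is
~10⁻³. Strain maps should therefore be read at cell scale (the ~30–40%
peak is two orders above the floor), and summaries report the peak
displacement both from the gridded map and directly from the measured bead
displacements (`max_bead_displacement_um`), the latter being the better
estimator of a sharp peak.

## Statistics

Class counts per condition are multinomial; p̂_k = n_k/N with the marginal
binomial SD √(p̂_k(1−p̂_k)/N) — the standard closed form for one component of
a multinomial. Independence against the control uses the exact conditional
test (Freeman–Halton for 2×3, reducing to two-sided Fisher for 2×2): all
tables with the observed margins are enumerated and the probabilities of
tables as-or-less-probable than the observed one are summed, with a 1e-12
relative slack on the probability comparison so enumeration order and
platform rounding cannot flip a tie. Classes with zero counts in both rows
are dropped (with a warning) before testing; margins admitting a single
table give p = 1. Enumeration is exhaustive — at cohort scale (N of order
hundreds) a 2×3 margin class contains at most a few thousand tables — and
per-margin-class results are cached. Significance is flagged at p < 0.05;
no multiple-testing correction is applied.

## Synthetic data generator

The generator reproduces the **structure** of the experiment, not its
optics or gel physics:

- **Probe trace**: a(t) = A·exp(−t/τ)·sin(2πft), defaults f = 140 Hz,
  A = 70 µm (zero-to-peak; the printed amplitude is read as zero-to-peak,
  matching the sinusoid parameterization), 0.5 s at 10 kHz. The decay
  envelope (τ) models the triggered, collision-driven vibration and is off
  by default; per-period energy decays monotonically when it is on.
- **Substrate field**: u(r) = P·g(d)·ê with d the distance from the probe
  edge; g rises smoothly (sin²) from 0.5 at the edge to 1 at
  d = 13 µm and decays as exp(−(d−13)/30) beyond, giving P = 13.5 µm at
  the cell-proximal position and <2% of peak at the far cell edge
  (~138 µm). The direction ê defaults to the probe→cell axis: that is the
  dominant displacement direction at the cell position and yields the
  observed ~30–40% peak normal strain there (a fixed horizontal ê would
  put most of the gradient into the shear terms that E omits). The
  closed-form gradient is returned alongside the sampled field and serves
  as the strain oracle; the profile is C¹ except at the peak ring, so
  convergence checks are evaluated on the smooth exponential tail.
- **Bead images**: a seeded uniform point process (default 0.02 beads/µm²,
  dense enough that the ~4 µm-wide peak ring is always sampled), Gaussian
  spots (σ = 1 µm), displaced by the field at each bead's reference
  position; optional Poisson noise.
- **FRET movies**: the calcium signal is separable, c(x,t) = A(x)·k(t),
  with A(x) = a·exp(−s(x)/λ) (s = distance from the stimulation-proximal
  cell edge along the probe axis) and k a unit-peak rise/recovery kernel.
  Channels: donor ∝ 1/(1+c), acceptor ∝ baseline_ratio·(1+c), so the ratio
  tracks baseline_ratio·(1+c)² — only this monotone response matters
  downstream, no spectral physics is modeled. Class templates:
  global (a = 0.4, λ = ∞), local (a = 0.4, λ = 25 µm), none (a = 0.03,
  chosen so the realized ratio change (1.03)²−1 ≈ 6% stays below the 10%
  threshold). Poisson noise at gains giving per-pixel ratio CV ≈ 5%
  (donor ≈ 800 counts, background 100) — high enough that classification
  is non-trivial per pixel, low enough that band averaging recovers the
  class reliably.
- **Cohorts**: classes drawn multinomially with the cohort seed; each
  movie uses an independent child seed, so cohorts are bit-reproducible.

What passing tests show — and what they do not: the phantoms are single
disk cells with separable, monotone responses and ring-symmetric substrate
deformation. Success on them validates the pipeline's arithmetic, rule
conformance, determinism and statistical calibration; it does not certify
performance on real movies with motion, photobleaching, bleed-through,
irregular cell shapes, or non-separable calcium waves (bleaching and
bleed-through corrections are explicitly out of scope).

## Problem sizes and numerical choices

Default scenes are 96×96 px movies at 2 µm/px (30 frames, stimulus at
frame 10) and 192×192 px bead images at 1 µm/px; grids use 2 µm nodes. The
end-to-end validation cohort is 300 cells (100 per class) and is classified
with ≥95% accuracy at default noise (measured: 100%). Exact-test
enumeration is validated exhaustively against an integer-arithmetic oracle
for all 2×2 and 2×3 tables with N ≤ 30. Degenerate inputs fail loudly:
empty ROIs, probes inside the mask, masks with <3 px extent, <3 samples
for finite differences, collinear beads, and zero-count conditions all
raise typed errors naming the offending stage.

## Known limitations

- The substrate model is phenomenological (fixed direction, radial
  profile); no gel constitutive model, no traction reconstruction.
- E omits shear and large-deformation terms, so it underestimates total
  deformation where displacement varies perpendicular to itself.
- Block matching needs the displacement to fit the search window
  (default ±15 px); re-scale images or widen the search for larger motion.
- The strain-map noise floor described above makes single-node strain
  values unreliable; use footprint-scale summaries.
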