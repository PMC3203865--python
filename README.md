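# vibracal

Analysis pipeline for **subcellular mechanostimulation experiments**: a
vibrating glass probe is inserted into an elastic gel next to a cell that
expresses an ECFP/YPet (Cameleon-type) FRET calcium biosensor, and the
question is whether the evoked calcium rise spreads over the whole cell
(**global**), stays near the stimulation site (**local**), or never exceeds
threshold (**none**). The package is aimed at labs doing ratiometric FRET
imaging on deformable substrates who want a scriptable, testable version of
this analysis — including a synthetic-data generator that emulates the whole
experiment, so the pipeline can be validated end to end without microscopy
data.

## What it computes

**Response classification.** For each cell, the two emission channels are
background-corrected (mean over a cell-free ROI, subtracted per frame), the
cell mask is split into three bands of equal extent along the probe→centroid
axis (*closer*, *middle*, *farther* from the probe), and each band's
YPet/ECFP ratio R(t) = mean(YPet)/mean(ECFP) is tracked over time. With
baseline R₀ (pre-stimulus mean) and ΔR/R₀ the baseline-normalized peak
increase after stimulation:

- *none* if max over bands of ΔR/R₀ ≤ 0.10,
- *global* if (ΔR/R₀)_farther ≥ ½ · (ΔR/R₀)_closer,
- *local* otherwise.

**Substrate mechanics.** Fiducial beads at the gel surface are tracked
between a reference and a displaced frame (normalized cross-correlation
block matching with sub-pixel refinement), interpolated onto a grid, and
differentiated by finite differences (central 3-point stencils inside,
one-sided 2-point at the boundary) to give the normal strains
E_x = ∂u_x/∂x, E_y = ∂u_y/∂y and the total strain E = √(E_x² + E_y²).

**Cohort statistics.** Per-condition counts (n_g, n_l, n_n) of N cells are
treated as a multinomial draw: p̂_k = n_k/N with SD √(p̂_k(1−p̂_k)/N), and each
treatment is compared with the control by Fisher's exact test in the
Freeman–Halton extension for 2×3 tables (exhaustive enumeration of tables
with the observed margins; two-sided "as-or-less-probable" convention).

**Synthetic data.** `vibracal.synthetic` generates every input with known
ground truth: a damped-sinusoid probe trace (defaults 140 Hz, 70 µm), an
analytic substrate displacement field peaking at ~13.5 µm some 13 µm beyond
the probe edge and decaying exponentially, bead image pairs rendered from
it, and two-channel FRET movies of 125 µm disk-shaped cell phantoms with
global/local/none responses.

## Worked example

```bash
vibracal simulate --out demo --n-cells 9 --probs 0.34,0.33,0.33 --seed 5
vibracal analyze  --bundle demo --out demo_results
vibracal strain   --reference demo/beads_reference.tif \
                  --displaced demo/beads_displaced.tif --out demo_strain
```

`analyze` logs one line per cell with the rule that fired, e.g.

```
cell 2: local (delta_farther 0.0187 < 0.50 * delta_closer 0.3628)
cell 3: global (delta_farther 0.9568 >= 0.50 * delta_closer 0.9576)
cell 1: none (max delta 0.0633 <= threshold 0.10)
analyzed 9 cells -> demo_results
```

— the deltas are the per-band fractional ratio increases; here all nine
phantoms are recovered as their ground-truth class.
`demo_results/report.csv` then holds the per-condition proportion estimates
with SDs, and `strain` prints the deformation summary

```
max |u| = 13.26 µm, max strain = 0.741
```

i.e. the tracked beads recover the generator's 13.5 µm displacement peak to
within a few percent; the strain maximum sits next to the probe, while the
footprint-restricted summary (`summarize_field` with a cell footprint) puts
the peak strain a cell experiences at ~0.4. Counts tables from real
experiments can be tested with
`vibracal report --counts counts.csv --out report/ [--plot]`.

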