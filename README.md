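# synaptiq

Quantification pipeline for cortical synapse loss studies: volumetric
pre/post synaptic-puncta colocalization densities from multichannel
fluorescence stacks, field-level morphometry (cell densities, thresholded
signal areas, axonal line crossings, lesion/perilesion partition), and
template-matching detection of miniature postsynaptic currents — together
with synthetic-data generators that stand in for tissue and recordings and
carry full ground truth, so every stage is testable by parameter recovery.

It is aimed at quantitative neuropathology / slice-physiology groups who
need the numeric core of such a study (segmentation, pairing, densities,
mini detection, group statistics) as reproducible, tested code rather than
a chain of one-off macros.

## The quantities it computes

**Structural synapse density.** Each channel of a section series (confocal
z-stack, 150 nm steps, or array-tomography ribbon, 70 nm sections) is
binarised per section with a local threshold `I(x,y) > μ_w(x,y) + k·σ_w(x,y)`
(window *w*, per-channel parameters, identical across sections), in-plane
8-connected components are linked into 3D objects wherever footprints on
consecutive sections overlap, and objects not present in ≥ 2 consecutive
sections are removed as single-section artifacts. A structural synapse is a
presynaptic and a postsynaptic object whose centres lie within a set
distance *d* (1.0 µm for human material, 0.5 µm for mouse); pairing is
greedy one-to-one by ascending centre distance. Densities are reported as
synapses/mm³ over the analysed neuropil volume — a grid of 10 × 10 µm ROIs
avoiding an exclusion mask (cell bodies, vessels) — and aggregated
ROIs → stack → subject → group.

**Morphometry.** Cells/mm², thresholded signal area in µm² (optionally
excluding soma-sized components), distinct foreground runs crossing a
100 µm line as the axonal-density measure, and the lesion / perilesion
(Euclidean band of 150 µm from the lesion border) / outside partition.

**Miniature PSCs.** At every lag the trace is fit by least squares to
`a·w(t) + b`, with `w` a unit-peak triexponential kernel
`w(t) ∝ (1 − e^(−t/τ_r)) (m·e^(−t/τ_d1) + (1 − m)·e^(−t/τ_d2))`;
the detection criterion is `a / SD(residual)`, thresholded in the
conventional 4–7 range (default 5), with a 3 × baseline-SD amplitude
filter. Recordings failing QC (|holding current| > 200 pA, series
resistance > 30 MΩ, or > 20 % series-resistance change) are rejected.
Summaries: frequency, amplitude, inter-event intervals, total charge (pC).

## Worked example

```python
import synaptiq as sq

cfg = sq.SimImageConfig(seed=1)              # 512 px field, 14 z-planes,
series, truth = sq.simulate_puncta_stack(cfg)  # human-cortex puncta densities
params = sq.SegmentationParams()             # local mean + 2·SD, window 17 px
pre  = sq.persistence_filter(sq.extract_objects(series, "pre",  params))
post = sq.persistence_filter(sq.extract_objects(series, "post", params))
pairing = sq.pair_puncta(pre, post, max_dist_um=0.5)
grid = sq.make_neuropil_rois(series.field_extent_um, depth_um=series.depth_um)
dens = sq.compute_densities(pairing, pre, post, grid)
print(f"estimated {dens.synapse_density_per_mm3:.3g} vs true {truth.pair_density_per_mm3:.3g} synapses/mm^3")
```

prints

```
estimated 2.41e+08 vs true 2.59e+08 synapses/mm^3
```

i.e. the pipeline recovers the generated pair density of ~2.6e8 synapses/mm³
to within ~7 % on this stack (merging of nearby puncta biases the estimate
slightly down, chance pairing slightly up; see `docs/methods.md`).

The numbered drivers under `analysis/` run the same machinery as narrative
steps — `01` writes example datasets in the on-disk formats, `02` the
five-seed density-recovery table, `03` the morphometry checks, `04` the
mini-PSC detection scores, `05` a two-group end-to-end study with Welch's
t-test — each writing tidy CSV under `results/`.

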