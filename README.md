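# wellcount

Digital particle/cell counting on microwell-array micrographs.

A liquid sample is partitioned into thousands of micrometre-scale wells;
one micrograph is taken per panel of the array; each well is classified
as occupied or empty from its mean intensity; and Poisson statistics
convert the occupied fraction into a number density with a confidence
interval. Because the algorithm recognises the *wells* — circular
objects of fabrication-defined radius — and never the particles inside
them, irregularly shaped samples and aggregates pose no recognition
difficulty. The method targets inexpensive, point-of-care counting of
beads, bacteria, and eukaryotic cells across several orders of magnitude
in density, for anyone who has a microwell chip and a basic microscope
rather than a flow cytometer.

## The model

With particles loaded at random into wells of volume V (µL), per-well
counts are Poisson with mean λ = c·V, so a well is occupied with
probability p = 1 − e^(−λ). From k occupied wells out of n:

    p̂ = k/n,    λ̂ = −ln(1 − p̂),    ĉ = λ̂/V   [particles/µL]

The 95% CI is a Wilson score interval on p mapped endpoint-wise through
the same transform. k = n is saturation: λ is unidentifiable and a
`SaturationError` carrying the one-sided lower density bound is raised.

The image pipeline feeding (k, n): mean-kernel denoising → Canny +
circular Hough transform restricted to radii within ±1 µm of the
nominal well radius → least-squares fit of the known rows × cols
lattice, so every well gets a centre even where detection missed —
occupancy never changes the number of analysed wells → per-well mean
interior intensity → histogram-valley threshold (occupied wells are the
darker mode in bright-field, the brighter one in fluorescence).

A synthetic micrograph generator with exact ground truth (Poisson or
clumped loading, rims, noise, illumination tilt, missing wells) and a
design-space simulator (CI width vs well count; measurable density
range vs well volume) make the whole pipeline testable without
microscopy data. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 4-panel device loaded at 5 × 10⁴ particles/µL and count it
back:

```python
import wellcount as wc
from wellcount.model import MicrowellCounter

g = wc.ArrayGeometry(panels=4, pixel_scale_um_per_px=2.0)
panels = []
for i in range(g.panels):
    truth = wc.seed_particles(g, 5e4, rng_seed=10 + i)
    panels.append(wc.render_panel(g, truth, noise=wc.NoiseSpec(rng_seed=60 + i)))

res = MicrowellCounter(panels, g).fit()
print(res.summary())
```

```
Microwell digital count
==========================================================
Panels analysed                                          4
Panels dropped                                           0
Wells analysed (n)                                    3600
Occupied wells (k)                                    1178
Occupied fraction p^                                0.3272
Mean occupancy lambda^                              0.3963
Well volume [uL]                                 7.854e-06
----------------------------------------------------------
Number density [1/uL]                            5.046e+04
95% CI low [1/uL]                                4.763e+04
95% CI high [1/uL]                               5.343e+04
CI half-width [% of mean]                             5.75
==========================================================
Modality: brightfield; pooling: device; grid 30x30 per panel
```

1178 of 3600 wells came out occupied; −ln(1 − 0.3272)/7.854 × 10⁻⁶ µL
estimates 5.05 × 10⁴ particles/µL, within 1% of the seeded 5 × 10⁴ and
with the truth inside the 95% interval. The generator's ground truth
for these seeds has exactly 1178 occupied wells — classification is
error-free at default contrast and noise.

The same pipeline is scriptable from the shell:

```sh
wellcount synth --density 5e4 --seed 1 --out device/
wellcount count --out results/ device/panel_*.png
wellcount simulate --mode ci_vs_wells --density 5e4 --out sim/
```

Every command writes a `run_manifest.json` with the geometry, parameters
and seeds needed to reproduce it.

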