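# phagoflux

Quantification of fluorescent-reporter dynamics on phagosomes and
macropinosomes, with synthetic ground-truth benchmarks for every stage.

Phagosomes and macropinosomes mature by the sequential exchange of
signaling lipids on their membrane. Lipid biosensors — e.g. the
*Dictyostelium* protein SnxA, whose PX domain binds the low-abundance
lipid PI(3,5)P₂ produced by the kinase PIKfyve — report these
transitions as transient enrichment of a fluorescent fusion on the
compartment membrane. Turning such movies into numbers requires a chain
of mundane but error-prone steps: segmenting the engulfed particle,
tracking it across frames, measuring reporter intensity in a thin ring
over the membrane against the local cytosolic background, referencing
each trace to its pre-engulfment level, and summarizing cohorts of
events into timings, retention curves and significance tests. This
package implements that chain as a tested, reusable library, together
with the companion in-vitro quantifications (membrane-coated-bead
binding affinity, lipid-array selectivity, mass-photometry oligomer
analysis) and a synthetic-data module that generates every input with
known ground truth, so the whole pipeline can be validated by parameter
recovery.

## The measurements

**Ring-based fold-enrichment.** For a tracked particle with mask M, two
annuli are built by Euclidean distance from M: an inner ring (0.2 µm
gap, 0.35 µm thick) over the compartment membrane and an outer ring
(0.85 µm gap) sampling cytosol. The per-frame enrichment is the ratio
of ring means, referenced to 10 s before engulfment:

    F(t) = [I_in(t) / I_out(t)] / [I_in(t_ref) / I_out(t_ref)],  t_ref ≈ −10 s

The double ratio cancels detector gain and expression level exactly.

**Timings.** Arrival and departure are half-maximum crossings of F(t)
(half level `1 + (peak − 1)/2`, linear interpolation between frames);
dwell is their difference, right-censored at movie end. Binary
positive/negative scoring uses an explicit rule (≥1.5-fold for ≥2
frames) in place of by-eye calls, and retention curves report the
proportion of still-observed events positive per time bin.

**Binding affinity.** Probe intensity on membrane-coated bead
circumferences, titrated against probe concentration c, is fit with the
one-site saturation model `I(c) = NS + Bmax·c/(Kd + c)`; the apparent
Kd error is the SD of independent per-experiment fits.

**Mass photometry.** Event masses (calibrated from landing contrasts by
a linear fit to standards) are decomposed into Gaussian populations by
a seeded EM mixture fit with BIC-based choice of component count.

## Worked example

`examples/04_bead_affinity.py` renders bead titration images at the
full-length probe's preset affinity, detects the beads, measures ring
fluorescence and fits the saturation curve:

```
$ python examples/04_bead_affinity.py
beads measured:   720
apparent Kd:      187.3 ± 3.0 nM (truth 187.3 nM)
Bmax:             0.997  nonspecific: -0.000
per-experiment:   [183.9, 189.9, 188.0]
```

720 beads (3 experiments × 8 concentrations × 30 beads) recover the
ground-truth apparent Kd of 187.3 nM to within the SD of the three
per-experiment fits — the imaging, detection and measurement steps add
no detectable bias. The other examples cover phagosome trace timing
(`01`), pulse-chase scoring (`02`), retention under kinase inhibition
(`03`), mass-photometry mixtures (`05`) and lipid selectivity (`06`);
each prints the numbers it computes and what they mean.

A thin CLI wraps the same functions for shell use
(`phagoflux show-defaults`, `phagoflux simulate …`, `phagoflux
phagosome --config run.yaml`, `phagoflux fit-kd`, `phagoflux mass`,
`phagoflux selectivity`); every run writes a manifest with the package
version and a hash of its configuration.

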