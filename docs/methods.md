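# Methods

This note documents the models and procedures phagoflux implements, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Recruitment model

Reporter enrichment on a single compartment is modeled as a trapezoid
(`KineticProfile`): baseline 1.0 until `t_on`, linear rise to `e_max`
at `t_peak`, plateau to `t_plateau_end`, linear fall to baseline at
`t_off` (times in seconds after engulfment). Real traces are smooth,
but a piecewise-linear shape is the simplest one with well-defined
arrival, peak and departure, and its half-max crossing times have
closed forms ((t_on+t_peak)/2 and (t_plateau_end+t_off)/2) that anchor
the recovery tests.

Shipped presets (`PROFILE_PRESETS`) encode the observed behaviour of
the PI(3,5)P₂ reporter and of the kinase itself:

| preset | t_on | t_peak | t_plateau_end | t_off | encodes |
|---|---|---|---|---|---|
| snxa_phagosome | 90 | 150 | 1290 | 1350 | arrival (half-max) 2 min, dwell 20 min |
| snxa_macropinosome | 120 | 240 | 240 | 330 | peak 4 min, removal by 5–6 min |
| pikfyve_untreated | 60 | 90 | 180 | 240 | recruited within 60 s, released ~4 min |
| pikfyve_apilimod | 60 | 120 | 10⁹ | 10⁹+60 | inhibited kinase never departs |
| pikfyve_null | — | — | — | — | flat (e_max = 1) negative control |

The phagosomal preset's rise is placed so that its *half-max* crossing
— the package's arrival definition — is exactly 120 s; breakpoints
themselves are not directly observable. `e_max = 2.5` throughout is a
generator choice: source traces report fold change on an arbitrary
scale, so peak magnitudes are illustrative, not measured.

## Synthetic scenes

`generate_timelapse` renders engulfed particles as disks (default
radius 1.5 µm, matching ~3 µm yeast) on a uniform cytosolic background
(the whole frame is one cell unless a mask is given), with:

* a membrane shell 0.7 µm thick just outside the particle at
  `cytosol_mean × profile(t − t_engulfment)` — wide enough that the
  0.2–0.55 µm measurement ring always falls inside it even when the
  segmented mask is off by a pixel, while staying clear of the outer
  (background) ring at 0.85 µm;
* the vesicle lumen dimmed to 0.4× cytosol (cytosolic reporter is
  excluded from the lumen);
* a particle channel at fixed intensity, optionally brightening by 50%
  from 60 s post-engulfment as a stand-in for a pH-sensitive label;
* additive Gaussian noise with sd = 5% of the cytosol mean by default
  (optional Poisson shot noise), then quantization to uint16.

Defaults: 0.1 µm/px, 10 s frame interval, stationary particles drawn
on a jittered grid with enough spacing that membrane shells and
measurement rings never overlap. Engulfment frames are scattered over
the first frames so every event retains a pre-engulfment reference.
Scenes with overlapping particles or particles leaving the usable area
are rejected rather than rendered ambiguously.

Not emulated: 3-D/Z sectioning, the microscope PSF, photobleaching,
cell motility and particle drift, cell-to-cell expression variability,
and autofluorescence structure. Passing recovery tests therefore show
that the measurement chain is unbiased and precise on clean geometry
at realistic SNR — not that segmentation or tracking are robust to
crowded, drifting, out-of-focus real data. Engulfment time is never
inferred from images (the original workflow selects it manually);
synthetic ground truth or a user annotation table supplies it.

Pulse-chase fields place ~48 vesicles per 512² field; vesicle ages at a
timepoint T are uniform over [max(0, T − pulse), T] with a 2-min pulse,
mimicking continuous formation during labeling. Bead fields render
equatorial rings (radius 5 µm, 0.6 µm thick, at 0.2 µm/px) with probe
signal `NS + Bmax·c/(Kd + c)` per bead, a per-bead N(1, 0.05) scale
factor for bead-to-bead variability, and 5%-of-Bmax pixel noise.

## Segmentation, linking, rings

Segmentation thresholds the particle channel (Otsu by default, fixed
value available), fills holes, and keeps 8-connected components with
area ≥ 1.5 µm² — the physical size filter that separates yeast-scale
particles from debris. Areas are pixel count × pixel_size²; centroids
are reported in µm from the top-left pixel center.

Frame linking scores candidate pairs with
`cost = dist/(max_displacement·Δf) + area_weight·|log(area_b/area_a)|`
(defaults 2 µm/frame, weight 1) and solves the gated minimum-total-cost
assignment with the Hungarian algorithm (gate 1.5). Optimal assignment
was chosen over greedy matching because it is order-independent by
construction and provably equals the brute-force minimum, which the
test suite checks by enumeration for small n. Tracks with gaps longer
than `max_frame_gap` (default 1, i.e. consecutive frames only) are
split; events shorter than 3 frames are dropped; every event carries an
accept/reject flag as the programmatic analogue of manual screening.

Ring masks are built by thresholding the Euclidean distance transform
of the particle mask — a pixel joins a ring when its center lies in the
ring's distance band — which avoids the anisotropy of structuring-
element dilation; corners are genuinely Euclidean. Defaults: inner gap
0.2 µm, outer gap 0.85 µm, thickness 0.35 µm (where sources disagree
between 0.30 and 0.35 µm the Methods-style value 0.35 is the default;
both are configurable). Geometry requiring
`inner_gap + thickness > outer_gap` is rejected so the rings are
disjoint by construction. Frames whose rings lose more than 10% of
their area to the image border are flagged unusable and excluded.

Normalization order is background division first (inner/outer per
frame), then referencing to the frame nearest −10 s *at or before* it.
Division rather than background subtraction was chosen because it makes
gain invariance exact (the test suite checks invariance under scaling
the whole stack). The reference frame's fold value is exactly 1.

## Cohort statistics

Event traces are resampled to a common grid by nearest frame, averaged
within each independent experiment first, and the cohort mean ± SEM is
computed across experiment means (n = experiments, never events). With
two conditions, an unpaired two-sided t-test runs per timepoint on the
experiment means; raw p-values are the primary output, with a
Holm-corrected column emitted as a clearly labeled extension. A single
experiment reports SEM as absent, not zero.

## Timing, positivity, retention

Half-max conventions are symmetric and standard; a trace whose peak
never reaches the positivity threshold (default 1.5-fold) is scored
never-positive with all timings absent. The 1.5-fold / 2-consecutive-
frame positivity rule replaces by-eye scoring; at the default 5% noise
its false-positive rate on flat profiles is below 2% (tested). Traces
still above half-max at the movie's last frame are censored: departure
is reported as the last observed time and dwell as a lower bound.
Retention curves count an event in a bin only while it is still
observed, so late bins are not diluted by short movies.

## Binding fits and selectivity

Bead circles are found by thresholding the membrane-dye channel,
taking connected components, and estimating center/radius from the
component's pixel-radial statistics, with a circularity gate (radial
sd ≤ 0.6 µm) and radius bounds (4–6 µm for 10 µm beads). Closed
equatorial rings are isolated annuli, so component statistics give the
circle exactly; a voting/Hough detector would add cost without
accuracy. Overlapping circles are both rejected. Probe intensity is
measured over the segmented ring pixels themselves (mask transfer), and
the field's off-bead median is subtracted.

The one-site model is fit by trust-region nonlinear least squares
(positivity bounds on Kd and Bmax). With experiment labels the Kd
error is the SD of per-experiment fits; otherwise a 1,000-resample
seeded bead bootstrap. A fit whose Bmax is within 2 SE of zero is
flagged `no_binding` (the expected outcome for negative-control
lipids), since Kd is then unidentifiable. Noiseless model data is
recovered to machine precision across Kd ∈ [10, 2000] nM; over seeded
noisy titrations the ±2·SD interval covers the truth ≥90% of the time
(both tested).

Selectivity is the target lipid's mean spot intensity over the
*maximum* mean among all other lipids — a conservative definition —
with negative means clipped to a small positive floor (logged).

## Mass photometry

Calibration is an OLS line through (contrast, known mass) standards.
Mixtures are fit by EM (scikit-learn GaussianMixture) with seeded
k-means initialization and 10 restarts; components are reported sorted
by mean so labeling is deterministic, with unconstrained per-component
variances. BIC over k ∈ [1, 4] supports automatic population-count
choice; on single-Gaussian data it selects k = 1 in ≥95% of seeded
replicates (tested). Components with mean below 100 kD carry a flag
because apparent masses of native proteins are unreliable below that
range. Generator default sd is 12 kD (10 kD for monomer presets) — an
instrument-spread choice, as sources report apparent masses without
spreads.

## Benchmark problem sizes

The acceptance benchmarks use: bead titrations of 3 experiments × 8
concentrations (10–2000 nM) × 30 beads; 5,000 mixture events (2,000
for monomers); pulse-chase with 2 × 48 vesicles per timepoint at
0/2/4/6/8/10 min; phagosome cohorts of 3 × 10 events in ~31-min movies
at 10-s frames; retention cohorts of 14 (untreated, 21-min movies) and
10 (inhibitor, ~16-min movies) events; and a 7-lipid × 8-replicate
panel. These sizes match the scale of the underlying experiments while
keeping a full benchmark run under a minute on one CPU; the test suite
uses smaller scenes of identical structure.

## Known limitations

* The trapezoid is a caricature of real recruitment kinetics; arrival
  and departure estimates inherit its assumption of a single positive
  interval per event.
* The similarity-linking cost and the positivity rule are explicit
  stand-ins for steps the original workflow performed by hand or with
  unpublished parameters; only the documented forms are guaranteed.
* Fold-enrichment assumes the outer ring samples pure cytosol; in
  crowded cells neighbouring compartments would contaminate it. The
  generators enforce the clean-geometry assumption rather than test it.
* No PSF means synthetic edges are one pixel sharp; absolute ring
  intensities on real, blurred data will be diluted in a thickness-
  dependent way that the fold reference only partly cancels.
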