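# Methods

This note documents the models, estimators and numerical choices behind
`oxyflow`, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying procedures were open.

## Line-scan velocimetry

A line scan sweeps a path that runs first along the vessel axis and then
across it; rows of the kymograph are successive sweeps (dt_line per line),
columns are position (px μm/pixel). RBCs exclude the plasma dye, so each
cell draws a dark stripe whose column-shift per line s encodes its
velocity, v = s·px/dt_line.

**Velocity.** Per 40 ms block (consecutive blocks share 10 ms; stride
30 ms — the stated overlap could also be read as a 10 ms stride, so both
are configurable), the stripe angle is found by maximising the variance of
the image projected perpendicular to a candidate stripe direction
(a Radon-style rotation search): coarse grid of 181 angles over
±arctan(v_max·dt/px), then golden-section refinement to 10⁻⁴ rad. Blocks
whose best-angle variance is < 1.2× the median over angles are flagged
low-quality (an essentially flat variance spectrum means no coherent
stripes). The estimator is equivariant under time reversal and mirror
flips (sign) and invariant to intensity gain/offset.

**Flux and haematocrit.** The along-vessel segment is binarized with a
per-recording Otsu threshold. Otsu always splits a histogram, so a
shadow-free segment would come out half "dark"; the threshold is therefore
only honoured when the two classes separate by more than six noise SDs
(noise estimated robustly from along-position first differences — RBC
shadows are many pixels wide, so adjacent-column differences are almost
pure noise). Flux counts connected dark runs of the centre three columns,
assigning each run to the 250 ms window containing its midpoint; runs
touching the first or last line are partial transits and are excluded,
which makes the count exactly the number of complete transits on noiseless
data. Haematocrit is the dark fraction per 40 ms block.

**Diameter (FWHM).** Lumen profiles use baseline = 5th percentile and
peak = maximum of a 3-sample median filter; the half-maximum crossings are
located by linear interpolation. A percentile-based peak (an alternative
considered) systematically underestimates the peak whenever the window is
much wider than the lumen — most samples are background — which widens the
apparent FWHM by several percent; the speck-robust maximum avoids that
bias while still rejecting single-pixel outliers. The measurement is
invariant to intensity gain and offset.

## Movie diameter and 3-D morphometry

Per frame, the lumen channel is segmented at half its 95th-percentile
intensity, skeletonised in 2-D, and the skeleton ordered along its
principal axis. Perpendicular profiles are sampled at every second
skeleton pixel, averaged over a running window of five skeleton positions,
and each profile's FWHM measured; the frame value is the mean over the
vessel. Skeleton ends are trimmed by roughly one vessel diameter because
perpendicular profiles there exit the lumen obliquely.

Stacks are smoothed (Gaussian, σ = 1 voxel), binarized (Otsu), and
skeletonised in 3-D. The mask is zero-padded by one voxel first: the
thinning algorithm otherwise deletes exactly even-width axis-aligned bars
entirely (a degenerate tie case that real, irregular vasculature does not
hit, but synthetic cylinders can). Per-point radii are exact Euclidean
distance-map values at skeleton voxels; branch points are skeleton voxels
with more than two 26-connected neighbours. Total length sums unique
26-neighbour edge lengths, and density divides by the stack volume
(reported in m of vessel per mm³). Tissue distances are background-voxel
EDT values (distance to the nearest vessel voxel, i.e. the vessel
surface to within half a voxel); histograms are averaged over seeded,
non-overlapping cubic substacks (100 μm per side on full-size stacks;
tests use 60–80 μm substacks inside 160–200 μm synthetic volumes so that
several disjoint substacks actually fit), and centiles are computed from
the pooled substack distances. Depth is distance below the first image
plane; depth bins are half-open [low, high), and empty bins report NaN
rather than zero.

## Event detection and response classification

Calcium traces are first min–max normalised over the recording; putative
events are local maxima above 0.10 with prominence ≥ 0.05 (normalised
units) and ≥ 1 s separation — the prominence and separation are package
choices, as only the 10%-of-max threshold is inherited. Each candidate is
re-expressed as ΔF/F against the mean of its own 5 s pre-peak baseline and
kept if the peak exceeds the baseline mean by 2 baseline SDs. Windows are
clipped, never padded: peaks within 5 s (10 s) of the start (end) are
dropped.

Because the global normalisation is scale-free, a recording containing
*only* noise normalises to full range and its maxima can pass both rules —
the detector is meaningful when at least one genuine transient sets the
recording maximum, which is the regime the shuffled null quantifies. This
is a property of the detection rule itself, not of the implementation.

A diameter window is *responsive* when a contiguous run longer than 0.5 s
within (0, 5] s after the event exceeds baseline mean + 1 SD. The run
threshold is the smallest sample count strictly exceeding 0.5 s at the
trace's rate. The dilation peak is the maximum of the baseline-normalised
response window; NVC index = dilation peak / calcium peak (undefined, and
the record dropped, for non-positive calcium peaks). The shuffled null
fully permutes the diameter samples per iteration (seeded; a circular-
shift mode is available) and reports the fraction of event × iteration
pairs classified responsive — on white noise this reproduces the
Monte-Carlo chance rate of the 1-SD/0.5-s rule (a few percent, matching
the scale of published shuffled rates).

Holm–Bonferroni: ascending p values multiplied by (m, m−1, …, 1) with a
running maximum and a cap at 1, equivalent to the step-down procedure with
stop-at-first-nonsignificant semantics encoded in the adjusted values.

## Probe channels and metabolic events

Hbt = HbO + Hbr; SO₂ = 100·HbO/Hbt; CMRO₂ = CBF·Hbr/Hbt, computed
samplewise and left missing where Hbt = 0. CMRO₂ is invariant to common
rescaling of the haemoglobin channels and linear in CBF — both are tested.
Rest is defined as |locomotion| < 0.25 cm/s with 1 s exclusion padding
around bouts and the stimulus off (the underlying definition is
qualitative — immobile and in the dark — so threshold and padding are
package defaults, exposed as arguments). CMRO₂ peaks are detected by the
*same* function as calcium peaks (one shared code path, asserted by a
cross-module test), with the 5 s pre-peak baseline convention carried
over; the regional NVC index is the baseline-normalised Hbt peak within
5 s divided by the CMRO₂ peak. The direction of this ratio is stated
inconsistently in the source material (Hbt/CMRO₂ in the figure definition,
the reciprocal in the body text); the figure convention is the default and
the reciprocal is available via an argument.

## Oxygen transport model

Conversions: Hill saturation s = p^h/(p^h + P50^h) with h = 2.59,
P50 = 40.2 mmHg (C57BL/6); concentration C = p·k_H(T) with
k_H(T) = 1.3×10⁻⁵·exp(1500·(1/T − 1/T₀)) mol m⁻³ Pa⁻¹, T = 310.15 K.
T₀, the reference temperature of the tabulated constant, is not stated in
the source and is set to 298.15 K; with that choice the four printed
pressure/concentration pairs (10→14, 15→21, 30→42, 43→60 μM) are
reproduced within 1.5 μM (the printed 42 and 60 appear to be rounded from
slightly different intermediate values, so integer agreement everywhere is
not expected under any single T₀).

The PDE ∂C/∂t = (1/r)∂_r(r·D·∂_r C) − V_max·C/(C+K_m) is discretised by a
conservative finite volume scheme on r ∈ [r_c, r_max]: ~50 nm cells across
the 200 nm wall (where D is multiplied by 0.6), 400 uniform cells outside,
harmonic-mean face conductances, Dirichlet C(r_c) = C_cap via a half-cell
flux and zero flux at r_max. Internally the solver works in μm/s/μM
(D = 1540 μm²/s; V_max in mM/min × 1000/60 μM/s). K_m is 1 μM (the
source's "1 μm" is a unit typo). Steady states use damped Newton on the
discrete equations (tridiagonal Jacobian, convergence on step size);
a stiff BDF time march to steady state is provided as an independent
cross-check and the two agree to ≤10⁻⁵ relative. Every accepted steady
solve must balance capillary influx against total consumption to 0.5%.
Halving the grid changes the midpoint concentration by <0.1%, and in the
K_m→0, no-wall limit the solution matches the classical Krogh closed form
to <1%.

Transients integrate from C(r) = 0 with the BDF method; the settling time
is the first time after which the midpoint (outer-boundary) concentration
stays within 1% of its steady value. `calibrate_rmax` bisects the outer
radius (to 0.05 μm) for a target midpoint consumption fraction — midpoint
VO₂/V_max is monotone decreasing in r_max, which the tests assert — since
the centile distances behind some printed geometries are not themselves
printed. The outer-boundary convention is deliberately explicit: the
printed median capillary separation (14.4 μm) is used directly as r_max
where stated, and calibration is used otherwise; no centile is assumed.
`centile_sweep` solves one steady profile per capillary spacing and
`inhibition_fractions` interpolates consumption over a measured tissue-
distance distribution (spacing = 2× distance), reporting the tissue
fraction with 1 − VO₂/V_max above each threshold; distances below the
swept range clamp to the nearest (best-oxygenated) solve, distances above
it are an error.

One printed pair is not reproducible under this model family: with the
hippocampal geometry calibrated so that C_cap = 14 μM gives 60% midpoint
consumption at V_max = 2 mM/min, raising C_cap to 18 μM yields ≈76%, not
the published ≈70%. The solver was cross-validated against an independent
shooting-method integration (agreement to 0.03 percentage points), and no
calibration point between 55% and 65% maps 18 μM near 70% — the two
printed percentages are mutually inconsistent at any single outer radius
of this PDE, so the corresponding check is left failing rather than
adjusted.

## Synthetic data

The generators emulate geometry and contrast with known ground truth; they
are deterministic given their seed, use a Gaussian PSF (σ = 0.4 μm) and
additive Gaussian noise on normalised intensity, and do **not** model
photon statistics, motion artefacts, scan-path distortion, or flow
mechanics. Passing tests therefore demonstrate correct recovery of the
encoded quantities under realistic blur and noise, not robustness to every
artefact of in vivo data.

Line scans place RBC centre-crossings on the lattice (k+½)/flux with the
axial position following the integrated velocity programme (the time axis
is extended beyond the record so cells mid-transit at the edges move
correctly). Shadow width is tied to the requested haematocrit
(w = hct·|v|/flux, the identity linking the three observables; 3 μm — an
RBC-scale shadow — when unconstrained), and tests sample velocity/flux
combinations keeping w at RBC scale and transits non-overlapping, since
sub-micron shadows are both unphysical and unresolvable under the PSF.
Movies render a tube of per-frame diameter along a polyline plus Gaussian
calcium ROIs driven by instant-rise, exponential-decay transients
(τ = 0.4 s, indicator-like). Volumes rasterise capillary segments
(explicit, or random until total centre-line length is within ±10% of a
target density of 0.9 m/mm³ by default); voxel centres sit on integer
multiples of the voxel size (see skeletonisation note). Probe sessions
multiply CBF by (1 + g_m·k(t)) and both haemoglobin channels by
(1 + g_h·k(t)), k a unit-peak gamma kernel (peak 1 s after onset), so the
relative CMRO₂ and Hbt excursions equal g_m and g_h in closed form; the
default gains (0.3, 0.06) give events comfortably above the 2-SD rule at
the default 0.5–1% noise. Note the detector's 5 s pre-peak baseline
contains the kernel's rising phase, whose window mean is t_p(e−2)/5, so
the detected ΔF/F peak is g(1−m̄)/(1+g·m̄) — the tests assert this exact
forward value rather than g itself.

## Problem sizes

Defaults are sized for interactive use and CI: synthetic volumes of
160–200 μm per side at 2 μm voxels, line scans of 0.2–1 s at 1 ms/line,
probe sessions of 1–3 minutes, 400-cell PDE grids. All are parameters of
the truth dataclasses or model spec and scale up directly.

## Known limitations

Velocity estimation assumes a single dominant stripe population per block
(no bidirectional flow within one vessel); flux undercounts when transits
overlap at the path centre (haematocrit near 1); movie diameter assumes
one vessel per field; the oxygen model is 1-D radial (no network topology,
no intravascular gradients, no RBC-resolved delivery); and laser-doppler
units are arbitrary, so CMRO₂ and the regional index are relative
quantities only.
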