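# oxyflow

Neurovascular coupling metrics and capillary oxygen transport modelling for
two-photon microscopy and combined laser-doppler/haemoglobin-spectroscopy
(oxy-CBF probe) data, built around the comparison of hippocampal (HC) and
primary visual cortex (V1) microvasculature in awake mice.

The hippocampus is more vulnerable than neocortex to hypoxia and
hypoperfusion. Asking *why* requires joining three kinds of measurement:
single-vessel haemodynamics from line scans (RBC velocity, flux,
haematocrit, diameter), event-triggered coupling between neuronal calcium
and vessel dilation, and the geometry of the capillary network — and then
feeding them into a model of oxygen diffusion and consumption in tissue.
`oxyflow` implements that full chain as a tested Python library, together
with a synthetic-data module that generates every input with known ground
truth, so each estimator is verifiable without access to raw imaging data.

## What it computes

**Line scans** (`oxyflow.linescan`). Kymographs (scan lines × path
position) carry RBC shadows. Velocity comes from the stripe angle via a
Radon-style projection-variance search over 40 ms blocks, v = tan φ ·
px/dt; flux from counting dark transits at the path centre per 250 ms
window; tube haematocrit from the dark fraction per block; diameter from
the sub-pixel FWHM of the across-vessel lumen profile.

**Movies and stacks** (`oxyflow.vesselgeom`). Per-frame vessel diameter
from perpendicular intensity profiles along the 2-D skeleton (profiles
averaged over a 5-pixel running window, FWHM each). From 3-D stacks:
skeletonisation, per-point radii from the exact Euclidean distance map,
capillary length density, diameter-by-depth histograms, and the
distribution of tissue distances from the nearest vessel with its
{50…95}th centiles.

**Neurovascular coupling** (`oxyflow.nvc`). Calcium traces are min–max
normalised (ΔF/F = (F−F_min)/(F_max−F_min)); putative peaks >10% of the
maximum are re-expressed against their own 5 s baseline
(ΔF/F = (F−F₀)/|F₀|) and kept if >2 baseline SDs. A vessel responds to an
event if its diameter exceeds baseline mean + 1 SD for >0.5 s within 5 s;
NVC index = dilation peak / calcium peak. A shuffled null (100 random
permutations of the diameter trace) gives the chance response rate.
Holm–Bonferroni step-down adjustment is included for multiple comparisons.

**Probe sessions** (`oxyflow.hemo`). From 40 Hz flux/HbO/Hbr channels:
Hbt = HbO + Hbr, SO₂ = HbO/Hbt, and

    CMRO₂(t) = CBF(t) · Hbr(t) / Hbt(t)

with rest segmentation (immobile, stimulus off), per-animal baselines,
CMRO₂ event detection (same code path as the calcium detector), and the
regional NVC index Hbt-peak/CMRO₂-peak.

**Oxygen model** (`oxyflow.oxymodel`). Saturation→pressure via the Hill
curve (h = 2.59, P50 = 40.2 mmHg), pressure→concentration via Henry's law
(k_H = 1.3×10⁻⁵ mol m⁻³ Pa⁻¹ at standard temperature, van 't Hoff factor
1500 K, T = 310.15 K), and the radial diffusion–consumption PDE

    ∂C/∂t = (1/r) ∂/∂r ( r·D·∂C/∂r ) − V_max·C/(C + K_m)

on r ∈ [2.5 μm, r_max], C fixed at the capillary edge, zero flux midway
between capillaries, D = 9.24×10⁻⁸ m²/min reduced 40% across a 200 nm
wall, K_m = 1 μM. Solved by a conservative finite-volume discretisation
with damped-Newton steady states (cross-checked by stiff time marching),
plus geometry calibration, centile sweeps over capillary spacings, and
tissue-fraction inhibition summaries.

## Worked example

`python examples/oxygen_model.py` prints:

```
10 mmHg -> 14.3 uM (HC capillary O2)
15 mmHg -> 21.4 uM (V1 capillary O2)

HC, median capillary spacing (r_max 14.4 um), Vmax 2 mM/min:
  midpoint [O2] 11.3 uM, consumption 92% of Vmax
  settles from anoxia in 0.38 s
HC far tissue (r_max 29.3 um), Vmax 2 mM/min: [O2] 1.45 uM, VO2 59% of Vmax
HC far tissue (r_max 29.3 um), Vmax 3 mM/min: [O2] 0.45 uM, VO2 31% of Vmax
```

Tissue at the median distance from a hippocampal capillary stays well
oxygenated, but in the tissue far from a vessel (domain calibrated so
consumption runs at 59% of V_max), raising demand from 2 to 3 mM/min
roughly halves the local [O₂] and drops oxidative ATP synthesis to ~31% of
its ceiling — oxygen becomes the limiting substrate exactly where the
capillary network is sparsest.

The other scripts in `examples/` demonstrate line-scan velocimetry
(`linescan_metrics.py`), movie-based coupling analysis with the shuffled
null (`movie_nvc.py`), 3-D morphometry (`stack_morphometry.py`) and probe
CMRO₂ analysis (`probe_cmro2.py`); each generates its own synthetic input
and prints estimates next to the generating truth.

`oxyflow.pipeline.run_pipeline` drives all stages from a single config
(YAML or in code) with one root seed and writes CSV/JSON outputs plus a
provenance record; `oxyflow.io` reads and writes the TIFF+JSON-sidecar and
CSV formats.

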