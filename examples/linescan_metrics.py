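"""Line-scan velocimetry: recover RBC velocity, flux and haematocrit.

Renders a kymograph of a capillary with known red-blood-cell kinetics,
then runs the stripe-angle, transit-count and dark-fraction estimators.
"""

import numpy as np

from oxyflow import linescan, synth

truth = synth.LineScanTruth(
    velocity_series=800.0,  # μm/s, constant
    flux=60.0,              # RBC transits per second
    hematocrit=0.25,        # dark fraction of the lumen
    diameter_series=5.0,    # μm
    duration=1.0, noise_sd=0.02, seed=7)
kym = synth.make_linescan(truth)

vel = linescan.estimate_velocity(kym)
flux = linescan.count_flux(kym)
hct = linescan.estimate_hematocrit(kym)
diam = linescan.diameter_from_linescan(kym, average_lines=50)

print(f"velocity    {np.nanmedian(vel.good_values()):7.1f} um/s   (truth {truth.velocity_series})")
print(f"flux        {np.nanmean(flux.good_values()):7.1f} RBC/s  (truth {truth.flux})")
print(f"hematocrit  {np.nanmean(hct.good_values()):7.3f}        (truth {truth.hematocrit})")
print(f"diameter    {np.nanmean(diam.values):7.2f} um     (truth {truth.diameter_series})")
print("Each value is recovered from the rendered image alone: stripe slope")
print("gives velocity, dark-run counts give flux, dark fraction gives")
print("haematocrit, and the across-vessel FWHM gives diameter.")
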