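"""Intensity-profile measurements shared by the line-scan and movie pipelines."""

from __future__ import annotations

import numpy as np

__all__ = ["fwhm"]


def fwhm(profile, spacing: float = 1.0, baseline_pct: float = 5.0) -> float:
    """Full width at half maximum of a bright peak in ``profile``.

    The baseline is the 5th percentile of the profile and the peak is the
    maximum of a 3-sample median filter of it, so isolated dark or bright
    specks do not shift the half-maximum level.  (A percentile peak would be
    biased low whenever the window is much wider than the lumen, widening
    the apparent FWHM, so the speck-robust maximum is used instead.)  The
    two half-level crossings flanking the argmax are located by linear
    interpolation, giving sub-sample resolution.  Returns NaN when no peak
    rises above the baseline.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3 or not np.any(np.isfinite(y)):
        return float("nan")
    base = np.nanpercentile(y, baseline_pct)
    med3 = np.median(np.lib.stride_tricks.sliding_window_view(y, 3), axis=-1)
    peak = np.nanmax(med3)
    if peak - base <= 0:
        return float("nan")
    half = 0.5 * (base + peak)
    above = y >= half
    if not above.any():
        return float("nan")
    imax = int(np.nanargmax(y))
    if not above[imax]:
        return float("nan")
    # walk out from the maximum to the first sub-half samples
    left = imax
    while left > 0 and above[left - 1]:
        left -= 1
    right = imax
    while right < y.size - 1 and above[right + 1]:
        right += 1
    # linear interpolation at the crossings; treat clipped edges as hard edges
    if left == 0:
        x_left = -0.5
    else:
        y0, y1 = y[left - 1], y[left]
        x_left = (left - 1) + (half - y0) / (y1 - y0)
    if right == y.size - 1:
        x_right = y.size - 0.5
    else:
        y0, y1 = y[right], y[right + 1]
        x_right = right + (y0 - half) / (y0 - y1)
    return float((x_right - x_left) * spacing)
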