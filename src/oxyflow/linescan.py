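"""RBC velocimetry and vessel metrics from two-photon line-scan kymographs.

A line scan repeatedly sweeps the laser along a fixed path; stacking the
sweeps gives a kymograph whose rows are successive scan lines (time) and
whose columns are position along the path.  Where the path runs along the
vessel axis, unlabelled RBCs cast dark stripes on the bright dye-filled
lumen; the stripe slope (pixels of displacement per line) encodes their
velocity, the number of stripes crossing the path centre encodes flux, and
the dark fraction of the lumen encodes tube haematocrit.  Where the path
crosses the vessel, the bright lumen profile gives the diameter as a full
width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._profiles import fwhm
from .traces import BlockSeries, DiameterTrace

__all__ = [
    "Kymograph",
    "estimate_velocity",
    "count_flux",
    "estimate_hematocrit",
    "diameter_from_linescan",
]


@dataclass
class Kymograph:
    """Line-scan image plus scan-path metadata.

    ``path_segments`` maps segment roles (``"along_vessel"``,
    ``"across_vessel"``) to half-open column ranges ``(start, stop)``.
    """

    intensity: np.ndarray  # (n_lines, n_columns)
    dt_line: float  # s per scanned line
    px: float  # μm per pixel
    path_segments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (lines × position)")
        if self.dt_line <= 0 or self.px <= 0:
            raise ValueError("dt_line and px must be positive")
        width = self.intensity.shape[1]
        seen = np.zeros(width, dtype=bool)
        for role, (c0, c1) in self.path_segments.items():
            if not (0 <= c0 < c1 <= width):
                raise ValueError(f"segment {role!r} range {(c0, c1)} outside image")
            if seen[c0:c1].any():
                raise ValueError("path segments overlap")
            seen[c0:c1] = True

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration(self) -> float:
        return self.n_lines * self.dt_line

    def segment(self, role: str) -> np.ndarray:
        if role not in self.path_segments:
            raise ValueError(f"kymograph has no {role!r} path segment")
        c0, c1 = self.path_segments[role]
        return self.intensity[:, c0:c1]


def _projection_variance(block: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Variance of the Radon-style projection of ``block`` at each angle.

    For angle φ each pixel (row, col) is projected onto
    ``p = col·cosφ − row·sinφ``; when tanφ equals the stripe slope
    (columns advanced per scan line) the stripes collapse onto single bins
    and the projected profile's variance is maximal.  Bins with low pixel
    counts (image corners under shear) are excluded.
    """
    rows, cols = np.indices(block.shape)
    rows = rows.ravel().astype(float)
    cols = cols.ravel().astype(float)
    vals = (block - block.mean()).ravel()
    out = np.empty(angles_rad.size)
    for i, phi in enumerate(angles_rad):
        p = cols * np.cos(phi) - rows * np.sin(phi)
        p = p - p.min()
        idx = p.astype(np.int64)
        counts = np.bincount(idx)
        sums = np.bincount(idx, weights=vals)
        keep = counts >= 0.5 * counts.max()
        if keep.sum() < 3:
            out[i] = 0.0
            continue
        prof = sums[keep] / counts[keep]
        out[i] = prof.var()
    return out


def estimate_velocity(k: Kymograph, block_len: float = 0.040,
                      overlap: float = 0.010, v_max: float = 5000.0,
                      quality_ratio: float = 1.2) -> BlockSeries:
    """Per-block RBC velocity [μm/s] from stripe angles in the along-vessel segment.

    Successive blocks of ``block_len`` seconds share ``overlap`` seconds
    (stride = block_len − overlap).  Within a block the stripe angle is
    found by a projection-variance rotation search (coarse grid then
    golden-section refinement) and converted to velocity as
    ``v = tan(φ)·px/dt_line``; the sign encodes direction along the scan
    path.  Blocks whose best-angle projection variance is less than
    ``quality_ratio`` times the median over angles carry too little stripe
    contrast and are flagged low quality.
    """
    seg = k.segment("along_vessel")
    n_block = int(round(block_len / k.dt_line))
    if n_block < 4:
        raise ValueError("block covers <4 lines; decrease dt_line or raise block_len")
    if seg.shape[0] < n_block:
        raise ValueError("recording shorter than one block")
    stride = max(1, int(round((block_len - overlap) / k.dt_line)))
    phi_max = np.arctan(v_max * k.dt_line / k.px)
    coarse = np.linspace(-phi_max, phi_max, 181)
    gr = (np.sqrt(5.0) - 1) / 2

    starts = np.arange(0, seg.shape[0] - n_block + 1, stride)
    centers = (starts + n_block / 2) * k.dt_line
    values = np.empty(starts.size)
    quality = np.ones(starts.size, dtype=bool)
    for bi, s0 in enumerate(starts):
        block = seg[s0:s0 + n_block]
        var = _projection_variance(block, coarse)
        best = int(np.argmax(var))
        med = np.median(var)
        if med <= 0 or var[best] < quality_ratio * med:
            quality[bi] = False
        # golden-section refinement of the variance maximum
        a = coarse[max(best - 1, 0)]
        b = coarse[min(best + 1, coarse.size - 1)]
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = _projection_variance(block, np.array([c]))[0]
        fd = _projection_variance(block, np.array([d]))[0]
        while b - a > 1e-4:
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = _projection_variance(block, np.array([c]))[0]
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = _projection_variance(block, np.array([d]))[0]
        values[bi] = np.tan(0.5 * (a + b)) * k.px / k.dt_line
    values[~quality] = np.nan
    return BlockSeries(block_centers=centers, values=values, block_len=block_len,
                       stride=stride * k.dt_line, quality=quality, kind="velocity")


def _binarize_dark(seg: np.ndarray) -> np.ndarray:
    """Boolean mask of dark (RBC) pixels via a per-recording Otsu threshold.

    Otsu always splits a distribution, so a shadow-free (noise-only) lumen
    would come out half dark; the threshold is therefore capped at three
    noise SDs below the median, with the noise SD estimated robustly from
    temporal first differences.
    """
    if np.ptp(seg) == 0:
        raise ValueError("degenerate segment: constant intensity")
    thr = threshold_otsu(seg)
    dark = seg < thr
    if dark.all() or not dark.any():
        return dark
    # RBC shadows are many pixels wide, so along-position first differences
    # estimate the noise floor; require the Otsu classes to separate well
    # beyond it, else the segment has no shadows at all
    noise_sd = 1.4826 * np.median(np.abs(np.diff(seg, axis=1))) / np.sqrt(2)
    if seg[~dark].mean() - seg[dark].mean() < 6.0 * noise_sd:
        return np.zeros_like(dark)
    return dark


def count_flux(k: Kymograph, window: float = 0.250, center_cols: int = 3) -> BlockSeries:
    """RBC flux [RBC/s] from dark-stripe counts at the segment centre.

    The along-vessel segment is binarized (Otsu) and the occupancy of the
    central ``center_cols`` columns collapsed to a 1-D time signal; each
    connected dark run is one RBC transit.  Runs are assigned to the
    ``window``-second bin containing their midpoint and counts scaled to
    RBC/s.  Windows whose centre signal is entirely dark or entirely
    bright while the block shows no transitions are flagged.
    """
    seg = k.segment("along_vessel")
    dark = _binarize_dark(seg)
    c = seg.shape[1] // 2
    h = center_cols // 2
    occ = dark[:, max(c - h, 0):c + h + 1].mean(axis=1) > 0.5
    labels, n_runs = ndimage.label(occ)
    if n_runs:
        ids = np.arange(1, n_runs + 1)
        # runs touching the first/last line are partial transits: exclude
        edge = set()
        if occ[0]:
            edge.add(labels[0])
        if occ[-1]:
            edge.add(labels[-1])
        ids = np.array([i for i in ids if i not in edge])
        mids = ndimage.center_of_mass(occ, labels, ids) if ids.size else []
        mid_t = np.array([m[0] for m in mids]) * k.dt_line
    else:
        mid_t = np.empty(0)
    n_win = int(k.duration / window)
    if n_win < 1:
        raise ValueError("recording shorter than one counting window")
    centers = (np.arange(n_win) + 0.5) * window
    counts = np.histogram(mid_t, bins=n_win, range=(0, n_win * window))[0]
    values = counts / window
    quality = np.ones(n_win, dtype=bool)
    for wi in range(n_win):
        r0 = int(round(wi * window / k.dt_line))
        r1 = int(round((wi + 1) * window / k.dt_line))
        w = occ[r0:r1]
        # all-dark or all-bright centre: no countable transitions
        if w.size and (w.all() or not w.any()):
            quality[wi] = False
    return BlockSeries(block_centers=centers, values=values, block_len=window,
                       stride=window, quality=quality, kind="flux")


def estimate_hematocrit(k: Kymograph, block_len: float = 0.040,
                        overlap: float = 0.010) -> BlockSeries:
    """Tube haematocrit per block: dark-pixel fraction of the binarized lumen.

    The along-vessel segment is thresholded once per recording (Otsu) and
    the RBC-shadow fraction computed over successive ``block_len`` blocks,
    consecutive blocks sharing ``overlap`` seconds.
    """
    seg = k.segment("along_vessel")
    n_block = int(round(block_len / k.dt_line))
    if n_block < 1 or seg.shape[0] < n_block:
        raise ValueError("recording shorter than one block")
    stride = max(1, int(round((block_len - overlap) / k.dt_line)))
    dark = _binarize_dark(seg)
    starts = np.arange(0, seg.shape[0] - n_block + 1, stride)
    centers = (starts + n_block / 2) * k.dt_line
    values = np.empty(starts.size)
    quality = np.ones(starts.size, dtype=bool)
    for bi, s0 in enumerate(starts):
        if np.ptp(seg[s0:s0 + n_block]) == 0:
            quality[bi] = False
            values[bi] = np.nan
        else:
            values[bi] = dark[s0:s0 + n_block].mean()
    return BlockSeries(block_centers=centers, values=values, block_len=block_len,
                       stride=stride * k.dt_line, quality=quality, kind="hematocrit")


def diameter_from_linescan(k: Kymograph, average_lines: int = 1) -> DiameterTrace:
    """Per-line lumen diameter [μm] from the across-vessel intensity profile.

    Each scan line's across-vessel profile (optionally averaged over
    ``average_lines`` consecutive lines) yields a sub-pixel FWHM; lines
    without a discernible peak give NaN.
    """
    seg = k.segment("across_vessel")
    if average_lines > 1:
        n = seg.shape[0] // average_lines
        seg = seg[:n * average_lines].reshape(n, average_lines, -1).mean(axis=1)
        rate = 1.0 / (k.dt_line * average_lines)
    else:
        rate = 1.0 / k.dt_line
    values = np.array([fwhm(row, spacing=k.px) for row in seg])
    return DiameterTrace(values=values, rate=rate)
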