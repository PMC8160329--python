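"""Synthetic two-photon and oxy-CBF probe data with known ground truth.

Every input the analysis pipeline consumes can be generated here with its
generating parameters ("truth") attached, so each estimator can be tested
for parameter recovery without any acquired data:

* :func:`make_linescan` — kymographs with RBC shadow stripes of known
  velocity, flux and haematocrit plus an across-vessel lumen profile of
  known diameter;
* :func:`make_movie` — two-channel XY time-lapse of a dilating lumen tube
  and calcium ROIs carrying exponential-kernel transients;
* :func:`make_volume` — 3-D stacks of capillary tubes, either explicit
  segments or a random network grown to a target length density;
* :func:`make_hemo` — coupled 40 Hz CBF/HbO/Hbr traces with metabolic
  events of stated CMRO2 and blood-volume gains, locomotion bouts and
  stimulus windows.

All generators are deterministic given their seed.  They emulate geometry
and contrast, not photon statistics: blur is a Gaussian PSF and noise is
additive Gaussian on normalised intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hemo import HemoTrace
from .linescan import Kymograph
from .vesselgeom import Movie, Volume

__all__ = [
    "LineScanTruth",
    "MovieTruth",
    "NetworkTruth",
    "HemoTruth",
    "make_linescan",
    "make_movie",
    "make_volume",
    "make_hemo",
]

_SHADOW = 0.15  # intensity of an RBC shadow (lumen = 1)
_BACKGROUND = 0.05  # extravascular intensity


def _piecewise(series, duration: float, t: np.ndarray) -> np.ndarray:
    """Evaluate a scalar or per-equal-subdivision series at times ``t``."""
    series = np.atleast_1d(np.asarray(series, dtype=float))
    idx = np.minimum((t / duration * series.size).astype(int), series.size - 1)
    return series[idx]


# ---------------------------------------------------------------------------
# line scans


@dataclass
class LineScanTruth:
    """Generating parameters of a synthetic line-scan kymograph.

    ``velocity_series`` is signed RBC velocity [μm/s], piecewise constant
    over equal subdivisions of ``duration``; ``flux`` is RBC transits per
    second through the path centre; ``hematocrit`` the dark fraction of the
    lumen (sets the RBC shadow width via w = hct·|v|/flux); and
    ``diameter_series`` the lumen diameter [μm] seen by the across-vessel
    path segment.
    """

    velocity_series: float | np.ndarray = 500.0
    flux: float = 50.0
    hematocrit: float = 0.3
    diameter_series: float | np.ndarray = 5.0
    duration: float = 1.0
    dt_line: float = 0.001
    px: float = 0.2
    along_len: float = 20.0  # μm of scan path along the vessel
    across_len: float = 16.0  # μm of scan path across the vessel
    psf_sigma: float = 0.4  # μm
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_line <= 0 or self.px <= 0 or self.duration <= 0:
            raise ValueError("dt_line, px and duration must be positive")
        if not (0 <= self.hematocrit <= 1):
            raise ValueError("hematocrit must lie in [0, 1]")
        if self.flux < 0:
            raise ValueError("flux must be non-negative")
        if np.any(np.atleast_1d(self.diameter_series) <= 0):
            raise ValueError("diameters must be positive")


def make_linescan(truth: LineScanTruth) -> Kymograph:
    """Render a kymograph whose stripes encode the truth parameters.

    RBC k crosses the path centre at time ``(k+0.5)/flux``; its axial
    position follows the integrated velocity, so stripe slope in pixels
    per line is ``v·dt_line/px``.  Shadows are anti-aliased slabs of width
    ``hct·|v̄|/flux`` (or 3 μm if haematocrit is zero/flux is zero), then
    the image is blurred along the path (Gaussian PSF) and Gaussian noise
    of ``noise_sd`` times the dynamic range is added.
    """
    rng = np.random.default_rng(truth.seed)
    n_lines = int(round(truth.duration / truth.dt_line))
    t = (np.arange(n_lines) + 0.5) * truth.dt_line
    v = _piecewise(truth.velocity_series, truth.duration, t)
    v_mean = float(np.mean(np.abs(v)))
    if truth.flux > 0 and v_mean > 0 and truth.hematocrit > 0:
        w = truth.hematocrit * v_mean / truth.flux
    else:
        w = 3.0  # default shadow extent when geometry leaves it unconstrained

    n_along = int(round(truth.along_len / truth.px))
    n_across = int(round(truth.across_len / truth.px))
    img = np.empty((n_lines, n_along + n_across))

    # cumulative displacement X(t); RBC k position = X(t) − X(t_k).
    # The time axis is extended beyond the record so RBCs mid-transit at the
    # edges carry the correct (edge-velocity) displacement.
    half_span = truth.along_len / 2 + w
    pad = half_span / max(v_mean, 1e-9) if v_mean > 0 else 0.0
    n_pad = int(np.ceil(pad / truth.dt_line)) + 1
    t_ext = (np.arange(-n_pad, n_lines + n_pad) + 0.5) * truth.dt_line
    v_ext = _piecewise(truth.velocity_series, truth.duration,
                       np.clip(t_ext, 0.0, truth.duration))
    x_ext = np.cumsum(v_ext) * truth.dt_line
    x_t = x_ext[n_pad:n_pad + n_lines]
    if truth.flux > 0:
        # crossings stay on the (k+0.5)/flux lattice, k extended past the record
        k0 = int(np.floor(-pad * truth.flux - 0.5))
        k1 = int(np.ceil((truth.duration + pad) * truth.flux + 0.5))
        t_k = (np.arange(k0, k1) + 0.5) / truth.flux
        xk0 = np.interp(t_k, t_ext, x_ext)
    else:
        t_k = np.empty(0)
        xk0 = np.empty(0)

    along = np.ones((n_lines, n_along))
    if t_k.size:
        # positions of all RBCs at all line times: (n_lines, n_rbc)
        pos = x_t[:, None] - xk0[None, :]
        edges_lo = (pos - w / 2 + truth.along_len / 2) / truth.px
        edges_hi = (pos + w / 2 + truth.along_len / 2) / truth.px
        cols = np.arange(n_along)
        cover = np.zeros((n_lines, n_along))
        for r in range(n_lines):
            lo, hi = edges_lo[r], edges_hi[r]
            keep = (hi > 0) & (lo < n_along)
            for a, b in zip(lo[keep], hi[keep]):
                ia, ib = int(np.floor(a)), int(np.ceil(b))
                frac = np.clip(np.minimum(b, cols[max(ia, 0):ib] + 1)
                               - np.maximum(a, cols[max(ia, 0):ib]), 0, 1)
                cover[r, max(ia, 0):ib] += frac
        along -= (1.0 - _SHADOW) * np.clip(cover, 0, 1)
    img[:, :n_along] = along

    # across-vessel lumen profile
    d = _piecewise(truth.diameter_series, truth.duration, t)
    u = (np.arange(n_across) + 0.5) * truth.px - truth.across_len / 2
    cover = np.clip(0.5 + (d[:, None] / 2 - np.abs(u[None, :])) / truth.px, 0, 1)
    img[:, n_along:] = _BACKGROUND + (1.0 - _BACKGROUND) * cover

    img = ndimage.gaussian_filter1d(img, truth.psf_sigma / truth.px, axis=1)
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, img.shape)
    return Kymograph(
        intensity=np.clip(img, 0.0, 1.2),
        dt_line=truth.dt_line,
        px=truth.px,
        path_segments={"along_vessel": (0, n_along),
                       "across_vessel": (n_along, n_along + n_across)},
    )


# ---------------------------------------------------------------------------
# movies


@dataclass
class MovieTruth:
    """Generating parameters of a two-channel XY time-lapse movie.

    The lumen channel holds a tube along ``vessel_path`` (polyline in μm;
    default horizontal through the frame centre) whose instantaneous
    diameter follows ``diameter_timecourse``.  The calcium channel holds
    Gaussian ROIs at ``roi_centres`` whose ΔF/F transients are unit-step
    events convolved with a single-exponential indicator kernel.
    """

    shape: tuple = (128, 128)  # (ny, nx) pixels
    n_frames: int = 100
    frame_rate: float = 7.0
    px: float = 0.4  # μm/pixel
    vessel_path: np.ndarray | None = None  # (n, 2) [μm] (x, y)
    diameter_timecourse: float | np.ndarray = 5.0
    roi_centres: tuple = ((20.0, 12.0),)  # μm (x, y)
    roi_sigma: float = 2.0  # μm
    calcium_event_times: tuple = ()
    calcium_amplitudes: tuple = ()  # ΔF/F per event
    kernel_tau: float = 0.4  # s
    f0: float = 100.0  # baseline fluorescence [a.u.]
    psf_sigma: float = 0.4  # μm
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.shape
        if self.frame_rate <= 0 or self.px <= 0:
            raise ValueError("frame_rate and px must be positive")
        d = np.atleast_1d(np.asarray(self.diameter_timecourse, dtype=float))
        if np.any(d <= 0):
            raise ValueError("diameters must be positive")
        dur = self.n_frames / self.frame_rate
        if any(not (0 <= te < dur) for te in self.calcium_event_times):
            raise ValueError("calcium event times must lie within the movie")
        if len(self.calcium_event_times) != len(self.calcium_amplitudes):
            raise ValueError("event times and amplitudes must pair up")
        for (cx, cy) in self.roi_centres:
            if not (0 <= cx < nx * self.px and 0 <= cy < ny * self.px):
                raise ValueError(f"ROI centre {(cx, cy)} outside the frame")

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


def _path_distance(truth: MovieTruth) -> np.ndarray:
    """Per-pixel distance [μm] to the vessel centre line."""
    ny, nx = truth.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    px_xy = np.stack([(xx + 0.5) * truth.px, (yy + 0.5) * truth.px], axis=-1)
    if truth.vessel_path is None:
        path = np.array([[0.0, ny * truth.px / 2], [nx * truth.px, ny * truth.px / 2]])
    else:
        path = np.asarray(truth.vessel_path, dtype=float)
    best = np.full((ny, nx), np.inf)
    for p0, p1 in zip(path[:-1], path[1:]):
        seg = p1 - p0
        L2 = seg @ seg
        tpar = np.clip(((px_xy - p0) @ seg) / max(L2, 1e-12), 0, 1)
        proj = p0 + tpar[..., None] * seg
        dist = np.linalg.norm(px_xy - proj, axis=-1)
        best = np.minimum(best, dist)
    return best


def make_movie(truth: MovieTruth):
    """Render the movie; returns ``(Movie, roi_traces, diameter_trace)``.

    ``roi_traces`` is a pandas DataFrame (column per ROI) of the true mean
    fluorescence inside each ROI disc; ``diameter_trace`` the true
    per-frame diameter.  Both are noise-free ground truth.
    """
    import pandas as pd

    from .traces import DiameterTrace

    rng = np.random.default_rng(truth.seed)
    ny, nx = truth.shape
    t = np.arange(truth.n_frames) / truth.frame_rate
    d = _piecewise(truth.diameter_timecourse, truth.duration, t)
    dist = _path_distance(truth)

    lumen = np.empty((truth.n_frames, ny, nx))
    for i in range(truth.n_frames):
        cover = np.clip(0.5 + (d[i] / 2 - dist) / truth.px, 0, 1)
        lumen[i] = _BACKGROUND + (1 - _BACKGROUND) * cover

    # ΔF/F: instantaneous-rise, exponential-decay kernel per event
    dff = np.zeros(truth.n_frames)
    for te, amp in zip(truth.calcium_event_times, truth.calcium_amplitudes):
        on = t >= te
        dff[on] += amp * np.exp(-(t[on] - te) / truth.kernel_tau)
    yy, xx = np.mgrid[0:ny, 0:nx]
    px_x = (xx + 0.5) * truth.px
    px_y = (yy + 0.5) * truth.px
    blobs = np.zeros((ny, nx))
    for (cx, cy) in truth.roi_centres:
        blobs += np.exp(-((px_x - cx) ** 2 + (px_y - cy) ** 2)
                        / (2 * truth.roi_sigma ** 2))
    calcium = (_BACKGROUND * truth.f0
               + truth.f0 * blobs[None] * (1.0 + dff[:, None, None]))

    sig_px = truth.psf_sigma / truth.px
    lumen = ndimage.gaussian_filter(lumen, (0, sig_px, sig_px))
    calcium = ndimage.gaussian_filter(calcium, (0, sig_px, sig_px))
    if truth.noise_sd > 0:
        lumen += rng.normal(0, truth.noise_sd, lumen.shape)
        calcium += rng.normal(0, truth.noise_sd * truth.f0, calcium.shape)

    movie = Movie(channels={"lumen": lumen, "calcium": calcium},
                  frame_rate=truth.frame_rate, px=truth.px)

    # true per-ROI fluorescence (no background, no PSF): ΔF/F equals the
    # generating transient amplitudes exactly
    roi_cols = {f"roi{ri}": truth.f0 * (1.0 + dff)
                for ri in range(len(truth.roi_centres))}
    roi_traces = pd.DataFrame(roi_cols, index=pd.Index(t, name="t"))
    return movie, roi_traces, DiameterTrace(values=d, rate=truth.frame_rate)


# ---------------------------------------------------------------------------
# volumes


@dataclass
class NetworkTruth:
    """Generating parameters of a 3-D capillary-network stack.

    Either pass explicit ``segments`` (list of ``(p0, p1, radius)`` with
    endpoints in μm, z-y-x order) or a ``target_density`` in m of vessel
    per mm³ of tissue, in which case random segments are drawn until the
    total centre-line length lies within ±10% of the target.
    """

    volume_shape: tuple = (100, 100, 100)  # voxels (z, y, x)
    voxel_size: float = 2.0  # μm
    segments: list | None = None
    target_density: float | None = 0.9  # m/mm³
    radius_range: tuple = (2.0, 3.5)  # μm
    seg_len_range: tuple = (30.0, 80.0)  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.segments is not None:
            if len(self.segments) == 0:
                raise ValueError("segment list must not be empty")
            ext = np.asarray(self.volume_shape) * self.voxel_size
            for p0, p1, r in self.segments:
                if r <= 0:
                    raise ValueError("segment radii must be positive")
                for p in (p0, p1):
                    if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > ext):
                        raise ValueError("segment endpoint outside the volume")
        elif self.target_density is None:
            raise ValueError("provide segments or a target density")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.volume_shape, dtype=float) * self.voxel_size


def _draw_segments(truth: NetworkTruth, rng) -> list:
    """Random segments totalling the target centre-line length (±10%)."""
    ext = truth.extent
    vol_um3 = float(np.prod(ext))
    # m/mm³ → μm/μm³ is ×1e-3
    target_len = truth.target_density * 1e-3 * vol_um3
    segs, total = [], 0.0
    while total < 0.95 * target_len:
        p0 = rng.uniform(0, ext)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(*truth.seg_len_range)
        if total + length > 1.05 * target_len:
            length = max(1.05 * target_len - total, truth.voxel_size)
        p1 = np.clip(p0 + direction * length, 0, ext)
        seg_len = np.linalg.norm(p1 - p0)
        if seg_len < truth.voxel_size:
            continue
        segs.append((p0, p1, rng.uniform(*truth.radius_range)))
        total += seg_len
    return segs


def make_volume(truth: NetworkTruth):
    """Rasterize the tube network; returns ``(Volume, stats)``.

    ``stats`` carries the true total centre-line length [μm] and density
    [m/mm³].  Voxels within a segment's radius of its axis are foreground
    (intensity 1).
    """
    rng = np.random.default_rng(truth.seed)
    segs = truth.segments if truth.segments is not None else _draw_segments(truth, rng)
    shape = tuple(truth.volume_shape)
    data = np.zeros(shape, dtype=float)
    vs = truth.voxel_size
    # voxel centres on integer multiples of the voxel size: axis-aligned tubes
    # then have odd-symmetric cross-sections, which skeletonize cleanly
    centres = [np.arange(n) * vs for n in shape]
    total_len = 0.0
    for p0, p1, r in segs:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        total_len += float(np.linalg.norm(p1 - p0))
        lo = np.minimum(p0, p1) - r - vs
        hi = np.maximum(p0, p1) + r + vs
        sl = tuple(slice(max(int(l // vs), 0), min(int(h // vs) + 2, n))
                   for l, h, n in zip(lo, hi, shape))
        zz, yy, xx = np.meshgrid(*(c[s] for c, s in zip(centres, sl)), indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1)
        seg = p1 - p0
        L2 = max(float(seg @ seg), 1e-12)
        tpar = np.clip(((pts - p0) @ seg) / L2, 0, 1)
        proj = p0 + tpar[..., None] * seg
        dist = np.linalg.norm(pts - proj, axis=-1)
        region = data[sl]
        region[dist <= r] = 1.0
        data[sl] = region
    vol_um3 = float(np.prod(truth.extent))
    stats = {
        "total_length_um": total_len,
        "density_m_per_mm3": total_len / vol_um3 * 1e3,
        "n_segments": len(segs),
        "segments": segs,
    }
    return Volume(data=data, voxel_size=vs), stats


# ---------------------------------------------------------------------------
# oxy-CBF probe traces


@dataclass
class HemoTruth:
    """Generating parameters of a synthetic 40 Hz oxy-CBF probe session.

    Metabolic events multiply CBF by ``1 + cmro2_gain·k(t)`` (k a gamma
    kernel peaking at 1) and both haemoglobin channels by
    ``1 + hbt_gain·k(t − lag)``; since CMRO2 = CBF·Hbr/Hbt, the relative
    CMRO2 excursion equals the CMRO2 gain and the relative Hbt excursion
    equals the Hbt gain, giving closed-form ground truth for the event
    detector and the regional NVC index.
    """

    duration: float = 120.0  # s
    rate: float = 40.0  # Hz
    cbf0: float = 200.0
    hbo0: float = 60.0
    hbr0: float = 40.0
    speed0: float = 20.0
    cmro2_event_times: tuple = ()
    cmro2_gain: float = 0.3  # relative CMRO2 peak per event
    hbt_gain: float = 0.06  # relative Hbt peak per event
    hbt_lag: float = 0.0  # s
    kernel_tp: float = 1.0  # s to kernel peak
    locomotion_bouts: tuple = ()  # (start, stop, speed cm/s)
    stimulus_windows: tuple = ()  # (start, stop)
    noise_sd: float = 0.0  # fractional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate != 40.0:
            raise ValueError("probe traces are defined at 40 Hz")
        if min(self.hbo0, self.hbr0) < 0:
            raise ValueError("haemoglobin baselines must be non-negative")
        bouts = sorted((b[0], b[1]) for b in self.locomotion_bouts)
        for (s0, e0), (s1, e1) in zip(bouts[:-1], bouts[1:]):
            if s1 < e0:
                raise ValueError("locomotion bouts overlap")
        for s, e, *_ in self.locomotion_bouts:
            if not (0 <= s < e <= self.duration):
                raise ValueError("bouts must lie within the recording")


def _gamma_kernel(t: np.ndarray, tp: float) -> np.ndarray:
    """Unit-peak gamma-like kernel, zero for t < 0, maximal (=1) at t = tp."""
    k = np.where(t >= 0, (t / tp) * np.exp(1.0 - t / tp), 0.0)
    return k


def make_hemo(truth: HemoTruth) -> HemoTrace:
    """Render the probe channels; truth peak times are event time + kernel peak."""
    rng = np.random.default_rng(truth.seed)
    n = int(round(truth.duration * truth.rate))
    t = np.arange(n) / truth.rate
    km = np.zeros(n)
    kh = np.zeros(n)
    for te in truth.cmro2_event_times:
        km += _gamma_kernel(t - te, truth.kernel_tp)
        kh += _gamma_kernel(t - te - truth.hbt_lag, truth.kernel_tp)
    cbf = truth.cbf0 * (1.0 + truth.cmro2_gain * km)
    hbo = truth.hbo0 * (1.0 + truth.hbt_gain * kh)
    hbr = truth.hbr0 * (1.0 + truth.hbt_gain * kh)
    speed = truth.speed0 * (1.0 + 0.5 * truth.cmro2_gain * km)
    locomotion = np.zeros(n)
    for s, e, v in truth.locomotion_bouts:
        locomotion[(t >= s) & (t < e)] = v
    stimulus = np.zeros(n, dtype=bool)
    for s, e in truth.stimulus_windows:
        stimulus[(t >= s) & (t < e)] = True
    if truth.noise_sd > 0:
        cbf = cbf * (1 + rng.normal(0, truth.noise_sd, n))
        hbo = hbo * (1 + rng.normal(0, truth.noise_sd, n))
        hbr = hbr * (1 + rng.normal(0, truth.noise_sd, n))
        speed = speed * (1 + rng.normal(0, truth.noise_sd, n))
    return HemoTrace(t=t, flux=cbf, speed=speed, hbo=hbo, hbr=hbr,
                     locomotion=locomotion, stimulus=stimulus)
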