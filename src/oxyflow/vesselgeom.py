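"""Vessel geometry: diameter from XY movies and 3-D morphometry from stacks.

Movies of a dye-filled lumen give a per-frame diameter trace (skeletonise
the vessel, take perpendicular intensity profiles along the axis, measure
each profile's FWHM).  3-D stacks of the vasculature give the skeleton with
per-point radii (Euclidean distance map sampled on the centre line), the
capillary length density, diameter-by-depth histograms, and the
distribution of tissue distances from the nearest vessel that parameterises
the oxygen diffusion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from ._profiles import fwhm
from .traces import DiameterTrace

__all__ = [
    "Movie",
    "Volume",
    "VesselSkeleton",
    "DistanceDistribution",
    "frame_diameter_trace",
    "skeletonize_volume",
    "capillary_density",
    "diameter_depth_profile",
    "tissue_distance_distribution",
]


@dataclass
class Movie:
    """Multi-channel XY time-lapse; ``channels`` maps role → (T, Y, X) array."""

    channels: dict
    frame_rate: float  # Hz
    px: float  # μm/pixel

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.px <= 0:
            raise ValueError("frame_rate and px must be positive")
        if "lumen" not in self.channels:
            raise ValueError("movie needs a 'lumen' channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channel shapes differ")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class Volume:
    """3-D image stack; axis order (z, y, x), isotropic ``voxel_size`` in μm."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.data.shape) * self.voxel_size


@dataclass
class VesselSkeleton:
    """Centre line of a vascular volume with per-point radii and depths.

    ``points`` are voxel coordinates (z, y, x); ``radii`` the distance-map
    value at each point [μm]; ``depth`` distance below the first image
    plane [μm]; ``branch_points`` indices into ``points`` with more than
    two skeleton neighbours.
    """

    points: np.ndarray
    radii: np.ndarray
    depth: np.ndarray
    voxel_size: float
    branch_points: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    volume_shape: tuple = ()

    def __post_init__(self) -> None:
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")


@dataclass
class DistanceDistribution:
    """Histogram and centiles of tissue distance from the nearest vessel."""

    bin_edges: np.ndarray  # μm
    mean_counts: np.ndarray  # averaged over substacks (fractions)
    sd_counts: np.ndarray
    centiles: dict  # rank (%) → distance [μm]

    def __post_init__(self) -> None:
        ranks = sorted(self.centiles)
        vals = [self.centiles[r] for r in ranks]
        if np.any(np.diff(vals) < 0):
            raise ValueError("centiles must be non-decreasing in rank")


# ---------------------------------------------------------------------------
# movies


def _order_skeleton(coords: np.ndarray) -> np.ndarray:
    """Order 2-D skeleton pixels along the vessel's principal axis."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    s = c @ vt[0]
    return coords[np.argsort(s)]


def frame_diameter_trace(m: Movie, vessel_mask: np.ndarray | None = None,
                         profile_len_factor: float = 3.0,
                         every: int = 2, running: int = 5) -> DiameterTrace:
    """Mean lumen FWHM per frame from perpendicular profiles along the skeleton.

    Per frame the lumen channel is segmented (threshold at half the 95th
    percentile intensity, optionally restricted to ``vessel_mask``), the
    mask is skeletonised, and at every ``every``-th skeleton pixel an
    intensity profile perpendicular to the local axis is sampled; profiles
    are averaged over a ``running``-pixel window along the axis before the
    FWHM is measured.  The trace value is the mean FWHM over the vessel;
    frames with an empty skeleton give NaN.
    """
    lumen = np.asarray(m.channels["lumen"], dtype=float)
    values = np.full(lumen.shape[0], np.nan)
    for fi, frame in enumerate(lumen):
        img = frame if vessel_mask is None else np.where(vessel_mask, frame, 0.0)
        thr = 0.5 * np.percentile(img, 95)
        mask = img > thr
        if mask.sum() < 10:
            continue
        skel = skeletonize(mask)
        coords = np.argwhere(skel)
        if coords.shape[0] < 3:
            continue
        coords = _order_skeleton(coords.astype(float))
        # smooth the path and estimate tangents
        win = min(7, coords.shape[0] // 2 * 2 + 1)
        kernel = np.ones(win) / win
        sm = np.column_stack([
            np.convolve(coords[:, 0], kernel, mode="valid"),
            np.convolve(coords[:, 1], kernel, mode="valid"),
        ])
        if sm.shape[0] < 3:
            sm = coords
        tang = np.gradient(sm, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = tang / np.maximum(norm, 1e-9)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])

        # expected diameter scale from the mask to size the profile
        d_px_guess = 2.0 * ndimage.distance_transform_edt(mask).max()
        half_len = profile_len_factor * max(d_px_guess, 4.0) / 2.0
        n_samp = int(np.ceil(half_len * 4)) + 1
        offs = np.linspace(-half_len, half_len, n_samp)

        # trim skeleton ends where perpendicular profiles leave the vessel
        n_pts = sm.shape[0]
        trim = min(int(d_px_guess), max(n_pts // 4, 0))
        idx = np.arange(trim, n_pts - trim, every)
        if idx.size == 0:
            idx = np.arange(0, n_pts, every)
        profiles = []
        for i in idx:
            pts = sm[i][None, :] + offs[:, None] * normal[i][None, :]
            prof = ndimage.map_coordinates(frame, pts.T, order=1, mode="nearest")
            profiles.append(prof)
        profiles = np.asarray(profiles)
        if profiles.shape[0] >= running:
            kern = np.ones((running, 1)) / running
            profiles = ndimage.convolve(profiles, kern, mode="nearest")
        spacing = offs[1] - offs[0]
        widths = np.array([fwhm(p, spacing=spacing * m.px) for p in profiles])
        widths = widths[np.isfinite(widths)]
        if widths.size:
            values[fi] = widths.mean()
    return DiameterTrace(values=values, rate=m.frame_rate)


# ---------------------------------------------------------------------------
# volumes


def _binarize_volume(v: Volume, smooth_sigma: float = 1.0) -> np.ndarray:
    data = np.asarray(v.data, dtype=float)
    if np.ptp(data) == 0:
        if data.max() > 0:
            return np.ones_like(data, dtype=bool)
        raise ValueError("volume has no foreground")
    sm = ndimage.gaussian_filter(data, smooth_sigma)
    return sm > threshold_otsu(sm)


def skeletonize_volume(v: Volume, smooth_sigma: float = 1.0) -> VesselSkeleton:
    """One-voxel-wide centre line with radii from the Euclidean distance map.

    The stack is smoothed (Gaussian, σ = 1 voxel), binarized (Otsu) and
    skeletonised in 3-D; the radius at each skeleton point is the exact
    Euclidean distance-transform value of the foreground there.  Branch
    points are skeleton voxels with more than two 26-connected neighbours.
    """
    mask = _binarize_volume(v, smooth_sigma)
    if not mask.any():
        raise ValueError("empty foreground after binarization")
    # zero-pad so tubes crossing the stack border keep their centre line
    skel = skeletonize(np.pad(mask, 1))[1:-1, 1:-1, 1:-1]
    pts = np.argwhere(skel)
    if pts.shape[0] == 0:
        raise ValueError("skeletonization produced no centre line")
    edt = ndimage.distance_transform_edt(mask, sampling=v.voxel_size)
    radii = edt[tuple(pts.T)]
    neigh = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3, 3), dtype=np.int8),
                             mode="constant") - 1
    branch = np.nonzero(neigh[tuple(pts.T)] > 2)[0]
    depth = pts[:, 0] * v.voxel_size
    return VesselSkeleton(points=pts, radii=radii, depth=depth,
                         voxel_size=v.voxel_size, branch_points=branch,
                         volume_shape=v.data.shape)


def _skeleton_length_um(s: VesselSkeleton) -> float:
    """Total centre-line length: sum of unique 26-neighbour edge lengths."""
    pts = s.points
    occ = np.zeros(s.volume_shape, dtype=bool)
    occ[tuple(pts.T)] = True
    total = 0.0
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) > (0, 0, 0)]  # half the neighbourhood → each edge once
    for off in offsets:
        shifted = pts + off
        ok = np.all((shifted >= 0) & (shifted < np.asarray(s.volume_shape)), axis=1)
        hits = occ[tuple(shifted[ok].T)]
        total += hits.sum() * np.linalg.norm(off)
    return total * s.voxel_size


def capillary_density(s: VesselSkeleton, volume_um3: float | None = None,
                      units: str = "m/mm3") -> float:
    """Skeleton length per tissue volume.

    ``volume_um3`` defaults to the full stack volume.  ``units`` is
    ``"m/mm3"`` (the field's convention) or ``"um/um3"``.
    """
    if volume_um3 is None:
        volume_um3 = float(np.prod(s.volume_shape)) * s.voxel_size ** 3
    if volume_um3 <= 0:
        raise ValueError("tissue volume must be positive")
    dens = _skeleton_length_um(s) / volume_um3  # μm/μm³
    if units == "um/um3":
        return dens
    if units == "m/mm3":
        return dens * 1e3
    raise ValueError(f"unknown units {units!r}")


def diameter_depth_profile(s: VesselSkeleton, bin_um: float = 10.0):
    """Mean vessel diameter (2×radius) ± SEM per depth bin.

    Bins are half-open ``[low, high)``; empty bins report NaN, not zero.
    Returns a pandas DataFrame with columns
    ``depth_low, depth_high, mean_diameter, sem_diameter, n``.
    """
    import pandas as pd

    depth = s.depth
    diam = 2.0 * s.radii
    n_bins = int(np.ceil((depth.max() + 1e-9) / bin_um)) if depth.size else 0
    rows = []
    for b in range(max(n_bins, 1)):
        lo, hi = b * bin_um, (b + 1) * bin_um
        sel = (depth >= lo) & (depth < hi)
        n = int(sel.sum())
        if n == 0:
            rows.append((lo, hi, np.nan, np.nan, 0))
        else:
            d = diam[sel]
            sem = d.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append((lo, hi, d.mean(), sem, n))
    return pd.DataFrame(rows, columns=["depth_low", "depth_high",
                                       "mean_diameter", "sem_diameter", "n"])


def tissue_distance_distribution(v: Volume, substack_um: float = 100.0,
                                 n_substacks: int = 5, seed: int = 0,
                                 bin_um: float = 1.0,
                                 centile_ranks=(50, 60, 70, 80, 90, 95),
                                 smooth_sigma: float = 1.0,
                                 max_tries: int = 2000) -> DistanceDistribution:
    """Distribution of tissue (background) distances from the nearest vessel.

    The stack is smoothed and binarized, an exact Euclidean distance map of
    the background computed, and ``n_substacks`` non-overlapping cubic
    substacks of ``substack_um`` per side placed uniformly at random
    (seeded).  Histograms (fractions per ``bin_um`` bin) are averaged
    across substacks; centiles are computed from the pooled substack
    distances.
    """
    mask = _binarize_volume(v, smooth_sigma)
    edt = ndimage.distance_transform_edt(~mask, sampling=v.voxel_size)
    side = int(round(substack_um / v.voxel_size))
    shape = np.asarray(v.data.shape)
    if np.any(side > shape):
        raise ValueError("substack larger than the volume")
    rng = np.random.default_rng(seed)
    placed = []
    tries = 0
    while len(placed) < n_substacks:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_substacks} non-overlapping substacks")
        org = np.array([rng.integers(0, s - side + 1) for s in shape])
        if any(np.all(np.abs(org - o) < side) for o in placed):
            continue
        placed.append(org)
    pooled = []
    hists = []
    max_d = edt.max()
    edges = np.arange(0.0, max_d + 2 * bin_um, bin_um)
    for org in placed:
        sub = edt[org[0]:org[0] + side, org[1]:org[1] + side, org[2]:org[2] + side]
        submask = mask[org[0]:org[0] + side, org[1]:org[1] + side, org[2]:org[2] + side]
        d = sub[~submask]
        pooled.append(d)
        h, _ = np.histogram(d, bins=edges)
        hists.append(h / max(d.size, 1))
    hists = np.asarray(hists)
    pooled = np.concatenate(pooled) if pooled else np.empty(0)
    centiles = {r: (float(np.percentile(pooled, r)) if pooled.size else 0.0)
                for r in centile_ranks}
    return DistanceDistribution(
        bin_edges=edges,
        mean_counts=hists.mean(axis=0),
        sd_counts=hists.std(axis=0, ddof=1) if hists.shape[0] > 1 else np.zeros(edges.size - 1),
        centiles=centiles,
    )
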