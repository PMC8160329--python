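"""Capillary-to-tissue oxygen transport: dissociation-curve conversions and a
radial diffusion--consumption model.

The model treats a capillary of radius ``r_c`` supplying a coaxial tissue
annulus out to ``r_max`` (half the separation between neighbouring
capillaries).  Oxygen concentration ``C(r, t)`` obeys Fick diffusion in
cylindrical geometry with a Michaelis--Menten sink representing oxidative
phosphorylation::

    dC/dt = (1/r) d/dr ( r D dC/dr ) - Vmax * C / (C + Km)

with Dirichlet ``C(r_c) = C_cap`` (the capillary-edge oxygen concentration)
and a zero-flux condition at ``r_max``.  A thin capillary wall (basement
membrane) can act as a diffusion barrier: over ``[r_c, r_c + wall]`` the
diffusion coefficient is multiplied by ``wall_D_factor``.

Units at the API boundary follow the conventions of the experimental
literature: micrometres, seconds, micromolar, mmHg and mM/min.  Internally
the solver works in μm / s / μM, in which D = 9.24e-8 m²/min = 1540 μm²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

__all__ = [
    "DissociationParams",
    "HenryParams",
    "OxygenModelSpec",
    "OxygenProfile",
    "hill_saturation",
    "hill_inverse",
    "pressure_to_concentration",
    "solve_radial",
    "steady_profile",
    "time_to_steady",
    "calibrate_rmax",
    "centile_sweep",
    "inhibition_fractions",
]

MMHG_TO_PA = 133.322

# m²/min → μm²/s
_D_DEFAULT_UM2_S = 9.24e-8 * 1e12 / 60.0


@dataclass(frozen=True)
class DissociationParams:
    """Haemoglobin O2 dissociation curve (Hill form) for C57BL/6 mice.

    ``h`` is the Hill coefficient, ``p50`` the partial pressure [mmHg] at
    half saturation.
    """

    h: float = 2.59
    p50: float = 40.2

    def __post_init__(self) -> None:
        if self.h <= 0 or self.p50 <= 0:
            raise ValueError("Hill coefficient and P50 must be positive")


@dataclass(frozen=True)
class HenryParams:
    """Henry's-law solubility of O2 with van 't Hoff temperature scaling.

    ``kh_stp`` is the solubility at the reference temperature ``t0`` [K];
    the constant at body temperature ``t`` is
    ``kh_stp * exp(temp_factor * (1/t - 1/t0))``.
    """

    kh_stp: float = 1.3e-5  # mol/(m³·Pa)
    temp_factor: float = 1500.0  # K
    t: float = 310.15  # K (37 °C)
    t0: float = 298.15  # K

    def __post_init__(self) -> None:
        if min(self.kh_stp, self.temp_factor, self.t, self.t0) <= 0:
            raise ValueError("Henry parameters must be positive")

    @property
    def kh(self) -> float:
        """Solubility [mol/(m³·Pa)] at temperature ``t``."""
        return self.kh_stp * math.exp(self.temp_factor * (1.0 / self.t - 1.0 / self.t0))


def hill_saturation(po2, params: DissociationParams = DissociationParams()):
    """Haemoglobin saturation (fraction in [0, 1]) at partial pressure ``po2`` [mmHg]."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    num = np.power(po2, params.h)
    out = num / (num + params.p50 ** params.h)
    return float(out) if out.ndim == 0 else out


def hill_inverse(so2, params: DissociationParams = DissociationParams()):
    """Partial pressure [mmHg] at fractional saturation ``so2`` ∈ (0, 1)."""
    so2 = np.asarray(so2, dtype=float)
    if np.any(so2 <= 0) or np.any(so2 >= 1):
        raise ValueError("sO2 must lie strictly between 0 and 1")
    out = params.p50 * np.power(so2 / (1.0 - so2), 1.0 / params.h)
    return float(out) if out.ndim == 0 else out


def pressure_to_concentration(po2_mmhg, params: HenryParams = HenryParams()):
    """Dissolved O2 concentration [μM] for partial pressure [mmHg] at body temperature.

    mol/m³ equals mmol/L, so the Henry product converts directly to mM;
    the result is returned in μM.
    """
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    conc_mm = po2 * MMHG_TO_PA * params.kh  # mol/m³ == mM
    out = conc_mm * 1e3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OxygenModelSpec:
    """Parameters of the radial oxygen diffusion--consumption model.

    Attributes
    ----------
    c_cap : capillary-edge O2 concentration [μM] (Dirichlet boundary).
    r_c : capillary radius [μm].
    r_max : outer (zero-flux) boundary [μm]; half the capillary separation.
    wall : capillary wall thickness [μm] over which diffusion is hindered.
    wall_d_factor : multiplier on D inside the wall (0.6 = 40% reduction).
    d_um2_s : free diffusion coefficient of O2 in brain [μm²/s].
    km : Michaelis constant of oxidative phosphorylation [μM].
    vmax_mm_min : maximal consumption rate [mM/min].
    n_cells : number of finite-volume cells outside the wall.
    wall_cell : target cell size across the wall layer [μm].
    t_end : default time horizon for transient solves [s].
    """

    c_cap: float
    r_max: float
    vmax_mm_min: float
    r_c: float = 2.5
    wall: float = 0.2
    wall_d_factor: float = 0.6
    d_um2_s: float = _D_DEFAULT_UM2_S
    km: float = 1.0
    n_cells: int = 400
    wall_cell: float = 0.05
    t_end: float = 20.0

    def __post_init__(self) -> None:
        if self.c_cap < 0:
            raise ValueError("c_cap must be non-negative")
        if self.vmax_mm_min < 0:
            raise ValueError("Vmax must be non-negative")
        if not (self.r_c < self.r_c + self.wall < self.r_max):
            raise ValueError("need r_c < r_c + wall < r_max")
        if self.n_cells < 10:
            raise ValueError("grid too coarse")

    @property
    def vmax(self) -> float:
        """Vmax in μM/s."""
        return self.vmax_mm_min * 1e3 / 60.0


@dataclass
class OxygenProfile:
    """Steady (or instantaneous) radial oxygen field and derived consumption."""

    r: np.ndarray  # cell centres [μm]
    c: np.ndarray  # [μM]
    spec: OxygenModelSpec
    steady: bool = True

    @property
    def vo2_frac(self) -> np.ndarray:
        """Local consumption as a fraction of Vmax: C/(C+Km)."""
        return self.c / (self.c + self.spec.km)

    @property
    def midpoint_c(self) -> float:
        """[O2] at the outer boundary (midway between capillaries) [μM]."""
        return float(self.c[-1])

    @property
    def midpoint_vo2_frac(self) -> float:
        return float(self.c[-1] / (self.c[-1] + self.spec.km))


# ---------------------------------------------------------------------------
# finite-volume discretization


class _Grid:
    """Conservative finite-volume grid in r with refinement across the wall."""

    def __init__(self, spec: OxygenModelSpec):
        n_wall = max(2, int(round(spec.wall / spec.wall_cell)))
        faces_wall = np.linspace(spec.r_c, spec.r_c + spec.wall, n_wall + 1)
        faces_out = np.linspace(spec.r_c + spec.wall, spec.r_max, spec.n_cells + 1)
        self.faces = np.concatenate([faces_wall, faces_out[1:]])
        self.centers = 0.5 * (self.faces[:-1] + self.faces[1:])
        self.dr = np.diff(self.faces)
        # cell "volume" per unit axial length / 2π : ∫ r dr
        self.vol = 0.5 * (self.faces[1:] ** 2 - self.faces[:-1] ** 2)
        d = np.where(self.centers < spec.r_c + spec.wall,
                     spec.d_um2_s * spec.wall_d_factor, spec.d_um2_s)
        # interior faces: harmonic-mean conductance g = r_f * D_h / dx
        dist = self.centers[1:] - self.centers[:-1]
        d_h = 2.0 * d[:-1] * d[1:] / (d[:-1] + d[1:])
        self.g_int = self.faces[1:-1] * d_h / dist
        # capillary (Dirichlet) face: half-cell conductance
        self.g_in = self.faces[0] * d[0] / (self.centers[0] - self.faces[0])
        self.n = self.centers.size
        self.spec = spec

    def rhs(self, c: np.ndarray) -> np.ndarray:
        s = self.spec
        flux = np.empty(self.n + 1)  # r*D*dC/dr at faces (outward positive)
        flux[0] = self.g_in * (c[0] - s.c_cap)
        flux[1:-1] = self.g_int * (c[1:] - c[:-1])
        flux[-1] = 0.0
        cpos = np.maximum(c, 0.0)
        sink = s.vmax * cpos / (cpos + s.km)
        return (flux[1:] - flux[:-1]) / self.vol - sink

    def jac_banded(self, c: np.ndarray) -> np.ndarray:
        """Tridiagonal Jacobian of :meth:`rhs` in ``solve_banded`` layout."""
        s = self.spec
        n = self.n
        lower = np.zeros(n)
        diag = np.zeros(n)
        upper = np.zeros(n)
        diag[0] -= self.g_in / self.vol[0]
        diag[:-1] -= self.g_int / self.vol[:-1]
        upper[1:] = self.g_int / self.vol[:-1]
        diag[1:] -= self.g_int / self.vol[1:]
        lower[:-1] = self.g_int / self.vol[1:]
        cpos = np.maximum(c, 0.0)
        dsink = s.vmax * s.km / (cpos + s.km) ** 2
        dsink[c < 0] = 0.0
        diag -= dsink
        ab = np.zeros((3, n))
        ab[0, 1:] = upper[1:]
        ab[1] = diag
        ab[2, :-1] = lower[:-1]
        return ab

    def influx(self, c: np.ndarray) -> float:
        """O2 entering the tissue across the capillary face (per 2π·unit length)."""
        return -self.g_in * (c[0] - self.spec.c_cap)

    def consumption(self, c: np.ndarray) -> float:
        s = self.spec
        cpos = np.maximum(c, 0.0)
        return float(np.sum(s.vmax * cpos / (cpos + s.km) * self.vol))


def solve_radial(spec: OxygenModelSpec, t_eval=None):
    """Time-resolved solve of the radial model from ``C(r, 0) = 0``.

    Returns ``(r, t, C)`` with ``C`` of shape ``(len(t), len(r))``.
    Uses a stiff (BDF) method-of-lines integration of the conservative
    finite-volume semi-discretization.
    """
    grid = _Grid(spec)
    if t_eval is None:
        t_eval = np.linspace(0.0, spec.t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    def f(_t, c):
        return grid.rhs(c)

    def jac(_t, c):
        ab = grid.jac_banded(c)
        n = grid.n
        j = np.zeros((n, n))
        idx = np.arange(n)
        j[idx, idx] = ab[1]
        j[idx[:-1], idx[1:]] = ab[0, 1:]
        j[idx[1:], idx[:-1]] = ab[2, :-1]
        return j

    sol = solve_ivp(f, (0.0, float(t_eval[-1])), np.zeros(grid.n), method="BDF",
                    t_eval=t_eval, jac=jac, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"transient solve failed: {sol.message}")
    return grid.centers, sol.t, sol.y.T


def _newton_steady(grid: _Grid, c0: np.ndarray | None = None,
                   max_iter: int = 100) -> np.ndarray:
    spec = grid.spec
    scale = max(spec.c_cap, 1.0)
    c = np.full(grid.n, spec.c_cap) if c0 is None else c0.copy()
    for _ in range(max_iter):
        r = grid.rhs(c)
        ab = grid.jac_banded(c)
        step = solve_banded((1, 1), ab, -r)
        # damped update keeping concentrations out of the sink singularity
        lam = 1.0
        while not np.all(c + lam * step > -0.5 * spec.km):
            lam *= 0.5
            if lam < 1e-8:
                raise RuntimeError("Newton damping failed")
        c = c + lam * step
        if lam == 1.0 and np.max(np.abs(step)) < 1e-10 * scale:
            return np.maximum(c, 0.0)
    raise RuntimeError("steady-state Newton iteration did not converge")


def steady_profile(spec: OxygenModelSpec, method: str = "newton",
                   check_balance: bool = True) -> OxygenProfile:
    """Steady-state oxygen profile ``C(r)``.

    ``method`` is ``"newton"`` (damped Newton on the discrete steady
    equations; default) or ``"march"`` (stiff time integration until the
    relative change falls below 1e-6 per second) — the two agree and serve
    as mutual cross-checks.

    Every accepted solve is checked for mass balance: influx across the
    capillary wall must match total Michaelis--Menten consumption to 0.5%.
    """
    grid = _Grid(spec)
    if method == "newton":
        c = _newton_steady(grid)
    elif method == "march":
        c = _march_steady(grid)
    else:
        raise ValueError(f"unknown method {method!r}")
    if check_balance and spec.vmax > 0:
        influx = grid.influx(c)
        cons = grid.consumption(c)
        if cons > 0 and abs(influx - cons) / cons > 5e-3:
            raise RuntimeError(
                f"steady-state flux imbalance: influx={influx:.6g}, consumption={cons:.6g}")
    return OxygenProfile(r=grid.centers, c=c, spec=spec, steady=True)


def _march_steady(grid: _Grid, rel_rate_tol: float = 1e-6) -> np.ndarray:
    spec = grid.spec

    def f(_t, c):
        return grid.rhs(c)

    def jac(_t, c):
        ab = grid.jac_banded(c)
        n = grid.n
        j = np.zeros((n, n))
        idx = np.arange(n)
        j[idx, idx] = ab[1]
        j[idx[:-1], idx[1:]] = ab[0, 1:]
        j[idx[1:], idx[:-1]] = ab[2, :-1]
        return j

    t_end = spec.t_end
    c = np.zeros(grid.n)
    for _ in range(8):
        sol = solve_ivp(f, (0.0, t_end), c, method="BDF", jac=jac,
                        rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise RuntimeError(f"time march failed: {sol.message}")
        c = sol.y[:, -1]
        rate = np.max(np.abs(grid.rhs(c))) / max(np.max(np.abs(c)), 1e-12)
        if rate < rel_rate_tol:
            return np.maximum(c, 0.0)
        t_end *= 2
    raise RuntimeError("time march did not reach steady state")


def time_to_steady(spec: OxygenModelSpec, tol: float = 0.01) -> float:
    """First time after which midpoint [O2] stays within ``tol`` of its steady value.

    The model is integrated from zero initial oxygen; the midpoint is the
    outer-boundary cell (midway between capillaries).
    """
    steady = steady_profile(spec)
    target = steady.midpoint_c
    if target <= 0:
        raise ValueError("steady midpoint concentration is zero; tolerance undefined")
    t_eval = np.linspace(0.0, spec.t_end, max(400, int(spec.t_end * 50)))
    _, t, c = solve_radial(spec, t_eval=t_eval)
    mid = c[:, -1]
    within = np.abs(mid - target) <= tol * target
    if not within[-1]:
        raise RuntimeError("horizon too short: midpoint not settled by t_end")
    # last index where it was outside tolerance
    outside = np.nonzero(~within)[0]
    if outside.size == 0:
        return float(t[0])
    return float(t[outside[-1] + 1])


def calibrate_rmax(spec_template: OxygenModelSpec, target_midpoint_vo2_frac: float,
                   bracket: tuple[float, float] = (None, 100.0),
                   tol_um: float = 0.05) -> float:
    """Outer radius at which the steady midpoint VO2 fraction equals the target.

    Midpoint VO2/Vmax decreases monotonically with ``r_max`` (a larger tissue
    annulus starves its far edge), so bisection applies.  ``spec_template``'s
    own ``r_max`` is ignored.
    """
    if not (0.0 < target_midpoint_vo2_frac < 1.0):
        raise ValueError("target must lie in (0, 1)")
    lo = bracket[0] if bracket[0] is not None else spec_template.r_c + 1.0
    hi = bracket[1]

    def mid_frac(r_max: float) -> float:
        return steady_profile(replace(spec_template, r_max=r_max)).midpoint_vo2_frac

    f_lo, f_hi = mid_frac(lo), mid_frac(hi)
    if not (f_hi <= target_midpoint_vo2_frac <= f_lo):
        raise ValueError(
            f"target {target_midpoint_vo2_frac} not bracketed by r_max in "
            f"[{lo}, {hi}] (VO2 frac range [{f_hi:.4f}, {f_lo:.4f}])")
    while hi - lo > tol_um:
        mid = 0.5 * (lo + hi)
        if mid_frac(mid) >= target_midpoint_vo2_frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def centile_sweep(spec_template: OxygenModelSpec, spacings) -> "pd.DataFrame":
    """Steady midpoint metrics for a list of capillary separations [μm].

    Each spacing is a centre-to-centre capillary separation; the solve uses
    ``r_max = spacing`` following the convention that the printed separation
    equals the model's outer radius.  Returns a DataFrame with columns
    ``spacing, midpoint_c, midpoint_vo2_frac``.
    """
    import pandas as pd

    spacings = np.asarray(spacings, dtype=float)
    if spacings.size and (np.any(spacings <= 0) or np.any(np.diff(spacings) <= 0)):
        raise ValueError("spacings must be positive and strictly ascending")
    rows = []
    for sp in spacings:
        prof = steady_profile(replace(spec_template, r_max=float(sp)))
        rows.append({"spacing": float(sp), "midpoint_c": prof.midpoint_c,
                     "midpoint_vo2_frac": prof.midpoint_vo2_frac})
    return pd.DataFrame(rows)


def inhibition_fractions(sweep, distances, thresholds=(0.10, 0.20)) -> dict:
    """Tissue fractions in which consumption is inhibited by at least each threshold.

    ``sweep`` is a :func:`centile_sweep` table mapping capillary spacing to
    midpoint VO2 fraction; ``distances`` are per-voxel tissue distances from
    the nearest capillary [μm] (a spacing of twice the distance is assumed,
    matching the sweep convention).  VO2 fraction is interpolated over the
    distance distribution and the fraction of tissue with inhibition
    ``1 - VO2_frac >= threshold`` is reported per threshold.
    """
    distances = np.asarray(distances, dtype=float)
    sp = np.asarray(sweep["spacing"], dtype=float)
    frac = np.asarray(sweep["midpoint_vo2_frac"], dtype=float)
    eq_spacing = 2.0 * distances
    if eq_spacing.size and eq_spacing.max() > sp.max() + 1e-9:
        raise ValueError("distance distribution extends beyond the sweep's spacing range")
    # tissue closer than the smallest swept spacing is at least as oxygenated;
    # np.interp clamps to the first row, which is conservative in that direction
    vo2 = np.interp(eq_spacing, sp, frac)
    inhib = 1.0 - vo2
    return {float(th): float(np.mean(inhib >= th)) for th in thresholds}
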