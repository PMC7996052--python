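"""Radial advection–diffusion–reaction phosphate uptake.

Each root (and root-hair) segment owns a cylindrical soil domain
``r0 ≤ r ≤ r1`` with the buffered diffusion equation

    b ∂C/∂t = (1/r) ∂/∂r ( r·De·b·∂C/∂r + r·v(r)·C ),   v(r) = v0·r0/r,

a Michaelis–Menten influx boundary at the segment surface,

    De·b·∂C/∂r|_{r0} = Imax (C − Cmin)/(Km + C − Cmin),

and zero flux at the outer radius r1 (half the local mean inter-root
distance).  C is the solution concentration (µmol mL⁻¹), b the buffer
power, De the effective diffusivity (cm² day⁻¹); advection defaults off
(v0 = 0; no transpiration-driven mass flow is modelled).

The discretization is conservative finite volumes on a logarithmic grid
(dense near the uptake surface) with implicit time stepping and Picard
iteration on the nonlinear boundary, so discrete mass balance holds to
linear-solver precision at every step.

Because the soil starts homogeneous and every new segment owns a fresh,
non-interacting domain, the cumulative uptake per cm of segment depends
only on segment age, radius and outer radius.  The system-level integrator
therefore solves one representative domain per (class, outer-radius) pair
and convolves its per-age uptake with the length-birth histogram of the
architecture — numerically identical to solving a domain per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .architecture import RootSystem, length_birth_histogram
from .params import CLASS_IDS, P_MOLAR_MASS_UG, Params, SoilP

__all__ = [
    "mm_influx", "RadialDomain", "step_radial", "solve_domain_series",
    "system_uptake", "uptake_from_histogram", "UptakeResult",
    "uptake_per_length", "calibrate_imax", "depletion_overlap",
    "hair_outer_radius", "outer_radii_by_class",
]


def mm_influx(c_surface, soil: SoilP):
    """Michaelis–Menten influx (µmol cm⁻² day⁻¹) at surface concentration C.

    influx = Imax·(C − Cmin)/(Km + C − Cmin), zero for C ≤ Cmin.
    """
    c = np.asarray(c_surface, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    x = np.clip(c - soil.cmin, 0.0, None)
    out = soil.imax * x / (soil.km + x)
    return float(out) if out.ndim == 0 else out


@dataclass
class RadialDomain:
    """State of one cylindrical soil domain (per cm of axis)."""

    r0: float
    r1: float
    soil: SoilP
    n_nodes: int = 40
    faces: np.ndarray = field(init=False)
    r: np.ndarray = field(init=False)      # cell centers
    vol: np.ndarray = field(init=False)    # annulus area per cm (cm²)
    C: np.ndarray = field(init=False)      # solution concentration
    c_init: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.r0 < self.r1):
            raise ValueError("need 0 < r0 < r1")
        self.faces = np.geomspace(self.r0, self.r1, self.n_nodes + 1)
        self.r = np.sqrt(self.faces[:-1] * self.faces[1:])
        self.vol = np.pi * (self.faces[1:] ** 2 - self.faces[:-1] ** 2)
        self.c_init = self.soil.c_solution_init
        self.C = np.full(self.n_nodes, self.c_init)

    @property
    def soil_p_per_cm(self) -> float:
        """Dissolved + buffered P in the domain, µmol per cm of axis."""
        return float(self.soil.buffer_power * (self.C * self.vol).sum())

    @property
    def depletion(self) -> float:
        """P removed from the domain since initialization (µmol cm⁻¹)."""
        return float(self.soil.buffer_power
                     * ((self.c_init - self.C) * self.vol).sum())

    def depletion_radius(self, threshold: float = 0.05) -> float:
        """Outer edge of the depletion zone: largest r where the draw-down
        C0 − C(r) still exceeds ``threshold`` × the surface draw-down."""
        draw = self.c_init - self.C
        if draw[0] <= 0:
            return self.r0
        rel = draw / draw[0]
        idx = np.nonzero(rel >= threshold)[0]
        if idx.size == 0:
            return self.r0
        i = idx[-1]
        if i == len(self.r) - 1:
            return self.r1
        # interpolate between node i and i+1
        f = (threshold - rel[i]) / (rel[i + 1] - rel[i])
        return float(self.r[i] + f * (self.r[i + 1] - self.r[i]))


def step_radial(domain: RadialDomain, dt: float, outer: str = "noflux",
                tol: float = 1e-10, max_iter: int = 60
                ) -> float:
    """Advance the domain one implicit step; return uptake (µmol cm⁻¹).

    Picard iteration on the Michaelis–Menten boundary flux; conservative
    finite volumes guarantee that the P removed from the soil equals the
    uptake through the inner surface at machine precision.
    """
    if dt <= 0 or dt > 0.2 + 1e-12:
        raise ValueError("dt must be in (0, 0.2]")
    soil = domain.soil
    r, faces, vol = domain.r, domain.faces, domain.vol
    n = domain.n_nodes
    b, de = soil.buffer_power, soil.de

    # interface conductances (per cm of axis, per unit concentration)
    g_int = 2.0 * np.pi * faces[1:-1] * de * b / np.diff(r)

    # advection (optional, inward for v0 > 0), upwind from the outer cell
    adv = np.zeros(n - 1)
    if soil.v0 != 0.0:
        v_face = soil.v0 * domain.r0 / faces[1:-1]
        adv = 2.0 * np.pi * faces[1:-1] * v_face

    storage = b * vol / dt

    lower = np.zeros(n)
    diag = storage.copy()
    upper = np.zeros(n)
    diag[:-1] += g_int
    diag[1:] += g_int
    upper[1:] = -g_int          # coefficient of C[i+1] in row i
    lower[:-1] = -g_int         # coefficient of C[i-1] in row i+1
    if soil.v0 != 0.0:
        # inward advection moves mass from cell i+1 into cell i
        diag[1:] += adv
        upper[1:] += -adv
    g_outer = 0.0
    if outer == "fixed":
        g_outer = 2.0 * np.pi * faces[-1] * de * b / (faces[-1] - r[-1])
        diag[-1] += g_outer
    elif outer != "noflux":
        raise ValueError("outer must be 'noflux' or 'fixed'")

    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]

    c_old = domain.C
    area0 = 2.0 * np.pi * domain.r0
    # Newton-linearized Michaelis-Menten boundary: influx(C) is expanded
    # about c_star and the slope goes on the matrix diagonal, which keeps
    # the step implicit in the flux (stable at large Imax).
    c_star = float(c_old[0])
    flux = 0.0
    for _ in range(max_iter):
        x = max(c_star - soil.cmin, 0.0)
        g0 = soil.imax * x / (soil.km + x)
        gp = soil.imax * soil.km / (soil.km + x) ** 2
        ab0 = ab.copy()
        ab0[1, 0] += area0 * gp
        rhs = storage * c_old
        rhs[0] -= area0 * (g0 - gp * c_star)
        if outer == "fixed":
            rhs[-1] += g_outer * domain.c_init
        c_new = solve_banded((1, 1), ab0, rhs)
        flux = g0 + gp * (float(c_new[0]) - c_star)
        if abs(float(c_new[0]) - c_star) < tol:
            break
        c_star = max(float(c_new[0]), 0.0)
    domain.C = c_new
    return float(flux * area0 * dt)


@dataclass
class DomainSeries:
    """Per-age uptake of one representative domain."""

    r0: float
    r1: float
    dt: float
    uptake: np.ndarray          # µmol cm⁻¹ per step (age-indexed)
    depletion: np.ndarray       # profile-integrated removal after each step
    final: RadialDomain
    mass_balance_rel: float     # max |depletion − Σ uptake| / Σ uptake
    profiles: np.ndarray | None = None
    depletion_radii: np.ndarray | None = None

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.uptake)


def solve_domain_series(r0: float, r1: float, soil: SoilP, horizon: float,
                        dt: float = 0.2, n_nodes: int = 40,
                        store_profiles: bool = False,
                        tol: float = 1e-10) -> DomainSeries:
    """Solve one fresh domain over ``horizon`` days; per-step uptake series."""
    dom = RadialDomain(r0=r0, r1=r1, soil=soil, n_nodes=n_nodes)
    n_steps = int(np.ceil(horizon / dt - 1e-9))
    uptake = np.zeros(n_steps)
    depletion = np.zeros(n_steps)
    profiles = np.zeros((n_steps, n_nodes)) if store_profiles else None
    radii = np.zeros(n_steps) if store_profiles else None
    for k in range(n_steps):
        step = min(dt, horizon - k * dt)
        uptake[k] = step_radial(dom, step, tol=tol)
        depletion[k] = dom.depletion
        if store_profiles:
            profiles[k] = dom.C
            radii[k] = dom.depletion_radius()
    cum = np.cumsum(uptake)
    denom = max(cum[-1], 1e-300)
    mbr = float(np.max(np.abs(depletion - cum)) / denom)
    return DomainSeries(r0=r0, r1=r1, dt=dt, uptake=uptake,
                        depletion=depletion, final=dom,
                        mass_balance_rel=mbr, profiles=profiles,
                        depletion_radii=radii)


# ---------------------------------------------------------------------------
# outer radii
# ---------------------------------------------------------------------------

def hair_outer_radius(root_diameter: float, max_density: float,
                      hair_diameter: float = 0.0005) -> float:
    """Outer radius of a hair's soil cylinder: half the mean spacing
    between hairs on the host surface (area per hair = 2π·r_root/density)."""
    r_root = root_diameter / 2.0
    spacing = np.sqrt(2.0 * np.pi * r_root / max_density)
    return max(0.5 * spacing, 3.0 * hair_diameter / 2.0)


def outer_radii_by_class(system: RootSystem, at: float | None = None,
                         voxel: float = 1.0, floor: float = 0.2,
                         cap: float = 2.0) -> dict[str, float]:
    """Per-class outer domain radius from local root-length density.

    Root length is binned into ``voxel`` cm³ voxels; each piece's local
    half inter-root distance is 1/sqrt(π·RLD); the class value is the
    length-weighted mean, clipped to [floor, cap].
    """
    at = system.clock if at is None else at
    cloud = system.segment_cloud(at, max_piece=1.0)
    if len(cloud) == 0:
        return {c: cap for c in CLASS_IDS}
    key = (np.floor(cloud[["x", "y", "z"]].to_numpy() / voxel)).astype(np.int64)
    # hash voxel indices
    h = key[:, 0] * 73856093 ^ key[:, 1] * 19349663 ^ key[:, 2] * 83492791
    import pandas as pd
    df = cloud.assign(vox=h)
    rld = df.groupby("vox")["length"].transform("sum") / voxel
    r_half = 1.0 / np.sqrt(np.pi * np.maximum(rld, 1e-9))
    df = df.assign(r_half=np.clip(r_half, floor, cap))
    out = {}
    for c in CLASS_IDS:
        sub = df[df["class_id"] == c]
        if len(sub) == 0:
            out[c] = cap
        else:
            out[c] = float(np.average(sub["r_half"], weights=sub["length"]))
    return out


# ---------------------------------------------------------------------------
# system-level integration
# ---------------------------------------------------------------------------

@dataclass
class UptakeResult:
    """Cumulative P uptake of a root system, per class and structure."""

    times: np.ndarray                        # bin right edges (days)
    root_uptake: dict[str, np.ndarray]       # µmol, cumulative, per class
    hair_uptake: dict[str, np.ndarray]       # µmol, cumulative, per host class
    conservation_rel: float                  # global mass-balance residual
    series: dict = field(default_factory=dict)  # representative DomainSeries

    def plant_p_ug(self, day: float | None = None) -> float:
        """Total plant P content (µg) at ``day`` (default: end of run)."""
        total = sum(self.root_uptake.values()) + sum(self.hair_uptake.values())
        if day is None:
            return float(total[-1] * P_MOLAR_MASS_UG)
        return float(np.interp(day, self.times, total) * P_MOLAR_MASS_UG)

    def per_class_ug(self, day: float | None = None) -> dict[str, float]:
        """Per-class root-surface uptake plus a pooled 'hairs' entry (µg)."""
        out = {}
        for c, arr in self.root_uptake.items():
            v = arr[-1] if day is None else np.interp(day, self.times, arr)
            out[c] = float(v * P_MOLAR_MASS_UG)
        hair_total = sum(self.hair_uptake.values())
        v = hair_total[-1] if day is None else np.interp(day, self.times, hair_total)
        out["hairs"] = float(v * P_MOLAR_MASS_UG)
        return out

    def daily_uptake_ug(self, day: float, window: float = 1.0
                        ) -> dict[str, float]:
        """Uptake rate (µg day⁻¹) around ``day``, per class + hairs."""
        a = self.per_class_ug(day)
        b = self.per_class_ug(day - window)
        return {k: (a[k] - b[k]) / window for k in a}


def _convolve_cumulative(hist: np.ndarray, per_age: np.ndarray) -> np.ndarray:
    inc = np.convolve(hist, per_age)[: len(hist)]
    return np.cumsum(inc)


def uptake_from_histogram(edges: np.ndarray, hist: dict[str, np.ndarray],
                          params: Params, r1_by_class: dict[str, float],
                          include_hairs: bool = True,
                          dt: float | None = None,
                          n_nodes: int | None = None,
                          soil: SoilP | None = None) -> UptakeResult:
    """Integrate uptake for a length-birth histogram (cm per bin per class).

    This is the core engine behind :func:`system_uptake`; it is also used
    directly for the hypothetical single-class systems of the cost-recovery
    analysis.
    """
    soil = params.soil if soil is None else soil
    dt = params.sim.max_step if dt is None else dt
    n_nodes = params.sim.radial_nodes if n_nodes is None else n_nodes
    horizon = float(edges[-1])
    n_bins = len(edges) - 1
    mid_birth = 0.5 * (edges[:-1] + edges[1:])
    root_uptake: dict[str, np.ndarray] = {}
    hair_uptake: dict[str, np.ndarray] = {}
    series: dict = {}
    cons_plant = 0.0
    cons_soil = 0.0
    for c in CLASS_IDS:
        h = hist.get(c)
        if h is None:
            continue
        p = params.classes[c]
        ser = solve_domain_series(p.diameter / 2.0, r1_by_class[c], soil,
                                  horizon, dt=dt, n_nodes=n_nodes,
                                  tol=params.sim.solver_tol)
        series[c] = ser
        root_uptake[c] = _convolve_cumulative(h, ser.uptake)
        cons_plant += root_uptake[c][-1]
        # soil-side depletion: length born in bin k has final age n_bins-1-k
        ages = np.clip(n_bins - 1 - np.arange(n_bins), 0, len(ser.depletion) - 1)
        cons_soil += float((h * ser.depletion[ages]).sum())

        if include_hairs and p.hair.max_density > 0 and p.hair.length > 0:
            hp = p.hair
            r1h = hair_outer_radius(p.diameter, hp.max_density, hp.diameter)
            serh = solve_domain_series(hp.diameter / 2.0, r1h, soil, horizon,
                                       dt=dt, n_nodes=n_nodes,
                                       tol=params.sim.solver_tol)
            series[c + "_hair"] = serh
            age_mid = (np.arange(n_bins) + 0.5) * dt
            dens = hp.density(age_mid)              # hairs per cm, by age
            per_age = dens * hp.length * serh.uptake
            hair_uptake[c] = _convolve_cumulative(h, per_age)
            cons_plant += hair_uptake[c][-1]
            # dying hairs freeze their domains: soil-side accounting by
            # summation over death times (equivalent by parts)
            # dying hairs freeze their domains at their death-age profile;
            # survivors carry the final-age profile (summation by parts)
            dep = serh.depletion
            dep_per_cm = np.zeros(n_bins)
            for k in range(n_bins):
                d_k = dens[: n_bins - k]
                w = d_k - np.append(d_k[1:], 0.0)
                dep_per_cm[k] = float((w * dep[: n_bins - k]).sum()) * hp.length
            cons_soil += float((h * dep_per_cm).sum())
        elif include_hairs:
            hair_uptake[c] = np.zeros(n_bins)
    if not include_hairs:
        hair_uptake = {c: np.zeros(n_bins) for c in root_uptake}
    denom = max(cons_plant, 1e-300)
    return UptakeResult(times=edges[1:], root_uptake=root_uptake,
                        hair_uptake=hair_uptake,
                        conservation_rel=abs(cons_soil - cons_plant) / denom,
                        series=series)


def system_uptake(system: RootSystem, at: float | None = None,
                  include_hairs: bool = True, dt: float | None = None,
                  n_nodes: int | None = None, soil: SoilP | None = None,
                  params: Params | None = None) -> UptakeResult:
    """P uptake of a grown root system up to day ``at`` (default: clock).

    The soil starts homogeneous; every segment (and hair) owns a fresh
    radial domain created at its birth.  ``params`` overrides the system's
    own parameter set for the uptake stage (used by the sensitivity scan to
    perturb hair or soil parameters without regrowing the architecture,
    which they do not affect).
    """
    params = system.params if params is None else params
    at = system.clock if at is None else at
    edges, hist = length_birth_histogram(system, at, step=dt)
    r1 = outer_radii_by_class(system, at)
    return uptake_from_histogram(edges, hist, params, r1,
                                 include_hairs=include_hairs, dt=dt,
                                 n_nodes=n_nodes, soil=soil)


def uptake_per_length(result: UptakeResult, system: RootSystem,
                      at: float | None = None) -> float:
    """Plant P content per root length (µg m⁻¹); hairs are not part of the
    denominator."""
    at = system.clock if at is None else at
    length_m = system.total_length(at) / 100.0
    if length_m <= 0:
        raise ValueError("total root length is zero")
    return result.plant_p_ug(at) / length_m


def calibrate_imax(params: Params, seed: int = 20210312,
                   target_ug: float = 774.3, day: float = 31.0,
                   rel_tol: float = 1e-3, lo: float = 1e-5, hi: float = 50.0,
                   n_nodes: int | None = None) -> float:
    """Bisect Imax so the day-``day`` plant P content hits ``target_ug``.

    Grows one reference architecture and re-evaluates uptake only; returns
    the calibrated Imax (µmol cm⁻² day⁻¹).
    """
    from .architecture import grow

    system = grow(params, seed=seed, horizon=day)

    def content(imax: float) -> float:
        import dataclasses as dc
        soil = dc.replace(params.soil, imax=imax)
        res = system_uptake(system, at=day, soil=soil, n_nodes=n_nodes)
        return res.plant_p_ug(day)

    f_lo, f_hi = content(lo) - target_ug, content(hi) - target_ug
    if f_lo > 0 or f_hi < 0:
        raise RuntimeError("calibration target not bracketed by [lo, hi]")
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        f_mid = content(mid) - target_ug
        if abs(f_mid) / target_ug < rel_tol:
            return float(mid)
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# depletion-zone overlap diagnostic
# ---------------------------------------------------------------------------

def _segseg_distance(p0, d0, l0, p1, d1, l1):
    """Min distance between segment pairs (vectorized, Lumelsky)."""
    # segments: p + t*d*l, t in [0,1], d unit
    u = d0 * l0[:, None]
    v = d1 * l1[:, None]
    w0 = p0 - p1
    a = (u * u).sum(1)
    b = (u * v).sum(1)
    c = (v * v).sum(1)
    d = (u * w0).sum(1)
    e = (v * w0).sum(1)
    den = a * c - b * b
    sc = np.where(den > 1e-12, (b * e - c * d) / np.where(den > 1e-12, den, 1.0), 0.0)
    sc = np.clip(sc, 0.0, 1.0)
    tc = np.where(c > 1e-12, (e + b * sc) / np.where(c > 1e-12, c, 1.0), 0.0)
    tc = np.clip(tc, 0.0, 1.0)
    sc = np.where(a > 1e-12, np.clip((b * tc - d) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0), sc)
    diff = w0 + u * sc[:, None] - v * tc[:, None]
    return np.sqrt((diff * diff).sum(1))


def depletion_overlap(system: RootSystem, at: float | None = None,
                      n_nodes: int | None = None, max_piece: float = 1.0
                      ) -> float:
    """Fraction of root length whose depletion zone intersects another
    root's depletion zone.

    Depletion radii come from the representative radial profiles (5%
    draw-down edge) at each segment's age.  Pairs on the same axis and
    parent–child pairs are excluded: a lateral always touches its parent at
    the junction, which says nothing about competition between roots
    exploring the same soil.
    """
    params = system.params
    at = system.clock if at is None else at
    n_nodes = params.sim.radial_nodes if n_nodes is None else n_nodes
    r1 = outer_radii_by_class(system, at)
    dt = params.sim.max_step
    radii_by_class = {}
    for c in CLASS_IDS:
        ser = solve_domain_series(params.classes[c].diameter / 2.0, r1[c],
                                  params.soil, at, dt=dt, n_nodes=n_nodes,
                                  store_profiles=True)
        radii_by_class[c] = ser.depletion_radii
    cloud = system.segment_cloud(at, max_piece=max_piece)
    if len(cloud) == 0:
        return 0.0
    age_idx = np.clip(((at - cloud["birth"].to_numpy()) / dt).astype(int),
                      0, None)
    rd = np.empty(len(cloud))
    for c in CLASS_IDS:
        m = (cloud["class_id"] == c).to_numpy()
        if m.any():
            arr = radii_by_class[c]
            rd[m] = arr[np.clip(age_idx[m], 0, len(arr) - 1)]
    mids = cloud[["x", "y", "z"]].to_numpy()
    dirs = cloud[["dx", "dy", "dz"]].to_numpy()
    lens = cloud["length"].to_numpy()
    p0 = mids - 0.5 * lens[:, None] * dirs
    axis_id = cloud["axis_id"].to_numpy()
    parent = cloud["parent_axis"].to_numpy()

    cell = max_piece + 2.0 * float(rd.max())
    key = np.floor(mids / cell).astype(np.int64)
    from collections import defaultdict
    buckets: dict[tuple, list] = defaultdict(list)
    for i, k in enumerate(map(tuple, key)):
        buckets[k].append(i)

    overlapped = np.zeros(len(cloud), dtype=bool)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    for k, idx in buckets.items():
        neigh = []
        for off in offsets:
            nb = buckets.get((k[0] + off[0], k[1] + off[1], k[2] + off[2]))
            if nb:
                neigh.extend(nb)
        if len(neigh) < 2:
            continue
        ii = np.asarray(idx)
        jj = np.asarray(neigh)
        I, J = np.meshgrid(ii, jj, indexing="ij")
        I, J = I.ravel(), J.ravel()
        m = I < J
        m &= axis_id[I] != axis_id[J]
        m &= parent[I] != axis_id[J]
        m &= parent[J] != axis_id[I]
        I, J = I[m], J[m]
        if len(I) == 0:
            continue
        dist = _segseg_distance(p0[I], dirs[I], lens[I], p0[J], dirs[J], lens[J])
        hit = dist < rd[I] + rd[J]
        overlapped[I[hit]] = True
        overlapped[J[hit]] = True
    total = lens.sum()
    return float(lens[overlapped].sum() / total) if total > 0 else 0.0
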