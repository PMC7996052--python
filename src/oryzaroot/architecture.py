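"""Stochastic 3D root-system growth engine.

The root system is a collection of axes.  Main axes (the primary root and
the three nodal-root classes) emerge from the seed/hypocotyl point at the
origin and are integrated step by step: at each step the tip extends along
its heading, the heading is updated by the tropism vector (gravitropism +
bounded random impedance), and a vertex is dropped behind the tip.  Lateral
axes (L-type and S-type) are emitted perpendicular to their parent at
IBD-sampled arc positions and grow straight along their emission heading
(laterals carry no gravitropism; upward headings are corrected to
horizontal — the "cannot grow up" rule), which makes their geometry a
closed form of axis age and keeps systems with thousands of S-type roots
cheap to evaluate.

Coordinates are right-handed with depth positive downward; the soil
surface is z = 0 and the seed sits at the origin.  Root growth angles are
measured from the horizontal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .params import (CLASS_IDS, LATERAL_CLASSES, MAIN_CLASSES, Params,
                     RootClassParams, TruncNorm)

__all__ = [
    "RootSystem", "MainAxis", "grow", "advance", "initial_angle",
    "tropism_update", "sample_ibd", "nodal_emergence_times",
    "class_geometry", "length_birth_histogram",
]

_DOWN = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# headings and tropism
# ---------------------------------------------------------------------------

def initial_angle(class_id: str, params: Params, rng: np.random.Generator) -> np.ndarray:
    """Initial unit heading of a main axis.

    The primary root points straight down.  Nodal roots sample a root
    growth angle (degrees from the horizontal surface) from a scaled Beta
    distribution on [8°, 90°] with mode ≈ 28° and P(angle ≤ 45°) = 0.62,
    and a uniform azimuth.
    """
    if class_id == "primary":
        return _DOWN.copy()
    if class_id not in MAIN_CLASSES:
        raise ValueError(f"initial_angle is for main axes, got {class_id!r}")
    sim = params.sim
    rga = sim.rga_lo + (sim.rga_hi - sim.rga_lo) * rng.beta(sim.rga_beta_a, sim.rga_beta_b)
    theta = np.deg2rad(rga)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta) * np.cos(phi),
                     np.cos(theta) * np.sin(phi),
                     np.sin(theta)])


def _cannot_grow_up(heading: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Correct an upward heading (negative depth component) to horizontal."""
    if heading[2] >= 0:
        return heading
    h = heading.copy()
    h[2] = 0.0
    n = np.linalg.norm(h)
    if n < 1e-12:  # was pointing straight up: pick a random horizontal
        phi = rng.uniform(0.0, 2.0 * np.pi)
        return np.array([np.cos(phi), np.sin(phi), 0.0])
    return h / n


def tropism_update(heading: np.ndarray, class_params: RootClassParams,
                   depth: float, rng: np.random.Generator, dt: float,
                   step_length: float | None = None,
                   impedance_scale: float = 0.08) -> np.ndarray:
    """One tropism step: gravitropism + bounded random impedance.

    The gravitropism parameter is the published per-class value (cm/cm/day,
    negative = downward pull); it deflects the heading toward vertical in
    proportion to the length grown during the step.  The random impedance
    adds an isotropic perturbation of magnitude ``impedance_scale``·sqrt(dt).
    The result is re-normalized; laterals are additionally corrected by the
    cannot-grow-up rule.
    """
    heading = np.asarray(heading, dtype=float)
    n = np.linalg.norm(heading)
    if n < 1e-12:
        raise ValueError("heading must be non-zero")
    h = heading / n
    if step_length is None:
        step_length = dt
    g = class_params.gravitropism
    h = h + (-g) * step_length * _DOWN
    if impedance_scale > 0 and dt > 0:
        u = rng.normal(size=3)
        nu = np.linalg.norm(u)
        if nu > 1e-12:
            h = h + impedance_scale * np.sqrt(dt) * u / nu
    n = np.linalg.norm(h)
    if n < 1e-12:
        h, n = _DOWN.copy(), 1.0
    h = h / n
    if class_params.class_id in LATERAL_CLASSES:
        h = _cannot_grow_up(h, rng)
    return h


def _perpendicular(tangent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vector perpendicular to ``tangent`` at a uniform radial angle."""
    t = tangent / np.linalg.norm(tangent)
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, a)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * u + np.sin(phi) * v


# ---------------------------------------------------------------------------
# IBD sampling
# ---------------------------------------------------------------------------

def sample_ibd(params: Params, parent_class: str, child_class: str,
               position_on_parent: float, clock: float,
               rng: np.random.Generator) -> float:
    """Draw the distance to the next child primordium (cm).

    The parent-class specific truncated-normal is scaled by the fast-nodal
    schedule: fast nodal roots roughly double their IBD during the first
    two weeks of system development and branch ever more sparsely with
    distance from the base thereafter (their basal halves are the densest).
    """
    pc = params.classes[parent_class]
    if child_class not in pc.ibd_by_child:
        raise ValueError(f"{child_class!r} cannot branch on {parent_class!r}")
    dist: TruncNorm = pc.ibd_by_child[child_class]
    mult = 1.0
    if parent_class == "nodal_fast":
        if clock < 14.0:
            mult = 2.0
        else:
            mult = 1.0 + position_on_parent / pc.max_length
    return float(dist.sample(rng)) * mult


def _ibd_sequence(params: Params, parent_class: str, child_class: str,
                  total_length: float, birth: float,
                  curve: GrowthCurve, multiplier: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Arc positions and birth times of all children along one parent axis.

    The first primordium sits one IBD behind the base.  Birth times follow
    from inverting the parent's elongation curve (a primordium is formed
    when the parent tip passes its position).
    """
    positions = []
    s = 0.0
    while True:
        t_here = birth + float(curve.inverse_cumulative(s, multiplier))
        s += sample_ibd(params, parent_class, child_class, s, t_here, rng)
        if s >= total_length:
            break
        positions.append(s)
    positions = np.asarray(positions)
    if positions.size == 0:
        return positions, positions
    births = birth + np.asarray(curve.inverse_cumulative(positions, multiplier))
    return positions, births


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------

@dataclass
class MainAxis:
    """A stepwise-integrated axis (primary or nodal root)."""

    axis_id: int
    class_id: str
    birth: float
    multiplier: float
    curve: GrowthCurve
    heading: np.ndarray
    points: list = field(default_factory=list)   # polyline vertices
    times: list = field(default_factory=list)    # vertex creation days
    arc: list = field(default_factory=list)      # cumulative arc length (cm)
    next_branch_arc: dict = field(default_factory=dict)  # child -> arc (cm)

    def length(self, at: float) -> float:
        if at < self.birth:
            return 0.0
        return float(self.curve.cumulative(at - self.birth, self.multiplier))

    def position_at_arc(self, s: float) -> np.ndarray:
        arc = np.asarray(self.arc)
        pts = np.asarray(self.points)
        s = min(max(s, 0.0), arc[-1])
        i = int(np.searchsorted(arc, s))
        if i == 0:
            return pts[0].copy()
        f = (s - arc[i - 1]) / max(arc[i] - arc[i - 1], 1e-12)
        return pts[i - 1] + f * (pts[i] - pts[i - 1])

    def tangent_at_arc(self, s: float) -> np.ndarray:
        arc = np.asarray(self.arc)
        pts = np.asarray(self.points)
        i = int(np.clip(np.searchsorted(arc, s), 1, len(arc) - 1))
        d = pts[i] - pts[i - 1]
        n = np.linalg.norm(d)
        return d / n if n > 1e-12 else self.heading.copy()


class _LateralStore:
    """Growable structure-of-arrays for the straight lateral axes."""

    _fields = ("origin", "heading", "birth", "multiplier",
               "attach_arc", "parent_axis", "axis_id")

    def __init__(self) -> None:
        self.origin: list = []
        self.heading: list = []
        self.birth: list = []
        self.multiplier: list = []
        self.attach_arc: list = []
        self.parent_axis: list = []
        self.axis_id: list = []

    def __len__(self) -> int:
        return len(self.birth)

    def append(self, origin, heading, birth, multiplier, attach_arc,
               parent_axis, axis_id) -> None:
        self.origin.append(np.asarray(origin, dtype=float))
        self.heading.append(np.asarray(heading, dtype=float))
        self.birth.append(float(birth))
        self.multiplier.append(float(multiplier))
        self.attach_arc.append(float(attach_arc))
        self.parent_axis.append(int(parent_axis))
        self.axis_id.append(int(axis_id))

    def arrays(self) -> dict[str, np.ndarray]:
        if len(self) == 0:
            return {"origin": np.zeros((0, 3)), "heading": np.zeros((0, 3)),
                    "birth": np.zeros(0), "multiplier": np.zeros(0),
                    "attach_arc": np.zeros(0),
                    "parent_axis": np.zeros(0, dtype=int),
                    "axis_id": np.zeros(0, dtype=int)}
        return {"origin": np.vstack(self.origin),
                "heading": np.vstack(self.heading),
                "birth": np.asarray(self.birth),
                "multiplier": np.asarray(self.multiplier),
                "attach_arc": np.asarray(self.attach_arc),
                "parent_axis": np.asarray(self.parent_axis, dtype=int),
                "axis_id": np.asarray(self.axis_id, dtype=int)}


# ---------------------------------------------------------------------------
# emergence schedule
# ---------------------------------------------------------------------------

def nodal_emergence_times(params: Params, horizon: float,
                          rng: np.random.Generator | None = None
                          ) -> list[tuple[float, str]]:
    """Emission events (day, class) for nodal roots up to ``horizon``.

    Crown-root formation is rapid until the slowdown day and slower after,
    so the cumulative count is concave (the observed slowdown of nodal-root
    number).  The first roots are all of the branched class; the fast class
    appears only after ``fast_start_day`` and its share of new roots ramps
    up with time.  Once tillers exist, a share of new crown roots emerges
    from tiller nodes instead of the hypocotyl, growing with tiller count.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    sim = params.sim
    if rng is None:
        rng = np.random.default_rng(0)
    events: list[tuple[float, str]] = []

    def count_rate_inverse(k: int) -> float:
        # day at which the cumulative emission count reaches k
        rapid_total = sim.nodal_rapid_rate * (sim.nodal_slowdown_day - sim.nodal_start_day)
        if k <= rapid_total:
            return sim.nodal_start_day + k / sim.nodal_rapid_rate
        return sim.nodal_slowdown_day + (k - rapid_total) / sim.nodal_slow_rate

    k = 1
    while True:
        t = count_rate_inverse(k)
        if t > horizon:
            break
        n_tillers = sum(1 for td in sim.tiller_days if td <= t)
        p_tiller = min(sim.tiller_share_cap,
                       sim.tiller_share_per_tiller * n_tillers)
        if n_tillers > 0 and rng.random() < p_tiller:
            cls = "nodal_tiller"
        elif t <= sim.fast_start_day:
            cls = "nodal_branched"
        else:
            p_fast = min(sim.fast_share_cap,
                         sim.fast_share_ramp * (t - sim.fast_start_day))
            cls = "nodal_fast" if rng.random() < p_fast else "nodal_branched"
        events.append((t, cls))
        k += 1
    return events


# ---------------------------------------------------------------------------
# the root system
# ---------------------------------------------------------------------------

class RootSystem:
    """Growing root system (graph of main-axis polylines + straight laterals)."""

    def __init__(self, params: Params, seed: int = 0,
                 horizon: float | None = None) -> None:
        self.params = params
        self.seed = int(seed)
        self.horizon = params.sim.horizon_days if horizon is None else float(horizon)
        ss = np.random.SeedSequence(seed)
        names = ("emergence", "angles", "ibd", "multipliers", "impedance")
        self.rng = {n: np.random.default_rng(s)
                    for n, s in zip(names, ss.spawn(len(names)))}
        self.clock = 0.0
        self.main_axes: list[MainAxis] = []
        self.laterals: dict[str, _LateralStore] = {c: _LateralStore()
                                                   for c in LATERAL_CLASSES}
        self._next_axis_id = 0
        self.tiller_count = 0
        self._schedule = nodal_emergence_times(params, self.horizon,
                                               self.rng["emergence"])
        self._schedule_pos = 0
        # primary root and hypocotyl emerge from the seed at day 0
        self._start_main_axis("primary", birth=0.0)

    # -- construction helpers ------------------------------------------------

    def _new_axis_id(self) -> int:
        self._next_axis_id += 1
        return self._next_axis_id - 1

    def _start_main_axis(self, class_id: str, birth: float) -> MainAxis:
        p = self.params.classes[class_id]
        m = float(p.rate_multiplier.sample(self.rng["multipliers"]))
        axis = MainAxis(
            axis_id=self._new_axis_id(), class_id=class_id, birth=birth,
            multiplier=m, curve=GrowthCurve.for_class(p),
            heading=initial_angle(class_id, self.params, self.rng["angles"]),
            points=[np.zeros(3)], times=[birth], arc=[0.0],
        )
        for child in p.ibd_by_child:
            axis.next_branch_arc[child] = sample_ibd(
                self.params, class_id, child, 0.0, birth, self.rng["ibd"])
        self.main_axes.append(axis)
        return axis

    def _emit_lateral(self, child_class: str, parent: "MainAxis | dict",
                      parent_class: str, parent_axis_id: int,
                      origin: np.ndarray, tangent: np.ndarray,
                      attach_arc: float, birth: float) -> None:
        rng = self.rng["angles"]
        heading = _perpendicular(tangent, rng)
        heading = _cannot_grow_up(heading, rng)
        m = float(self.params.classes[child_class].rate_multiplier.sample(
            self.rng["multipliers"]))
        axis_id = self._new_axis_id()
        self.laterals[child_class].append(
            origin, heading, birth, m, attach_arc, parent_axis_id, axis_id)
        # L-type laterals bear S-type children; their straight geometry and
        # deterministic elongation let us emit the whole brood at once.
        p = self.params.classes[child_class]
        if "stype" in p.ibd_by_child:
            curve = GrowthCurve.for_class(p)
            total = curve.cumulative(curve.lifetime, m)
            pos, births = _ibd_sequence(self.params, child_class, "stype",
                                        total, birth, curve, m, self.rng["ibd"])
            for s, bt in zip(pos, births):
                if bt > self.horizon:
                    continue
                self._emit_lateral(
                    "stype", None, child_class, axis_id,
                    origin + heading * s, heading, s, float(bt))

    # -- queries -------------------------------------------------------------

    def lateral_arrays(self, class_id: str) -> dict[str, np.ndarray]:
        return self.laterals[class_id].arrays()

    def lateral_lengths(self, class_id: str, at: float) -> np.ndarray:
        arr = self.lateral_arrays(class_id)
        p = self.params.classes[class_id]
        curve = GrowthCurve.for_class(p)
        age = np.clip(at - arr["birth"], 0.0, None)
        return curve.cumulative(age, 1.0) * arr["multiplier"]

    def axis_count(self, class_id: str) -> int:
        if class_id in LATERAL_CLASSES:
            return len(self.laterals[class_id])
        return sum(1 for a in self.main_axes if a.class_id == class_id)

    def axis_counts(self) -> dict[str, int]:
        return {c: self.axis_count(c) for c in CLASS_IDS}

    def lengths_by_class(self, at: float | None = None) -> dict[str, float]:
        at = self.clock if at is None else at
        if at > self.clock + 1e-9:
            raise ValueError("cannot query geometry beyond the current clock")
        out = {c: 0.0 for c in CLASS_IDS}
        for a in self.main_axes:
            out[a.class_id] += a.length(at)
        for c in LATERAL_CLASSES:
            out[c] += float(self.lateral_lengths(c, at).sum())
        return out

    def total_length(self, at: float | None = None) -> float:
        return float(sum(self.lengths_by_class(at).values()))

    def depth_fraction(self, cutoff_cm: float = 25.0,
                       at: float | None = None) -> float:
        """Fraction of total root length shallower than ``cutoff_cm``."""
        at = self.clock if at is None else at
        above = 0.0
        total = 0.0
        for a in self.main_axes:
            pts = np.asarray(a.points)
            times = np.asarray(a.times)
            if len(pts) < 2:
                continue
            keep = times[1:] <= at + 1e-12
            if not keep.any():
                continue
            p0, p1 = pts[:-1][keep], pts[1:][keep]
            seg = np.linalg.norm(p1 - p0, axis=1)
            mid = 0.5 * (p0[:, 2] + p1[:, 2])
            total += seg.sum()
            above += seg[mid < cutoff_cm].sum()
        for c in LATERAL_CLASSES:
            arr = self.lateral_arrays(c)
            ln = self.lateral_lengths(c, at)
            if ln.size == 0:
                continue
            z0 = arr["origin"][:, 2]
            hz = arr["heading"][:, 2]
            with np.errstate(divide="ignore", invalid="ignore"):
                s_star = np.where(hz > 1e-12, (cutoff_cm - z0) / np.where(hz > 1e-12, hz, 1.0), np.inf)
            frac = np.clip(np.where(z0 < cutoff_cm, s_star / np.maximum(ln, 1e-12), 0.0), 0.0, 1.0)
            total += ln.sum()
            above += (ln * frac).sum()
        return above / total if total > 0 else 0.0

    def segment_cloud(self, at: float | None = None, max_piece: float = 0.5
                      ) -> pd.DataFrame:
        """Root length broken into short pieces (for overlap diagnostics).

        Columns: x, y, z (piece midpoints), dx, dy, dz (unit direction),
        length, class_id, birth, axis_id, parent_axis.
        """
        at = self.clock if at is None else at
        rows = []
        for a in self.main_axes:
            pts = np.asarray(a.points)
            times = np.asarray(a.times)
            if len(pts) < 2:
                continue
            keep = times[1:] <= at + 1e-12
            p0, p1 = pts[:-1][keep], pts[1:][keep]
            t1 = times[1:][keep]
            if len(p0) == 0:
                continue
            mid = 0.5 * (p0 + p1)
            seg = np.linalg.norm(p1 - p0, axis=1)
            d = (p1 - p0) / np.maximum(seg, 1e-12)[:, None]
            rows.append(pd.DataFrame({
                "x": mid[:, 0], "y": mid[:, 1], "z": mid[:, 2],
                "dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
                "length": seg, "class_id": a.class_id, "birth": t1,
                "axis_id": a.axis_id, "parent_axis": -1,
            }))
        for c in LATERAL_CLASSES:
            arr = self.lateral_arrays(c)
            ln = self.lateral_lengths(c, at)
            alive = np.flatnonzero(ln > 0)
            if alive.size == 0:
                continue
            n_piece = np.ceil(ln[alive] / max_piece).astype(int)
            rep = np.repeat(alive, n_piece)
            k = np.arange(n_piece.sum()) - np.repeat(
                np.concatenate(([0], np.cumsum(n_piece)[:-1])), n_piece)
            piece_len = ln[rep] / np.repeat(n_piece, n_piece)
            s = (k + 0.5) * piece_len
            mid = arr["origin"][rep] + arr["heading"][rep] * s[:, None]
            hd = arr["heading"][rep]
            rows.append(pd.DataFrame({
                "x": mid[:, 0], "y": mid[:, 1], "z": mid[:, 2],
                "dx": hd[:, 0], "dy": hd[:, 1], "dz": hd[:, 2],
                "length": piece_len, "class_id": c,
                "birth": arr["birth"][rep],
                "axis_id": arr["axis_id"][rep],
                "parent_axis": arr["parent_axis"][rep],
            }))
        if not rows:
            return pd.DataFrame(columns=["x", "y", "z", "dx", "dy", "dz",
                                         "length", "class_id", "birth",
                                         "axis_id", "parent_axis"])
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def advance(system: RootSystem, dt: float) -> RootSystem:
    """Advance the system clock by ``dt`` (days), growing every axis.

    Tips extend by their elongation-curve increment along tropism-updated
    headings; pending branch distances crossed during the step emit child
    axes at the exact crossing position (linear interpolation within the
    step), after which a fresh IBD is drawn.
    """
    max_step = system.params.sim.max_step
    if dt < 0 or dt > max_step + 1e-12:
        raise ValueError(f"dt must be in (0, {max_step}], got {dt}")
    if dt == 0:
        return system
    t0 = system.clock
    t1 = t0 + dt

    # nodal emergence events inside the step
    while (system._schedule_pos < len(system._schedule)
           and system._schedule[system._schedule_pos][0] <= t1):
        day, cls = system._schedule[system._schedule_pos]
        system._schedule_pos += 1
        system._start_main_axis(cls, birth=day)
        if cls == "nodal_tiller":
            system.tiller_count = max(system.tiller_count, 1 + sum(
                1 for td in system.params.sim.tiller_days if td <= day))

    impedance = system.params.sim.impedance_scale
    for axis in system.main_axes:
        if axis.birth >= t1:
            continue
        p = system.params.classes[axis.class_id]
        len0 = axis.length(t0)
        len1 = axis.length(t1)
        dl = len1 - len0
        if dl <= 1e-12:
            continue
        step_dt = t1 - max(t0, axis.birth)
        axis.heading = tropism_update(
            axis.heading, p, float(axis.points[-1][2]),
            system.rng["impedance"], step_dt, step_length=dl,
            impedance_scale=impedance)
        new_pt = axis.points[-1] + axis.heading * dl
        axis.points.append(new_pt)
        axis.times.append(t1)
        axis.arc.append(axis.arc[-1] + dl)
        # branch crossings within [len0, len1]
        for child in list(axis.next_branch_arc):
            while axis.next_branch_arc[child] <= len1:
                s = axis.next_branch_arc[child]
                birth = axis.birth + float(
                    axis.curve.inverse_cumulative(s, axis.multiplier))
                origin = axis.position_at_arc(s)
                tangent = axis.tangent_at_arc(s)
                system._emit_lateral(child, axis, axis.class_id,
                                     axis.axis_id, origin, tangent, s, birth)
                s_next = s + sample_ibd(system.params, axis.class_id, child,
                                        s, birth, system.rng["ibd"])
                axis.next_branch_arc[child] = s_next

    system.clock = t1
    return system


def grow(params: Params, seed: int = 0, horizon: float | None = None,
         dt: float | None = None) -> RootSystem:
    """Grow a root system from seed to ``horizon`` days (default 35)."""
    system = RootSystem(params, seed=seed, horizon=horizon)
    dt = params.sim.max_step if dt is None else dt
    n_steps = int(np.ceil(system.horizon / dt - 1e-9))
    for _ in range(n_steps):
        advance(system, min(dt, system.horizon - system.clock))
    return system


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def class_geometry(system: RootSystem, at: float | None = None) -> pd.DataFrame:
    """Per-class root length/surface/volume/weight ledger (cylinders).

    surface = π·d·L, volume = π·(d/2)²·L, weight = volume × tissue density.
    Units: length cm, surface cm², volume cm³, weight g.
    """
    at = system.clock if at is None else at
    lengths = system.lengths_by_class(at)
    rows = {}
    for c in CLASS_IDS:
        p = system.params.classes[c]
        L = lengths[c]
        surface = np.pi * p.diameter * L
        volume = np.pi * (p.diameter / 2.0) ** 2 * L
        rows[c] = {"length_cm": L, "surface_cm2": surface,
                   "volume_cm3": volume,
                   "weight_g": volume * p.tissue_density}
    df = pd.DataFrame(rows).T
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "class_id"
    return df


def length_birth_histogram(system: RootSystem, at: float | None = None,
                           step: float | None = None
                           ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Root length (cm) born per time bin per class, up to ``at``.

    Returns (bin edges, {class: length array}); ``edges`` has one more
    entry than each length array.  The histogram is the
    bridge between architecture and the radial uptake model: because the
    soil is homogeneous and each new segment owns a fresh radial domain,
    uptake depends only on how much length of each class was born when.
    """
    at = system.clock if at is None else at
    step = system.params.sim.max_step if step is None else step
    n_bins = int(np.ceil(at / step - 1e-9))
    edges = np.append(np.arange(n_bins) * step, at)
    hist: dict[str, np.ndarray] = {}
    for c in CLASS_IDS:
        hist[c] = np.zeros(n_bins)
    for a in system.main_axes:
        lo = a.curve.cumulative(np.clip(edges[:-1] - a.birth, 0, None), a.multiplier)
        hi = a.curve.cumulative(np.clip(edges[1:] - a.birth, 0, None), a.multiplier)
        hist[a.class_id] += hi - lo
    for c in LATERAL_CLASSES:
        arr = system.lateral_arrays(c)
        if len(arr["birth"]) == 0:
            continue
        curve = GrowthCurve.for_class(system.params.classes[c])
        b = arr["birth"][:, None]
        m = arr["multiplier"][:, None]
        lo = curve.cumulative(np.clip(edges[None, :-1] - b, 0, None), 1.0) * m
        hi = curve.cumulative(np.clip(edges[None, 1:] - b, 0, None), 1.0) * m
        hist[c] += (hi - lo).sum(axis=0)
    return edges, hist
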