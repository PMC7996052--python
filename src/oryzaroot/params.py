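"""Parameterization of the DJ123 upland-rice root system and its soil.

Holds the per-class geometry/growth constants, root-hair traits, soil
phosphate constants, multiplicative perturbation machinery used by the
sensitivity and hypothetical-architecture scans, and the published
calibration anchors the test-suite checks against.

All lengths are cm, times are days, concentrations are µmol mL⁻¹ (so
1 nM = 1e-6 µmol mL⁻¹), masses are g unless a field name says otherwise.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TruncNorm",
    "TruncLogNorm",
    "HairParams",
    "RootClassParams",
    "SoilP",
    "SimulationParams",
    "Params",
    "ScenarioSpec",
    "ConfigError",
    "default_dj123_params",
    "make_scenario",
    "apply_factor",
    "calibration_targets",
    "reference_class_table",
    "CLASS_IDS",
    "MAIN_CLASSES",
    "LATERAL_CLASSES",
    "NODAL_CLASSES",
    "P_MOLAR_MASS_UG",
]

#: µg of phosphorus per µmol
P_MOLAR_MASS_UG = 30.973762

CLASS_IDS = ("primary", "nodal_branched", "nodal_fast", "nodal_tiller", "ltype", "stype")
MAIN_CLASSES = ("primary", "nodal_branched", "nodal_fast", "nodal_tiller")
NODAL_CLASSES = ("nodal_branched", "nodal_fast", "nodal_tiller")
LATERAL_CLASSES = ("ltype", "stype")


class ConfigError(ValueError):
    """Raised when a configuration value or parameter path is invalid."""


@dataclass
class TruncNorm:
    """Normal distribution with hard truncation bounds (used for IBDs)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ConfigError(
                f"truncation bounds must satisfy lo <= mean <= hi, got {self}"
            )
        if self.sd < 0:
            raise ConfigError(f"sd must be >= 0, got {self.sd}")

    def _frozen(self):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        # inverse-CDF sampling (fast for scalar draws)
        from scipy.special import ndtr, ndtri
        fa = ndtr((self.lo - self.mean) / self.sd)
        fb = ndtr((self.hi - self.mean) / self.sd)
        u = rng.uniform(fa, fb, size)
        return self.mean + self.sd * ndtri(u)

    def moments(self) -> tuple[float, float]:
        """Theoretical (mean, sd) of the truncated distribution."""
        if self.sd == 0:
            return self.mean, 0.0
        f = self._frozen()
        return float(f.mean()), float(f.std())

    def scaled(self, factor: float) -> "TruncNorm":
        """Scale the whole distribution (mean, sd and both bounds)."""
        return TruncNorm(self.mean * factor, self.sd * factor,
                         self.lo * factor, self.hi * factor)


@dataclass
class TruncLogNorm:
    """Lognormal growth-rate multiplier, median ``median``, truncated."""

    median: float = 1.0
    sigma: float = 0.3
    lo: float = 0.25
    hi: float = 2.5

    def __post_init__(self) -> None:
        if not (self.lo <= self.median <= self.hi) or self.sigma < 0:
            raise ConfigError(f"invalid multiplier distribution {self}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.sigma == 0:
            return self.median if size is None else np.full(size, self.median)
        from scipy.special import ndtr, ndtri
        mu = np.log(self.median)
        fa = ndtr((np.log(self.lo) - mu) / self.sigma)
        fb = ndtr((np.log(self.hi) - mu) / self.sigma)
        u = rng.uniform(fa, fb, size)
        return np.exp(mu + self.sigma * ndtri(u))


@dataclass
class HairParams:
    """Root-hair traits of one root class.

    ``max_density`` is the ceiling density (hairs per cm of root) on young
    segments; density declines linearly with segment age from
    ``decline_anchor_age`` on, at ``decline_frac_per_day`` of the ceiling per
    day, clamped at zero.  The default decline reproduces the observed drop
    from 600 hairs cm⁻¹ on a 3-day-old root to 330 on a 40-day-old root,
    i.e. (1 − 330/600)/37 per day.
    """

    max_density: float
    length: float
    diameter: float = 0.0005
    decline_anchor_age: float = 3.0
    decline_frac_per_day: float = (1.0 - 330.0 / 600.0) / 37.0
    tissue_density: float = 0.1  # g cm⁻³

    def density(self, age) -> np.ndarray | float:
        """Hairs per cm of root on a segment of the given age (days)."""
        age = np.asarray(age, dtype=float)
        decline = np.clip(age - self.decline_anchor_age, 0.0, None)
        rel = np.clip(1.0 - self.decline_frac_per_day * decline, 0.0, None)
        out = self.max_density * rel
        return float(out) if out.ndim == 0 else out


@dataclass
class RootClassParams:
    """All per-class constants of one root class."""

    class_id: str
    diameter: float               # cm
    max_length: float             # cm
    peak_growth_rate: float       # cm day⁻¹
    gravitropism: float           # cm/cm/day, negative pulls downward
    tissue_density: float         # g cm⁻³
    hair: HairParams
    ibd_by_child: dict[str, TruncNorm] = field(default_factory=dict)
    rate_multiplier: TruncLogNorm = field(default_factory=TruncLogNorm)
    rise_days: float = 2.0        # emergence phase: rate ramps up to peak
    decline_window: float = 1.0   # days over which the rate falls to zero
    tissue_p_conc: float = 0.8    # mg P per g of root tissue


@dataclass
class SoilP:
    """Soil-solution phosphate parameters (Andosol defaults).

    ``c_solution_init`` defaults to the recalibrated 540 nM solution
    concentration; the directly measured value, 83 nM, is kept alongside so
    both study conditions can be simulated.  ``buffer_power`` multiplies
    storage in the radial diffusion equation; when it is perturbed the
    effective diffusivity is co-scaled so that De·b stays constant.

    ``imax`` is the Michaelis–Menten maximal influx (µmol cm⁻² day⁻¹); its
    default was fixed once by bisection so that the day-31 plant P content
    of the default architecture matches the measured 774.3 µg (see
    ``oryzaroot.uptake.calibrate_imax``).
    """

    c_solution_init: float = 5.4e-4    # µmol mL⁻¹ (= 540 nM)
    c_solution_measured: float = 8.3e-5  # µmol mL⁻¹ (= 83 nM)
    buffer_power: float = 6000.0
    de: float = 9.227e-6               # cm² day⁻¹
    imax: float = 0.7591              # µmol cm⁻² day⁻¹ (calibrated)
    km: float = 5.8e-3                 # µmol mL⁻¹
    cmin: float = 1.0e-5               # µmol mL⁻¹
    v0: float = 0.0                    # cm day⁻¹ water influx at the surface

    def __post_init__(self) -> None:
        if not (self.c_solution_init > self.cmin >= 0):
            raise ConfigError("need c_solution_init > cmin >= 0")
        if self.km <= 0 or self.imax < 0:
            raise ConfigError("need km > 0 and imax >= 0")


@dataclass
class SimulationParams:
    """Run control and whole-plant development schedule."""

    horizon_days: float = 35.0
    max_step: float = 0.2
    emergence_day: float = 3.0       # sim day of shoot emergence (DAE 0)
    report_day: float = 31.0         # = 28 DAE
    # nodal-root emergence: rapid phase then slowdown
    nodal_start_day: float = 4.0
    nodal_rapid_rate: float = 2.3    # roots day⁻¹ until the slowdown
    nodal_slowdown_day: float = 10.0
    nodal_slow_rate: float = 1.5     # roots day⁻¹ after the slowdown
    fast_start_day: float = 10.0     # first fast nodal roots (sim time)
    fast_share_ramp: float = 0.06    # share of new roots that are fast, per day
    fast_share_cap: float = 0.75
    tiller_days: tuple[float, ...] = (12.0, 16.0, 20.0)
    tiller_share_per_tiller: float = 0.15  # share of new crown roots per tiller
    tiller_share_cap: float = 0.45
    impedance_scale: float = 0.08    # random tropism perturbation per sqrt(day)
    # nodal root growth angle: rga = lo + (hi-lo)*Beta(a, b), degrees from
    # the horizontal soil surface; defaults give mode 28.5° and
    # P(rga <= 45°) = 0.62 on the 8–90° support.
    rga_lo: float = 8.0
    rga_hi: float = 90.0
    rga_beta_a: float = 1.4
    rga_beta_b: float = 2.2
    # radial uptake solver
    radial_nodes: int = 40
    solver_tol: float = 1e-10


@dataclass
class Params:
    """Complete parameter set: root classes + soil + run control."""

    classes: dict[str, RootClassParams]
    soil: SoilP = field(default_factory=SoilP)
    sim: SimulationParams = field(default_factory=SimulationParams)

    def copy(self) -> "Params":
        return copy.deepcopy(self)


def _hair(density: float, length: float) -> HairParams:
    return HairParams(max_density=density, length=length)


def default_dj123_params() -> Params:
    """The complete DJ123 parameter set.

    Diameters, maximum lengths, peak growth rates and hair traits are the
    published DJ123 measurements.  Inter-branching distances and the
    nodal-emergence schedule are calibrated defaults (the raw branching
    tables were not published): they reproduce the observed day-31 class
    length shares (S-type >~ half of root length, L-type ≈ one third) and a
    total root length near 60 m.  The tiller-nodal class interpolates the
    branched and fast classes.
    """
    # Tissue densities for cost/weight: 0.06 (primary/nodal), 0.07 (L-type),
    # 0.1 g cm⁻³ (S-type, hairs) — the set the cost analysis states.  An
    # alternative set (0.08/0.09/0.1) is reported for specific root volume;
    # switch per class via `tissue_density` if that convention is wanted.
    # IBD distributions, cm.  Calibrated, not measured (see module docs).
    ibd_l_on_nodal = TruncNorm(3.1, 1.1, 1.1, 6.2)
    ibd_s_on_nodal = TruncNorm(0.6, 0.18, 0.28, 1.2)
    # the primary root is the most densely branched root: 0.9x the means
    ibd_l_on_primary = ibd_l_on_nodal.scaled(0.9)
    ibd_s_on_primary = ibd_s_on_nodal.scaled(0.9)
    ibd_s_on_ltype = TruncNorm(0.6, 0.18, 0.28, 1.2)

    classes = {
        "primary": RootClassParams(
            class_id="primary", diameter=0.065, max_length=46.0,
            peak_growth_rate=2.19, gravitropism=-0.065, tissue_density=0.06,
            hair=_hair(1400.0, 0.02),
            ibd_by_child={"ltype": ibd_l_on_primary, "stype": ibd_s_on_primary},
        ),
        "nodal_branched": RootClassParams(
            class_id="nodal_branched", diameter=0.05, max_length=35.0,
            peak_growth_rate=1.46, gravitropism=-0.0001, tissue_density=0.06,
            hair=_hair(1400.0, 0.015),
            ibd_by_child={"ltype": ibd_l_on_nodal, "stype": ibd_s_on_nodal},
        ),
        "nodal_fast": RootClassParams(
            class_id="nodal_fast", diameter=0.065, max_length=45.0,
            peak_growth_rate=2.14, gravitropism=-0.0001, tissue_density=0.06,
            hair=_hair(1400.0, 0.015),
            ibd_by_child={"ltype": ibd_l_on_nodal, "stype": ibd_s_on_nodal},
        ),
        "nodal_tiller": RootClassParams(
            class_id="nodal_tiller", diameter=0.06, max_length=40.0,
            peak_growth_rate=1.8, gravitropism=-0.0001, tissue_density=0.06,
            hair=_hair(1400.0, 0.015),
            ibd_by_child={"ltype": ibd_l_on_nodal, "stype": ibd_s_on_nodal},
        ),
        "ltype": RootClassParams(
            class_id="ltype", diameter=0.02, max_length=14.6,
            peak_growth_rate=0.73, gravitropism=0.0, tissue_density=0.07,
            hair=_hair(700.0, 0.015),
            ibd_by_child={"stype": ibd_s_on_ltype},
        ),
        "stype": RootClassParams(
            class_id="stype", diameter=0.0045, max_length=1.08,
            peak_growth_rate=0.14, gravitropism=0.0, tissue_density=0.10,
            hair=_hair(400.0, 0.012),
        ),
    }
    return Params(classes=classes)


# ---------------------------------------------------------------------------
# perturbations / scenarios
# ---------------------------------------------------------------------------

def _resolve(obj, parts: Sequence[str], path: str):
    """Walk a dotted path through dataclasses / dicts; return (owner, key)."""
    for i, part in enumerate(parts[:-1]):
        if isinstance(obj, Mapping):
            if part not in obj:
                raise ConfigError(f"unknown parameter path {path!r} (at {part!r})")
            obj = obj[part]
        elif dataclasses.is_dataclass(obj) and hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigError(f"unknown parameter path {path!r} (at {part!r})")
    return obj, parts[-1]


def apply_factor(params: Params, path: str, factor: float) -> Params:
    """Return a copy of ``params`` with the value at ``path`` multiplied.

    ``path`` is dotted, e.g. ``"soil.c_solution_init"`` or
    ``"classes.nodal_fast.diameter"``.  A path ending on a :class:`TruncNorm`
    scales the whole distribution.  Perturbing ``soil.buffer_power`` co-scales
    the diffusivity so that De·b stays constant.
    """
    if factor <= 0:
        raise ConfigError(f"perturbation factor must be > 0, got {factor}")
    new = params.copy()
    parts = path.split(".")
    owner, key = _resolve(new, parts, path)
    if isinstance(owner, Mapping):
        if key not in owner:
            raise ConfigError(f"unknown parameter path {path!r} (at {key!r})")
        cur = owner[key]
    elif dataclasses.is_dataclass(owner) and hasattr(owner, key):
        cur = getattr(owner, key)
    else:
        raise ConfigError(f"unknown parameter path {path!r} (at {key!r})")

    if isinstance(cur, TruncNorm):
        val = cur.scaled(factor)
    elif isinstance(cur, (int, float)) and not isinstance(cur, bool):
        val = cur * factor
    else:
        raise ConfigError(f"path {path!r} does not point at a numeric field")

    if isinstance(owner, Mapping):
        owner[key] = val
    else:
        setattr(owner, key, val)

    if path == "soil.buffer_power":
        # De·b is held constant under buffer perturbation
        new.soil.de = new.soil.de / factor
    return new


@dataclass
class ScenarioSpec:
    """A fully deterministic simulation scenario.

    ``perturbations`` is a list of (dotted-path, multiplicative factor)
    applied to ``base``; ``seeds`` holds one integer per replicate, spawned
    deterministically from the scenario seed.
    """

    base: Params
    perturbations: list[tuple[str, float]]
    replicates: int
    seeds: tuple[int, ...]
    horizon_days: float = 35.0
    max_step: float = 0.2

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.horizon_days < self.max_step:
            raise ConfigError("horizon_days must be >= max_step")
        for _, f in self.perturbations:
            if f <= 0:
                raise ConfigError("perturbation factors must be > 0")

    def resolved(self) -> Params:
        p = self.base
        for path, f in self.perturbations:
            p = apply_factor(p, path, f)
        return p


def replicate_seeds(master_seed: int, n: int) -> tuple[int, ...]:
    """Deterministic replicate seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return tuple(int(s) % (2**31 - 1) for s in ss.generate_state(n))


def make_scenario(base: Params, perturbations: Iterable[tuple[str, float]],
                  replicates: int = 1, seed: int = 0,
                  horizon_days: float | None = None,
                  max_step: float | None = None) -> ScenarioSpec:
    """Build a deterministic :class:`ScenarioSpec`; validates every path."""
    perturbations = list(perturbations)
    for path, f in perturbations:
        apply_factor(base, path, f)  # raises ConfigError on a bad path
    return ScenarioSpec(
        base=base, perturbations=perturbations, replicates=replicates,
        seeds=replicate_seeds(seed, replicates),
        horizon_days=base.sim.horizon_days if horizon_days is None else horizon_days,
        max_step=base.sim.max_step if max_step is None else max_step,
    )


# ---------------------------------------------------------------------------
# published anchors
# ---------------------------------------------------------------------------

def calibration_targets() -> dict[str, float]:
    """Published scalar anchors for DJ123 used by the test-suite.

    P contents are µg per plant; uptake-per-length values are µg P m⁻¹;
    ``day_offset`` maps simulation time to days-after-emergence
    (sim day 31 = 28 DAE).
    """
    return {
        "measured_P_28DAE": 774.3,
        "sim_P_83nM_28DAE": 150.6,
        "tissue_P_mg_per_g": 0.8,
        "day_offset": 3.0,
        "field_uptake_per_length_28DAE": 12.1,
        "sim_uptake_per_length_28DAE": 11.6,
        "sim_uptake_per_length_48DAE": 12.4,
        "field_uptake_per_length_48DAE": 26.2,
        "longest_fast_nodal_cm": 45.0,
        "longest_fast_nodal_age_days": 21.0,
        "hair_uptake_ug": 110.0,
        "total_uptake_ug": 689.2,
    }


def reference_class_table() -> dict[str, dict[str, float | None]]:
    """Published per-class simulation results for DJ123 at 28 DAE.

    Base columns (uptake µg, length m, surface cm², weight mg) and the
    printed derived columns (cost µg, efficiencies, benefit:cost, cost
    recovery days).  Used as arithmetic cross-check anchors; ``None`` marks
    cells the source leaves blank.
    """
    cols = ("uptake_ug", "length_m", "surface_cm2", "weight_mg", "cost_ug",
            "eff_length", "eff_surface", "eff_weight", "benefit_cost",
            "case1_days", "case2_days", "case3_days")
    rows = {
        "hairs": (110.0, 395.9, 62.2, 0.78, 0.6, 0.3, 1.77, 141.4, 176.8,
                  None, None, None),
        "stype": (107.4, 33.7, 47.7, 4.6, 3.7, 3.2, 2.25, 23.1, 28.9,
                  0.4, 1.0, 1.0),
        "ltype": (174.5, 21.9, 138.2, 50.5, 40.4, 7.9, 1.26, 3.5, 4.3,
                  2.7, 4.8, 5.1),
        "nodal": (297.4, 10.8, 220.5, 399.9, 319.9, 27.6, 1.35, 0.7, 0.9,
                  12.5, 24.8, float("inf")),
        "total": (689.2, 462.4, 468.6, 455.9, 364.7, 1.5, 1.47, 1.5, 1.9,
                  None, None, None),
    }
    return {name: dict(zip(cols, vals)) for name, vals in rows.items()}
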