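"""Phosphorus economics of the root system.

Under severe P limitation every structure built costs P (tissue weight ×
tissue P concentration, 0.8 µg P per mg for DJ123 at 28 DAE) and earns P
through uptake.  This module builds the per-class ledger (dimensions,
cost, uptake efficiencies per length/surface/weight, benefit-to-cost
ratio), estimates the pay-off time of each class under three cost-recovery
scenarios, and compares hypothetical architectures (shorter/longer
laterals, thinner fast nodal roots).

Cost-recovery cases:

* Case 1 — static: cost and daily uptake both frozen at the report day;
  days = cost / daily uptake.
* Case 2 — a hypothetical root system made of a single root class (one
  axis elongating along its class curve, re-initiating whenever it reaches
  its maximum length, with class-default hairs): the break-even day is the
  first day cumulative uptake covers cumulative cost.
* Case 3 — Case 2 without root hairs.

The primary root is folded into the nodal row throughout (main axes are
costed and credited together).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import RootSystem, class_geometry
from .growth import GrowthCurve
from .hairs import hair_geometry
from .params import CLASS_IDS, Params
from .uptake import UptakeResult, uptake_from_histogram

__all__ = [
    "build_ledger", "ledger_from_components", "benefit_cost", "cost_from_weight",
    "recovery_case1", "recovery_case2", "recovery_case3",
    "single_class_histogram", "hypothetical_scan", "LEDGER_ROWS",
]

LEDGER_ROWS = ("hairs", "stype", "ltype", "nodal", "total")

#: ledger row per root class (primary root counts as nodal)
_ROW_OF_CLASS = {"primary": "nodal", "nodal_branched": "nodal",
                 "nodal_fast": "nodal", "nodal_tiller": "nodal",
                 "ltype": "ltype", "stype": "stype"}


def cost_from_weight(weight_mg: float, tissue_p_ug_per_mg: float = 0.8) -> float:
    """P construction cost (µg) of ``weight_mg`` of root tissue."""
    return weight_mg * tissue_p_ug_per_mg


def benefit_cost(uptake_ug: float, cost_ug: float) -> float:
    """Benefit-to-cost ratio: P taken up per P invested."""
    if cost_ug <= 0:
        raise ValueError("benefit:cost is undefined at zero cost")
    return uptake_ug / cost_ug


def build_ledger(system: RootSystem, uptake: UptakeResult,
                 at: float | None = None) -> pd.DataFrame:
    """Per-class P economics ledger at day ``at`` (default: report day).

    Rows hairs/stype/ltype/nodal/total; columns: uptake µg, length m,
    surface cm², weight mg, cost µg, efficiency per length (µg m⁻¹), per
    surface (µg cm⁻²), per weight (µg mg⁻¹), and benefit:cost.  Derived
    columns are exact quotients/products of the base columns.
    """
    at = system.params.sim.report_day if at is None else at
    geom = class_geometry(system, at)
    hair = hair_geometry(system, at)
    per_class = uptake.per_class_ug(at)
    tissue_p = system.params.classes["primary"].tissue_p_conc
    return ledger_from_components(geom, hair, per_class, tissue_p)


def ledger_from_components(geom: pd.DataFrame, hair: pd.DataFrame,
                           per_class: dict[str, float],
                           tissue_p: float = 0.8) -> pd.DataFrame:
    """Assemble the ledger from a geometry table, hair table and per-class
    uptake values (µg); see :func:`build_ledger`."""
    rows = {r: dict.fromkeys(
        ("uptake_ug", "length_m", "surface_cm2", "weight_mg"), 0.0)
        for r in LEDGER_ROWS}
    for c in CLASS_IDS:
        row = rows[_ROW_OF_CLASS[c]]
        row["uptake_ug"] += per_class.get(c, 0.0)
        row["length_m"] += geom.loc[c, "length_cm"] / 100.0
        row["surface_cm2"] += geom.loc[c, "surface_cm2"]
        row["weight_mg"] += geom.loc[c, "weight_g"] * 1000.0
    rows["hairs"]["uptake_ug"] = per_class.get("hairs", 0.0)
    rows["hairs"]["length_m"] = hair.loc["total", "length_cm"] / 100.0
    rows["hairs"]["surface_cm2"] = hair.loc["total", "surface_cm2"]
    rows["hairs"]["weight_mg"] = hair.loc["total", "weight_g"] * 1000.0
    for key in ("uptake_ug", "length_m", "surface_cm2", "weight_mg"):
        rows["total"][key] = sum(rows[r][key] for r in LEDGER_ROWS
                                 if r != "total")

    df = pd.DataFrame(rows).T.loc[list(LEDGER_ROWS)]
    for r in LEDGER_ROWS:
        if df.loc[r, "weight_mg"] <= 0 and df.loc[r, "uptake_ug"] > 0:
            raise RuntimeError(
                f"ledger row {r!r} has uptake but zero weight")
    df["cost_ug"] = df["weight_mg"] * tissue_p
    with np.errstate(divide="ignore", invalid="ignore"):
        df["eff_length"] = np.where(df["length_m"] > 0,
                                    df["uptake_ug"] / df["length_m"], 0.0)
        df["eff_surface"] = np.where(df["surface_cm2"] > 0,
                                     df["uptake_ug"] / df["surface_cm2"], 0.0)
        df["eff_weight"] = np.where(df["weight_mg"] > 0,
                                    df["uptake_ug"] / df["weight_mg"], 0.0)
        df["benefit_cost"] = np.where(df["cost_ug"] > 0,
                                      df["uptake_ug"] / df["cost_ug"], 0.0)
    df.index.name = "row"
    return df


# ---------------------------------------------------------------------------
# cost recovery
# ---------------------------------------------------------------------------

def recovery_case1(cost_ug: float, daily_uptake_ug: float) -> float:
    """Days to recover a cost at a static daily uptake (inf = never)."""
    if cost_ug <= 0:
        return 0.0
    if daily_uptake_ug <= 0:
        return float("inf")
    return cost_ug / daily_uptake_ug


def single_class_histogram(class_id: str, params: Params, horizon: float,
                           dt: float | None = None
                           ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Length-birth histogram of a continuously growing single-class system.

    One axis elongates along the class growth curve (multiplier 1) and a
    fresh axis starts whenever the previous one reaches its maximum length,
    so the system keeps growing for the whole horizon.
    """
    dt = params.sim.max_step if dt is None else dt
    curve = GrowthCurve.for_class(params.classes[class_id])
    n_bins = int(np.ceil(horizon / dt - 1e-9))
    edges = np.append(np.arange(n_bins) * dt, horizon)
    T = curve.lifetime
    total_per_cycle = curve.cumulative(T)
    grown = np.floor(edges / T) * total_per_cycle + curve.cumulative(edges % T)
    hist = {class_id: np.clip(np.diff(grown), 0.0, None)}
    return edges, hist


def _recovery_growing(class_id: str, params: Params, horizon: float,
                      include_hairs: bool, r1: float = 0.5,
                      dt: float | None = None,
                      n_nodes: int | None = None) -> float:
    dt = params.sim.max_step if dt is None else dt
    edges, hist = single_class_histogram(class_id, params, horizon, dt)
    res = uptake_from_histogram(edges, hist, params,
                                {class_id: r1}, include_hairs=include_hairs,
                                dt=dt, n_nodes=n_nodes)
    p = params.classes[class_id]
    length = np.cumsum(hist[class_id])                    # cm
    weight_mg = length * np.pi * (p.diameter / 2) ** 2 * p.tissue_density * 1e3
    cost = weight_mg * p.tissue_p_conc                    # µg P
    if include_hairs and p.hair.max_density > 0:
        hp = p.hair
        age_mid = (np.arange(len(length)) + 0.5) * dt
        dens = hp.density(age_mid)
        hair_mg_per_cm = (dens * hp.length * np.pi * (hp.diameter / 2) ** 2
                          * hp.tissue_density * 1e3)
        live_hair_mg = np.convolve(hist[class_id], hair_mg_per_cm)[: len(length)]
        cost = cost + live_hair_mg * p.tissue_p_conc
    total = (sum(res.root_uptake.values()) + sum(res.hair_uptake.values()))
    uptake_ug = total * 30.973762
    ok = np.nonzero((uptake_ug >= cost) & (cost > 0))[0]
    if ok.size == 0:
        return float("inf")
    return float(res.times[ok[0]])


def recovery_case2(class_id: str, params: Params, horizon: float = 60.0,
                   n_nodes: int | None = None) -> float:
    """Break-even day of a growing single-class system with its hairs.

    Returns inf ("never") when cumulative uptake never covers cumulative
    cost within ``horizon`` days.
    """
    return _recovery_growing(class_id, params, horizon, include_hairs=True,
                             n_nodes=n_nodes)


def recovery_case3(class_id: str, params: Params, horizon: float = 60.0,
                   n_nodes: int | None = None) -> float:
    """Break-even day of a growing single-class system without root hairs."""
    return _recovery_growing(class_id, params, horizon, include_hairs=False,
                             n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# hypothetical architectures
# ---------------------------------------------------------------------------

def length_perturbation(class_id: str, factor: float) -> list[tuple[str, float]]:
    """Paths scaling a class's final length: peak rate and maximum length
    jointly (the phase timing is unchanged, the lifetime integral scales)."""
    return [(f"classes.{class_id}.max_length", factor),
            (f"classes.{class_id}.peak_growth_rate", factor)]


DEFAULT_VARIANTS: dict[str, list[tuple[str, float]]] = {
    "stype_half": length_perturbation("stype", 0.5),
    "stype_double": length_perturbation("stype", 2.0),
    "ltype_half": length_perturbation("ltype", 0.5),
    "ltype_double": length_perturbation("ltype", 2.0),
    "nodal_thin": [("classes.nodal_fast.diameter", 0.050 / 0.065)],
}


def hypothetical_scan(params: Params, variants: dict | None = None,
                      seed: int = 0, at: float | None = None,
                      n_nodes: int | None = None) -> pd.DataFrame:
    """Compare hypothetical root systems against the default architecture.

    For every variant (a list of parameter perturbations) the system is
    regrown with the same seed and the ledger recomputed; the table reports
    whole-plant Δuptake %, Δcost % and the per-row benefit:cost ratios.
    """
    from .architecture import grow
    from .params import apply_factor
    from .uptake import system_uptake

    variants = DEFAULT_VARIANTS if variants is None else variants
    at = params.sim.report_day if at is None else at
    records = []

    def run(p: Params, name: str) -> pd.Series:
        system = grow(p, seed=seed, horizon=at)
        res = system_uptake(system, at=at, n_nodes=n_nodes)
        led = build_ledger(system, res, at)
        rec = {"variant": name,
               "uptake_ug": led.loc["total", "uptake_ug"],
               "cost_ug": led.loc["total", "cost_ug"]}
        for r in LEDGER_ROWS:
            rec[f"bc_{r}"] = led.loc[r, "benefit_cost"]
        return rec

    base = run(params, "base")
    records.append({**base, "d_uptake_pct": 0.0, "d_cost_pct": 0.0})
    for name, perturbs in variants.items():
        p = params
        for path, f in perturbs:
            p = apply_factor(p, path, f)
        rec = run(p, name)
        rec["d_uptake_pct"] = 100.0 * (rec["uptake_ug"] / base["uptake_ug"] - 1.0)
        rec["d_cost_pct"] = 100.0 * (rec["cost_ug"] / base["cost_ug"] - 1.0)
        records.append(rec)
    return pd.DataFrame(records).set_index("variant")
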