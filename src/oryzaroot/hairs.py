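"""Explicit root-hair cohorts.

Every root segment carries a cohort of root hairs: identical cylinders of
class-specific length and 5 µm diameter, at a density (hairs per cm of
root) that declines linearly with the age of the host segment.  Hairs
appear with their segment and the cohort thins as the segment ages, so the
hair population of a segment born at time τ is
``density(age) × segment length`` at age = t − τ.

Because all hairs of a cohort share their geometry, cohort totals
(count × one cylinder) are exact, not an approximation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import RootSystem, length_birth_histogram
from .params import CLASS_IDS, HairParams, RootClassParams

__all__ = ["hair_density", "hair_geometry", "hair_share_report",
           "hair_cylinder_totals"]


def hair_cylinder_totals(total_length_cm: float, diameter: float = 0.0005,
                         tissue_density: float = 0.1) -> dict[str, float]:
    """Aggregate geometry of a hair population of known total length.

    surface = π·d·L (cm²), volume = π·d²/4·L (cm³),
    weight = volume × tissue density (g).
    """
    surface = np.pi * diameter * total_length_cm
    volume = np.pi * (diameter / 2.0) ** 2 * total_length_cm
    return {"surface_cm2": surface, "volume_cm3": volume,
            "weight_g": volume * tissue_density}


def hair_density(class_params: RootClassParams | HairParams, root_age: float):
    """Hairs per cm of root on a segment of age ``root_age`` (days).

    Density holds at the class ceiling up to the anchor age (3 d) and then
    declines linearly (the published reference decline, 600 → 330 hairs
    cm⁻¹ between ages 3 and 40 d, scaled to the class ceiling), clamped at
    zero.
    """
    hp = class_params.hair if isinstance(class_params, RootClassParams) else class_params
    age = np.asarray(root_age, dtype=float)
    if np.any(age < 0):
        raise ValueError("root age must be >= 0")
    return hp.density(root_age)


def _hair_counts_by_class(system: RootSystem, at: float) -> dict[str, float]:
    """Total live hairs per host class at time ``at`` (density × length)."""
    edges, hist = length_birth_histogram(system, at)
    mid_age = np.clip(at - 0.5 * (edges[:-1] + edges[1:]), 0.0, None)
    counts = {}
    for c in CLASS_IDS:
        hp = system.params.classes[c].hair
        counts[c] = float((hist[c] * hp.density(mid_age)).sum())
    return counts


def hair_geometry(system: RootSystem, at: float | None = None) -> pd.DataFrame:
    """Hair ledger per host class: count, length, surface, volume, weight.

    Totals are Σ over cohorts of n_hairs × (one cylinder): length in cm,
    surface π·d·L cm², volume π·d²/4·L cm³, weight = volume × 0.1 g cm⁻³.
    """
    at = system.clock if at is None else at
    counts = _hair_counts_by_class(system, at)
    rows = {}
    for c in CLASS_IDS:
        hp = system.params.classes[c].hair
        n = counts[c]
        length = n * hp.length
        rows[c] = {
            "n_hairs": n,
            "length_cm": length,
            "surface_cm2": np.pi * hp.diameter * length,
            "volume_cm3": np.pi * (hp.diameter / 2.0) ** 2 * length,
            "weight_g": np.pi * (hp.diameter / 2.0) ** 2 * length * hp.tissue_density,
        }
    df = pd.DataFrame(rows).T
    df.loc["total"] = df.sum(axis=0)
    df.index.name = "host_class"
    return df


def hair_share_report(system: RootSystem, at: float | None = None) -> dict:
    """Per-host-class shares of hair length/surface/volume, plus the hair
    fraction of whole-system surface and volume and the hair-to-root length
    ratio.

    Note: the published hair-to-root length ratio (6.9×) does not reconcile
    with the published per-class hair and root lengths (482.3 m vs 52.9 m
    gives 9.1×; the class table gives 395.9 vs 66.4 m, 6.0×); the report
    simply prints the ratio this model computes.
    """
    from .architecture import class_geometry

    at = system.clock if at is None else at
    hairs = hair_geometry(system, at)
    geom = class_geometry(system, at)
    tot = hairs.loc["total"]
    shares = {}
    for c in CLASS_IDS:
        shares[c] = {
            "length_pct": 100.0 * hairs.loc[c, "length_cm"] / tot["length_cm"]
            if tot["length_cm"] > 0 else 0.0,
            "surface_pct": 100.0 * hairs.loc[c, "surface_cm2"] / tot["surface_cm2"]
            if tot["surface_cm2"] > 0 else 0.0,
            "volume_pct": 100.0 * hairs.loc[c, "volume_cm3"] / tot["volume_cm3"]
            if tot["volume_cm3"] > 0 else 0.0,
        }
    root = geom.loc["total"]
    combined_surface = root["surface_cm2"] + tot["surface_cm2"]
    combined_volume = root["volume_cm3"] + tot["volume_cm3"]
    return {
        "shares": shares,
        "hair_length_cm": float(tot["length_cm"]),
        "root_length_cm": float(root["length_cm"]),
        "hair_to_root_length_ratio": float(tot["length_cm"] / root["length_cm"])
        if root["length_cm"] > 0 else float("nan"),
        "hair_surface_fraction_pct": 100.0 * float(tot["surface_cm2"] / combined_surface)
        if combined_surface > 0 else 0.0,
        "hair_volume_fraction_pct": 100.0 * float(tot["volume_cm3"] / combined_volume)
        if combined_volume > 0 else 0.0,
    }
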