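import numpy as np
import pytest

from oryzaroot.architecture import (advance, class_geometry, grow,
                                    initial_angle, length_birth_histogram,
                                    nodal_emergence_times, sample_ibd,
                                    tropism_update, RootSystem)
from oryzaroot.params import LATERAL_CLASSES, NODAL_CLASSES, TruncNorm


class TestInitialAngles:
    def test_primary_points_straight_down(self, params):
        h = initial_angle("primary", params, np.random.default_rng(0))
        assert h == pytest.approx([0.0, 0.0, 1.0])

    def test_nodal_rga_distribution(self, params):
        rng = np.random.default_rng(123)
        angles = []
        for _ in range(10_000):
            h = initial_angle("nodal_branched", params, rng)
            angles.append(np.rad2deg(np.arcsin(h[2])))
        angles = np.asarray(angles)
        assert angles.min() >= 8.0 and angles.max() <= 90.0
        frac45 = (angles <= 45.0).mean()
        assert 0.57 <= frac45 <= 0.67

    def test_laterals_rejected(self, params):
        with pytest.raises(ValueError):
            initial_angle("stype", params, np.random.default_rng(0))


class TestTropism:
    def test_no_forces_leaves_heading_unchanged(self, params):
        h0 = np.array([0.6, 0.0, 0.8])
        p = params.classes["ltype"]
        import dataclasses as dc
        p0 = dc.replace(p, gravitropism=0.0)
        h1 = tropism_update(h0, p0, 5.0, np.random.default_rng(0), 0.2,
                            impedance_scale=0.0)
        assert h1 == pytest.approx(h0)

    def test_upward_stype_heading_corrected_to_horizontal(self, params):
        h0 = np.array([0.6, 0.0, -0.8])
        h1 = tropism_update(h0, params.classes["stype"], 5.0,
                            np.random.default_rng(0), 0.2,
                            impedance_scale=0.0)
        assert h1[2] == 0.0
        assert np.linalg.norm(h1) == pytest.approx(1.0)

    def test_horizontal_primary_turns_downward(self, params):
        h = np.array([1.0, 0.0, 0.0])
        p = params.classes["primary"]
        z = [h[2]]
        for _ in range(25):  # 5 days of 0.2-day steps, ~0.44 cm per step
            h = tropism_update(h, p, 10.0, np.random.default_rng(0), 0.2,
                               step_length=0.44, impedance_scale=0.0)
            z.append(h[2])
        assert all(b > a for a, b in zip(z, z[1:]))

    def test_zero_heading_rejected(self, params):
        with pytest.raises(ValueError):
            tropism_update(np.zeros(3), params.classes["primary"], 0.0,
                           np.random.default_rng(0), 0.2)


class TestIBD:
    def test_degenerate_sd_returns_multiplied_mean(self, params):
        p = params.copy()
        p.classes["nodal_fast"].ibd_by_child["stype"] = TruncNorm(
            0.6, 0.0, 0.28, 1.2)
        rng = np.random.default_rng(0)
        early = sample_ibd(p, "nodal_fast", "stype", 1.0, 5.0, rng)
        late = sample_ibd(p, "nodal_fast", "stype", 0.0, 20.0, rng)
        assert early == pytest.approx(1.2)     # doubled in the first 2 weeks
        assert late == pytest.approx(0.6)      # base-position mean after

    def test_fast_nodal_ibd_grows_with_distance_from_base(self, params):
        p = params.copy()
        p.classes["nodal_fast"].ibd_by_child["stype"] = TruncNorm(
            0.6, 0.0, 0.28, 1.2)
        rng = np.random.default_rng(0)
        basal = sample_ibd(p, "nodal_fast", "stype", 0.0, 20.0, rng)
        distal = sample_ibd(p, "nodal_fast", "stype", 40.0, 20.0, rng)
        assert distal > basal

    def test_impermissible_pair_rejected(self, params):
        with pytest.raises(ValueError):
            sample_ibd(params, "stype", "ltype", 0.0, 5.0,
                       np.random.default_rng(0))

    def test_monte_carlo_mean_within_3_se(self, params):
        dist = params.classes["nodal_branched"].ibd_by_child["stype"]
        mean, sd = dist.moments()
        rng = np.random.default_rng(5)
        draws = np.array([sample_ibd(params, "nodal_branched", "stype",
                                     0.0, 20.0, rng) for _ in range(10_000)])
        assert abs(draws.mean() - mean) < 3 * sd / 100.0


class TestEmergenceSchedule:
    def test_first_nodal_roots_are_branched(self, params):
        events = nodal_emergence_times(params, 5.0, np.random.default_rng(0))
        assert len(events) > 0
        assert all(cls == "nodal_branched" for _, cls in events)

    def test_near_zero_horizon_is_empty_or_single(self, params):
        events = nodal_emergence_times(params, 0.1, np.random.default_rng(0))
        assert len(events) <= 1

    def test_count_curve_is_concave_after_slowdown(self, params):
        events = nodal_emergence_times(params, 25.0, np.random.default_rng(0))
        days = np.array([t for t, _ in events])
        n10, n15, n20 = [(days <= d).sum() for d in (10, 15, 20)]
        assert (n20 - n15) - (n15 - n10) <= 0

    def test_fast_class_appears_only_after_day_10(self, params):
        events = nodal_emergence_times(params, 31.0, np.random.default_rng(1))
        fast_days = [t for t, cls in events if cls == "nodal_fast"]
        assert fast_days and min(fast_days) > 10.0

    def test_invalid_horizon(self, params):
        with pytest.raises(ValueError):
            nodal_emergence_times(params, 0.0)


class TestAdvance:
    def test_zero_step_leaves_system_unchanged(self, params):
        system = grow(params, seed=0, horizon=5)
        before = system.total_length()
        advance(system, 0.0)
        assert system.total_length() == before

    def test_step_larger_than_max_rejected(self, params):
        system = RootSystem(params, seed=0)
        with pytest.raises(ValueError):
            advance(system, 0.5)

    def test_child_attached_at_crossing_position(self, params):
        """A pending branch distance crossed during a step yields a child
        attached at exactly that arc position on the parent."""
        system = grow(params, seed=2, horizon=15)
        for c in LATERAL_CLASSES:
            arr = system.lateral_arrays(c)
            for i in range(min(20, len(arr["birth"]))):
                parent = arr["parent_axis"][i]
                main = {a.axis_id: a for a in system.main_axes}.get(parent)
                if main is None:
                    continue
                # attachment position <= parent length at emission time
                assert arr["attach_arc"][i] <= main.length(arr["birth"][i]) + 1e-6


class TestGrownSystem:
    def test_stype_outnumber_ltype_outnumber_nodal(self, system31):
        counts = system31.axis_counts()
        nodal = sum(counts[c] for c in NODAL_CLASSES) + counts["primary"]
        assert counts["stype"] > counts["ltype"] > nodal

    def test_seed_determinism_is_bit_exact(self, params):
        a = grow(params, seed=9, horizon=12)
        b = grow(params, seed=9, horizon=12)
        assert a.total_length() == b.total_length()
        assert a.axis_counts() == b.axis_counts()
        c = grow(params, seed=10, horizon=12)
        assert c.total_length() != a.total_length()

    def test_no_axis_exceeds_its_length_ceiling(self, system31):
        for a in system31.main_axes:
            assert a.length(31) <= a.curve.max_length * a.multiplier + 1e-9
        for c in LATERAL_CLASSES:
            arr = system31.lateral_arrays(c)
            lens = system31.lateral_lengths(c, 31)
            cap = system31.params.classes[c].max_length
            assert np.all(lens <= cap * arr["multiplier"] + 1e-9)

    def test_total_length_matches_birth_histogram(self, system31):
        edges, hist = length_birth_histogram(system31, 31)
        total = sum(h.sum() for h in hist.values())
        assert total == pytest.approx(system31.total_length(31), rel=1e-6)

    def test_most_root_length_in_top_25cm(self, system31):
        assert system31.depth_fraction(25.0) >= 0.80

    def test_depth_is_never_negative(self, system31):
        cloud = system31.segment_cloud(31)
        assert (cloud["z"] >= -1e-6).all()

    def test_laterals_have_valid_parents(self, system31):
        main_ids = {a.axis_id for a in system31.main_axes}
        l_ids = set(system31.lateral_arrays("ltype")["axis_id"])
        s_parents = set(system31.lateral_arrays("stype")["parent_axis"])
        assert set(system31.lateral_arrays("ltype")["parent_axis"]) <= main_ids
        assert s_parents <= (main_ids | l_ids)


class TestClassGeometry:
    def test_cylinder_formulas(self, system31):
        geom = class_geometry(system31, 31)
        stype_len = geom.loc["stype", "length_cm"]
        assert geom.loc["stype", "surface_cm2"] == pytest.approx(
            np.pi * 0.0045 * stype_len)
        assert geom.loc["stype", "volume_cm3"] == pytest.approx(
            np.pi * 0.00225**2 * stype_len)
        assert geom.loc["total", "length_cm"] == pytest.approx(
            geom.drop("total").sum()["length_cm"])

    def test_337m_of_stype_gives_476_cm2(self):
        # 33.7 m of S-type root at 45 um: pi * 0.0045 * 3370
        assert np.pi * 0.0045 * 3370 == pytest.approx(47.6, abs=0.05)

    def test_empty_system_has_zero_ledger(self, params):
        system = RootSystem(params, seed=0)
        geom = class_geometry(system, 0.0)
        assert geom["length_cm"].sum() == 0.0
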