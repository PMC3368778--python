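"""Treatments, damage and inter-element interactions."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

import ocellus as oc
from ocellus.errors import InputError
from ocellus.scenario import apply_damage, apply_treatment
from tests.conftest import bisect_contact

UNIT = oc.UniformField(-1.0)


def extents(scenario, t, angle=0.0):
    return {
        (rb.organiser_index, rb.label): (float(rb.rear), float(rb.front))
        for rb in oc.resolve_interactions(scenario, t, angle)
    }


class TestTreatments:
    def test_identity_factors_leave_scenario_unchanged(self, typical_eyespot):
        same = apply_treatment(
            typical_eyespot, "tungstate", 2.0,
            factors={"k_v": 1.0, "k_D": 1.0, "k_I": 1.0, "k_prop": 1.0},
        )
        for t in (5.0, 9.0, 10.0, 14.0):
            assert extents(same, t) == pytest.approx(extents(typical_eyespot, t))

    def test_tungstate_rescales_unreleased_signal(self, typical_eyespot):
        treated = apply_treatment(typical_eyespot, "tungstate", 0.0)
        w = treated.organisers[0].trains[0].windows[0]
        assert w.v0 == pytest.approx(6.0)
        assert oc.final_position(w.v0, -1.0) == pytest.approx(18.0)  # vs 50

    def test_heat_on_released_pfe_travels_farther_and_narrower(
        self, pfe_scenario
    ):
        treated = apply_treatment(pfe_scenario, "heat", 3.0)
        t_snap = 5.0
        rear_u, front_u = extents(pfe_scenario, t_snap)[(0, "pfe")]
        rear_h, front_h = extents(treated, t_snap)[(0, "pfe")]
        assert rear_h > rear_u and front_h > front_u
        assert (front_h - rear_h) < (front_u - rear_u)
        # initial velocity untouched: same settled position eventually
        w = treated.organisers[0].trains[0].windows[0]
        assert w.v0 == 10.0

    def test_cold_on_released_pfe_lags_and_stays_wider(self, pfe_scenario):
        treated = apply_treatment(pfe_scenario, "cold", 3.0)
        rear_u, front_u = extents(pfe_scenario, 5.0)[(0, "pfe")]
        rear_c, front_c = extents(treated, 5.0)[(0, "pfe")]
        assert rear_c < rear_u and front_c < front_u
        assert (front_c - rear_c) > (front_u - rear_u)

    def test_treatment_series_ordering(self, typical_eyespot):
        """Radius shrinks and light-ring proportion grows from untreated
        through mild to strong treatment (all compared mid-signalling)."""
        mild = apply_treatment(
            typical_eyespot, "tungstate", 0.0,
            factors={"k_v": 0.8, "k_D": 0.8, "k_I": 1.25},
        )
        strong = apply_treatment(typical_eyespot, "tungstate", 0.0)
        t_snap = 7.5
        radii, props = [], []
        for sc in (typical_eyespot, mild, strong):
            m = oc.measure_rings(oc.radial_profile(sc, t_snap))
            radii.append(m.radius)
            props.append(m.proportions["light"])
        assert radii[0] > radii[1] > radii[2]
        assert props[0] < props[1] < props[2]

    def test_unknown_kind_and_bad_factor_rejected(self, typical_eyespot):
        with pytest.raises(InputError):
            apply_treatment(typical_eyespot, "gamma", 1.0)
        with pytest.raises(InputError):
            apply_treatment(typical_eyespot, "cold", 1.0, factors={"k_v": -1.0})


class TestDamage:
    def test_focal_damage_after_settlement_is_invisible(self, typical_eyespot):
        damaged = apply_damage(typical_eyespot, 20.0, (0.0, 0.0), 2.0)
        for t in (10.0, 25.0):
            g0 = oc.render_grid(typical_eyespot, t, 0.5, 55.0)
            g1 = oc.render_grid(damaged, t, 0.5, 55.0)
            assert np.array_equal(g0.classes, g1.classes)

    def test_focal_damage_before_release_gives_background(self, typical_eyespot):
        damaged = apply_damage(typical_eyespot, 0.0, (0.0, 0.0), 2.0)
        g = oc.render_grid(damaged, 10.0, 0.5, 55.0)
        assert set(np.unique(g.classes)) == {oc.BACKGROUND}

    def test_mid_train_ablation_cancels_later_rings(self, typical_eyespot):
        # outer window [0,3] already closed, inner [6,9] not yet open
        damaged = apply_damage(typical_eyespot, 4.0, (0.0, 0.0), 2.0)
        prof = oc.radial_profile(damaged, 10.0)
        classes = {c for c, _, _ in prof.segments}
        assert oc.OUTER in classes and oc.CORE not in classes

    def test_non_focal_damage_adds_one_ectopic_ring_system(
        self, typical_eyespot
    ):
        damaged = apply_damage(typical_eyespot, 2.0, (80.0, 0.0), 1.0)
        assert len(damaged.organisers) == 2

        def n_ring_systems(sc, t):
            g = oc.render_grid(sc, t, 0.5, 100.0)
            dark = np.isin(g.classes, (oc.CORE, oc.OUTER))
            _, n = ndimage.label(dark)
            return n

        t_snap = 6.0  # ectopic band still has positive width here
        assert (
            n_ring_systems(damaged, t_snap)
            == n_ring_systems(typical_eyespot, t_snap) + 1
        )

    def test_negative_radius_rejected(self, typical_eyespot):
        with pytest.raises(InputError):
            apply_damage(typical_eyespot, 1.0, (0.0, 0.0), -1.0)


class TestInteractions:
    def test_barrier_clamps_front_on_blocked_ray_only(self, typical_eyespot):
        barrier = oc.LineBarrier(point=(30.0, 0.0), normal=(1.0, 0.0))
        sc = replace(typical_eyespot, barriers=(barrier,))
        blocked = extents(sc, 30.0, angle=0.0)
        free = extents(sc, 30.0, angle=np.pi)
        assert blocked[(0, "outer")] == pytest.approx((30.0, 30.0))
        assert free[(0, "outer")] == pytest.approx((50.0, 50.0))

    def test_first_contact_matches_bisection_oracle(self):
        p = oc.preset("double_focus")
        tc = oc.first_contact_time(p.scenario, 0, 1)

        def span(t):
            e = extents(p.scenario, t)
            return e[(0, "outer")][1] + e[(1, "outer")][1]

        ref = bisect_contact(span, 20.0, 0.0, 5.0)
        assert tc == pytest.approx(10.0 - np.sqrt(80.0), abs=1e-6)
        assert tc == pytest.approx(ref, abs=1e-6)

    def test_fusion_below_threshold_unions_occupancies(self):
        p = oc.preset("double_focus")  # t_inhib=5 > contact ~1.056
        assert oc.fused_pairs(p.scenario) == {(0, 1)}
        e = extents(p.scenario, 30.0)
        assert e[(0, "outer")][1] == pytest.approx(50.0)  # no midpoint clamp

    def test_late_contact_clamps_at_midpoint(self):
        p = oc.preset("double_focus")
        sc = replace(p.scenario, t_inhib=0.5)
        assert oc.fused_pairs(sc) == set()
        e = extents(sc, 30.0, angle=0.0)  # ray towards the partner
        assert e[(0, "outer")][1] == pytest.approx(10.0)

    def test_min_gap_holds_at_all_times(self):
        sc = oc.preset("dorsal_min_gap").scenario
        for t in np.linspace(4.0, 30.0, 27):
            e = extents(sc, t)
            if (0, "inner") in e and (0, "outer") in e:
                inner_front = e[(0, "inner")][1]
                outer_rear = e[(0, "outer")][0]
                assert inner_front <= outer_rear - sc.min_gap + 1e-9

    def test_clamps_never_increase_extents(self, typical_eyespot):
        barrier = oc.LineBarrier(point=(20.0, 0.0), normal=(1.0, 0.0))
        clamped_sc = replace(
            typical_eyespot, barriers=(barrier,), min_gap=2.0
        )
        for t in (5.0, 8.0, 10.0, 14.0):
            free = extents(typical_eyespot, t)
            clamped = extents(clamped_sc, t)
            for key in free:
                assert clamped[key][0] <= free[key][0] + 1e-12
                assert clamped[key][1] <= free[key][1] + 1e-12

    def test_soft_barrier_approaches_but_never_reaches(self, typical_eyespot):
        soft = oc.LineBarrier(
            point=(30.0, 0.0), normal=(1.0, 0.0), mode="soft", margin=2.0
        )
        sc = replace(typical_eyespot, barriers=(soft,))
        fronts = [extents(sc, t)[(0, "outer")][1] for t in (6.0, 8.0, 12.0, 30.0)]
        assert all(f < 30.0 for f in fronts)
        assert all(b >= a for a, b in zip(fronts, fronts[1:]))
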