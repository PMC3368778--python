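"""Ring-structure metrics, the inside-wide rule, PFE laws and round trips."""

import numpy as np
import pytest

import ocellus as oc
from ocellus.errors import InputError, NormalizationError


class TestMeasureRings:
    def test_typical_eyespot_widths(self, typical_eyespot):
        m = oc.measure_rings(oc.radial_profile(typical_eyespot, 10.0))
        assert m.core_width == pytest.approx(22.5)
        assert m.light_width == pytest.approx(13.5)
        assert m.outer_width == pytest.approx(4.5)
        assert m.radius == pytest.approx(50.0)
        assert m.inside_wide

    def test_proportions_sum_to_one(self, typical_eyespot):
        for t in (2.0, 8.0, 10.0, 12.0):
            m = oc.measure_rings(oc.radial_profile(typical_eyespot, t))
            assert sum(m.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_blank_core_has_no_core_ring(self):
        sc = oc.preset("blank_core").scenario
        m = oc.measure_rings(oc.radial_profile(sc, 10.0))
        assert m.core_width == 0.0
        assert not m.inside_wide
        assert m.outer_width > 0

    def test_pattern_without_rings_yields_zero_metrics(self):
        sc = oc.Scenario(organisers=())
        m = oc.measure_rings(oc.radial_profile(sc, 5.0, r_max=20.0))
        assert m.radius == 0.0 and not m.inside_wide

    def test_focus_only_preset_has_tiny_reach(self):
        p = oc.preset("focus_only")
        w = p.scenario.organisers[0].trains[0].windows[0]
        r_f = p.scenario.organisers[0].focus_radius
        assert oc.final_position(w.v0, -1.0) < 2.0 * r_f


class TestInsideWideWindow:
    @pytest.mark.parametrize("t", [8, 9, 10, 11, 12])
    def test_inside_wide_throughout_typical_window(self, typical_eyespot, t):
        m = oc.measure_rings(oc.radial_profile(typical_eyespot, float(t)))
        assert m.inside_wide
        assert m.light_width > 0


class TestMeasurePfe:
    @pytest.mark.parametrize(
        "t,distance,width", [(5.0, 25.5, 12.0), (8.0, 42.0, 6.0)]
    )
    def test_band_position_and_width(self, pfe_scenario, t, distance, width):
        m = oc.measure_pfe(oc.radial_profile(pfe_scenario, t))
        assert m.distance == pytest.approx(distance)
        assert m.width == pytest.approx(width)

    def test_reference_normalises_to_exactly_one(self, pfe_scenario):
        prof = oc.radial_profile(pfe_scenario, 5.0)
        ref = oc.measure_pfe(prof)
        m = oc.measure_pfe(prof, reference=ref)
        assert (m.norm_distance, m.norm_width) == (1.0, 1.0)

    def test_zero_width_reference_rejected(self, pfe_scenario):
        bad_ref = oc.PFEMetrics(distance=10.0, width=0.0)
        prof = oc.radial_profile(pfe_scenario, 5.0)
        with pytest.raises(NormalizationError):
            oc.measure_pfe(prof, reference=bad_ref)

    def test_profile_without_pfe_rejected(self, typical_eyespot):
        with pytest.raises(InputError):
            oc.measure_pfe(oc.radial_profile(typical_eyespot, 10.0))

    def test_distance_grows_and_width_shrinks_until_settlement(
        self, pfe_scenario
    ):
        rows = oc.pfe_table(pfe_scenario, list(range(3, 12)))
        assert np.all(np.diff(rows["distance"]) > 0)
        assert np.all(np.diff(rows["width"]) < 0)


class TestSizeStructureLaw:
    def test_small_eyespot_series_orders_radius_and_light(self):
        """Weaker organisers give smaller eyespots with proportionally
        wider light rings."""
        sc = oc.preset("figure7_small_series").scenario
        radii, light_props = [], []
        for k in range(len(sc.organisers)):
            m = oc.measure_rings(
                oc.radial_profile(sc, 10.0, organiser_index=k)
            )
            radii.append(m.radius)
            light_props.append(m.proportions["light"])
        assert all(b < a for a, b in zip(radii, radii[1:]))
        assert all(b > a for a, b in zip(light_props, light_props[1:]))

    def test_graft_weakened_is_smaller_with_wider_light(self, typical_eyespot):
        m_norm = oc.measure_rings(oc.radial_profile(typical_eyespot, 10.0))
        m_graft = oc.measure_rings(
            oc.radial_profile(oc.preset("graft_weakened").scenario, 10.0)
        )
        assert m_graft.radius < m_norm.radius
        assert m_graft.proportions["light"] > m_norm.proportions["light"]


class TestRenderMeasureRoundTrip:
    @pytest.mark.parametrize("h", [1.0, 0.5, 0.25])
    @pytest.mark.parametrize("preset_name", ["figure6_typical", "figure7_small_series"])
    def test_grid_measurement_recovers_analytic_widths(self, preset_name, h):
        sc = oc.preset(preset_name).scenario
        exact = oc.measure_rings(oc.radial_profile(sc, 10.0))
        grid = oc.render_grid(sc, 10.0, h, extent=exact.radius + 5.0)
        measured = oc.measure_rings(grid)
        for attr in ("core_width", "light_width", "outer_width", "radius"):
            assert getattr(measured, attr) == pytest.approx(
                getattr(exact, attr), abs=2 * h
            )

    def test_metrics_table_shape(self, typical_eyespot):
        tbl = oc.metrics_table(typical_eyespot, list(range(1, 13)))
        assert len(tbl) == 12
        assert tbl["inside_wide"].iloc[9]  # t = 10
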