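"""Mesh generator, wavefront simulator, presets, linear maps, cohorts."""

import networkx as nx
import numpy as np
import pytest

from crtsync.geometry import LV, RV, PacingSetting, triangle_areas
from crtsync.metrics import DEFAULT_FRACTIONS, activation_curve, chamber_metrics, time_to_fraction
from crtsync.synthetic import (
    CohortSimParams,
    ConfigurationError,
    SimulationConfig,
    _edge_geometry,
    _edge_weights,
    _scope_times_from_sorted,
    lv_lateral_vertex,
    make_biv_shell_mesh,
    make_linear_activation_map,
    make_preset_map,
    preset_config,
    rv_apex_vertex,
    rv_freewall_vertex,
    simulate_activation,
    simulate_cohort,
    warp_activation_times,
)

from conftest import random_sphere_mesh


def oracle_times(mesh, config):
    """Independent shortest-path reference: networkx Dijkstra per source."""
    edges, lengths, edge_class = _edge_geometry(mesh)
    weights = _edge_weights(mesh, edges, lengths, edge_class, config)
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    for (a, b), w in zip(edges, weights):
        g.add_edge(int(a), int(b), weight=w)
    best = np.full(mesh.n_vertices, np.inf)
    for site, delay in config.breakthrough_sites:
        dist = nx.single_source_dijkstra_path_length(g, site)
        for v, d in dist.items():
            best[v] = min(best[v], d + delay)
    return best - best.min()


class TestShellMesh:
    def test_coarse_mesh_valid_with_both_labels(self):
        mesh = make_biv_shell_mesh(0)
        assert set(mesh.chamber_label) == {LV, RV}
        assert mesh.n_triangles == 20

    def test_subdivision_quadruples_triangle_count(self):
        n0 = make_biv_shell_mesh(0).n_triangles
        assert make_biv_shell_mesh(2).n_triangles == 16 * n0

    def test_lv_area_fraction_near_symmetric_half(self, fine_mesh):
        """Septal plane through the center splits the continuum shell area
        exactly in half; the discrete labeling converges to it."""
        areas = triangle_areas(fine_mesh)
        lv_frac = areas[fine_mesh.chamber_label == LV].sum() / areas.sum()
        assert lv_frac == pytest.approx(0.5, abs=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            make_biv_shell_mesh(-1)
        with pytest.raises(ConfigurationError):
            make_biv_shell_mesh(1, radii=(45.0, 0.0, 60.0))


class TestSimulateActivation:
    def test_single_source_uniform_velocity_closed_form(self):
        """With one site and uniform velocity v, time = graph distance / v."""
        mesh = make_biv_shell_mesh(1)
        v = 2.0
        config = SimulationConfig(
            breakthrough_sites=[(0, 0.0)],
            base_velocity=v,
            seam_velocity_scale=1.0,
        )
        amap = simulate_activation(mesh, config)
        g = nx.Graph()
        for a, b in mesh.edges():
            g.add_edge(
                int(a),
                int(b),
                weight=float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b])),
            )
        dist = nx.single_source_dijkstra_path_length(g, 0)
        for vtx in range(mesh.n_vertices):
            assert amap.vertex_time[vtx] == pytest.approx(dist[vtx] / v, rel=1e-12)

    def test_two_sites_min_superposition(self, shell_mesh):
        base = dict(base_velocity=1.1, seam_velocity_scale=0.5)
        c1 = SimulationConfig(breakthrough_sites=[(3, 0.0)], **base)
        c2 = SimulationConfig(breakthrough_sites=[(77, 30.0)], **base)
        both = SimulationConfig(breakthrough_sites=[(3, 0.0), (77, 30.0)], **base)
        edges, lengths, ec = _edge_geometry(shell_mesh)
        w = _edge_weights(shell_mesh, edges, lengths, ec, c1)
        from crtsync.synthetic import _graph
        from scipy.sparse.csgraph import dijkstra

        d = dijkstra(_graph(shell_mesh, edges, w), directed=False, indices=[3, 77])
        expected = np.minimum(d[0], d[1] + 30.0)
        amap = simulate_activation(shell_mesh, both)
        np.testing.assert_array_equal(amap.vertex_time, expected - expected.min())

    def test_matches_brute_force_dijkstra_oracle(self, shell_mesh):
        rng = np.random.default_rng(42)
        config = SimulationConfig(
            breakthrough_sites=[(10, 0.0), (50, 15.0)],
            base_velocity=0.9,
            chamber_velocity_scale={LV: 0.8, RV: 1.1},
            seam_velocity_scale=0.5,
            scar_patches=[(int(rng.integers(shell_mesh.n_vertices)), 12.0, 0.4)],
        )
        amap = simulate_activation(shell_mesh, config)
        np.testing.assert_array_equal(amap.vertex_time, oracle_times(shell_mesh, config))

    def test_delay_translation_invariance(self, shell_mesh):
        sites = [(5, 0.0), (120, 20.0)]
        shifted = [(5, 17.0), (120, 37.0)]
        a = simulate_activation(
            shell_mesh, SimulationConfig(breakthrough_sites=sites)
        )
        b = simulate_activation(
            shell_mesh, SimulationConfig(breakthrough_sites=shifted)
        )
        np.testing.assert_allclose(a.vertex_time, b.vertex_time, atol=1e-12)

    def test_halving_velocity_doubles_travel_times(self, shell_mesh):
        fast = simulate_activation(
            shell_mesh,
            SimulationConfig(breakthrough_sites=[(8, 0.0)], base_velocity=1.0),
        )
        slow = simulate_activation(
            shell_mesh,
            SimulationConfig(breakthrough_sites=[(8, 0.0)], base_velocity=0.5),
        )
        np.testing.assert_allclose(slow.vertex_time, 2.0 * fast.vertex_time, rtol=1e-12)

    def test_invalid_configs_rejected(self, shell_mesh):
        with pytest.raises(ConfigurationError):
            SimulationConfig(breakthrough_sites=[])
        with pytest.raises(ConfigurationError):
            SimulationConfig(breakthrough_sites=[(0, -1.0)])
        with pytest.raises(ConfigurationError):
            simulate_activation(
                shell_mesh, SimulationConfig(breakthrough_sites=[(10**6, 0.0)])
            )


class TestPresets:
    def test_bbb_ordering(self, shell_mesh):
        for seed in range(10):
            lbbb = chamber_metrics(make_preset_map(shell_mesh, "LBBB", seed=seed))
            rbbb = chamber_metrics(make_preset_map(shell_mesh, "RBBB", seed=seed))
            assert lbbb.time("LV", 0.8) > lbbb.time("RV", 0.8)
            assert rbbb.time("RV", 0.8) > rbbb.time("LV", 0.8)

    def test_bivp_lv30_offsets(self, shell_mesh):
        config = preset_config(shell_mesh, "BIVP_LV30", seed=0, jitter=False)
        delays = dict(config.breakthrough_sites)
        assert delays[lv_lateral_vertex(shell_mesh)] == 0.0
        assert delays[rv_apex_vertex(shell_mesh)] == 30.0
        assert PacingSetting.BIVP_LV30.lv_offset_ms == 30.0

    def test_landmarks_lie_in_expected_chambers(self, shell_mesh):
        assert shell_mesh.vertices[lv_lateral_vertex(shell_mesh), 0] > 0
        assert shell_mesh.vertices[rv_freewall_vertex(shell_mesh), 0] < 0
        assert shell_mesh.vertices[rv_apex_vertex(shell_mesh), 0] <= 0

    def test_unknown_preset_rejected(self, shell_mesh):
        with pytest.raises(ConfigurationError, match="unknown preset"):
            make_preset_map(shell_mesh, "HIS_BUNDLE")

    def test_preset_map_deterministic_given_seed(self, shell_mesh):
        a = make_preset_map(shell_mesh, "LVP", seed=123)
        b = make_preset_map(shell_mesh, "LVP", seed=123)
        np.testing.assert_array_equal(a.vertex_time, b.vertex_time)


class TestLinearActivationMap:
    def granularity(self, mesh):
        areas = triangle_areas(mesh)
        return areas.max() / areas.sum()

    def test_time_to_80pct_near_analytic(self, fine_mesh):
        amap = make_linear_activation_map(fine_mesh, "BIV", 150.0)
        curve = activation_curve(amap, "BIV")
        gran_ms = self.granularity(fine_mesh) * 150.0
        assert time_to_fraction(curve, 0.8) == pytest.approx(120.0, abs=2 * gran_ms)

    @pytest.mark.parametrize("duration", [130.0, 150.0])
    def test_all_ratios_near_point_eight(self, fine_mesh, duration):
        amap = make_linear_activation_map(fine_mesh, "BIV", duration)
        m = chamber_metrics(amap)
        tol = 4 * self.granularity(fine_mesh)
        for scope in ("LV", "RV", "BIV"):
            assert m.ratio(scope, 0.8) == pytest.approx(0.8, abs=tol)

    def test_midpoint_fraction(self, fine_mesh):
        amap = make_linear_activation_map(fine_mesh, "BIV", 150.0)
        curve = activation_curve(amap, "BIV")
        assert curve.fraction_at(75.0) == pytest.approx(0.5, abs=4 * self.granularity(fine_mesh))

    def test_invalid_duration_rejected(self, fine_mesh):
        with pytest.raises(ConfigurationError):
            make_linear_activation_map(fine_mesh, "BIV", 0.0)


class TestWarp:
    def test_monotone_warp_preserves_order(self, shell_mesh):
        amap = make_linear_activation_map(shell_mesh, "BIV", 100.0)
        warped = warp_activation_times(amap, [(0.0, 0.0), (80.0, 50.0), (100.0, 130.0)])
        assert warped.vertex_time.max() == pytest.approx(130.0, abs=1.0)
        order_a = np.argsort(amap.vertex_time, kind="stable")
        order_w = np.argsort(warped.vertex_time, kind="stable")
        np.testing.assert_array_equal(order_a, order_w)


class TestCohort:
    def test_fixed_seed_is_bitwise_reproducible(self, shell_mesh):
        p = CohortSimParams(n_patients=8, seed=99)
        a = simulate_cohort(shell_mesh, p)
        b = simulate_cohort(shell_mesh, CohortSimParams(n_patients=8, seed=99))
        assert a.equals(b)

    def test_noiseless_outcomes_exactly_linear(self, shell_mesh):
        params = CohortSimParams(
            n_patients=6,
            seed=5,
            noise_sd={k: 0.0 for k in CohortSimParams().noise_sd},
        )
        tab = simulate_cohort(shell_mesh, params)
        np.testing.assert_allclose(
            tab["lvesvi_fc_lvp"], -0.30 + 0.005 * tab["lvrvdiff_lvp"], rtol=1e-12
        )
        np.testing.assert_allclose(
            tab["delta_peak_vo2"], 0.3 - 3.0 * tab["rv80_fc_bivp"], rtol=1e-12
        )

    def test_bbb_proportions_and_schema(self, shell_mesh):
        tab = simulate_cohort(shell_mesh, CohortSimParams(n_patients=40, seed=3))
        assert set(tab["bbb"]) <= {"LBBB", "RBBB"}
        for col in (
            "qrs_ms",
            "qlv_ms",
            "lv80_intrinsic",
            "rv80_bivp",
            "lvrvdiff_lvp",
            "rv80_fc_bivp",
            "lvesvi_fc_lvp",
            "log_bnp_post",
            "delta_peak_vo2",
            "rvef",
        ):
            assert col in tab.columns, col
        assert tab["patient_id"].is_unique

    def test_fast_scope_times_match_public_metrics(self, shell_mesh):
        """The cohort engine's vectorised scope times equal chamber_metrics."""
        amap = make_preset_map(shell_mesh, "LBBB", seed=17)
        areas = triangle_areas(shell_mesh)
        masks = {
            "LV": shell_mesh.chamber_label == LV,
            "RV": shell_mesh.chamber_label == RV,
            "BIV": np.ones(shell_mesh.n_triangles, dtype=bool),
        }
        fast = _scope_times_from_sorted(
            amap.triangle_times(), areas, masks, DEFAULT_FRACTIONS
        )
        ref = chamber_metrics(amap)
        for scope in ("LV", "RV", "BIV"):
            for f in DEFAULT_FRACTIONS:
                assert fast[scope][f] == pytest.approx(ref.time(scope, f), abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSimParams(prop_lbbb=1.5)
        with pytest.raises(ConfigurationError):
            CohortSimParams(noise_sd={"rvef": -1.0})

    def test_unknown_outcome_predictor_rejected(self, shell_mesh):
        params = CohortSimParams(
            n_patients=3,
            outcome_coefficients={"y": {"intercept": 0.0, "not_a_column": 1.0}},
        )
        with pytest.raises(ConfigurationError, match="unknown predictor"):
            simulate_cohort(shell_mesh, params)


class TestOracleEquivalenceRandomMeshes:
    def test_random_mesh_exact_equality(self):
        rng = np.random.default_rng(1)
        mesh = random_sphere_mesh(rng, 200)
        sites = rng.choice(mesh.n_vertices, size=2, replace=False)
        config = SimulationConfig(
            breakthrough_sites=[(int(sites[0]), 0.0), (int(sites[1]), 25.0)],
            base_velocity=float(rng.uniform(0.5, 1.5)),
            chamber_velocity_scale={LV: 0.9, RV: 1.2},
            seam_velocity_scale=0.6,
        )
        amap = simulate_activation(mesh, config)
        np.testing.assert_array_equal(amap.vertex_time, oracle_times(mesh, config))
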