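import math

import numpy as np
import pytest
from dataclasses import replace

import smfishq as sq
from smfishq.simulate import (
    _sample_nb,
    _sample_ztp,
    make_ts_ladder_scene,
    zero_truncated_poisson_mean,
    zero_truncated_poisson_rate,
)


class TestCountLaws:
    def test_ztp_rate_inverts_mean(self):
        lam = zero_truncated_poisson_rate(3.6)
        assert zero_truncated_poisson_mean(lam) == pytest.approx(3.6, abs=1e-9)
        with pytest.raises(ValueError):
            zero_truncated_poisson_rate(0.9)

    def test_ztp_samples_have_no_zeros_and_right_mean(self):
        rng = np.random.default_rng(0)
        lam = zero_truncated_poisson_rate(3.6)
        draws = _sample_ztp(rng, lam, 20000)
        assert draws.min() >= 1
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 3.6) < 3 * se

    def test_negative_binomial_mean_at_study_scale(self):
        """10,000 expressing-cell counts at the study mean (10.1/cell)."""
        rng = np.random.default_rng(1)
        draws = _sample_nb(rng, 10.1, 3.0, 10000)
        se = draws.std() / 100.0
        assert abs(draws.mean() - 10.1) < 3 * se
        # NB variance mu + mu^2/r, clearly overdispersed vs Poisson
        assert draws.var() > 2 * draws.mean()


class TestSampleScene:
    def test_deterministic_given_seed(self, small_params):
        a = sq.sample_scene(small_params)
        b = sq.sample_scene(small_params)
        assert len(a.cells) == len(b.cells)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.phase == cb.phase
            np.testing.assert_array_equal(ca.mrnas, cb.mrnas)
            assert ca.ts == cb.ts

    def test_expression_switched_off(self):
        params = sq.ScenarioParams(seed=2, n_cells=8, expressing_fraction_G1=0.0)
        scene = sq.sample_scene(params)
        assert all(len(c.mrnas) == 0 and c.ts is None for c in scene.cells)

    def test_zero_cells_is_a_valid_empty_scene(self):
        scene = sq.sample_scene(sq.ScenarioParams(seed=0, n_cells=0))
        assert scene.n_cells == 0

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            sq.sample_scene(sq.ScenarioParams(seed=0, n_cells=500))

    def test_geometry_invariants(self, cell_scene):
        from shapely.geometry import Point, Polygon

        for c in cell_scene.cells:
            cell = Polygon(c.cell_polygon)
            nucleus = Polygon(c.nucleus_polygon)
            assert cell.buffer(1e-6).covers(nucleus)
            for x, y, _, _ in c.mrnas:
                assert cell.covers(Point(x, y))
                assert not nucleus.covers(Point(x, y))  # cytoplasmic
            if c.ts is not None:
                assert nucleus.covers(Point(c.ts["x"], c.ts["y"]))
                assert c.ts["nascent_n"] >= 1

    def test_expression_restricted_to_g1(self, cell_scene):
        for c in cell_scene.cells:
            if c.phase != "G1":
                assert len(c.mrnas) == 0 and c.ts is None

    def test_brightness_is_binomial_probe_occupancy(self):
        params = sq.ScenarioParams(seed=5, n_cells=12, expressing_fraction_G1=1.0,
                                   phase_fractions={"G1": 1.0, "S": 0, "G2": 0, "M": 0},
                                   mature_mean=30.0)
        qs = sq.sample_scene(params).all_mrnas()[:, 3]
        assert len(qs) > 100
        # every brightness is q_probe times an integer in [0, n_probes]
        ks = qs / params.q_probe
        np.testing.assert_allclose(ks, np.round(ks), atol=1e-9)
        assert ks.max() <= params.n_probes
        cv_expected = math.sqrt((1 - params.p_bind) / (params.n_probes * params.p_bind))
        cv = qs.std() / qs.mean()
        assert cv == pytest.approx(cv_expected, rel=0.35)


class TestRenderStack:
    def test_photon_conservation_noise_free(self, cell_scene):
        """With noise off, rendered signal above offset equals the summed
        ground-truth integrated intensities to better than 1%."""
        stack = sq.render_stack(cell_scene, "FISH", noise=False)
        total = stack.data.sum() - cell_scene.params.noise["offset"] * stack.data.size
        q_truth = cell_scene.all_mrnas()[:, 3].sum() + sum(
            c.ts["Q_true"] for c in cell_scene.cells if c.ts
        )
        assert total == pytest.approx(q_truth, rel=0.01)

    def test_empty_scene_renders_flat_offset(self):
        scene = sq.sample_scene(sq.ScenarioParams(seed=0, n_cells=0))
        stack = sq.render_stack(scene, "FISH", noise=False)
        assert np.all(stack.data == scene.params.noise["offset"])

    def test_render_deterministic_with_noise(self, cell_scene):
        a = sq.render_stack(cell_scene, "FISH")
        b = sq.render_stack(cell_scene, "FISH")
        np.testing.assert_array_equal(a.data, b.data)

    def test_ts_is_superposition_of_molecule_equivalents(self):
        """At p_bind=1 a TS of n transcripts integrates to exactly n times
        the single-molecule intensity."""
        params = sq.ScenarioParams(seed=8, n_cells=4, p_bind=1.0,
                                   expressing_fraction_G1=1.0,
                                   phase_fractions={"G1": 1.0, "S": 0, "G2": 0, "M": 0})
        scene = make_ts_ladder_scene([4, 4], params, n_singles=2)
        single_q = params.q_probe * params.n_probes
        for c in scene.cells[:2]:
            assert c.ts["Q_true"] == pytest.approx(4 * single_q)

    def test_if_channel_intensity_increases_after_g1(self, cell_scene, if_stack):
        proj = sq.max_project(if_stack)
        bg = np.median(proj)
        outlines = sq.scene_outlines(cell_scene)
        by_phase: dict[str, list[float]] = {}
        for o, c in zip(outlines, cell_scene.cells):
            val = sq.if_integrated_intensity(if_stack, o)
            by_phase.setdefault(c.phase, []).append(val)
        if "G1" in by_phase and len(by_phase) > 1:
            g1 = np.mean(by_phase["G1"])
            others = [np.mean(v) for p, v in by_phase.items() if p != "G1"]
            assert all(g1 < o for o in others)


class TestArtifacts:
    def test_zero_drift_is_identity(self, fish_stack):
        out = sq.inject_z_drift(fish_stack, (0.0, 0.0))
        np.testing.assert_array_equal(out.data, fish_stack.data)

    def test_unit_drift_shifts_last_plane_by_its_index(self):
        data = np.zeros((41, 8, 64))
        data[:, 4, 10] = 100.0
        stack = sq.ImageStack(data)
        out = sq.inject_z_drift(stack, (0.0, 1.0))
        assert out.data[40, 4, 50] == pytest.approx(100.0)
        assert out.data[0, 4, 10] == pytest.approx(100.0)

    def test_bottom_debris_confined_to_low_planes(self, if_stack):
        clean = sq.render_stack
        out = sq.add_bottom_debris(if_stack, n_blobs=6, planes=3, seed=1)
        delta = out.data - if_stack.data
        assert delta[:4].sum() > 0
        assert delta[6:].sum() == pytest.approx(0.0, abs=1e-6 * delta.sum())


class TestExports:
    def test_truth_table_covers_all_cells(self, cell_scene):
        df = sq.scene_truth_table(cell_scene)
        assert set(df["cell_id"]) == {c.cell_id for c in cell_scene.cells}
        n_mols = sum(len(c.mrnas) for c in cell_scene.cells)
        assert (df["kind"] == "mature").sum() == n_mols

    def test_outline_export_units_are_pixels(self, cell_scene):
        outlines = sq.scene_outlines(cell_scene)
        nx = cell_scene.params.field_shape[2]
        for o in outlines:
            xs = [v[0] for v in o.cell_polygon]
            assert 0 <= min(xs) and max(xs) <= nx
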