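import numpy as np
import pytest

import smfishq as sq
from smfishq.cells import ScoringThresholds, measure_bud_ratio, score_cell_cycle
from smfishq.detect import SpotFit, SpotTable
from smfishq.io import CellOutline, DetectionSettings


def _spot(x_px, y_px, **kw):
    defaults = dict(z=20 * 200.0, amplitude=50.0, background=100.0, sigma_xy=130.0,
                    sigma_z=350.0, Q=6912.0, residual_rms=1.0, converged=True,
                    accepted=True)
    defaults.update(kw)
    return SpotFit(x=(x_px + 0.5) * 64.5, y=(y_px + 0.5) * 64.5, **defaults)


def _square(cx, cy, r):
    return [(cx - r, cy - r), (cx + r, cy - r), (cx + r, cy + r), (cx - r, cy + r)]


class TestAssignSpots:
    def test_centroid_spot_assigned(self):
        o = CellOutline("c1", _square(50, 50, 20))
        table = SpotTable("p", [_spot(50, 50)], DetectionSettings())
        assigned, unassigned = sq.assign_spots(table, [o])
        assert len(assigned["c1"]) == 1 and not unassigned

    def test_outside_spot_unassigned(self):
        o = CellOutline("c1", _square(50, 50, 20))
        table = SpotTable("p", [_spot(100, 100)], DetectionSettings())
        assigned, unassigned = sq.assign_spots(table, [o])
        assert not assigned["c1"] and len(unassigned) == 1

    def test_on_edge_counts_inside(self):
        o = CellOutline("c1", _square(50, 50, 20))
        # spot whose pixel coordinate lands exactly on the left edge (30 px)
        table = SpotTable("p", [_spot(30.0, 50.0)], DetectionSettings())
        assigned, unassigned = sq.assign_spots(table, [o])
        assert len(assigned["c1"]) == 1 and not unassigned

    def test_overlapping_polygons_smaller_wins(self):
        big = CellOutline("big", _square(50, 50, 30))
        small = CellOutline("small", _square(50, 50, 10))
        table = SpotTable("p", [_spot(50, 50)], DetectionSettings())
        assigned, _ = sq.assign_spots(table, [big, small])
        assert len(assigned["small"]) == 1 and not assigned["big"]

    def test_conservation_of_accepted_spots(self, position_result, cell_scene):
        """Every accepted spot lands in exactly one cell or the unassigned
        bucket."""
        assigned, unassigned = sq.assign_spots(
            position_result.table, sq.scene_outlines(cell_scene)
        )
        total = sum(len(v) for v in assigned.values()) + len(unassigned)
        assert total == len(position_result.table.accepted)


class TestIFIntegration:
    def test_blank_stack_integrates_to_zero(self):
        o = CellOutline("c1", _square(20, 20, 10))
        stack = sq.ImageStack(np.full((41, 64, 64), 50.0), channel="IF")
        assert sq.if_integrated_intensity(stack, o) == pytest.approx(0.0, abs=1e-6)

    def test_doubling_signal_doubles_integral(self, cell_scene, if_stack):
        o = sq.scene_outlines(cell_scene)[0]
        v1 = sq.if_integrated_intensity(if_stack, o)
        boosted = sq.ImageStack(
            np.median(if_stack.data) + 2.0 * (if_stack.data - np.median(if_stack.data)),
            if_stack.voxel_size, "IF",
        )
        v2 = sq.if_integrated_intensity(boosted, o)
        assert v2 == pytest.approx(2.0 * v1, rel=0.05)

    def test_bottom_debris_excluded_from_quantification(self, cell_scene, if_stack):
        """Debris confined to the slide bottom changes the per-cell IF
        integral by <1% when the bottom planes are excluded."""
        dirty = sq.add_bottom_debris(if_stack, n_blobs=20, planes=3,
                                     amplitude=2000.0, seed=5)
        for o in sq.scene_outlines(cell_scene)[:4]:
            clean_v = sq.if_integrated_intensity(if_stack, o, exclude_bottom=3)
            dirty_v = sq.if_integrated_intensity(dirty, o, exclude_bottom=3)
            assert dirty_v == pytest.approx(clean_v, rel=0.01, abs=50.0)

    def test_empty_range_after_exclusion_rejected(self, if_stack):
        o = CellOutline("c1", _square(20, 20, 10))
        with pytest.raises(ValueError):
            sq.if_integrated_intensity(if_stack, o, z_range=(5, 3))

    def test_invariant_to_planes_outside_range(self, cell_scene, if_stack):
        o = sq.scene_outlines(cell_scene)[0]
        v1 = sq.if_integrated_intensity(if_stack, o, z_range=(5, 35))
        shuffled = if_stack.data.copy()
        shuffled[[0, 1, 2]] = shuffled[[2, 0, 1]]
        v2 = sq.if_integrated_intensity(
            sq.ImageStack(shuffled, if_stack.voxel_size, "IF"), o, z_range=(5, 35)
        )
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestScoring:
    TH = ScoringThresholds(r_S=0.05, r_G2=0.35, span_M=2000.0)

    def test_rule_order(self):
        base = dict(if_integrated=10.0, bud_ratio=0.0, spindle_span=0.0)
        assert score_cell_cycle(base, tau_G1=100.0, thresholds=self.TH) == "G1"
        assert score_cell_cycle({**base, "spindle_span": 3000.0}, 100.0, self.TH) == "M"
        assert score_cell_cycle({**base, "bud_ratio": 0.5}, 100.0, self.TH) == "G2"
        assert score_cell_cycle({**base, "bud_ratio": 0.15}, 100.0, self.TH) == "S"
        assert score_cell_cycle({**base, "if_integrated": 500.0}, 100.0, self.TH) == "unscored"

    def test_missing_feature_unscored(self):
        assert score_cell_cycle({"bud_ratio": 0.1}, 100.0, self.TH) == "unscored"
        assert score_cell_cycle(
            {"bud_ratio": None, "spindle_span": 1.0, "if_integrated": 1.0}, 100.0, self.TH
        ) == "unscored"

    def test_bud_ratio_zero_for_round_cell(self):
        import math

        pts = [(50 + 20 * math.cos(t), 50 + 20 * math.sin(t))
               for t in np.linspace(0, 2 * math.pi, 40, endpoint=False)]
        assert measure_bud_ratio(CellOutline("round", pts)) == 0.0

    def test_bud_ratio_recovers_generator_morphology(self, cell_scene):
        for o, c in zip(sq.scene_outlines(cell_scene), cell_scene.cells):
            measured = measure_bud_ratio(o)
            if c.phase == "G1":
                assert measured < 0.05
            else:
                assert measured == pytest.approx(c.bud_ratio_true, abs=0.12)

    def test_cohort_phase_accuracy(self, position_result, cell_scene):
        truth = {c.cell_id: c.phase for c in cell_scene.cells}
        hits = [r.phase == truth[r.cell_id] for r in position_result.records]
        assert np.mean(hits) >= 0.9


class TestCellRecords:
    def test_counts_match_generator(self, position_result, cell_scene):
        truth = {c.cell_id: c for c in cell_scene.cells}
        for r in position_result.records:
            c = truth[r.cell_id]
            assert abs(r.n_mature - len(c.mrnas)) <= 1
            if c.ts is None:
                assert r.n_nascent == 0

    def test_expressing_flag_definition(self, position_result):
        for r in position_result.records:
            assert r.expressing == (r.n_mature + r.n_nascent >= 1)

    def test_nascent_backed_by_ts_record(self, position_result):
        with_ts = {t.cell_id for t in position_result.ts_records}
        for r in position_result.records:
            if r.n_nascent > 0:
                assert r.cell_id in with_ts
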