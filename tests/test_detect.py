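import numpy as np
import pytest
from dataclasses import replace

import smfishq as sq
from smfishq.detect import predetect, table_to_frame, frame_to_table
from smfishq.io import DetectionSettings
from smfishq.qc import bandpass_filter
from tests.conftest import single_spot_stack


class TestPredetect:
    def test_blank_stack_yields_no_candidates(self):
        stack = sq.ImageStack(np.zeros((9, 32, 32)))
        s = DetectionSettings(predetect_threshold=5.0)
        assert predetect(stack, s) == []

    def test_two_separated_spots_found_at_centers(self):
        from smfishq.simulate import _add_gaussian

        voxel = (200.0, 64.5, 64.5)
        E = np.zeros((21, 40, 40))
        centers = [(10 * 64.5, 20 * 64.5, 10 * 200), (30 * 64.5, 20 * 64.5, 10 * 200)]
        for cx, cy, cz in centers:
            _add_gaussian(E, voxel, cx, cy, cz, 6912.0, 130.0, 350.0)
        stack = sq.ImageStack(E, voxel_size=voxel)
        s = DetectionSettings(predetect_threshold=1.0, min_separation=3)
        filt = bandpass_filter(stack, s)
        cands = predetect(filt, s)
        assert len(cands) == 2
        found_x = sorted(c[2] for c in cands)
        assert abs(found_x[0] - 9.5) <= 1 and abs(found_x[1] - 29.5) <= 1

    def test_plateau_resolves_to_single_candidate(self):
        data = np.zeros((5, 9, 9))
        data[2, 4, 4] = data[2, 4, 5] = 10.0  # two-voxel plateau
        s = DetectionSettings(predetect_threshold=5.0)
        cands = predetect(sq.ImageStack(data), s)
        assert cands == [(2, 4, 4)]  # first in (z, y, x) order wins

    def test_nonpositive_threshold_rejected(self):
        s = DetectionSettings(predetect_threshold=0.0)
        with pytest.raises(ValueError):
            predetect(sq.ImageStack(np.zeros((5, 8, 8))), s)


class TestFitSpot3D:
    def test_noiseless_fit_recovers_forward_model_exactly(self):
        """Oracle equivalence: on a noise-free rendered spot the fit recovers
        the generator parameters far inside the 1e-3 relative band."""
        stack, center = single_spot_stack(Q=6912.0, sigma_xy=130.0, sigma_z=350.0)
        fit = sq.fit_spot_3d(stack, (10, 12, 12), DetectionSettings())
        assert fit.converged
        assert abs(fit.x - center[0]) < 1.0 and abs(fit.y - center[1]) < 1.0
        assert abs(fit.z - center[2]) < 1.0
        assert fit.Q == pytest.approx(6912.0, rel=1e-3)
        assert fit.sigma_xy == pytest.approx(130.0, rel=1e-3)
        assert fit.sigma_z == pytest.approx(350.0, rel=1e-3)
        assert fit.background == pytest.approx(100.0, abs=0.1)

    def test_localization_precision_at_study_snr(self):
        """Lateral RMSE well under 30 nm for spots at the default SNR."""
        errs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            dx = rng.uniform(-32, 32)
            stack, center = single_spot_stack(
                center=(12.5 * 64.5 + dx, 12.5 * 64.5, 10.5 * 200.0), noise_seed=seed
            )
            fit = sq.fit_spot_3d(stack, (10, 12, 12), DetectionSettings())
            errs.append(fit.x - center[0])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 30.0

    def test_flat_background_is_a_fit_failure(self):
        stack = sq.ImageStack(np.full((21, 25, 25), 100.0))
        fit = sq.fit_spot_3d(stack, (10, 12, 12), DetectionSettings())
        assert not fit.converged
        assert fit.reject_reason == "fit_failure"

    def test_cropped_window_flagged_not_rejected(self):
        stack, _ = single_spot_stack(center=(3 * 64.5, 12.5 * 64.5, 10.5 * 200.0))
        fit = sq.fit_spot_3d(stack, (10, 12, 2), DetectionSettings())
        assert fit.cropped


class TestFilterSpots:
    def test_wide_bounds_accept_all_converged(self, sparse_fish):
        table = sq.detect_spots(sparse_fish, DetectionSettings())
        wide = replace(table.settings, accept_Q=(0.0, np.inf),
                       accept_amplitude=(0.0, np.inf),
                       accept_sigma_xy=(0.0, np.inf), accept_sigma_z=(0.0, np.inf))
        out = sq.filter_spots(table, wide)
        dup = [s for s in out.spots if s.reject_reason == "duplicate"]
        assert len(out.accepted) + len(dup) == sum(s.converged for s in out.spots)

    def test_q_ceiling_below_everything_rejects_all(self, sparse_table):
        tight = replace(sparse_table.settings, accept_Q=(0.0, 1.0))
        out = sq.filter_spots(sparse_table, tight)
        assert not out.accepted
        assert all(
            s.reject_reason in ("Q_high", "fit_failure", "duplicate")
            for s in out.spots
        )

    def test_widening_bounds_never_loses_accepted_spots(self, sparse_table):
        s = sparse_table.settings
        narrow = replace(s, accept_Q=(5000.0, 8000.0))
        wide = replace(s, accept_Q=(3000.0, 12000.0))
        n_narrow = len(sq.filter_spots(sparse_table, narrow).accepted)
        n_wide = len(sq.filter_spots(sparse_table, wide).accepted)
        assert n_wide >= n_narrow

    def test_rejected_fits_are_retained_with_reason(self, sparse_table):
        tight = replace(sparse_table.settings, accept_sigma_xy=(50.0, 100.0))
        out = sq.filter_spots(sparse_table, tight)
        assert len(out.spots) == len(sparse_table.spots)
        assert all(s.reject_reason for s in out.spots if not s.accepted)


class TestDetectSpots:
    def test_all_singles_recovered_on_sparse_scene(self, sparse_scene, sparse_table):
        truth = sparse_scene.all_mrnas()
        found = np.array([[s.x, s.y] for s in sparse_table.accepted])
        assert len(found) == len(truth)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth[:, :2]).query(found)
        assert (d < 2 * 64.5).all()

    def test_empty_stack_detects_nothing(self):
        rng = np.random.default_rng(0)
        stack = sq.ImageStack(rng.normal(100, 2, (41, 128, 128)).clip(0))
        table = sq.detect_spots(stack, DetectionSettings())
        assert table.accepted == []

    def test_deterministic(self, sparse_fish):
        a = sq.detect_spots(sparse_fish, DetectionSettings())
        b = sq.detect_spots(sparse_fish, DetectionSettings())
        assert len(a.spots) == len(b.spots)
        for sa, sb in zip(a.spots, b.spots):
            assert (sa.x, sa.y, sa.z, sa.Q) == (sb.x, sb.y, sb.z, sb.Q)

    def test_accepted_q_histogram_matches_generator_brightness(self, sparse_scene, sparse_table):
        """Accepted intensities form one narrow mode whose CV tracks the
        binomial probe-occupancy CV of the generator."""
        import math

        p = sparse_scene.params
        qs = np.array([s.Q for s in sparse_table.accepted])
        cv = qs.std() / qs.mean()
        cv_gen = math.sqrt((1 - p.p_bind) / (p.n_probes * p.p_bind))
        assert cv == pytest.approx(cv_gen, rel=0.35)

    def test_table_round_trips_through_frame(self, sparse_table):
        df = table_to_frame(sparse_table)
        back = frame_to_table(df, sparse_table.settings)
        assert len(back.spots) == len(sparse_table.spots)
        assert len(back.accepted) == len(sparse_table.accepted)
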