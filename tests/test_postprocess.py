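import numpy as np
import pytest

from fhrcluster.clustering import ClusterConfig, assign_roles, kmedoids_pp
from fhrcluster.feature_select import select_feature
from fhrcluster.maxmin_features import MaxMinPoint, find_maxmin_points
from fhrcluster.postprocess import (
    CorrectionConfig,
    RefineConfig,
    correct_fp_fn,
    refine_fetal_cluster,
)
from fhrcluster.synth_aecg import generate_aecg, scenario_preset
from fhrcluster.wavelet_denoise import denoise


def _train(rr: int, n: int, start: int = 1000) -> np.ndarray:
    return start + rr * np.arange(n, dtype=np.int64)


def _points_at(indices, amplitude=1.0, width=20):
    return [MaxMinPoint(int(i), int(i) + width, amplitude, amplitude - amplitude) for i in indices]


class TestRefine:
    @pytest.fixture()
    def clustered_window(self, scenario1_recording):
        pts = find_maxmin_points(denoise(scenario1_recording.record))
        choice = select_feature(pts)
        res = assign_roles(kmedoids_pp(choice.feature_values, ClusterConfig(seed=0)))
        return pts, res, choice.summary

    def test_low_amplitude_point_removed(self, clustered_window):
        pts, res, summary = clustered_window
        kept = refine_fetal_cluster(pts, res, summary, RefineConfig(amp_low=10.0))
        assert kept == []  # bound above every amplitude removes everything

    def test_wide_rs_span_removed(self, clustered_window):
        pts, res, summary = clustered_window
        base = refine_fetal_cluster(pts, res, summary, RefineConfig(rs_width_max_ms=60.0))
        none_left = refine_fetal_cluster(pts, res, summary, RefineConfig(rs_width_max_ms=0.0))
        assert len(base) > 0
        assert none_left == []
        assert all(p.n_samples <= 60 for p in base)

    def test_output_sorted_by_max_idx(self, clustered_window):
        pts, res, summary = clustered_window
        kept = refine_fetal_cluster(pts, res, summary)
        idx = [p.max_idx for p in kept]
        assert idx == sorted(idx)

    def test_refinement_keeps_true_fetal_beats(self, scenario2_recording):
        """With low noise, no candidate within 50 ms of a fetal truth beat is refined away."""
        rec = scenario2_recording
        pts = find_maxmin_points(denoise(rec.record))
        choice = select_feature(pts)
        res = assign_roles(kmedoids_pp(choice.feature_values, ClusterConfig(seed=0)))
        before = refine_fetal_cluster(pts, res, choice.summary, RefineConfig(rs_width_max_ms=1e9, amp_low=-1.0, amp_high=1e9))
        after = refine_fetal_cluster(pts, res, choice.summary)
        truth = rec.fetal_truth.indices
        near_before = {p.max_idx for p in before if np.min(np.abs(truth - p.max_idx)) <= 50}
        near_after = {p.max_idx for p in after if np.min(np.abs(truth - p.max_idx)) <= 50}
        assert near_before == near_after

    def test_roles_required(self, clustered_window):
        pts, res, summary = clustered_window
        from dataclasses import replace

        with pytest.raises(ValueError, match="roles"):
            refine_fetal_cluster(pts, replace(res, roles=None), summary)


class TestCorrectFpFn:
    def test_extra_beat_removed(self):
        cand = _train(430, 12)
        spurious = int(cand[5] + 80)
        with_fp = np.sort(np.append(cand, spurious))
        pts = _points_at(cand, amplitude=1.0) + _points_at([spurious], amplitude=0.4)
        out = correct_fp_fn(with_fp, 1000.0, points=pts)
        np.testing.assert_array_equal(out, cand)

    def test_missing_beat_reinserted_near_true_position(self):
        cand = _train(430, 12)
        missing = int(cand[6])
        gappy = np.delete(cand, 6)
        pts = _points_at(cand, amplitude=1.0)
        out = correct_fp_fn(gappy, 1000.0, points=pts)
        assert np.any(np.abs(out - missing) <= 50)
        assert out.size == cand.size

    def test_single_candidate_passthrough(self):
        out = correct_fp_fn(np.array([5000]), 1000.0)
        np.testing.assert_array_equal(out, [5000])

    def test_identity_on_clean_train(self):
        cand = _train(430, 30)
        out = correct_fp_fn(cand, 1000.0, points=_points_at(cand))
        np.testing.assert_array_equal(out, cand)

    def test_output_strictly_increasing_with_audit(self, rng):
        cand = np.unique(rng.integers(0, 120_000, 250))
        pts = _points_at(cand)
        audit = []
        out = correct_fp_fn(cand, 1000.0, points=pts, audit=audit)
        assert np.all(np.diff(out) > 0)
        known = {p.max_idx for p in pts}
        assert all(int(i) in known for i in out)
        assert all(a["action"] in ("remove_fp", "insert_fn") for a in audit)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CorrectionConfig(fhr_min_bpm=250.0)
        with pytest.raises(ValueError):
            CorrectionConfig(short_rr_frac=1.2)
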