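"""End-to-end orchestration of the clustering-based FHR detection method.

The record is denoised once in full (avoiding window-edge wavelet
artifacts), then processed in consecutive windows of ``window_samples``
(default 50,000): per window, max-min point extraction, automatic feature
selection, k-medoids++ classification into noise/fetal/maternal, role
assignment, and fetal-cluster refinement. Window-local detections are
offset to global indices, duplicates across window seams are merged
keeping the larger amplitude, and the RR-based FP/FN correction runs once
over the concatenated fetal train. A final partial window of at least
10,000 samples stands alone; a shorter one is merged into the previous
window (detection quality is insensitive to window length in roughly the
10,000-60,000 sample range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import ROLE_FETAL, ROLE_MATERNAL, ClusterConfig, assign_roles, kmedoids_pp
from .evaluation import EvalReport, evaluate
from .feature_select import select_feature
from .maxmin_features import MaxMinPoint, find_maxmin_points
from .postprocess import CorrectionConfig, RefineConfig, correct_fp_fn, refine_fetal_cluster
from .signal_io import AnnotationSet, EcgRecord
from .wavelet_denoise import DenoiseConfig, denoise

logger = logging.getLogger(__name__)

MIN_RECORD_SAMPLES = 1_000
MIN_STANDALONE_WINDOW = 10_000


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for the full detection pipeline."""

    window_samples: int = 50_000
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    eval_tol_ms: float = 50.0
    per_window_denoise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_samples < MIN_RECORD_SAMPLES:
            raise ValueError("window_samples must be >= 1000")


def _window_bounds(n: int, window: int) -> list[tuple[int, int]]:
    """Consecutive [start, stop) windows; a short final remainder is merged."""
    if n <= window:
        return [(0, n)]
    starts = list(range(0, n, window))
    bounds = [(s, min(s + window, n)) for s in starts]
    if bounds[-1][1] - bounds[-1][0] < min(MIN_STANDALONE_WINDOW, window):
        last = bounds.pop()
        prev = bounds.pop()
        bounds.append((prev[0], last[1]))
    return bounds


def _merge_seam_duplicates(
    points: list[MaxMinPoint], tol_samples: float
) -> list[MaxMinPoint]:
    """Drop the weaker of two detections closer than the matching tolerance
    (can only occur across a window seam)."""
    if len(points) < 2:
        return points
    out = [points[0]]
    for p in points[1:]:
        if p.max_idx - out[-1].max_idx <= tol_samples:
            if p.amplitude > out[-1].amplitude:
                out[-1] = p
        else:
            out.append(p)
    return out


def run_pipeline(
    record: EcgRecord, config: PipelineConfig = PipelineConfig()
) -> tuple[AnnotationSet, AnnotationSet, list[dict]]:
    """Run the full method on one record.

    Returns ``(fetal, maternal, diagnostics)``: the corrected fetal R-peak
    annotations, the maternal-cluster R-peak annotations, and one
    diagnostics dict per window (case id, cluster sizes, corrections).
    """
    if record.n < MIN_RECORD_SAMPLES:
        raise ValueError(f"record too short: {record.n} < {MIN_RECORD_SAMPLES} samples")

    work = record if config.per_window_denoise else denoise(record, config.denoise)

    fetal_points: list[MaxMinPoint] = []
    maternal_points: list[MaxMinPoint] = []
    all_points: list[MaxMinPoint] = []
    diagnostics: list[dict] = []

    bounds = _window_bounds(work.n, config.window_samples)
    for w, (start, stop) in enumerate(bounds):
        seg = work.samples[start:stop]
        if config.per_window_denoise:
            seg_rec = EcgRecord(record.record_id, record.channel, record.fs, seg)
            seg = denoise(seg_rec, config.denoise).samples
        local = find_maxmin_points(seg)
        points = [
            MaxMinPoint(p.max_idx + start, p.min_idx + start, p.max_val, p.min_val) for p in local
        ]
        all_points.extend(points)
        diag = {"window": w, "start": start, "stop": stop, "n_points": len(points)}
        try:
            choice = select_feature(points)
            ccfg = replace(config.cluster, seed=config.cluster.seed + config.seed * 1_000 + w)
            result = assign_roles(kmedoids_pp(choice.feature_values, ccfg))
            fetal = refine_fetal_cluster(
                points, result, choice.summary, config.refine, fs=record.fs
            )
            maternal_cluster = result.cluster_of(ROLE_MATERNAL)
            maternal = [p for p, lab in zip(points, result.labels) if lab == maternal_cluster]
            diag.update(
                case_id=choice.case_id,
                feature=choice.feature_name,
                cluster_sizes=np.bincount(result.labels, minlength=3).tolist(),
                n_fetal=len(fetal),
                n_refined_out=int(np.sum(result.labels == result.cluster_of(ROLE_FETAL))) - len(fetal),
            )
            fetal_points.extend(fetal)
            maternal_points.extend(maternal)
        except ValueError as exc:
            logger.warning("window %d [%d:%d): skipped (%s)", w, start, stop, exc)
            diag["skipped"] = str(exc)
        diagnostics.append(diag)

    tol_samples = config.eval_tol_ms * record.fs / 1000.0
    fetal_points = _merge_seam_duplicates(sorted(fetal_points, key=lambda p: p.max_idx), tol_samples)

    audit: list[dict] = []
    fetal_idx = correct_fp_fn(
        np.array([p.max_idx for p in fetal_points], dtype=np.int64),
        record.fs,
        config.correction,
        points=all_points,
        audit=audit,
    )
    if diagnostics:
        diagnostics[-1]["corrections"] = audit

    maternal_idx = np.unique(np.array([p.max_idx for p in maternal_points], dtype=np.int64))
    fetal_ann = AnnotationSet(record.record_id, "fetal_detected", fetal_idx)
    maternal_ann = AnnotationSet(record.record_id, "maternal_detected", maternal_idx)
    return fetal_ann, maternal_ann, diagnostics


def run_evaluation(
    detected: AnnotationSet,
    reference: AnnotationSet,
    fs: float,
    tol_ms: float = 50.0,
) -> EvalReport:
    """Score a detection against reference annotations (thin wrapper)."""
    return evaluate(detected, reference, fs, tol_ms)


__all__ = ["PipelineConfig", "run_pipeline", "run_evaluation"]
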