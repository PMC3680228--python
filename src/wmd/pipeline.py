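"""End-to-end composition: recordings → features → trained model → report.

Stages, per subject/session:

1. zero-phase bandpass of every recording;
2. noise-template estimation from the background (rest) recording;
3. spectral subtraction of the template from each flexion recording;
4. amplitude standardization by one session-level RMS constant (the RMS
   of the class-1 recordings), which preserves the *relative* MUAP
   magnitudes that encode muscle identity;
5. persistent wavelet-maxima extraction;
6. 300 ms windowing, 4-group magnitude clustering, feature assembly;
7. TSVM training and repeated-subsampling (or k-fold) evaluation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluate import EvaluationReport, cross_validate
from .features import (FEATURE_COLUMNS, flexion_features, global_window_stats,
                       segment, window_stats)
from .maxima import persistent_maxima
from .preprocess import (bandpass, estimate_noise_template, spectral_subtract)
from .synth import EMGRecording, LabeledDataset

__all__ = ["extract_feature_table", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error tied to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _session_rms_constant(flexions: list[EMGRecording], class_names) -> float:
    """RMS of the (bandpassed) class-1 recordings: the session amplitude unit."""
    first = class_names[0]
    parts = [r.samples for r in flexions if r.label == first]
    if not parts:
        raise PipelineError("normalize", f"no recordings of class {first!r} "
                                         "to set the session RMS constant")
    x = np.concatenate(parts)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        raise PipelineError("normalize", "class-1 recordings are all zero")
    return rms


def extract_feature_table(dataset: LabeledDataset,
                          config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run stages 1–6 and return one feature row per window (or flexion).

    Columns: ``subject_id, trial_id, window_index, label, c1..c4, d1..d4``.
    With ``config.per_window_features`` off, windows of a flexion are
    averaged rank-wise into a single row (window_index −1).
    """
    cfg = config or PipelineConfig()
    fs = cfg.sampling.fs
    k = cfg.clustering.k

    background = dataset.background
    if not background:
        raise PipelineError("noise-template", "dataset has no background recording "
                                              "for noise-template estimation")
    flexions = dataset.flexions
    if not flexions:
        raise PipelineError("segment", "dataset has no flexion recordings")

    filtered = [bandpass(r, cfg.filter) for r in flexions]
    template = estimate_noise_template(
        background[0], window_len=cfg.stft.window_len, filter_spec=cfg.filter)
    denoised = [
        spectral_subtract(r, template, cfg.oversubtraction_alpha) for r in filtered
    ]
    norm = _session_rms_constant(denoised, dataset.class_names)
    logger.info("session RMS constant: %.6g", norm)

    rows = []
    n_chains_total = 0
    n_windows_valid = 0
    for rec in denoised:
        x = rec.samples / norm
        maxima = persistent_maxima(x, n_scales=cfg.wavelet.n_scales,
                                   wavelet=cfg.wavelet.name,
                                   signed=cfg.wavelet.signed_maxima)
        n_chains_total += len(maxima)
        windows = segment(maxima, len(x), cfg.window, fs)
        if cfg.clustering.mode == "flexion":
            stats = global_window_stats(windows, k=k)
        else:
            stats = window_stats(windows, k=k)
        n_windows_valid += len(stats)
        if not stats:
            logger.warning("flexion %s/%s t%d: no valid windows; excluded",
                           rec.subject_id, rec.label, rec.trial_id)
            continue
        if cfg.per_window_features:
            for s in stats:
                rows.append({
                    "subject_id": rec.subject_id, "trial_id": rec.trial_id,
                    "window_index": s.window_index, "label": rec.label,
                    **dict(zip(FEATURE_COLUMNS, s.feature_vector())),
                })
        else:
            f = flexion_features(stats, label=rec.label)
            rows.append({
                "subject_id": rec.subject_id, "trial_id": rec.trial_id,
                "window_index": -1, "label": rec.label,
                **dict(zip(FEATURE_COLUMNS, f.feature_vector())),
            })
    logger.info("persistent chains: %d; valid windows: %d; feature rows: %d",
                n_chains_total, n_windows_valid, len(rows))
    if not rows:
        raise PipelineError("features", "no feature rows produced")
    return pd.DataFrame(rows)


def run_pipeline(dataset: LabeledDataset,
                 config: PipelineConfig | None = None,
                 seed: int | None = None) -> tuple[pd.DataFrame, EvaluationReport]:
    """Full pipeline: feature table plus TSVM evaluation report."""
    cfg = config or PipelineConfig()
    table = extract_feature_table(dataset, cfg)
    X = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    report = cross_validate(
        X, y, mode=cfg.eval.mode, n_repetitions=cfg.eval.n_repetitions,
        n_train=cfg.eval.n_train, n_test=cfg.eval.n_test,
        n_folds=cfg.eval.n_folds,
        seed=cfg.eval.seed if seed is None else seed,
        c1=cfg.tsvm.c1, c2=cfg.tsvm.c2, eps=cfg.tsvm.eps,
        class_names=dataset.class_names,
    )
    return table, report
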