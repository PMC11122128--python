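"""End-to-end helpers: synthetic dataset -> per-method feature tables.

Ties the stages together the way the full experiment runs: render labeled
sequences, extract the SVD-based and EAR-based temporal signals and the
gaze metrics from each, and assemble the per-method feature tables
(SVD-stats, SVD-spectral, EAR-stats, EAR-spectral, Gaze) that the
classifier comparison consumes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import synthetic_eye_data as synth
from .ear_signal import ear_temporal_signal
from .gaze_features import gaze_summary
from .svd_signal import extract_svd_signal
from .ts_features import extract_features

__all__ = [
    "sequence_features",
    "build_feature_tables",
    "average_signals",
    "DATASET_NAMES",
]

DATASET_NAMES = ("SVD-stats", "SVD-spectral", "EAR-stats", "EAR-spectral", "Gaze")


def average_signals(left, right):
    """Fuse the left- and right-eye temporal signals by averaging.

    Off by default throughout the pipeline (the left eye alone feeds the
    features); provided for two-eye processing of real landmark tracks.
    """
    from .svd_signal import TemporalSignal

    if len(left.values) != len(right.values) or left.fps != right.fps:
        raise ValueError("signals must share length and frame rate")
    if left.source != right.source:
        raise ValueError("cannot fuse signals from different methods")
    return TemporalSignal(
        values=(np.asarray(left.values) + np.asarray(right.values)) / 2.0,
        fps=left.fps,
        source=left.source,
        selected_rank=left.selected_rank,
    )


def sequence_features(frames, log, params, fps: float = 30.0) -> dict[str, dict[str, float]]:
    """All per-method feature dicts for one rendered sequence."""
    svd_sig = extract_svd_signal(frames, fps=fps)
    landmarks = synth.landmarks_from_log(log, params)
    ear_sig = ear_temporal_signal(landmarks, fps=fps)
    gaze = gaze_summary(np.asarray(log.iris_x_series, dtype=float))
    return {
        "SVD-stats": extract_features(svd_sig, domain="statistical"),
        "SVD-spectral": extract_features(svd_sig, domain="spectral"),
        "EAR-stats": extract_features(ear_sig, domain="statistical"),
        "EAR-spectral": extract_features(ear_sig, domain="spectral"),
        "Gaze": gaze.as_dict(),
    }


def build_feature_tables(
    n_sequences: int = 120,
    focus_fraction: float = 5.0 / 6.0,
    params: synth.EyeSceneParams | None = None,
    regimes=synth.DEFAULT_REGIMES,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Generate a labeled synthetic dataset and return one feature table
    per method/domain, each with a binary ``label`` column."""
    if params is None:
        params = synth.EyeSceneParams()
    plan = synth.dataset_plan(n_sequences, focus_fraction, regimes, seed)
    rows: dict[str, list[dict[str, float]]] = {name: [] for name in DATASET_NAMES}
    labels = []
    # one sequence in memory at a time: each rendered sequence is ~7 MB
    for regime, seq_seed in plan:
        p = replace(params, seed=seq_seed)
        frames, log, label = synth.generate_sequence(regime, p)
        feats = sequence_features(frames, log, p, fps=p.fps)
        for name in DATASET_NAMES:
            rows[name].append(feats[name])
        labels.append(label)
    tables = {}
    for name in DATASET_NAMES:
        df = pd.DataFrame(rows[name])
        df["label"] = labels
        tables[name] = df
    return tables
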