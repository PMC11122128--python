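"""Probe-caught session windowing.

A recording session is periodically probed (a ding every ``probe_period``
seconds, default 40 s) and the participant reports Focus / non-Focus /
Skip.  Only the last ``keep_window`` seconds (default 20 s) of each probe
interval are retained for analysis — the report labels the time just before
the probe, and discarding the first half avoids the distraction of the
previous ding.  Skip probes are dropped.  At 30 FPS the default window is
600 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbedSession", "segment"]

LABEL_MAP = {"Focus": 1, "nonFocus": 0}


@dataclass
class ProbedSession:
    """Full-session frames (or a 1D signal) with per-probe labels."""

    frames: np.ndarray  # leading axis = frame index
    labels: list[str]  # one per probe, in {"Focus", "nonFocus", "Skip"}
    fps: float = 30.0
    probe_period: float = 40.0
    keep_window: float = 20.0

    def __post_init__(self):
        if self.keep_window > self.probe_period:
            raise ValueError("keep_window must be <= probe_period")


def segment(session: ProbedSession) -> list[tuple[np.ndarray, int]]:
    """Cut the retained window of every non-Skip probe.

    Probe i (1-based) ends at t_i = i * probe_period; its window covers
    [t_i - keep_window, t_i).  Labels must cover every complete probe
    period in the session.  Returns ``(window, binary_label)`` pairs with
    Focus -> 1, nonFocus -> 0.
    """
    n_frames = len(session.frames)
    frames_per_probe = int(round(session.probe_period * session.fps))
    win = int(round(session.keep_window * session.fps))
    n_probes = n_frames // frames_per_probe
    if n_probes > len(session.labels):
        raise ValueError(
            f"{n_probes} complete probe periods but only {len(session.labels)} labels"
        )
    out = []
    for i in range(1, n_probes + 1):
        label = session.labels[i - 1]
        if label == "Skip":
            continue
        if label not in LABEL_MAP:
            raise ValueError(f"unknown probe label {label!r}")
        end = i * frames_per_probe
        out.append((session.frames[end - win : end], LABEL_MAP[label]))
    return out
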