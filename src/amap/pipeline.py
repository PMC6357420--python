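"""End-to-end trial analysis: signals in, component matrix out.

Chains the stages in their canonical order — filter (raw EMG only),
gait events from vertical GRF, six-region stride segmentation,
peak normalization, k-means on/off detection, per-stride components —
so callers (the model layer and the CLI) share one code path.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import DEFAULT_K, OnOffMask, kmeans_onoff
from .gait import (
    DEFAULT_DEBOUNCE_S,
    DEFAULT_THRESHOLD_N,
    GaitEvents,
    GaitSegmentation,
    PropulsionResult,
    detect_events,
    paretic_propulsion,
    segment_strides,
)
from .io import EmgRecording, GrfRecording
from .preprocess import EnvelopeRecording, filter_chain, normalize_to_step_peaks
from .scoring import ComponentMatrix, compute_components

__all__ = ["TrialAnalysis", "analyze_trial"]


@dataclass
class TrialAnalysis:
    """Intermediate and final products of one trial's analysis."""

    components: ComponentMatrix
    envelope: EnvelopeRecording
    mask: OnOffMask
    events: GaitEvents
    strides: list[GaitSegmentation]
    propulsion: PropulsionResult | None = None


def analyze_trial(
    emg: EmgRecording | EnvelopeRecording,
    grf: GrfRecording,
    leg: str | None = None,
    threshold_n: float = DEFAULT_THRESHOLD_N,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    k: int = DEFAULT_K,
    paretic_leg: str | None = None,
    speed_mps: float | None = None,
) -> TrialAnalysis:
    """Run read -> (filter) -> events -> segment -> normalize -> on/off -> components.

    ``emg`` may be a raw recording (the filter chain is applied) or an
    already-extracted envelope recording. ``leg`` defaults to the
    recording's leg. If ``paretic_leg`` is given, paretic propulsion is
    computed over the window spanned by that leg's complete strides.
    """
    leg = leg or emg.leg
    env = filter_chain(emg) if isinstance(emg, EmgRecording) else emg
    events = detect_events(grf, threshold_n=threshold_n, debounce_s=debounce_s)
    strides = segment_strides(events, leg)
    env = normalize_to_step_peaks(env, strides)
    mask = kmeans_onoff(env, k=k)
    components = compute_components(env, mask, strides, speed_mps=speed_mps)
    propulsion = None
    if paretic_leg is not None:
        hs = events.heel_strikes[paretic_leg]
        window = (float(hs[0]), float(hs[-1])) if len(hs) >= 2 else None
        propulsion = paretic_propulsion(grf, paretic_leg, window_s=window)
    return TrialAnalysis(
        components=components,
        envelope=env,
        mask=mask,
        events=events,
        strides=strides,
        propulsion=propulsion,
    )
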