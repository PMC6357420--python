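"""Gait events, six-region stride segmentation, and paretic propulsion.

Heel strike (HS) and toe off (TO) are detected from each belt's vertical
ground reaction force as threshold crossings (default 20 N) sustained for
at least 50 ms, with sub-sample linear interpolation of the crossing time.

Each stride of the analyzed leg — ipsilateral HS to next ipsilateral HS —
is partitioned into six biomechanically matched regions:

========  =============================================================
 DS1      first double support: ipsilateral HS -> contralateral TO
 SS1/SS2  single-leg stance, split at its temporal midpoint
 DS2      second double support: contralateral HS -> ipsilateral TO
 SW1/SW2  swing, split at its temporal midpoint
========  =============================================================

The regions are half-open ``[start, end)`` intervals that tile the stride
exactly, however asymmetric the event timing, which is what makes the
downstream scores comparable across legs with different spatiotemporal
asymmetry.

Paretic propulsion (Pp) is the paretic leg's share of the total forward
impulse: the time integral of the positive anterior GRF of the paretic
leg divided by the summed positive anterior impulse of both legs, in %.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EventSequenceError,
    InsufficientDataError,
    NoGaitDetectedError,
    UndefinedPropulsionError,
)
from .io import GrfRecording

__all__ = [
    "REGIONS",
    "GaitEvents",
    "GaitSegmentation",
    "PropulsionResult",
    "detect_events",
    "segment_strides",
    "paretic_propulsion",
]

logger = logging.getLogger(__name__)

REGIONS = ("DS1", "SS1", "SS2", "DS2", "SW1", "SW2")

DEFAULT_THRESHOLD_N = 20.0
DEFAULT_DEBOUNCE_S = 0.050


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per leg.

    Per leg the merged sequence must be strictly increasing and strictly
    alternating between HS and TO. A leading TO (recording started
    mid-stance) is legal in the container; :func:`detect_events` itself
    drops partial edge contacts so its output starts with a heel strike.
    """

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.heel_strikes = {k: np.asarray(v, float) for k, v in self.heel_strikes.items()}
        self.toe_offs = {k: np.asarray(v, float) for k, v in self.toe_offs.items()}
        for leg in self.heel_strikes:
            hs, to = self.heel_strikes[leg], self.toe_offs[leg]
            merged = sorted(
                [(t, "HS") for t in hs] + [(t, "TO") for t in to], key=lambda e: e[0]
            )
            times = np.array([e[0] for e in merged])
            kinds = [e[1] for e in merged]
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise EventSequenceError(f"leg {leg!r}: event times must strictly increase")
            if any(a == b for a, b in zip(kinds[:-1], kinds[1:])):
                raise EventSequenceError(
                    f"leg {leg!r}: events do not strictly alternate HS, TO, ..."
                )

    @property
    def legs(self) -> tuple[str, ...]:
        return tuple(self.heel_strikes)


@dataclass
class GaitSegmentation:
    """One stride's six-region partition for one leg.

    ``boundaries`` holds 7 strictly increasing times (s):
    ipsilateral HS, contralateral TO, single-support midpoint,
    contralateral HS, ipsilateral TO, swing midpoint, next ipsilateral HS.
    """

    boundaries: np.ndarray
    leg: str = "left"
    regions: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (7,):
            raise EventSequenceError("a stride needs exactly 7 boundary times")
        if not np.all(np.diff(self.boundaries) > 0):
            raise EventSequenceError(
                f"stride boundaries must strictly increase, got {self.boundaries}"
            )

    @property
    def stride_start(self) -> float:
        return float(self.boundaries[0])

    @property
    def stride_end(self) -> float:
        return float(self.boundaries[-1])

    @property
    def stride_duration(self) -> float:
        return float(self.boundaries[-1] - self.boundaries[0])

    @property
    def region_durations(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def region_interval(self, region: str) -> tuple[float, float]:
        i = self.regions.index(region)
        return float(self.boundaries[i]), float(self.boundaries[i + 1])


@dataclass
class PropulsionResult:
    """Anterior impulses (N*s) per leg and paretic propulsion (%)."""

    paretic_impulse: float
    nonparetic_impulse: float
    pp_percent: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.paretic_impulse + self.nonparetic_impulse
        if total <= 0:
            raise UndefinedPropulsionError("both legs have zero propulsive impulse")
        self.pp_percent = 100.0 * self.paretic_impulse / total


def _crossing_time(t: np.ndarray, v: np.ndarray, i: int, threshold: float) -> float:
    """Linear-interpolated time where v crosses threshold between i-1 and i."""
    if i == 0:
        return float(t[0])
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t[i])
    frac = (threshold - v0) / (v1 - v0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def detect_events(
    grf: GrfRecording,
    threshold_n: float = DEFAULT_THRESHOLD_N,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
) -> GaitEvents:
    """Detect heel strikes and toe offs from vertical GRF, per leg.

    A heel strike is an upward crossing of ``threshold_n`` sustained at
    least ``debounce_s``; a toe off is the symmetric downward crossing.
    Shorter contact or flight runs are treated as noise and merged away.
    Leading toe offs and trailing heel strikes (partial contacts) are
    dropped so the sequence is HS, TO, ..., HS, TO.
    """
    heel_strikes, toe_offs = {}, {}
    for leg in grf.legs:
        v = grf.vertical[leg]
        t = grf.times(leg)
        contact = v >= threshold_n
        if contact.all() or not contact.any():
            raise NoGaitDetectedError(
                f"leg {leg!r}: vertical force never crosses {threshold_n} N "
                "in both directions (standing or threshold above peak?)"
            )
        min_run = max(1, int(round(debounce_s * grf.rate_hz)))
        contact = _debounce(contact, min_run)
        if contact.all() or not contact.any():
            raise NoGaitDetectedError(
                f"leg {leg!r}: no sustained contacts after {debounce_s*1e3:.0f} ms debounce"
            )
        rises = np.flatnonzero(~contact[:-1] & contact[1:]) + 1
        falls = np.flatnonzero(contact[:-1] & ~contact[1:]) + 1
        hs = [_crossing_time(t, v, i, threshold_n) for i in rises]
        to = [_crossing_time(t, v, i, threshold_n) for i in falls]
        # drop partial contacts at the edges: start at first HS, end at a TO
        to = [x for x in to if hs and x > hs[0]]
        hs = hs[: len(to)]
        if not hs:
            raise NoGaitDetectedError(f"leg {leg!r}: no complete contact in record")
        heel_strikes[leg] = np.array(hs)
        toe_offs[leg] = np.array(to)
    return GaitEvents(heel_strikes=heel_strikes, toe_offs=toe_offs)


def _debounce(contact: np.ndarray, min_run: int) -> np.ndarray:
    """Merge contact/flight runs shorter than ``min_run`` samples."""
    if min_run <= 1:
        return contact
    out = contact.copy()
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(np.diff(out.astype(np.int8)))
        starts = np.concatenate(([0], idx + 1))
        ends = np.concatenate((idx + 1, [out.size]))
        # never flip the first/last run: edges are genuinely partial
        for s, e in zip(starts[1:-1], ends[1:-1]):
            if e - s < min_run:
                out[s:e] = ~out[s]
                changed = True
                break
    return out


def segment_strides(events: GaitEvents, leg: str) -> list[GaitSegmentation]:
    """Partition each complete stride of ``leg`` into the six regions.

    Strides whose contralateral events are missing or out of order are
    skipped with a logged warning; at least one valid stride must remain.
    """
    others = [k for k in events.legs if k != leg]
    if leg not in events.legs or len(others) != 1:
        raise EventSequenceError(f"cannot resolve contralateral leg of {leg!r}")
    contra = others[0]
    hs_i, to_i = events.heel_strikes[leg], events.toe_offs[leg]
    hs_c, to_c = events.heel_strikes[contra], events.toe_offs[contra]
    if len(hs_i) < 2:
        raise InsufficientDataError(
            f"leg {leg!r}: need >= 2 heel strikes, got {len(hs_i)}"
        )
    segments: list[GaitSegmentation] = []
    for t0, t1 in zip(hs_i[:-1], hs_i[1:]):
        cto = to_c[(to_c > t0) & (to_c < t1)]
        chs = hs_c[(hs_c > t0) & (hs_c < t1)]
        ito = to_i[(to_i > t0) & (to_i < t1)]
        if len(cto) != 1 or len(chs) != 1 or len(ito) != 1:
            logger.warning(
                "skipping stride [%.3f, %.3f) s of leg %s: expected exactly one "
                "contralateral TO/HS and ipsilateral TO, got %d/%d/%d",
                t0, t1, leg, len(cto), len(chs), len(ito),
            )
            continue
        cto, chs, ito = float(cto[0]), float(chs[0]), float(ito[0])
        if not (t0 < cto < chs < ito < t1):
            logger.warning(
                "skipping stride [%.3f, %.3f) s of leg %s: events out of order",
                t0, t1, leg,
            )
            continue
        boundaries = [t0, cto, (cto + chs) / 2.0, chs, ito, (ito + t1) / 2.0, t1]
        segments.append(GaitSegmentation(boundaries=np.array(boundaries), leg=leg))
    if not segments:
        raise InsufficientDataError(f"leg {leg!r}: no complete stride survived")
    return segments


def paretic_propulsion(
    grf: GrfRecording,
    paretic_leg: str,
    window_s: tuple[float, float] | None = None,
) -> PropulsionResult:
    """Paretic propulsion from bilateral anterior GRF.

    Per leg the anterior impulse is the trapezoidal integral of the
    positive part of the anterior force, over ``window_s`` if given
    (use a whole number of strides for unbiased shares) else the whole
    record.
    """
    nonparetic = grf.contralateral(paretic_leg)
    impulses = {}
    for leg in (paretic_leg, nonparetic):
        a = grf.anterior[leg]
        t = grf.times(leg)
        if window_s is not None:
            sel = (t >= window_s[0]) & (t <= window_s[1])
            a, t = a[sel], t[sel]
        impulses[leg] = float(np.trapezoid(np.clip(a, 0.0, None), t))
    return PropulsionResult(
        paretic_impulse=impulses[paretic_leg],
        nonparetic_impulse=impulses[nonparetic],
    )
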