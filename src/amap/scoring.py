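"""Timing/amplitude components, normative profiles, and AMAP scores.

For each muscle and each of the six gait regions, two components are
computed per stride and averaged across strides:

* timing component — "on" time within the region as a percentage of the
  region's duration (0-100);
* amplitude component — integrated envelope over the "on" samples in the
  region as a percentage of the integrated envelope over all "on" samples
  of the whole gait cycle (the six regions therefore sum to 100 whenever
  the muscle is on at all during the cycle).

A normative profile is the cell-wise mean and SD (n-1 denominator) of
these components over a healthy cohort walking at a matched speed; both
legs of a healthy subject count as separate observations. A subject's
AMAP score per cell is the z-score against that profile — negative means
reduced timing/amplitude relative to normal, positive means increased.
Scores within +/-2.57 (~99% central coverage of a standard normal) are
considered normal; the per-muscle total AMAP score is the mean of the six
absolute region scores per component.

Because some regions are consistently "on" or "off" across healthy
walkers while others vary widely, dividing by the cell SD penalizes
deviations in low-variability regions more — that weighting is the point
of the z-score construction.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import OnOffMask
from .errors import (
    DegenerateProfileError,
    DomainError,
    InsufficientDataError,
    MismatchError,
    UndefinedCorrelationError,
)
from .gait import REGIONS, GaitSegmentation
from .preprocess import EnvelopeRecording

__all__ = [
    "COMPONENTS",
    "DEFAULT_WINDOW",
    "ComponentMatrix",
    "NormativeProfile",
    "AmapReport",
    "compute_components",
    "build_normative_profile",
    "score_subject",
    "select_speed_band",
    "cohort_outlier_fraction",
    "correlate_totals",
    "normal_window_coverage",
    "normal_window_halfwidth",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("timing", "amplitude")
#: half-width of the "normal" score window (~99% central normal coverage)
DEFAULT_WINDOW = 2.57
#: the narrower post-hoc window (~96% coverage) offered as an alternative
NARROW_WINDOW = 2.05

SPEED_BANDS = ("0.3", "0.6", "0.9", "self-selected")


def normal_window_coverage(halfwidth: float) -> float:
    """Central probability mass of a standard normal within +/-halfwidth."""
    return float(1.0 - 2.0 * stats.norm.sf(halfwidth))


def normal_window_halfwidth(coverage: float) -> float:
    """Exact two-sided standard-normal critical value for central coverage."""
    if not 0.0 < coverage < 1.0:
        raise DomainError(f"coverage must be in (0, 1), got {coverage}")
    return float(stats.norm.ppf((1.0 + coverage) / 2.0))


@dataclass
class ComponentMatrix:
    """Per-muscle, per-region timing and amplitude components (%) for one leg.

    ``timing`` and ``amplitude`` are muscle x region DataFrames.
    """

    timing: pd.DataFrame
    amplitude: pd.DataFrame
    n_strides: int = 1
    subject_id: str = ""
    speed_mps: float | None = None
    leg: str = "left"

    def __post_init__(self) -> None:
        if not self.timing.index.equals(self.amplitude.index) or not self.timing.columns.equals(
            self.amplitude.columns
        ):
            raise MismatchError("timing and amplitude must share muscles and regions")
        tv = self.timing.to_numpy()
        av = self.amplitude.to_numpy()
        if np.any(tv < -1e-9) or np.any(tv > 100 + 1e-9):
            raise DomainError("timing components must lie in [0, 100]")
        if np.any(av < -1e-9):
            raise DomainError("amplitude components must be nonnegative")
        sums = av.sum(axis=1)
        bad = ~(np.isclose(sums, 100.0, atol=1e-6) | np.isclose(sums, 0.0, atol=1e-9))
        if bad.any():
            raise DomainError(
                "amplitude components must sum to 100 per muscle (or be all "
                f"zero); offending muscles: {list(self.timing.index[bad])}"
            )

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.timing.index)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.timing.columns)

    def component(self, name: str) -> pd.DataFrame:
        if name not in COMPONENTS:
            raise DomainError(f"component must be one of {COMPONENTS}, got {name!r}")
        return self.timing if name == "timing" else self.amplitude


def compute_components(
    env: EnvelopeRecording,
    mask: OnOffMask,
    strides: Sequence[GaitSegmentation],
    subject_id: str | None = None,
    speed_mps: float | None = None,
) -> ComponentMatrix:
    """Per-stride timing/amplitude components, averaged across strides.

    A stride in which a muscle is never "on" contributes 0 to every
    region's amplitude for that muscle (logged), so amplitude rows sum to
    100 only when the muscle shows any activity.
    """
    if len(strides) < 1:
        raise InsufficientDataError("need at least one stride")
    if mask.mask.shape != env.envelopes.shape:
        raise MismatchError("mask is not aligned to the envelope samples")
    t = env.times
    dt = 1.0 / env.rate_hz
    muscles = env.channel_names
    timing = np.zeros((len(muscles), len(REGIONS)))
    amplitude = np.zeros_like(timing)
    for seg in strides:
        in_stride = (t >= seg.stride_start) & (t < seg.stride_end)
        for c in range(len(muscles)):
            on = mask.mask[c]
            total_on_integral = float(env.envelopes[c][in_stride & on].sum() * dt)
            if total_on_integral <= 0.0:
                logger.warning(
                    "muscle %s has zero on-time in stride [%.3f, %.3f) s; "
                    "amplitude components set to 0 for this stride",
                    muscles[c], seg.stride_start, seg.stride_end,
                )
            for r, region in enumerate(REGIONS):
                a, b = seg.region_interval(region)
                sel = (t >= a) & (t < b)
                on_time = float((sel & on).sum() * dt)
                timing[c, r] += min(100.0, 100.0 * on_time / (b - a))
                if total_on_integral > 0.0:
                    num = float(env.envelopes[c][sel & on].sum() * dt)
                    amplitude[c, r] += 100.0 * num / total_on_integral
    timing /= len(strides)
    amplitude /= len(strides)
    # strides tile exactly, so row sums are 100 (or 0) up to accumulated
    # rounding; renormalize the float dust away
    sums = amplitude.sum(axis=1)
    nz = sums > 0
    amplitude[nz] *= 100.0 / sums[nz, None]
    return ComponentMatrix(
        timing=pd.DataFrame(timing, index=list(muscles), columns=list(REGIONS)),
        amplitude=pd.DataFrame(amplitude, index=list(muscles), columns=list(REGIONS)),
        n_strides=len(strides),
        subject_id=subject_id if subject_id is not None else env.subject_id,
        speed_mps=speed_mps,
        leg=env.leg,
    )


@dataclass
class NormativeProfile:
    """Cell-wise mean and SD of components over a healthy cohort.

    One profile per walking-speed band ("0.3", "0.6", "0.9" m/s or
    "self-selected"); ``n_observations`` counts legs x subjects.
    """

    speed_band: str
    mean: dict[str, pd.DataFrame]
    sd: dict[str, pd.DataFrame]
    n_observations: int

    def __post_init__(self) -> None:
        for comp in COMPONENTS:
            if comp not in self.mean or comp not in self.sd:
                raise MismatchError(f"profile missing component {comp!r}")
            sd = self.sd[comp].to_numpy()
            if np.any(sd <= 0):
                i, j = np.argwhere(sd <= 0)[0]
                raise DegenerateProfileError(
                    f"zero SD in {comp} cell "
                    f"({self.sd[comp].index[i]}, {self.sd[comp].columns[j]})"
                )

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.mean["timing"].index)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.mean["timing"].columns)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "band": self.speed_band,
            "muscles": list(self.muscles),
            "regions": list(self.regions),
            "n": self.n_observations,
            "components": {
                comp: {
                    "mean": self.mean[comp].to_numpy().tolist(),
                    "sd": self.sd[comp].to_numpy().tolist(),
                }
                for comp in COMPONENTS
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeProfile":
        payload = json.loads(Path(path).read_text())
        muscles, regions = payload["muscles"], payload["regions"]
        mean = {
            comp: pd.DataFrame(payload["components"][comp]["mean"], index=muscles, columns=regions)
            for comp in COMPONENTS
        }
        sd = {
            comp: pd.DataFrame(payload["components"][comp]["sd"], index=muscles, columns=regions)
            for comp in COMPONENTS
        }
        return cls(speed_band=payload["band"], mean=mean, sd=sd, n_observations=payload["n"])


def build_normative_profile(
    cohort: Sequence[ComponentMatrix], speed_band: str = "self-selected"
) -> NormativeProfile:
    """Cell-wise mean and SD (ddof=1) over healthy observations.

    Each element of ``cohort`` is one observation (one leg of one
    subject); at least two observations are required and every cell must
    show spread, otherwise z-scores would be undefined.
    """
    if len(cohort) < 2:
        raise InsufficientDataError(
            f"need >= 2 normative observations, got {len(cohort)}"
        )
    first = cohort[0]
    for cm in cohort[1:]:
        if cm.muscles != first.muscles or cm.regions != first.regions:
            raise MismatchError("cohort members disagree on muscles/regions")
    mean, sd = {}, {}
    for comp in COMPONENTS:
        stacked = np.stack([cm.component(comp).to_numpy() for cm in cohort])
        mean[comp] = pd.DataFrame(
            stacked.mean(axis=0), index=list(first.muscles), columns=list(first.regions)
        )
        sd[comp] = pd.DataFrame(
            stacked.std(axis=0, ddof=1), index=list(first.muscles), columns=list(first.regions)
        )
    return NormativeProfile(
        speed_band=speed_band, mean=mean, sd=sd, n_observations=len(cohort)
    )


@dataclass
class AmapReport:
    """AMAP z-scores, outlier flags and per-muscle totals for one subject."""

    z: dict[str, pd.DataFrame]
    outlier: dict[str, pd.DataFrame]
    totals: pd.DataFrame
    window_halfwidth: float = DEFAULT_WINDOW
    subject_id: str = ""
    speed_band: str | None = None

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.z)

    @property
    def muscles(self) -> tuple[str, ...]:
        comps = self.components
        return tuple(self.z[comps[0]].index) if comps else ()


def score_subject(
    subject: ComponentMatrix,
    norm: NormativeProfile,
    window: float = DEFAULT_WINDOW,
) -> AmapReport:
    """Z-score a subject's components against a normative profile.

    A negative score means the subject's timing or amplitude component is
    reduced relative to the healthy mean for that muscle and region; the
    per-muscle total is the mean of the six absolute region scores.
    """
    if tuple(subject.muscles) != tuple(norm.muscles) or tuple(subject.regions) != tuple(
        norm.regions
    ):
        raise MismatchError(
            f"subject muscles/regions {subject.muscles}/{subject.regions} do not "
            f"match profile {norm.muscles}/{norm.regions}"
        )
    if window <= 0:
        raise DomainError(f"window half-width must be positive, got {window}")
    z, outlier = {}, {}
    for comp in COMPONENTS:
        zdf = (subject.component(comp) - norm.mean[comp]) / norm.sd[comp]
        z[comp] = zdf
        outlier[comp] = zdf.abs() > window
    totals = pd.DataFrame(
        {comp: z[comp].abs().mean(axis=1) for comp in COMPONENTS}
    )
    return AmapReport(
        z=z,
        outlier=outlier,
        totals=totals,
        window_halfwidth=window,
        subject_id=subject.subject_id,
        speed_band=norm.speed_band,
    )


def select_speed_band(self_selected_speed: float) -> str:
    """Map a self-selected walking speed to its normative speed band.

    Household ambulators (< 0.4 m/s) are compared against the 0.3 m/s
    healthy profile, limited community ambulators (0.4-0.8 m/s) against
    0.6 m/s, community ambulators (> 0.8 m/s) against 0.9 m/s.
    """
    if not self_selected_speed > 0:
        raise DomainError(f"speed must be positive, got {self_selected_speed}")
    if self_selected_speed < 0.4:
        return "0.3"
    if self_selected_speed <= 0.8:
        return "0.6"
    return "0.9"


def cohort_outlier_fraction(
    reports: Sequence[AmapReport],
    component: str,
    muscle: str | None = None,
) -> float:
    """Percentage of altered observations in a cohort of reports.

    With ``muscle`` given: the percentage of subjects for whom ANY of the
    six region scores of that muscle/component falls outside the window
    (the per-muscle "altered pattern" convention). Without: the
    percentage of all muscle x region cells outside the window.
    """
    if component not in COMPONENTS:
        raise DomainError(f"component must be one of {COMPONENTS}, got {component!r}")
    if not reports:
        raise InsufficientDataError("need at least one report")
    if muscle is not None:
        for rep in reports:
            if muscle not in rep.muscles:
                raise MismatchError(f"muscle {muscle!r} absent from report")
        hits = sum(bool(rep.outlier[component].loc[muscle].any()) for rep in reports)
        return 100.0 * hits / len(reports)
    flags = np.concatenate([rep.outlier[component].to_numpy().ravel() for rep in reports])
    return 100.0 * float(flags.mean())


def correlate_totals(
    reports: Sequence[AmapReport],
    covariate: Sequence[float],
    muscle: str,
    component: str,
) -> tuple[float, float]:
    """Pearson correlation of per-subject total AMAP scores with a covariate.

    Typical covariates: paretic propulsion (%) or self-selected walking
    speed (m/s). Returns (r, two-sided p) with p from the t distribution
    on n-2 degrees of freedom.
    """
    if len(reports) < 3:
        raise InsufficientDataError("need >= 3 subjects for a correlation")
    if len(covariate) != len(reports):
        raise MismatchError("covariate must align 1:1 with reports")
    totals = []
    for rep in reports:
        if muscle not in rep.muscles:
            raise MismatchError(f"muscle {muscle!r} absent from report")
        totals.append(float(rep.totals.at[muscle, component]))
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(totals)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in covariate or totals")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
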