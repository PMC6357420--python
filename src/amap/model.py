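"""Model/results interface for AMAP scoring.

:class:`AmapModel` pairs one subject's component matrix with a normative
profile (given directly, built from a healthy cohort, or selected by
speed band from a set of profiles); :meth:`AmapModel.fit` returns an
:class:`AmapResults` carrying the z-scores, outlier flags, per-muscle
totals, and a printable summary. Plotting hangs off the results object.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .scoring import (
    COMPONENTS,
    DEFAULT_WINDOW,
    AmapReport,
    ComponentMatrix,
    NormativeProfile,
    build_normative_profile,
    score_subject,
    select_speed_band,
)

__all__ = ["AmapModel", "AmapResults"]


class AmapModel:
    """Scores one subject's EMG components against a normative profile.

    Parameters
    ----------
    subject : ComponentMatrix
        The subject's muscle x region timing/amplitude components.
    norm : NormativeProfile
        The healthy reference (means and SDs per cell) at a matched speed.
    window : float
        Half-width of the "normal" z-score window (default 2.57).
    """

    def __init__(
        self,
        subject: ComponentMatrix,
        norm: NormativeProfile,
        window: float = DEFAULT_WINDOW,
    ) -> None:
        if window <= 0:
            raise DomainError("window half-width must be positive")
        self.subject = subject
        self.norm = norm
        self.window = window

    @classmethod
    def from_cohort(
        cls,
        subject: ComponentMatrix,
        cohort: Sequence[ComponentMatrix],
        speed_band: str | None = None,
        window: float = DEFAULT_WINDOW,
        leave_one_out: bool = False,
    ) -> "AmapModel":
        """Build the normative profile from healthy observations, then score.

        With ``leave_one_out`` the subject (matched by ``subject_id`` and
        leg) is excluded from the profile; by default a leave-in profile
        is used, which is the natural choice when a cohort member is
        scored against its own cohort.
        """
        if speed_band is None:
            speed_band = (
                select_speed_band(subject.speed_mps)
                if subject.speed_mps
                else "self-selected"
            )
        members = list(cohort)
        if leave_one_out:
            members = [
                cm
                for cm in members
                if not (cm.subject_id == subject.subject_id and cm.leg == subject.leg)
            ]
        norm = build_normative_profile(members, speed_band=speed_band)
        return cls(subject, norm, window=window)

    def fit(self) -> "AmapResults":
        report = score_subject(self.subject, self.norm, window=self.window)
        return AmapResults(self, report)


class AmapResults:
    """Fitted AMAP scores for one subject.

    Attributes
    ----------
    report : AmapReport
        The underlying report (z, outlier flags, totals, window).
    """

    def __init__(self, model: AmapModel, report: AmapReport) -> None:
        self.model = model
        self.report = report

    @property
    def z(self) -> dict[str, pd.DataFrame]:
        return self.report.z

    @property
    def outlier(self) -> dict[str, pd.DataFrame]:
        return self.report.outlier

    @property
    def totals(self) -> pd.DataFrame:
        return self.report.totals

    def outlier_fraction(self, component: str | None = None) -> float:
        """Percentage of this subject's cells outside the normal window."""
        comps = [component] if component else list(COMPONENTS)
        flags = np.concatenate([self.report.outlier[c].to_numpy().ravel() for c in comps])
        return 100.0 * float(flags.mean())

    def altered_muscles(self, component: str) -> list[str]:
        """Muscles with any region score outside the window."""
        o = self.report.outlier[component]
        return [m for m in o.index if o.loc[m].any()]

    def summary(self) -> str:
        """Plain-text summary: per-muscle z-scores and totals per component."""
        lines = [
            f"AMAP scores for subject {self.report.subject_id!r} "
            f"(speed band: {self.report.speed_band}, window: "
            f"±{self.report.window_halfwidth})",
            f"normative observations: {self.model.norm.n_observations}",
        ]
        for comp in self.report.components:
            zdf = self.report.z[comp].round(2)
            zdf = zdf.assign(total=self.report.totals[comp].round(2))
            lines += ["", f"{comp} component (z-scores; total = mean |z|):", zdf.to_string()]
            altered = self.altered_muscles(comp)
            lines.append(f"altered ({comp}): {', '.join(altered) if altered else 'none'}")
        return "\n".join(lines)

    def plot_scores(self, component: str = "amplitude", ax=None):
        """Bar chart of z-scores per muscle and region with the normal band."""
        import matplotlib.pyplot as plt

        zdf = self.report.z[component]
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        w = self.report.window_halfwidth
        ax.axhspan(-w, w, color="0.85", zorder=0, label=f"normal (±{w})")
        n_m, n_r = zdf.shape
        xs = np.arange(n_m)
        width = 0.8 / n_r
        for r, region in enumerate(zdf.columns):
            ax.bar(xs + r * width, zdf[region], width=width, label=region)
        ax.set_xticks(xs + 0.4 - width / 2)
        ax.set_xticklabels(zdf.index)
        ax.set_ylabel(f"{component} AMAP score (z)")
        ax.legend(ncol=4, fontsize="small")
        return ax
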