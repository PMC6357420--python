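"""Synthetic gait trials (EMG envelopes + GRF) with analytic ground truth.

The generator exists so every stage of the pipeline can be tested against
known truth without any recorded data. A :class:`GaitModel` specifies a
periodic gait: stride duration, per-leg stance fraction, the contralateral
phase lag, per-muscle activation bursts in gait-phase coordinates (% of
the cycle, ipsilateral heel strike = 0), and parametric ground reaction
force shapes, plus multiplicative envelope noise (EMG envelope
variability scales with activation level, so the noise SD is ``noise_sd``
times the local noiseless envelope, truncated at zero). Everything the
pipeline is supposed to recover — event
times, the on/off mask, the six-region timing/amplitude components, the
anterior impulses — is computed in closed form from the model, never from
the pipeline under test.

Bursts are plateaus with raised-cosine ramps rather than Gaussians: a
burst of half-width ``w`` and ramp ``r`` rises from 0 to its amplitude
over ``r`` % of the cycle, holds, and falls symmetrically. The true "on"
support is the half-amplitude support (``|phase - center| <= w + r/2``),
which is an analytic property of the shape; with a compact shape the true
mask does not depend on where an amplitude cut happens to fall, which is
what makes the ground truth independent of the detector.

Vertical GRF during stance (stance-normalized time ``u`` in [0, 1]) is the
classic double bump ``peak * (sin(pi u) + 0.3 sin(3 pi u))``; anterior GRF
is a braking lobe followed by a propulsion lobe,
``-b sin(2 pi u)`` for ``u <= 0.5`` and ``-p sin(2 pi u)`` after, so the
positive anterior impulse per stride is exactly ``p * stance_s / pi``.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DomainError
from .gait import REGIONS, GaitEvents
from .io import EmgRecording, GrfRecording
from .preprocess import EnvelopeRecording
from .scoring import ComponentMatrix

__all__ = [
    "BurstSpec",
    "MuscleModel",
    "GaitModel",
    "GroundTruth",
    "healthy_model",
    "hemiparetic_model",
    "preset",
    "simulate_trial",
    "simulate_cohort",
    "CohortVariation",
    "sample_component_cohort",
]

MUSCLES = ("SO", "MG", "TA", "VM", "RF", "LH", "MH", "GM")


@dataclass(frozen=True)
class BurstSpec:
    """One activation burst in gait-phase coordinates (% of cycle)."""

    center_pct: float
    halfwidth_pct: float
    ramp_pct: float = 4.0
    amplitude: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.center_pct < 100:
            raise DomainError(f"burst center must be in [0, 100), got {self.center_pct}")
        if self.halfwidth_pct <= 0 or self.ramp_pct <= 0 or self.amplitude <= 0:
            raise DomainError("burst halfwidth, ramp and amplitude must be positive")
        if self.halfwidth_pct + self.ramp_pct >= 50:
            raise DomainError("burst support may not cover the whole cycle")

    @property
    def on_halfwidth(self) -> float:
        """Half-width of the true 'on' support (half-amplitude point)."""
        return self.halfwidth_pct + self.ramp_pct / 2.0

    def shape(self, phase_pct: np.ndarray) -> np.ndarray:
        """Burst profile (0..1) at wrapped gait phases, vectorized."""
        d = np.abs((phase_pct - self.center_pct + 50.0) % 100.0 - 50.0)
        out = np.zeros_like(d, dtype=float)
        out[d <= self.halfwidth_pct] = 1.0
        ramp = (d > self.halfwidth_pct) & (d <= self.halfwidth_pct + self.ramp_pct)
        out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - self.halfwidth_pct) / self.ramp_pct))
        return out

    def _G(self, u: float) -> float:
        """Antiderivative of the (even) shape from 0 to u, u in % units."""
        sign = 1.0 if u >= 0 else -1.0
        u = abs(u)
        w, r = self.halfwidth_pct, self.ramp_pct
        if u <= w:
            val = u
        elif u <= w + r:
            val = w + 0.5 * (u - w) + (r / (2 * np.pi)) * np.sin(np.pi * (u - w) / r)
        else:
            val = w + 0.5 * r
        return sign * val

    def integral(self, a: float, b: float) -> float:
        """Exact integral of amplitude*shape over phase interval [a, b] (%).

        The interval must not wrap (split wrapped intervals first); the
        burst itself may — the shape is evaluated on the wrapped distance,
        so the integral sums the contributions of the periodic images.
        """
        if b < a:
            raise DomainError("integral interval must have a <= b")
        total = 0.0
        for image in (self.center_pct - 100.0, self.center_pct, self.center_pct + 100.0):
            total += self._G(b - image) - self._G(a - image)
        return self.amplitude * total

    def on_intervals(self) -> list[tuple[float, float]]:
        """True-on support as non-wrapping intervals within [0, 100)."""
        lo = self.center_pct - self.on_halfwidth
        hi = self.center_pct + self.on_halfwidth
        parts = []
        for a, b in ((lo, hi),):
            a_, b_ = a % 100.0, a % 100.0 + (b - a)
            if b_ <= 100.0:
                parts.append((a_, b_))
            else:
                parts.append((a_, 100.0))
                parts.append((0.0, b_ - 100.0))
        return parts


@dataclass(frozen=True)
class MuscleModel:
    """Baseline level plus a list of activation bursts for one muscle."""

    name: str
    bursts: tuple[BurstSpec, ...] = ()
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise DomainError("baseline must be nonnegative")
        for b in self.bursts:
            if b.amplitude < self.baseline:
                raise DomainError(
                    f"muscle {self.name!r}: burst amplitude below baseline"
                )


@dataclass(frozen=True)
class GaitModel:
    """Parametric periodic gait for one subject.

    The analyzed (EMG) leg has its heel strike at phase 0; the
    contralateral heel strike occurs ``phase_lag`` of a stride later.
    ``propulsion_n``/``braking_n`` are peak anterior-force magnitudes (N)
    per leg; ``vertical_peak_n`` scales the double-bump vertical force.
    """

    stride_s: float = 1.0
    stance_fraction: dict[str, float] = field(
        default_factory=lambda: {"left": 0.6, "right": 0.6}
    )
    phase_lag: float = 0.5
    muscles: tuple[MuscleModel, ...] = ()
    emg_leg: str = "left"
    vertical_peak_n: float = 750.0
    braking_n: dict[str, float] = field(default_factory=lambda: {"left": 120.0, "right": 120.0})
    propulsion_n: dict[str, float] = field(
        default_factory=lambda: {"left": 150.0, "right": 150.0}
    )
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_s <= 0:
            raise DomainError("stride_s must be positive")
        for leg, f in self.stance_fraction.items():
            if not 0 < f < 1:
                raise DomainError(f"stance fraction of leg {leg!r} must be in (0,1)")
        if not 0 < self.phase_lag < 1:
            raise DomainError("phase_lag must be in (0, 1)")
        if self.emg_leg not in self.stance_fraction:
            raise DomainError(f"emg_leg {self.emg_leg!r} has no stance fraction")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")
        # the six regions must be well ordered for the analyzed leg
        b = self.region_boundaries_pct()
        if not np.all(np.diff(b) > 0):
            raise DomainError(
                f"degenerate gait timing: region boundaries {b} not increasing"
            )

    @property
    def contra_leg(self) -> str:
        others = [k for k in self.stance_fraction if k != self.emg_leg]
        if len(others) != 1:
            raise DomainError("model must have exactly two legs")
        return others[0]

    def hs_offset(self, leg: str) -> float:
        """Heel-strike time offset (s) of ``leg`` within a stride."""
        return 0.0 if leg == self.emg_leg else self.phase_lag * self.stride_s

    def region_boundaries_pct(self) -> np.ndarray:
        """Analytic six-region boundaries for the analyzed leg, % of cycle."""
        stance_i = self.stance_fraction[self.emg_leg]
        stance_c = self.stance_fraction[self.contra_leg]
        cto = ((self.phase_lag + stance_c) % 1.0) * 100.0
        chs = self.phase_lag * 100.0
        ito = stance_i * 100.0
        return np.array(
            [0.0, cto, (cto + chs) / 2.0, chs, ito, (ito + 100.0) / 2.0, 100.0]
        )

    def muscle(self, name: str) -> MuscleModel:
        for m in self.muscles:
            if m.name == name:
                return m
        raise DomainError(f"no muscle named {name!r} in model")


@dataclass
class GroundTruth:
    """Analytic truth for one simulated trial (never touches the pipeline)."""

    events: GaitEvents
    mask: np.ndarray
    components: ComponentMatrix
    impulse_per_stride: dict[str, float]
    pp_percent: float
    region_boundaries_pct: np.ndarray
    n_strides: int


# ---------------------------------------------------------------------------
# presets

def healthy_model(noise_sd: float = 0.03, seed: int = 0) -> GaitModel:
    """Symmetric gait with textbook lower-limb EMG phasing.

    Plantarflexors (SO, MG) are active through single support into the
    second double support; TA through swing into loading; quadriceps (VM,
    RF) around loading response; hamstrings (LH, MH) in terminal swing
    into early stance; GM through early/mid stance. Placements are package
    constants chosen to emulate textbook phasing, not cohort estimates.
    """
    muscles = (
        MuscleModel("SO", (BurstSpec(33, 14, 4, 0.90),)),
        MuscleModel("MG", (BurstSpec(36, 12, 4, 0.85),)),
        MuscleModel("TA", (BurstSpec(95, 13, 4, 0.70),)),
        MuscleModel("VM", (BurstSpec(3, 9, 4, 0.75),)),
        MuscleModel("RF", (BurstSpec(5, 8, 4, 0.70),)),
        MuscleModel("LH", (BurstSpec(92, 9, 4, 0.65),)),
        MuscleModel("MH", (BurstSpec(94, 9, 4, 0.65),)),
        MuscleModel("GM", (BurstSpec(12, 11, 4, 0.80),)),
    )
    return GaitModel(muscles=muscles, noise_sd=noise_sd, seed=seed)


def hemiparetic_model(
    propulsion_scale: float = 0.4, noise_sd: float = 0.03, seed: int = 0
) -> GaitModel:
    """Asymmetric hemiparetic-like gait of the paretic ('left') leg.

    Emulates the classic post-stroke alterations: early plantarflexor
    activity in first double support wrapping into terminal swing with
    reduced second-half-of-stance activity, TA co-activation in second
    double support with early termination of its swing burst, GM shifted
    from early stance into second double support and swing, and a weak
    paretic push-off (propulsion peak scaled by ``propulsion_scale``).
    """
    if not 0 < propulsion_scale:
        raise DomainError("propulsion_scale must be positive")
    muscles = (
        MuscleModel("SO", (BurstSpec(8, 8, 4, 0.85), BurstSpec(24, 5, 3, 0.45))),
        MuscleModel("MG", (BurstSpec(10, 7, 4, 0.80), BurstSpec(26, 5, 3, 0.40))),
        MuscleModel("TA", (BurstSpec(70, 8, 4, 0.65), BurstSpec(56, 4, 3, 0.55))),
        MuscleModel("VM", (BurstSpec(4, 9, 4, 0.75),)),
        MuscleModel("RF", (BurstSpec(6, 8, 4, 0.70),)),
        MuscleModel("LH", (BurstSpec(92, 9, 4, 0.65),)),
        MuscleModel("MH", (BurstSpec(94, 9, 4, 0.65),)),
        MuscleModel("GM", (BurstSpec(56, 5, 3, 0.70), BurstSpec(88, 7, 4, 0.60))),
    )
    return GaitModel(
        stance_fraction={"left": 0.62, "right": 0.66},
        phase_lag=0.52,
        muscles=muscles,
        emg_leg="left",
        propulsion_n={"left": 150.0 * propulsion_scale, "right": 150.0},
        noise_sd=noise_sd,
        seed=seed,
    )


def preset(name: str, **kwargs) -> GaitModel:
    """Look up a named preset model ('healthy' or 'hemiparetic')."""
    factories = {"healthy": healthy_model, "hemiparetic": hemiparetic_model}
    if name not in factories:
        raise DomainError(f"unknown preset {name!r}; choose from {sorted(factories)}")
    return factories[name](**kwargs)


# ---------------------------------------------------------------------------
# waveforms

def _vertical_wave(u: np.ndarray) -> np.ndarray:
    return np.sin(np.pi * u) + 0.3 * np.sin(3 * np.pi * u)


def _grf_for_leg(model: GaitModel, leg: str, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    stance = model.stance_fraction[leg]
    phase = ((t - model.hs_offset(leg)) / model.stride_s) % 1.0
    u = phase / stance
    in_stance = phase < stance
    v = np.where(in_stance, model.vertical_peak_n * _vertical_wave(np.minimum(u, 1.0)), 0.0)
    lobes = np.where(u <= 0.5, model.braking_n[leg], model.propulsion_n[leg])
    a = np.where(in_stance, -lobes * np.sin(2 * np.pi * np.minimum(u, 1.0)), 0.0)
    return np.clip(v, 0.0, None), a


def _true_events(model: GaitModel, duration_s: float) -> GaitEvents:
    hs, to = {}, {}
    for leg in model.stance_fraction:
        off = model.hs_offset(leg)
        stance_s = model.stance_fraction[leg] * model.stride_s
        starts = np.arange(off, duration_s, model.stride_s)
        ends = starts + stance_s
        keep = ends <= duration_s
        hs[leg], to[leg] = starts[keep], ends[keep]
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def _union_intervals(parts: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    if not parts:
        return []
    parts = sorted(parts)
    merged = [list(parts[0])]
    for a, b in parts[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _true_components(model: GaitModel) -> ComponentMatrix:
    """Closed-form six-region timing/amplitude components of the model."""
    bounds = model.region_boundaries_pct()
    names = [m.name for m in model.muscles]
    timing = np.zeros((len(names), len(REGIONS)))
    amplitude = np.zeros_like(timing)
    for i, m in enumerate(model.muscles):
        on = _union_intervals([iv for b in m.bursts for iv in b.on_intervals()])
        # integral of the noiseless envelope over on ∩ region, per region
        integrals = np.zeros(len(REGIONS))
        for r in range(len(REGIONS)):
            a, b = bounds[r], bounds[r + 1]
            for lo, hi in on:
                x0, x1 = max(a, lo), min(b, hi)
                if x1 <= x0:
                    continue
                timing[i, r] += x1 - x0
                seg = m.baseline * (x1 - x0)
                for burst in m.bursts:
                    seg += burst.integral(x0, x1)
                integrals[r] += seg
            timing[i, r] *= 100.0 / (b - a)
        total = integrals.sum()
        if total > 0:
            amplitude[i] = 100.0 * integrals / total
    import pandas as pd

    return ComponentMatrix(
        timing=pd.DataFrame(timing, index=names, columns=list(REGIONS)),
        amplitude=pd.DataFrame(amplitude, index=names, columns=list(REGIONS)),
        n_strides=1,
        subject_id="truth",
        leg=model.emg_leg,
    )


def simulate_trial(
    model: GaitModel,
    duration_s: float = 40.0,
    rate_hz: float = 2000.0,
    raw_emg: bool = False,
) -> tuple[EnvelopeRecording | EmgRecording, GrfRecording, GroundTruth]:
    """Generate one trial: envelopes (or raw EMG), bilateral GRF, truth.

    By default envelopes are produced directly (the pipeline from on/off
    detection onward consumes envelopes); with ``raw_emg=True`` the
    noiseless envelope amplitude-modulates white noise, producing an
    interference-like signal to exercise the filter chain.
    """
    if duration_s < 2 * model.stride_s:
        raise DomainError("duration must cover at least 2 strides")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(model.seed)

    phase_pct = ((t / model.stride_s) % 1.0) * 100.0
    names = tuple(m.name for m in model.muscles)
    clean = np.zeros((len(names), n))
    true_mask = np.zeros((len(names), n), dtype=bool)
    for i, m in enumerate(model.muscles):
        env = np.full(n, m.baseline)
        for b in m.bursts:
            env += b.amplitude * b.shape(phase_pct)
            d = np.abs((phase_pct - b.center_pct + 50.0) % 100.0 - 50.0)
            true_mask[i] |= d <= b.on_halfwidth
        clean[i] = env

    vertical, anterior = {}, {}
    for leg in model.stance_fraction:
        vertical[leg], anterior[leg] = _grf_for_leg(model, leg, t)
    grf = GrfRecording(vertical=vertical, anterior=anterior, rate_hz=rate_hz)

    if raw_emg:
        carrier = rng.standard_normal((len(names), n))
        signals = clean * carrier + model.noise_sd * rng.standard_normal((len(names), n))
        emg: EnvelopeRecording | EmgRecording = EmgRecording(
            signals=signals, rate_hz=rate_hz, channel_names=names, leg=model.emg_leg
        )
    else:
        # envelope noise is signal-dependent: EMG envelope variability scales
        # with activation level, and a real linear envelope's baseline is
        # tight (everything has passed the same smoothing filter)
        noisy = np.clip(
            clean * (1.0 + rng.normal(0.0, model.noise_sd, clean.shape)), 0.0, None
        )
        emg = EnvelopeRecording(
            envelopes=noisy, rate_hz=rate_hz, channel_names=names, leg=model.emg_leg
        )

    events = _true_events(model, duration_s)
    impulse = {
        leg: model.propulsion_n[leg] * model.stance_fraction[leg] * model.stride_s / np.pi
        for leg in model.stance_fraction
    }
    ipsi, contra = model.emg_leg, model.contra_leg
    pp = 100.0 * impulse[ipsi] / (impulse[ipsi] + impulse[contra])
    truth = GroundTruth(
        events=events,
        mask=true_mask,
        components=_true_components(model),
        impulse_per_stride=impulse,
        pp_percent=pp,
        region_boundaries_pct=model.region_boundaries_pct(),
        n_strides=int(duration_s / model.stride_s),
    )
    return emg, grf, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortVariation:
    """Between-subject SDs for cohort simulation.

    ``center_pct`` jitters burst centers (percentage points of the cycle),
    ``amplitude_frac`` scales burst amplitudes multiplicatively,
    ``stride_frac`` scales stride duration, ``stance_pct`` jitters stance
    fractions (absolute, in fraction units).
    """

    center_pct: float = 2.0
    amplitude_frac: float = 0.15
    stride_frac: float = 0.05
    stance_pct: float = 0.015

    def is_zero(self) -> bool:
        return (
            self.center_pct == 0
            and self.amplitude_frac == 0
            and self.stride_frac == 0
            and self.stance_pct == 0
        )


def _subject_model(model: GaitModel, var: CohortVariation, rng: np.random.Generator) -> GaitModel:
    muscles = []
    for m in model.muscles:
        bursts = tuple(
            replace(
                b,
                center_pct=(b.center_pct + rng.normal(0, var.center_pct)) % 100.0
                if var.center_pct
                else b.center_pct,
                amplitude=b.amplitude
                * float(np.clip(1 + rng.normal(0, var.amplitude_frac), 0.3, 2.0))
                if var.amplitude_frac
                else b.amplitude,
            )
            for b in m.bursts
        )
        muscles.append(replace(m, bursts=bursts))
    stance = {
        leg: float(np.clip(f + rng.normal(0, var.stance_pct), 0.45, 0.75))
        if var.stance_pct
        else f
        for leg, f in model.stance_fraction.items()
    }
    stride = model.stride_s * (
        float(np.clip(1 + rng.normal(0, var.stride_frac), 0.6, 1.6)) if var.stride_frac else 1.0
    )
    return replace(model, muscles=tuple(muscles), stance_fraction=stance, stride_s=stride)


def _param_seed(master_seed: int, model: GaitModel) -> int:
    """Deterministic per-subject seed derived from the subject's parameters.

    Identical parameters (e.g. zero between-subject variation) give the
    same seed, hence bit-identical trials.
    """
    key = repr(
        (
            master_seed,
            round(model.stride_s, 12),
            sorted((k, round(v, 12)) for k, v in model.stance_fraction.items()),
            tuple(
                (m.name, m.baseline, tuple((b.center_pct, b.halfwidth_pct, b.ramp_pct, b.amplitude) for b in m.bursts))
                for m in model.muscles
            ),
        )
    ).encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def simulate_cohort(
    model: GaitModel,
    n_subjects: int,
    between_subject_sd: CohortVariation | None = None,
    seed: int = 0,
    duration_s: float = 40.0,
    rate_hz: float = 2000.0,
    raw_emg: bool = False,
) -> list[tuple[EnvelopeRecording | EmgRecording, GrfRecording, GroundTruth]]:
    """Simulate a cohort: per-subject parameters drawn around ``model``.

    Same ``seed`` gives bit-identical cohorts; zero between-subject SD
    gives identical subjects.
    """
    if n_subjects < 2:
        raise DomainError(f"a cohort needs >= 2 subjects, got {n_subjects}")
    var = between_subject_sd if between_subject_sd is not None else CohortVariation()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        subj = _subject_model(model, var, rng)
        subj = replace(subj, seed=_param_seed(seed, subj))
        out.append(simulate_trial(subj, duration_s=duration_s, rate_hz=rate_hz, raw_emg=raw_emg))
    return out


def sample_component_cohort(
    n_subjects: int,
    seed: int = 0,
    legs: int = 2,
    template: ComponentMatrix | None = None,
    timing_sd: float = 6.0,
    amplitude_sd: float = 3.0,
) -> list[ComponentMatrix]:
    """Draw healthy component matrices cell-wise from a Gaussian model.

    Each observation (one leg of one subject) draws every muscle x region
    cell independently: timing ~ N(template, timing_sd) clipped to
    [0, 100]; amplitude ~ N(template, amplitude_sd) clipped at 0 and
    renormalized so each muscle's six regions sum to 100. The template
    defaults to the healthy preset's analytic components.
    """
    import pandas as pd

    if n_subjects < 1 or legs < 1:
        raise DomainError("need at least one subject and one leg")
    if template is None:
        template = _true_components(healthy_model())
    rng = np.random.default_rng(seed)
    mu_t = template.timing.to_numpy()
    mu_a = template.amplitude.to_numpy()
    muscles, regions = list(template.muscles), list(template.regions)
    out = []
    leg_names = ("left", "right")
    for i in range(n_subjects):
        for j in range(legs):
            tv = np.clip(rng.normal(mu_t, timing_sd), 0.0, 100.0)
            av = np.clip(rng.normal(mu_a, amplitude_sd), 0.0, None)
            sums = av.sum(axis=1)
            nz = sums > 0
            av[nz] *= 100.0 / sums[nz, None]
            out.append(
                ComponentMatrix(
                    timing=pd.DataFrame(tv, index=muscles, columns=regions),
                    amplitude=pd.DataFrame(av, index=muscles, columns=regions),
                    n_strides=1,
                    subject_id=f"H{i:02d}",
                    leg=leg_names[j % 2],
                )
            )
    return out
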