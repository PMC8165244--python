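"""Synthetic cohort generator: ground-truth facial RGB traces with known beats.

The generator is a forward model of the measurement chain that the analysis
pipeline inverts.  Beat trains come from an integral pulse frequency
modulation (IPFM) model: beats fire when the integral of an instantaneous
rate ``m(t)/T0`` crosses successive integers, with

    m(t) = 1 + A_LF sin(2 pi f_LF t + phi_LF) + A_HF sin(2 pi f_HF t + phi_HF)

so the RR tachogram carries controllable low-frequency (sympathetic+vagal,
0.04-0.15 Hz) and high-frequency (respiratory/vagal, 0.15-0.4 Hz) power.
Each beat deposits a raised-cosine hemoglobin pulse into a log-density skin
color model together with melanin drift, uniform-illumination (shade)
fluctuation and sensor noise; exponentiating gives the per-frame ROI-mean
RGB trace a 30 Hz camera would record.

A cohort is 21 typically-developed (TD) and 17 ASD adult participants, each
viewing six clips (happy, fear, sad, neutral, line drawing, machine factory)
with a 30 s pre-clip baseline.  Group-dependent phasic autonomic change is
injected as additive shifts of the IPFM parameters during clip viewing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chromophore_separation import RGBTrace, SHADE_AXIS

__all__ = [
    "IPFMParams",
    "RenderParams",
    "CohortConfig",
    "Segment",
    "Condition",
    "Session",
    "generate_beat_train",
    "render_rgb_trace",
    "hb_pulse_train",
    "generate_session",
    "generate_cohort",
    "write_cohort",
    "read_trace",
]

CLIP_NAMES = ("happy", "fear", "sad", "neutral", "line", "machine")

#: Default clip durations (s); all within the stimuli's 1.5-4.5 min range.
DEFAULT_CLIP_DURATIONS = {
    "happy": 270.0,
    "fear": 150.0,
    "sad": 240.0,
    "neutral": 120.0,
    "line": 180.0,
    "machine": 120.0,
}

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: Hemoglobin log-density direction: hemoglobin absorbs strongly in the
#: green and blue bands and weakly in red, so the pulsatile density vector
#: is dominantly chromatic (little of it lies along the shading axis).
HB_DIRECTION = _unit([0.15, 0.75, 0.64])
#: Melanin log-density direction: broadband, decreasing with wavelength.
MELANIN_DIRECTION = _unit([0.70, 0.60, 0.38])
#: Baseline log densities giving a plausible skin tone (R > G > B).
BASE_DENSITY = np.array([0.80, 1.00, 1.20])


@dataclass(frozen=True)
class IPFMParams:
    """IPFM beat-train parameters for one segment.

    ``phi_lf``/``phi_hf`` of ``None`` mean the phases are drawn from the
    seed passed to :func:`generate_beat_train`.
    """

    t0: float = 0.85  # mean beat period, s
    a_lf: float = 0.08  # LF modulation amplitude (dimensionless)
    f_lf: float = 0.095  # Hz, inside the LF band
    a_hf: float = 0.10
    f_hf: float = 0.25  # Hz, inside the HF band
    phi_lf: float | None = None
    phi_hf: float | None = None

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("T0 must be positive")
        if self.a_lf < 0 or self.a_hf < 0:
            raise ValueError("modulation amplitudes must be nonnegative")
        if self.a_lf + self.a_hf >= 1:
            raise ValueError("A_LF + A_HF must be < 1 so m(t) stays positive")
        if not (LF_BAND[0] <= self.f_lf <= LF_BAND[1]):
            raise ValueError(f"f_lf must lie in the LF band {LF_BAND}")
        if not (HF_BAND[0] <= self.f_hf <= HF_BAND[1]):
            raise ValueError(f"f_hf must lie in the HF band {HF_BAND}")


@dataclass(frozen=True)
class RenderParams:
    """Forward rendering parameters for the RGB skin-color model."""

    frame_rate: float = 30.0
    pulse_amplitude: float = 0.11  # peak hemoglobin density deflection per beat
    pulse_width: float = 0.35  # raised-cosine full width, s
    hb_direction: tuple[float, float, float] = tuple(HB_DIRECTION)
    melanin_drift: float = 0.01  # slow melanin-direction drift amplitude
    shade_modulation: float = 0.02  # uniform-illumination fluctuation amplitude
    noise_sd: float = 0.003  # additive per-channel density noise

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        direction = np.asarray(self.hb_direction, dtype=float)
        if abs(np.linalg.norm(direction) - 1.0) > 1e-8:
            raise ValueError("hb_direction must be a unit vector")
        if abs(float(direction @ SHADE_AXIS)) > 0.999:
            raise ValueError("hb_direction must not be collinear with (1,1,1)")


@dataclass(frozen=True)
class ParticipantVariation:
    """Between-participant SDs / ranges for baseline IPFM parameters."""

    t0_sd: float = 0.08
    a_lf_sd: float = 0.02
    a_hf_sd: float = 0.03
    f_lf_range: tuple[float, float] = (0.07, 0.12)
    f_hf_range: tuple[float, float] = (0.20, 0.30)


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration: 21 TD + 17 ASD, six clips, 30 s baselines."""

    n_td: int = 21
    n_asd: int = 17
    clip_durations: dict = field(
        default_factory=lambda: dict(DEFAULT_CLIP_DURATIONS)
    )
    baseline_duration: float = 30.0
    base_params: IPFMParams = IPFMParams()
    variation: ParticipantVariation = ParticipantVariation()
    render: RenderParams = RenderParams()
    #: group -> clip -> (dT0, dA_LF, dA_HF) additive shift during clip viewing
    group_effects: dict = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be positive")
        for clip, dur in self.clip_durations.items():
            if dur <= 0:
                raise ValueError(f"duration of clip {clip!r} must be positive")

    def effect(self, group: str, clip: str) -> tuple[float, float, float]:
        return tuple(self.group_effects.get(group, {}).get(clip, (0.0, 0.0, 0.0)))


def strong_effect_config(**kwargs) -> CohortConfig:
    """Cohort with a large planted ASD effect: +0.15 on A_LF during the three
    social-emotional clips (happy, fear, sad).  Used for power/recovery checks."""
    effects = {"ASD": {c: (0.0, 0.15, 0.0) for c in ("happy", "fear", "sad")}}
    return CohortConfig(group_effects=effects, **kwargs)


# ---------------------------------------------------------------------------
# IPFM beat train


def _modulation_integral(t: np.ndarray, p: IPFMParams, phi_lf: float, phi_hf: float):
    """Closed-form integral of m(t)/T0 from 0 to t."""
    w_lf = 2 * np.pi * p.f_lf
    w_hf = 2 * np.pi * p.f_hf
    out = t.astype(float).copy()
    if p.a_lf > 0:
        out -= p.a_lf / w_lf * (np.cos(w_lf * t + phi_lf) - np.cos(phi_lf))
    if p.a_hf > 0:
        out -= p.a_hf / w_hf * (np.cos(w_hf * t + phi_hf) - np.cos(phi_hf))
    return out / p.t0


def generate_beat_train(
    params: IPFMParams, duration: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Generate IPFM beat times on ``[0, duration]``.

    Beats ``t_k`` satisfy ``integral_{t_k}^{t_{k+1}} m(t)/T0 dt = 1``; the
    first beat is at the first unit crossing of the integral from 0.  The
    seed only matters when a phase offset is left unset (``None``).
    """
    if duration <= 2 * params.t0:
        raise ValueError("duration must exceed 2*T0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phi_lf = params.phi_lf if params.phi_lf is not None else rng.uniform(0, 2 * np.pi)
    phi_hf = params.phi_hf if params.phi_hf is not None else rng.uniform(0, 2 * np.pi)
    # dense grid; the closed-form integral is exact at the nodes, and linear
    # interpolation of the smooth monotone integral gives sub-0.1 ms beat error
    dt = 0.005
    t = np.arange(0.0, duration + dt / 2, dt)
    t[-1] = min(t[-1], duration)
    m_int = _modulation_integral(t, params, phi_lf, phi_hf)
    n_beats = int(np.floor(m_int[-1]))
    if n_beats < 1:
        return np.empty(0)
    return np.interp(np.arange(1, n_beats + 1, dtype=float), m_int, t)


# ---------------------------------------------------------------------------
# RGB rendering


def hb_pulse_train(
    beats: np.ndarray, duration: float, frame_rate: float, amplitude: float, width: float
) -> np.ndarray:
    """Hemoglobin density signal: raised-cosine pulse at each beat time."""
    n = int(round(duration * frame_rate))
    out = np.zeros(n)
    if len(beats) == 0:
        return out
    half = width / 2.0
    for tk in np.asarray(beats, dtype=float):
        lo = max(0, int(np.ceil((tk - half) * frame_rate)))
        hi = min(n - 1, int(np.floor((tk + half) * frame_rate)))
        if hi < lo:
            continue
        tt = np.arange(lo, hi + 1) / frame_rate
        out[lo : hi + 1] += amplitude * 0.5 * (1 + np.cos(np.pi * (tt - tk) / half))
    return out


def render_rgb_trace(
    beats: np.ndarray,
    rp: RenderParams,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> RGBTrace:
    """Render a segment's RGB trace from its beat times.

    Log density per frame =
    ``BASE + shade(t)*(1,1,1)/sqrt(3) + hb(t)*hb_dir + mel(t)*mel_dir + noise``
    with RGB recovered as ``exp(-density)``.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size and (beats.min() < 0 or beats.max() > duration):
        raise ValueError("beats must lie within [0, duration]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(round(duration * rp.frame_rate))
    t = np.arange(n) / rp.frame_rate
    hb = hb_pulse_train(beats, duration, rp.frame_rate, rp.pulse_amplitude, rp.pulse_width)
    shade_freq = rng.uniform(0.05, 0.15)
    shade = rp.shade_modulation * np.sin(2 * np.pi * shade_freq * t + rng.uniform(0, 2 * np.pi))
    mel = rp.melanin_drift * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
    density = (
        BASE_DENSITY
        + np.outer(shade, SHADE_AXIS)
        + np.outer(hb, np.asarray(rp.hb_direction))
        + np.outer(mel, MELANIN_DIRECTION)
    )
    if rp.noise_sd > 0:
        density = density + rng.normal(0.0, rp.noise_sd, size=density.shape)
    rgb = np.clip(np.exp(-density), 1e-6, 1.0)
    return RGBTrace(samples=rgb, frame_rate=rp.frame_rate)


# ---------------------------------------------------------------------------
# Sessions and cohorts


@dataclass
class Segment:
    """One analyzed segment (baseline or clip) with its ground truth."""

    duration: float
    params: IPFMParams
    beats: np.ndarray
    hb_truth: np.ndarray  # noiseless hemoglobin density signal at frame rate
    trace: RGBTrace | None = None  # rendered RGB, None on the truth-only path


@dataclass
class Condition:
    clip: str
    baseline: Segment
    clip_segment: Segment


@dataclass
class Session:
    participant: str
    group: str  # "TD" | "ASD"
    conditions: dict  # clip name -> Condition

    def __post_init__(self) -> None:
        if set(self.conditions) != set(CLIP_NAMES):
            raise ValueError("a session must hold exactly the six clip conditions")


def _draw_participant_params(config: CohortConfig, rng: np.random.Generator) -> IPFMParams:
    base, var = config.base_params, config.variation
    t0 = float(np.clip(rng.normal(base.t0, var.t0_sd), 0.55, 1.25))
    a_lf = float(np.clip(rng.normal(base.a_lf, var.a_lf_sd), 0.01, 0.4))
    a_hf = float(np.clip(rng.normal(base.a_hf, var.a_hf_sd), 0.01, 0.4))
    f_lf = float(rng.uniform(*var.f_lf_range))
    f_hf = float(rng.uniform(*var.f_hf_range))
    return IPFMParams(t0=t0, a_lf=a_lf, f_lf=f_lf, a_hf=a_hf, f_hf=f_hf)


def _shifted(params: IPFMParams, effect: tuple[float, float, float]) -> IPFMParams:
    d_t0, d_alf, d_ahf = effect
    a_lf = max(0.0, params.a_lf + d_alf)
    a_hf = max(0.0, params.a_hf + d_ahf)
    if a_lf + a_hf >= 1:  # keep m(t) positive under extreme shifts
        scale = 0.98 / (a_lf + a_hf)
        a_lf, a_hf = a_lf * scale, a_hf * scale
    return replace(params, t0=max(0.4, params.t0 + d_t0), a_lf=a_lf, a_hf=a_hf)


def _make_segment(
    params: IPFMParams, duration: float, rp: RenderParams,
    rng: np.random.Generator, render: bool,
) -> Segment:
    beats = generate_beat_train(params, duration, rng)
    hb_truth = hb_pulse_train(beats, duration, rp.frame_rate, rp.pulse_amplitude, rp.pulse_width)
    trace = render_rgb_trace(beats, rp, duration, rng) if render else None
    return Segment(duration=duration, params=params, beats=beats, hb_truth=hb_truth, trace=trace)


def generate_session(
    config: CohortConfig,
    participant: str,
    group: str,
    seed_sequence: np.random.SeedSequence,
    render: bool = True,
) -> Session:
    """Generate one participant's session: six (baseline, clip) segment pairs.

    Clip-segment IPFM parameters equal the participant's baseline parameters
    plus the configured group/clip effect shift; phases are redrawn per
    segment.  Reproducible given the seed sequence.
    """
    rng = np.random.default_rng(seed_sequence)
    base = _draw_participant_params(config, rng)
    conditions = {}
    for clip in CLIP_NAMES:
        baseline = _make_segment(
            base, config.baseline_duration, config.render, rng, render
        )
        clip_params = _shifted(base, config.effect(group, clip))
        clip_seg = _make_segment(
            clip_params, config.clip_durations[clip], config.render, rng, render
        )
        conditions[clip] = Condition(clip=clip, baseline=baseline, clip_segment=clip_seg)
    return Session(participant=participant, group=group, conditions=conditions)


def generate_cohort(config: CohortConfig, render: bool = True) -> list[Session]:
    """Generate the full cohort (TD then ASD participants), reproducibly."""
    root = np.random.SeedSequence(config.master_seed)
    children = root.spawn(config.n_td + config.n_asd)
    sessions = []
    for i in range(config.n_td):
        sessions.append(
            generate_session(config, f"TD{i + 1:02d}", "TD", children[i], render)
        )
    for j in range(config.n_asd):
        sessions.append(
            generate_session(
                config, f"ASD{j + 1:02d}", "ASD", children[config.n_td + j], render
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# On-disk layout


def write_cohort(cohort: list[Session], directory: str | Path) -> pd.DataFrame:
    """Write one trace CSV and one ground-truth beats CSV per segment plus a
    manifest.  Refuses to overwrite an existing manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    if manifest_path.exists():
        raise FileExistsError(f"manifest already exists at {manifest_path}")
    rows = []
    for session in cohort:
        for clip, cond in session.conditions.items():
            for segment_kind, seg in (("baseline", cond.baseline), ("clip", cond.clip_segment)):
                if seg.trace is None:
                    raise ValueError(
                        f"segment {session.participant}/{clip}/{segment_kind} was "
                        "generated without rendering; nothing to write"
                    )
                stem = f"{session.participant}_{clip}_{segment_kind}"
                trace_path = directory / f"{stem}.csv"
                pd.DataFrame(
                    {
                        "frame": np.arange(seg.trace.n_frames),
                        "R": seg.trace.samples[:, 0],
                        "G": seg.trace.samples[:, 1],
                        "B": seg.trace.samples[:, 2],
                    }
                ).to_csv(trace_path, index=False)
                pd.DataFrame({"t_sec": seg.beats}).to_csv(
                    directory / f"{stem}_beats.csv", index=False
                )
                rows.append(
                    {
                        "participant": session.participant,
                        "group": session.group,
                        "condition": clip,
                        "segment": segment_kind,
                        "path": trace_path.name,
                        "duration_s": seg.duration,
                        "frame_rate": seg.trace.frame_rate,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def read_trace(path: str | Path, frame_rate: float) -> RGBTrace:
    """Read a trace CSV (``frame,R,G,B``) back into an :class:`RGBTrace`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return RGBTrace(samples=df[["R", "G", "B"]].to_numpy(), frame_rate=frame_rate)
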