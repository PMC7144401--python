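"""Synthetic cohorts with ground-truth vigilance dynamics.

The generator emulates a four-group observational study (healthy
controls, obese, depressed, obese-depressed; default sizes 66/68/16/43)
in which every subject contributes a ~20-minute eyes-closed resting EEG
and a battery of sleepiness questionnaires.  Its generative model:

* each subject carries a latent Gaussian *trait sleepiness* z ~ N(0,1);
* the per-second vigilance trajectory is a first-order Markov chain over
  the seven stages whose downward drift increases with
  ``coupling * z`` — ``coupling`` in [-1, 1] is the single knob tying
  the subjective to the objective side (0 = independence);
* questionnaire responses are discretized linear functions of z plus a
  group-level shift plus Gaussian noise, calibrated so that the
  depressed groups report markedly higher situational sleepiness while
  objective measures differ little between groups;
* the ASLEEP self-report is a discretization of the subject's true
  share of drowsy/sleep seconds, gated by ``coupling``;
* the multichannel signal for each second realizes the defining
  characteristic of its stage (occipital/temporal-parietal/frontal
  alpha for A1/A2/A3, a slow EOG deflection for B1, raised delta+theta
  for B2/3, an inserted spindle burst — sometimes with a K-complex —
  for C) on top of broadband background noise, in microvolts.

Everything is reproducible bitwise from the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arousal import summarize_arousal
from .questionnaires import GROUPS, QuestionnaireRecord, Subject
from .staging import Recording, Stage, StageSequence, _STAGE_ORDER

__all__ = [
    "TransitionModel",
    "NoiseScales",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_vigilance_trajectory",
    "synthesize_recording",
    "simulate_cohort",
    "DEFAULT_MONTAGE",
]

_N_STAGES = 7

#: 12 scalp channels of the 10-20 system plus one EOG channel
DEFAULT_MONTAGE: dict[str, str] = {
    "Fp1": "frontal",
    "F3": "frontal",
    "Fz": "frontal",
    "F4": "frontal",
    "C3": "temporal-parietal",
    "Cz": "temporal-parietal",
    "C4": "temporal-parietal",
    "P3": "temporal-parietal",
    "Pz": "temporal-parietal",
    "P4": "temporal-parietal",
    "O1": "occipital",
    "O2": "occipital",
    "EOG": "eog",
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TransitionModel:
    """Markov model of the per-second vigilance trajectory.

    States are ordered by declining vigilance (0, A1, A2, A3, B1, B2/3,
    C).  Each second the chain steps down one stage with probability
    ``p_down[s] * exp(drift_gain * drift)``, up with probability
    ``p_up[s] * exp(-drift_gain * drift)`` and stays otherwise, so a
    positive drift (sleepier subject) tilts the walk toward lower
    stages.  ``matrix(drift)`` materializes the full 7x7 row-stochastic
    transition matrix.
    """

    initial: tuple[float, ...] = (0.25, 0.60, 0.10, 0.05, 0.0, 0.0, 0.0)
    p_down: tuple[float, ...] = (0.022, 0.028, 0.032, 0.030, 0.018, 0.007, 0.0)
    p_up: tuple[float, ...] = (0.0, 0.005, 0.014, 0.018, 0.018, 0.034, 0.12)
    drift_gain: float = 0.7

    def __post_init__(self) -> None:
        for name in ("initial", "p_down", "p_up"):
            value = tuple(float(v) for v in getattr(self, name))
            if len(value) != _N_STAGES:
                raise ConfigurationError(f"{name} must have {_N_STAGES} entries")
            if any(v < 0 for v in value):
                raise ConfigurationError(f"{name} contains negative probabilities")
            object.__setattr__(self, name, value)
        if abs(sum(self.initial) - 1.0) > 1e-12:
            raise ConfigurationError("initial stage distribution must sum to 1")
        if self.p_down[-1] != 0 or self.p_up[0] != 0:
            raise ConfigurationError("boundary states cannot step outside 0..C")
        self.matrix(0.0)  # validates row sums at neutral drift

    def rates(self, drift: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-state down/up step probabilities at a given drift."""
        down = np.asarray(self.p_down) * math.exp(self.drift_gain * drift)
        up = np.asarray(self.p_up) * math.exp(-self.drift_gain * drift)
        total = down + up
        over = total > 0.9  # keep a positive stay probability
        if np.any(over):
            scale = 0.9 / total[over]
            down[over] *= scale
            up[over] *= scale
        return down, up

    def matrix(self, drift: float = 0.0) -> np.ndarray:
        """Row-stochastic 7x7 transition matrix at a given drift."""
        down, up = self.rates(drift)
        mat = np.zeros((_N_STAGES, _N_STAGES))
        for s in range(_N_STAGES):
            if s < _N_STAGES - 1:
                mat[s, s + 1] = down[s]
            if s > 0:
                mat[s, s - 1] = up[s]
            mat[s, s] = 1.0 - down[s] - up[s]
            if mat[s, s] < 0:
                raise ConfigurationError(f"row {s} has negative stay probability")
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ConfigurationError("transition rows must sum to 1")
        return mat


@dataclass(frozen=True)
class NoiseScales:
    """Signal amplitudes (microvolts) of the synthetic EEG."""

    background: float = 4.0  # white-noise SD, every channel
    alpha: float = 30.0  # dominant-region alpha amplitude
    alpha_freq: float = 10.0  # Hz
    delta: float = 20.0
    theta: float = 15.0
    spindle: float = 40.0
    spindle_freq: float = 13.0  # Hz, inside the 11-16 Hz band
    k_complex: float = 55.0
    sem: float = 100.0  # slow EOG deflection amplitude


#: questionnaire mean shifts per group, in latent SD units; calibrated to
#: the ordering DEP/OBDEP > HC/OB on pre-recording sleepiness
DEFAULT_GROUP_EFFECTS: dict[str, float] = {
    "HC": 0.0,
    "OB": 0.15,
    "DEP": 0.75,
    "OBDEP": 0.90,
}

#: pre-to-post latent change per group (drives the delta scores)
_POST_SHIFT = {"HC": 0.35, "OB": -0.10, "DEP": -0.05, "OBDEP": -0.25}
_AGE_SHIFT = {"HC": -3.5, "OB": 1.5, "DEP": 0.5, "OBDEP": 3.5}
_FEMALE_P = {"HC": 0.61, "OB": 0.79, "DEP": 0.44, "OBDEP": 0.72}

#: trait loading of every questionnaire latent; residual SD makes unit variance
TRAIT_LOADING = 0.8
_RESID_SD = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 66, "OB": 68, "DEP": 16, "OBDEP": 43}
    )
    duration: int = 1200  # seconds of recording
    sampling_rate: float = 200.0  # Hz (1000 supported)
    transition_model: TransitionModel = field(default_factory=TransitionModel)
    coupling: float = 0.4  # subjective-objective link, in [-1, 1]
    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    noise: NoiseScales = field(default_factory=NoiseScales)
    montage: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MONTAGE))
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"negative size for group {g}")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling rate must be positive")
        if not -1.0 <= self.coupling <= 1.0:
            raise ConfigurationError("coupling must lie in [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a simulated cohort.

    Stored for validation only; the analysis modules never consume it."""

    traits: np.ndarray  # latent trait sleepiness per subject
    sequences: tuple[StageSequence, ...]  # true stage trajectories
    groups: tuple[str, ...]


@dataclass(frozen=True)
class Cohort:
    """Simulated subjects plus the config that produced them."""

    subjects: tuple[Subject, ...]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self):
        """One analysis row per subject (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame([s.to_row() for s in self.subjects])


def _simulate_paths(
    rng: np.random.Generator,
    model: TransitionModel,
    drifts: np.ndarray,
    duration: int,
) -> np.ndarray:
    """Simulate one Markov trajectory per drift value, vectorized over
    subjects (returns subjects x duration int8 stage codes)."""
    n = drifts.size
    down = np.empty((n, _N_STAGES))
    up = np.empty((n, _N_STAGES))
    for i, d in enumerate(drifts):
        down[i], up[i] = model.rates(float(d))
    states = np.empty((n, duration), dtype=np.int8)
    current = rng.choice(_N_STAGES, size=n, p=np.asarray(model.initial))
    rows = np.arange(n)
    states[:, 0] = current
    u = rng.random((n, duration - 1))
    for t in range(1, duration):
        pd_ = down[rows, current]
        pu = up[rows, current]
        step_down = u[:, t - 1] < pd_
        step_up = (~step_down) & (u[:, t - 1] < pd_ + pu)
        current = current + step_down.astype(np.int8) - step_up.astype(np.int8)
        states[:, t] = current
    return states


def simulate_vigilance_trajectory(
    config: SimulationConfig, trait: float, seed: int
) -> StageSequence:
    """Simulate one subject's true per-second vigilance trajectory.

    The downward drift of the Markov chain is ``coupling * trait``:
    sleepier subjects (higher trait) descend faster when coupling is
    positive, and the trajectory is trait-independent at coupling 0.
    """
    if config.duration < 60:
        raise ConfigurationError("trajectory needs a duration of at least 60 s")
    rng = np.random.default_rng(seed)
    drift = np.array([config.coupling * trait])
    codes = _simulate_paths(rng, config.transition_model, drift, config.duration)[0]
    return StageSequence(codes)


def _region_weights(stage: Stage) -> dict[str, float]:
    if stage is Stage.A1:
        return {"occipital": 1.0, "temporal-parietal": 1 / 3, "frontal": 0.2}
    if stage is Stage.A2:
        return {"occipital": 0.4, "temporal-parietal": 1.0, "frontal": 0.25}
    if stage is Stage.A3:
        return {"occipital": 0.3, "temporal-parietal": 0.4, "frontal": 1.0}
    return {}


def synthesize_recording(
    trajectory: StageSequence, config: SimulationConfig, seed: int
) -> Recording:
    """Render a stage trajectory as a multichannel EEG+EOG recording.

    Every second's signal carries the defining characteristic of its
    stage; amplitudes come from ``config.noise``.  Deterministic given
    the seed.
    """
    fs = int(round(config.sampling_rate))
    if fs != config.sampling_rate:
        raise ConfigurationError("sampling rate must be a whole number of Hz")
    duration = len(trajectory)
    if duration * fs <= 0:
        raise ConfigurationError("empty trajectory")
    rng = np.random.default_rng(seed)
    ns = config.noise
    channels = tuple(config.montage)
    regions = config.montage
    n_ch = len(channels)
    scalp = [i for i, ch in enumerate(channels) if regions[ch] != "eog"]
    eog = [i for i, ch in enumerate(channels) if regions[ch] == "eog"]
    if len(eog) != 1:
        raise ConfigurationError("montage must have exactly one EOG channel")
    region_of = [regions[ch] for ch in channels]

    data = rng.normal(0.0, ns.background, size=(n_ch, duration * fs))
    t1 = np.arange(fs) / fs  # within-second time axis

    for sec, stage in enumerate(trajectory.labels):
        sl = slice(sec * fs, (sec + 1) * fs)
        if stage in (Stage.A1, Stage.A2, Stage.A3):
            weights = _region_weights(stage)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(2 * np.pi * ns.alpha_freq * t1 + phase)
            for i in scalp:
                data[i, sl] += ns.alpha * weights[region_of[i]] * wave
        elif stage is Stage.B1:
            # slow horizontal eye movement: half-sine sweep on the EOG
            sign = rng.choice((-1.0, 1.0))
            data[eog[0], sl] += sign * ns.sem * np.sin(np.pi * t1)
        elif stage is Stage.B23:
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
            slow = ns.delta * np.sin(2 * np.pi * 2.3 * t1 + ph1)
            slow += ns.theta * np.sin(2 * np.pi * 5.7 * t1 + ph2)
            for i in scalp:
                data[i, sl] += slow
        elif stage is Stage.C:
            # spindle burst, frontally accentuated, every sleep-onset second
            start = rng.uniform(0.05, 0.25)
            dur = 0.65
            idx = (t1 >= start) & (t1 < start + dur)
            burst = np.zeros(fs)
            tb = t1[idx] - start
            burst[idx] = np.sin(2 * np.pi * ns.spindle_freq * tb) * np.hanning(
                idx.sum()
            )
            weight = {"frontal": 1.0, "temporal-parietal": 0.8, "occipital": 0.5}
            for i in scalp:
                data[i, sl] += ns.spindle * weight[region_of[i]] * burst
            if rng.random() < 0.25:
                from .staging import _k_complex_template

                template = ns.k_complex * _k_complex_template(fs)
                offset = int(0.1 * fs)
                end = min(fs, offset + template.size)
                for i in scalp:
                    data[i, sl][offset:end] += template[: end - offset]
        # stage 0: background only

    return Recording(
        data=data, sfreq=float(fs), channels=channels, regions=dict(regions)
    )


def _discretize(latent: np.ndarray, offset: float, slope: float, lo: int, hi: int):
    return np.clip(np.rint(offset + slope * latent), lo, hi).astype(int)


#: ASLEEP cut points (standard-normal scale) reproducing roughly
#: 12% / 22% / 18% / 48% for codes 1 (definitely slept) .. 4 (surely not)
_ASLEEP_CUTS = (1.175, 0.412, 0.050)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a full cohort: groups, traits, trajectories, objective
    summaries and questionnaires.

    Recordings are not rendered here; each subject carries a
    ``recording_seed`` so its signal can be synthesized reproducibly via
    :func:`synthesize_recording` on its true trajectory.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    groups: list[str] = []
    for g in GROUPS:
        groups.extend([g] * config.group_sizes.get(g, 0))

    if n == 0:
        return Cohort(subjects=(), config=config), GroundTruth(
            traits=np.empty(0), sequences=(), groups=()
        )

    traits = rng.normal(0.0, 1.0, size=n)
    drifts = config.coupling * traits
    codes = _simulate_paths(rng, config.transition_model, drifts, config.duration)
    sequences = tuple(StageSequence(row) for row in codes)
    summaries = [summarize_arousal(seq) for seq in sequences]

    shift = np.array([config.group_effects.get(g, 0.0) for g in groups])
    post_shift = np.array([_POST_SHIFT[g] for g in groups])

    def latent(extra_shift=0.0):
        return (
            TRAIT_LOADING * traits
            + shift
            + extra_shift
            + _RESID_SD * rng.normal(size=n)
        )

    kss_pre = _discretize(latent(), 3.4, 1.4, 1, 10)
    kss_post = _discretize(latent(post_shift), 3.4, 1.4, 1, 10)
    sss_pre = _discretize(latent(), 2.1, 1.0, 1, 7)
    sss_post = _discretize(latent(post_shift), 2.1, 1.0, 1, 7)
    vas_pre = np.clip(30.0 + 22.0 * latent(), 0.0, 100.0)
    vas_post = np.clip(30.0 + 22.0 * latent(post_shift), 0.0, 100.0)

    ess_latent = TRAIT_LOADING * traits + shift
    ess_items = np.clip(
        np.rint(0.95 + 0.45 * ess_latent[:, None] + 0.8 * rng.normal(size=(n, 8))),
        0,
        3,
    ).astype(int)
    rest_items = np.clip(
        np.rint(
            3.3 - 0.45 * (TRAIT_LOADING * traits + shift)[:, None]
            + 0.7 * rng.normal(size=(n, 8))
        ),
        1,
        5,
    ).astype(int)
    ssd = np.clip(np.rint(rng.normal(432.0, 72.0, size=n)), 120, 720)

    # ASLEEP: coupling-gated discretization of the true drowsy/sleep share
    prop_bc = np.array([s.prop_b + s.prop_c for s in summaries])
    sd = prop_bc.std()
    z_bc = (prop_bc - prop_bc.mean()) / sd if sd > 0 else np.zeros(n)
    c = config.coupling
    asleep_latent = c * z_bc + math.sqrt(max(0.0, 1 - c * c)) * rng.normal(size=n)
    asleep = np.full(n, 4, dtype=int)
    asleep[asleep_latent >= _ASLEEP_CUTS[2]] = 3
    asleep[asleep_latent >= _ASLEEP_CUTS[1]] = 2
    asleep[asleep_latent >= _ASLEEP_CUTS[0]] = 1

    age = np.clip(
        np.rint(
            rng.normal(37.6, 11.0, size=n) + np.array([_AGE_SHIFT[g] for g in groups])
        ),
        18,
        70,
    )
    female = rng.random(n) < np.array([_FEMALE_P[g] for g in groups])

    bmi = np.empty(n)
    bdi = np.empty(n)
    for i, g in enumerate(groups):
        if g in ("OB", "OBDEP"):
            mean = 43.0 if g == "OB" else 45.0
            bmi[i] = np.clip(rng.normal(mean, 8.0), 30.1, 75.0)
        else:
            bmi[i] = np.clip(rng.normal(24.0, 2.9), 16.0, 29.9)
        if g in ("DEP", "OBDEP"):
            bdi[i] = np.clip(np.rint(rng.normal(24.0, 8.5)), 14, 63)
        else:
            bdi[i] = np.clip(np.rint(rng.normal(5.0, 4.2)), 0, 13)

    recording_seeds = rng.integers(0, 2**31 - 1, size=n)

    subjects = []
    for i, g in enumerate(groups):
        q = QuestionnaireRecord(
            ess_items=tuple(int(v) for v in ess_items[i]),
            kss_pre=int(kss_pre[i]),
            kss_post=int(kss_post[i]),
            sss_pre=int(sss_pre[i]),
            sss_post=int(sss_post[i]),
            vas_pre=float(vas_pre[i]),
            vas_post=float(vas_post[i]),
            asleep=int(asleep[i]),
            restedness_items=tuple(int(v) for v in rest_items[i]),
            ssd=float(ssd[i]),
        )
        subjects.append(
            Subject(
                id=f"S{i + 1:03d}",
                age=float(age[i]),
                gender="female" if female[i] else "male",
                bmi=float(bmi[i]),
                bdi=float(bdi[i]),
                questionnaire=q,
                arousal=summaries[i],
                recording_seed=int(recording_seeds[i]),
            )
        )

    cohort = Cohort(subjects=tuple(subjects), config=config)
    truth = GroundTruth(traits=traits, sequences=sequences, groups=tuple(groups))
    return cohort, truth
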