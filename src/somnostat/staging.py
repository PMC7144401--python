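"""Second-by-second EEG-vigilance staging.

Resting-state EEG with eyes closed passes through a characteristic
sequence of arousal states, from active wakefulness (low-voltage,
desynchronized EEG) through relaxed wakefulness (posterior alpha that
drifts anteriorly as arousal declines) and drowsiness (alpha drop-out,
slow horizontal eye movements, then rising delta/theta power) to sleep
onset (sleep spindles and K-complexes).  This module classifies every
1-second segment of a multichannel recording into one of seven vigilance
stages:

======  =====  ==============================================
stage   score  defining characteristic
======  =====  ==============================================
0       7      low-voltage EEG, no alpha, no slow eye movement
A1      6      predominant occipital alpha
A2      5      high temporal/parietal alpha
A3      4      predominant frontal alpha
B1      3      low-voltage EEG, no alpha, slow eye movements
B2/3    2      increased delta and theta power
C       1      sleep spindles / K-complexes
======  =====  ==============================================

The classifier is a transparent decision cascade over per-segment
spectral band powers, alpha topography, an EOG slow-eye-movement
detector and spindle / K-complex detectors.  Amplitude-based artifact
masking excludes contaminated seconds from every downstream summary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Stage",
    "STAGE_SCORES",
    "Recording",
    "SegmentFeatures",
    "StageSequence",
    "StagingSettings",
    "extract_segment_features",
    "classify_segment",
    "detect_sem",
    "detect_spindle",
    "detect_k_complex",
    "mask_artifacts",
    "stage_recording",
]

SCALP_REGIONS = ("frontal", "temporal-parietal", "occipital")


class Stage(str, enum.Enum):
    """The seven vigilance stages plus the artifact marker."""

    STAGE_0 = "0"
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B1 = "B1"
    B23 = "B2/3"
    C = "C"
    ARTIFACT = "ARTIFACT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def score(self) -> int:
        """Numeric vigilance score, 7 (stage 0) down to 1 (stage C)."""
        if self is Stage.ARTIFACT:
            raise ValueError("artifact seconds carry no vigilance score")
        return STAGE_SCORES[self]


#: fixed bijection stage -> vigilance score
STAGE_SCORES: dict[Stage, int] = {
    Stage.STAGE_0: 7,
    Stage.A1: 6,
    Stage.A2: 5,
    Stage.A3: 4,
    Stage.B1: 3,
    Stage.B23: 2,
    Stage.C: 1,
}

#: integer codes used for compact storage (order matches declining vigilance)
_STAGE_ORDER: tuple[Stage, ...] = (
    Stage.STAGE_0,
    Stage.A1,
    Stage.A2,
    Stage.A3,
    Stage.B1,
    Stage.B23,
    Stage.C,
)
_ARTIFACT_CODE = 7
_STAGE_TO_CODE = {s: i for i, s in enumerate(_STAGE_ORDER)}
_STAGE_TO_CODE[Stage.ARTIFACT] = _ARTIFACT_CODE
_CODE_TO_STAGE = {i: s for s, i in _STAGE_TO_CODE.items()}


def stage_from_label(label: "Stage | str") -> Stage:
    """Coerce a label ('A1', 'B2/3', Stage.C, ...) to a :class:`Stage`."""
    if isinstance(label, Stage):
        return label
    return Stage(str(label))


@dataclass(frozen=True)
class StageSequence:
    """Per-second stage labels with an artifact mask.

    ``codes`` stores one small integer per second (0..6 for the stages in
    declining-vigilance order, 7 for artifact).  Masked seconds are by
    definition the artifact seconds and are excluded from all summaries.
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 1:
            raise ValueError("stage codes must be one-dimensional")
        if codes.size and (codes.min() < 0 or codes.max() > _ARTIFACT_CODE):
            raise ValueError("stage codes must lie in 0..7")
        object.__setattr__(self, "codes", codes)

    @classmethod
    def from_labels(
        cls, labels, artifact_mask: np.ndarray | None = None
    ) -> "StageSequence":
        codes = np.array(
            [_STAGE_TO_CODE[stage_from_label(l)] for l in labels], dtype=np.int8
        )
        if artifact_mask is not None:
            artifact_mask = np.asarray(artifact_mask, dtype=bool)
            if artifact_mask.shape != codes.shape:
                raise ValueError("artifact mask length must match labels")
            codes = codes.copy()
            codes[artifact_mask] = _ARTIFACT_CODE
        return cls(codes)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def duration(self) -> int:
        """Sequence length in seconds (1-s segments)."""
        return len(self)

    @property
    def artifact_mask(self) -> np.ndarray:
        return self.codes == _ARTIFACT_CODE

    @property
    def labels(self) -> list[Stage]:
        return [_CODE_TO_STAGE[int(c)] for c in self.codes]

    @property
    def scores(self) -> np.ndarray:
        """Float vigilance scores per second; NaN on artifact seconds."""
        table = np.array([float(STAGE_SCORES[s]) for s in _STAGE_ORDER] + [np.nan])
        return table[self.codes]

    def unmasked_codes(self) -> np.ndarray:
        return self.codes[self.codes != _ARTIFACT_CODE]


@dataclass(frozen=True)
class Recording:
    """Multichannel scalp EEG + one EOG channel, in microvolts.

    ``data`` is channels x samples.  ``regions`` maps each channel name to
    one of 'frontal', 'temporal-parietal', 'occipital' or 'eog'; at least
    one channel per scalp region and exactly one EOG channel are required.
    """

    data: np.ndarray
    sfreq: float
    channels: tuple[str, ...]
    regions: dict[str, str]
    start_time: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {data.shape[0]} rows"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        missing = [ch for ch in self.channels if ch not in self.regions]
        if missing:
            raise ValueError(f"channels without region assignment: {missing}")
        by_region: dict[str, list[int]] = {}
        for i, ch in enumerate(self.channels):
            region = self.regions[ch]
            if region not in SCALP_REGIONS + ("eog",):
                raise ValueError(f"unknown region {region!r} for channel {ch!r}")
            by_region.setdefault(region, []).append(i)
        for region in SCALP_REGIONS:
            if not by_region.get(region):
                raise ValueError(f"montage has no {region} channel")
        if len(by_region.get("eog", [])) != 1:
            raise ValueError("montage must designate exactly one EOG channel")
        object.__setattr__(self, "_region_index", by_region)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_seconds(self) -> int:
        return int(self.n_samples // round(self.sfreq))

    @property
    def scalp_index(self) -> list[int]:
        idx: list[int] = []
        for region in SCALP_REGIONS:
            idx.extend(self._region_index[region])
        return sorted(idx)

    @property
    def eog_index(self) -> int:
        return self._region_index["eog"][0]

    def region_index(self, region: str) -> list[int]:
        return list(self._region_index[region])

    def segment(self, second: int) -> np.ndarray:
        """Return the 1-s slice (all channels) for ``second``."""
        fs = int(round(self.sfreq))
        if not 0 <= second < self.n_seconds:
            raise IndexError(f"second {second} outside recording")
        return self.data[:, second * fs : (second + 1) * fs]


@dataclass(frozen=True)
class SegmentFeatures:
    """Spectral/topographic features of a single 1-s segment."""

    band_power: dict[str, dict[str, float]]  # region -> band -> uV^2
    relative_alpha: float  # alpha / total power, scalp average, in [0, 1]
    alpha_region: str  # region of maximal alpha power
    sem: bool  # slow horizontal eye movement on EOG
    spindle: bool
    k_complex: bool
    peak_amplitude: float  # max |uV| over scalp channels

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_alpha <= 1.0:
            raise ValueError("relative alpha share must lie in [0, 1]")
        for region, bands in self.band_power.items():
            for band, value in bands.items():
                if value < 0:
                    raise ValueError(f"negative {band} power in {region}")

    @property
    def delta_theta(self) -> float:
        """Scalp-average delta + theta power (uV^2)."""
        powers = [
            self.band_power[r]["delta"] + self.band_power[r]["theta"]
            for r in SCALP_REGIONS
        ]
        return float(np.mean(powers))


@dataclass(frozen=True)
class StagingSettings:
    """Tunable thresholds of the staging cascade.

    Band edges follow clinical convention (delta 1-4 Hz, theta 4-8 Hz,
    alpha 8-12 Hz, spindles 11-16 Hz); total power is taken over 1-30 Hz.
    Alpha is "predominant" when it carries more than
    ``alpha_share_threshold`` of total scalp power; delta+theta is
    "increased" when it exceeds ``b23_elevation`` times the recording's
    unmasked median while also carrying at least ``b23_share`` of the
    segment's total power (so spectral leakage from a strong alpha or
    spindle second cannot mimic slow-wave drowsiness).
    """

    delta_band: tuple[float, float] = (1.0, 4.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    spindle_band: tuple[float, float] = (11.0, 16.0)
    total_band: tuple[float, float] = (1.0, 30.0)
    alpha_share_threshold: float = 0.3
    b23_elevation: float = 1.5
    b23_share: float = 0.4  # delta+theta fraction of total power
    artifact_threshold: float = 100.0  # uV, absolute, scalp channels
    sem_cutoff: float = 0.6  # Hz low-pass for the EOG
    sem_amplitude: float = 25.0  # uV peak-to-peak after low-pass
    spindle_envelope_threshold: float = 10.0  # uV
    spindle_min_duration: float = 0.3  # s sustained above threshold
    k_complex_p2p: float = 75.0  # uV peak-to-peak in the slow band
    k_complex_corr: float = 0.5  # normalized template correlation


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs < band[1])


def _segment_psd(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # Hann-tapered periodogram of a 1-s segment, per channel.
    freqs, psd = sps.periodogram(segment, fs=fs, window="hann", axis=-1)
    return freqs, psd


def detect_sem(eog_segment: np.ndarray, sfreq: float, settings: StagingSettings | None = None) -> bool:
    """Detect a slow horizontal eye movement in >= 1 s of EOG signal.

    The EOG is low-passed at ``sem_cutoff`` (zero-phase Butterworth); a
    SEM is flagged when the residual slow deflection exceeds
    ``sem_amplitude`` microvolts peak-to-peak.
    """
    settings = settings or StagingSettings()
    x = np.asarray(eog_segment, dtype=float)
    if x.size < sfreq:
        raise ValueError("need at least one second of EOG signal")
    nyq = sfreq / 2.0
    sos = sps.butter(2, settings.sem_cutoff / nyq, btype="low", output="sos")
    slow = sps.sosfiltfilt(sos, x, padtype="constant")
    return bool(np.ptp(slow) > settings.sem_amplitude)


def detect_spindle(segment: np.ndarray, sfreq: float, settings: StagingSettings | None = None) -> bool:
    """Detect a sleep-spindle burst (11-16 Hz) in a 1-s scalp segment.

    The band-limited analytic envelope must stay above
    ``spindle_envelope_threshold`` for at least ``spindle_min_duration``
    seconds on some channel.
    """
    settings = settings or StagingSettings()
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    nyq = sfreq / 2.0
    lo, hi = settings.spindle_band
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    band = sps.sosfiltfilt(sos, x, axis=-1)
    envelope = np.abs(sps.hilbert(band, axis=-1))
    above = envelope > settings.spindle_envelope_threshold
    min_run = int(round(settings.spindle_min_duration * sfreq))
    for row in above:
        run = 0
        for flag in row:
            run = run + 1 if flag else 0
            if run >= min_run:
                return True
    return False


def _k_complex_template(sfreq: float) -> np.ndarray:
    # Biphasic slow transient: sharp negative lobe then a broader positive one.
    fs = int(round(sfreq))
    neg = -np.sin(np.pi * np.arange(int(0.25 * fs)) / (0.25 * fs))
    pos = 0.6 * np.sin(np.pi * np.arange(int(0.55 * fs)) / (0.55 * fs))
    return np.concatenate([neg, pos])


def detect_k_complex(segment: np.ndarray, sfreq: float, settings: StagingSettings | None = None) -> bool:
    """Detect a K-complex: a large biphasic slow transient.

    The slow (<4 Hz) component must exceed ``k_complex_p2p`` microvolts
    peak-to-peak and correlate with a biphasic template above
    ``k_complex_corr`` on some channel.
    """
    settings = settings or StagingSettings()
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    nyq = sfreq / 2.0
    sos = sps.butter(2, 4.0 / nyq, btype="low", output="sos")
    slow = sps.sosfiltfilt(sos, x, axis=-1, padtype="constant")
    template = _k_complex_template(sfreq)
    t_norm = (template - template.mean()) / (np.linalg.norm(template) + 1e-12)
    for row in slow:
        if np.ptp(row) <= settings.k_complex_p2p:
            continue
        corr = np.correlate(row - row.mean(), t_norm, mode="valid")
        denom = np.linalg.norm(row - row.mean()) + 1e-12
        if corr.size and np.max(np.abs(corr)) / denom > settings.k_complex_corr:
            return True
    return False


def extract_segment_features(
    recording: Recording,
    second: int,
    settings: StagingSettings | None = None,
) -> SegmentFeatures:
    """Compute the spectral/topographic features of one 1-s segment."""
    settings = settings or StagingSettings()
    seg = recording.segment(second)
    fs = recording.sfreq
    scalp = recording.scalp_index
    freqs, psd = _segment_psd(seg, fs)
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    bands = {
        "delta": settings.delta_band,
        "theta": settings.theta_band,
        "alpha": settings.alpha_band,
        "total": settings.total_band,
    }
    band_power: dict[str, dict[str, float]] = {}
    for region in SCALP_REGIONS:
        idx = recording.region_index(region)
        region_psd = psd[idx].mean(axis=0)
        band_power[region] = {
            name: float(region_psd[_band_slice(freqs, b)].sum() * df)
            for name, b in bands.items()
        }
    scalp_psd = psd[scalp].mean(axis=0)
    alpha_p = float(scalp_psd[_band_slice(freqs, settings.alpha_band)].sum() * df)
    total_p = float(scalp_psd[_band_slice(freqs, settings.total_band)].sum() * df)
    rel_alpha = alpha_p / total_p if total_p > 0 else 0.0
    # tie-break favors the higher stage: occipital > temporal-parietal > frontal
    priority = ("occipital", "temporal-parietal", "frontal")
    alpha_region = max(priority, key=lambda r: band_power[r]["alpha"])
    eog = seg[recording.eog_index]
    return SegmentFeatures(
        band_power=band_power,
        relative_alpha=min(max(rel_alpha, 0.0), 1.0),
        alpha_region=alpha_region,
        sem=detect_sem(eog, fs, settings),
        spindle=detect_spindle(seg[scalp], fs, settings),
        k_complex=detect_k_complex(seg[scalp], fs, settings),
        peak_amplitude=float(np.max(np.abs(seg[scalp]))),
    )


_ALPHA_REGION_STAGE = {
    "occipital": Stage.A1,
    "temporal-parietal": Stage.A2,
    "frontal": Stage.A3,
}


def classify_segment(
    features: SegmentFeatures,
    baseline_delta_theta: float,
    settings: StagingSettings | None = None,
) -> Stage:
    """Assign a vigilance stage to one segment.

    Decision cascade: (1) spindle or K-complex -> C; (2) delta+theta
    elevated against the recording baseline -> B2/3; (3) alpha not
    predominant -> B1 if a SEM is present else 0; (4) alpha predominant
    -> A1/A2/A3 by the region of maximal alpha power.
    """
    settings = settings or StagingSettings()
    if features.spindle or features.k_complex:
        return Stage.C
    total = float(
        np.mean([features.band_power[r]["total"] for r in SCALP_REGIONS])
    )
    if (
        baseline_delta_theta > 0
        and features.delta_theta >= settings.b23_elevation * baseline_delta_theta
        and total > 0
        and features.delta_theta / total >= settings.b23_share
    ):
        return Stage.B23
    if features.relative_alpha <= settings.alpha_share_threshold:
        return Stage.B1 if features.sem else Stage.STAGE_0
    return _ALPHA_REGION_STAGE[features.alpha_region]


def mask_artifacts(
    recording: Recording, amplitude_threshold: float | None = None
) -> np.ndarray:
    """Boolean mask per second: True where any scalp channel exceeds the
    absolute amplitude threshold within that second."""
    threshold = (
        StagingSettings().artifact_threshold
        if amplitude_threshold is None
        else amplitude_threshold
    )
    if threshold <= 0:
        raise ValueError("amplitude threshold must be positive")
    fs = int(round(recording.sfreq))
    n = recording.n_seconds
    scalp = recording.data[recording.scalp_index, : n * fs]
    per_second = np.abs(scalp).reshape(scalp.shape[0], n, fs).max(axis=(0, 2))
    return per_second > threshold


def stage_recording(
    recording: Recording, settings: StagingSettings | None = None
) -> StageSequence:
    """Stage a whole recording: artifact mask, per-second features,
    recording-level baseline, then the classification cascade.

    The delta+theta baseline is the median over unmasked seconds, making
    the B2/3 elevation criterion relative to the subject's own recording.
    """
    settings = settings or StagingSettings()
    if recording.n_seconds < 60:
        raise ValueError("recording shorter than 60 s: baseline not estimable")
    mask = mask_artifacts(recording, settings.artifact_threshold)
    features: list[SegmentFeatures | None] = []
    for second in range(recording.n_seconds):
        if mask[second]:
            features.append(None)
        else:
            features.append(extract_segment_features(recording, second, settings))
    dt = [f.delta_theta for f in features if f is not None]
    if not dt:
        raise ValueError("all seconds are artifacted")
    baseline = float(np.median(dt))
    labels = [
        Stage.ARTIFACT if f is None else classify_segment(f, baseline, settings)
        for f in features
    ]
    return StageSequence.from_labels(labels)
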