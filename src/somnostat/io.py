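"""Reading and writing recordings, stage sequences and subject tables.

Recordings travel either as EDF (read via :mod:`mne`, optional
dependency) or as plain delimited signal tables: a TSV whose header
comment lines carry the sampling rate and the channel-to-region map,
followed by one column per channel in microvolts.  Stage sequences are
two-column tables (second index, label) plus the artifact mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .staging import Recording, Stage, StageSequence

__all__ = [
    "read_recording",
    "write_recording_table",
    "read_stage_sequence",
    "write_stage_sequence",
    "infer_regions",
    "decimate_recording",
]

_REGION_PREFIXES = (
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("F", "frontal"),
    ("C", "temporal-parietal"),
    ("T", "temporal-parietal"),
    ("P", "temporal-parietal"),
    ("O", "occipital"),
)


def infer_regions(channels) -> dict[str, str]:
    """Map 10-20 channel names to scalp regions by prefix.

    Channels containing 'EOG' map to the EOG region; unknown names raise.
    """
    regions: dict[str, str] = {}
    for ch in channels:
        upper = ch.upper()
        if "EOG" in upper:
            regions[ch] = "eog"
            continue
        for prefix, region in _REGION_PREFIXES:
            if upper.startswith(prefix.upper()):
                regions[ch] = region
                break
        else:
            raise ValueError(f"cannot infer scalp region for channel {ch!r}")
    return regions


def write_recording_table(recording: Recording, path) -> None:
    """Write a recording as a delimited signal table (TSV, microvolts)."""
    path = Path(path)
    header = {
        "sfreq": recording.sfreq,
        "regions": recording.regions,
        "units": "uV",
    }
    with open(path, "w") as fh:
        fh.write(f"# somnostat-recording {json.dumps(header)}\n")
        fh.write("\t".join(recording.channels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.4f", delimiter="\t")


def _read_table(path: Path) -> Recording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# somnostat-recording"):
            raise ValueError(f"{path}: not a recording table (missing header)")
        meta = json.loads(first.split(None, 2)[2])
        channels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    regions = meta.get("regions") or infer_regions(channels)
    return Recording(
        data=data.T,
        sfreq=float(meta["sfreq"]),
        channels=tuple(channels),
        regions=regions,
    )


def _read_edf(path: Path, regions: dict[str, str] | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = tuple(raw.ch_names)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        channels=channels,
        regions=regions or infer_regions(channels),
    )


def read_recording(
    path,
    regions: dict[str, str] | None = None,
    analysis_rate: float | None = None,
) -> Recording:
    """Read a recording from EDF or a delimited signal table.

    ``regions`` overrides the channel-to-region map (otherwise inferred
    from 10-20 names).  If ``analysis_rate`` is given and lower than the
    file's rate, the signal is decimated with an anti-alias filter.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path, regions)
    else:
        rec = _read_table(path)
        if regions is not None:
            rec = Recording(rec.data, rec.sfreq, rec.channels, regions)
    if analysis_rate is not None and analysis_rate < rec.sfreq:
        rec = decimate_recording(rec, analysis_rate)
    return rec


def decimate_recording(recording: Recording, target_rate: float) -> Recording:
    """Downsample by an integer factor with an anti-alias filter."""
    factor = recording.sfreq / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"cannot decimate {recording.sfreq} Hz to {target_rate} Hz: "
            "non-integer factor"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording
    data = sps.decimate(recording.data, factor, ftype="iir", zero_phase=True, axis=-1)
    return Recording(
        data=data,
        sfreq=recording.sfreq / factor,
        channels=recording.channels,
        regions=recording.regions,
        start_time=recording.start_time,
    )


def write_stage_sequence(sequence: StageSequence, path) -> None:
    """Write per-second labels and the artifact mask as a TSV."""
    labels = [str(s) for s in sequence.labels]
    frame = pd.DataFrame(
        {
            "second": np.arange(len(sequence)),
            "stage": labels,
            "artifact": sequence.artifact_mask.astype(int),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_stage_sequence(path) -> StageSequence:
    frame = pd.read_csv(path, sep="\t", dtype={"stage": str})
    if not {"second", "stage", "artifact"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns second, stage, artifact")
    frame = frame.sort_values("second")
    return StageSequence.from_labels(
        frame["stage"].tolist(), artifact_mask=frame["artifact"].to_numpy(bool)
    )
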