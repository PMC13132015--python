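"""Reading and writing recordings, manifests and tables.

EDF export uses a minimal single-segment writer (16-bit samples, one data
record per second); reading goes through mne, which also handles EEGLAB
.set files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import mne

from .core import Recording, RecordingMetadata
from .montage import Montage, make_geodesic_montage
from .synthetic import GroundTruthManifest, ArtifactEvent, BurstSpec

__all__ = [
    "write_edf",
    "read_edf",
    "read_eeglab_set",
    "write_manifest",
    "read_manifest",
    "spectrum_to_csv",
    "fit_to_json",
]


def spectrum_to_csv(spectrum, path) -> None:
    """Long-format (frequency, channel, power) CSV."""
    import pandas as pd

    n_ch = spectrum.power.shape[0]
    frame = pd.DataFrame(
        {
            "frequency_hz": np.tile(spectrum.frequencies, n_ch),
            "channel": np.repeat(np.arange(n_ch), spectrum.frequencies.size),
            "power_uv2_hz": spectrum.power.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def fit_to_json(fit, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "offset": fit.offset,
                "exponent": fit.exponent,
                "peaks": [list(p) for p in fit.peaks],
                "mae": fit.mae,
                "r_squared": fit.r_squared,
                "fit_range": list(fit.fit_range),
            },
            fh,
            indent=2,
        )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a recording to EDF (16-bit, µV, 1-s data records).

    The duration is truncated to whole seconds.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    nch = recording.n_channels
    sig = recording.signal[:, : n_records * fs]
    phys_min = np.floor(sig.min(axis=1))
    phys_max = np.ceil(sig.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)

    header = b""
    header += _edf_field(0, 8)  # version
    header += _edf_field(recording.metadata.participant, 80)
    header += _edf_field("wakeosc synthetic", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + nch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)  # record duration s
    header += _edf_field(nch, 4)

    labels = recording.montage.labels
    header += b"".join(_edf_field(l, 16) for l in labels)
    header += b"".join(_edf_field("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_field(f"{v:.1f}", 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.1f}", 8) for v in phys_max)
    header += b"".join(_edf_field(-32768, 8) for _ in labels)
    header += b"".join(_edf_field(32767, 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field(fs, 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)

    gain = (phys_max - phys_min) / 65535.0
    digital = np.round((sig - phys_min[:, None]) / gain[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def _recording_from_mne(raw, montage: Montage | None) -> Recording:
    data = raw.get_data() * 1e6  # volts → µV
    if montage is None:
        full = make_geodesic_montage(include_reference=True)
        try:
            montage = full.subset(list(raw.ch_names))
        except ValueError:
            montage = Montage(
                labels=list(raw.ch_names),
                positions=np.zeros((len(raw.ch_names), 3)),
            )
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        montage=montage,
        metadata=RecordingMetadata(),
    )


def read_edf(path, montage: Montage | None = None) -> Recording:
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _recording_from_mne(raw, montage)


def read_eeglab_set(path, montage: Montage | None = None) -> Recording:
    raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    return _recording_from_mne(raw, montage)


def write_manifest(manifest: GroundTruthManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_json_dict(), fh, indent=2)


def read_manifest(path) -> GroundTruthManifest:
    with open(path) as fh:
        d = json.load(fh)
    manifest = GroundTruthManifest(
        duration=d["duration"],
        n_channels=d["n_channels"],
        aperiodic_offset=d.get("aperiodic_offset"),
        aperiodic_exponent=d.get("aperiodic_exponent"),
    )
    for b in d["burst_specs"]:
        manifest.burst_specs.append(
            BurstSpec(
                channels=tuple(b["channels"]),
                onset=b["onset"],
                frequency=b["frequency"],
                n_cycles=b["n_cycles"],
                peak_to_peak=b["peak_to_peak"],
                asymmetry=b.get("asymmetry", 0.0),
            )
        )
    for a in d["artifact_events"]:
        manifest.artifact_events.append(
            ArtifactEvent(
                kind=a["kind"],
                channel=a["channel"],
                start=a["start"],
                duration=a["duration"],
            )
        )
    return manifest
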