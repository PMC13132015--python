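"""End-to-end assembly: recording → the six channel-averaged measures.

One row per recording: burst amplitude (µV) and pooled 4–16 Hz density (%)
from burst clusters, aperiodic exponent and offset, and band power /
periodic power (log10 units) averaged over the non-edge channels.
"""

from __future__ import annotations

import numpy as np

from .bursts import detect_recording_bursts
from .core import Recording
from .metrics import (
    UndefinedMeasure,
    cluster_bursts,
    compute_amplitude,
    compute_density,
)
from .spectral import band_measures, fit_specparam, smooth_spectrum, welch

__all__ = ["measure_row", "spectral_measures"]


def spectral_measures(
    recording: Recording,
    channels: list[int] | None = None,
    fit_range: tuple[float, float] = (2.0, 35.0),
    band: tuple[float, float] = (4.0, 16.0),
) -> dict[str, float]:
    """Channel-averaged exponent, offset, power and periodic power.

    Fits every requested channel's 2-Hz-smoothed Welch spectrum and
    averages the parameters; by default only non-edge analysis channels
    contribute (98 on the full montage).
    """
    montage = recording.montage
    if channels is None:
        keep = set(montage.nonedge_labels)
        channels = [i for i, l in enumerate(montage.labels) if l in keep]
    spectrum = smooth_spectrum(welch(recording.signal[channels], recording.fs))
    rows = {"Exponent": [], "Offset": [], "Power": [], "PeriodicPower": [], "MAE": [], "R2": []}
    for i in range(len(channels)):
        fit = fit_specparam(spectrum, fit_range=fit_range, channel=i)
        power, periodic = band_measures(spectrum, fit, band=band, channel=i)
        rows["Exponent"].append(fit.exponent)
        rows["Offset"].append(fit.offset)
        rows["Power"].append(power)
        rows["PeriodicPower"].append(periodic)
        rows["MAE"].append(fit.mae)
        rows["R2"].append(fit.r_squared)
    return {k: float(np.mean(v)) for k, v in rows.items()}


def measure_row(
    recording: Recording,
    channels: list[int] | None = None,
    use_clusters: bool = True,
) -> dict:
    """Compute the full measure-table row for one preprocessed recording."""
    bursts = detect_recording_bursts(recording, channels=channels)
    analysis = [b for b in bursts if b.frequency >= 4.0]
    if use_clusters:
        clusters = cluster_bursts(analysis)
        density = compute_density(
            clusters, recording.duration, recording.fs, pooled=True
        )
    else:
        density = compute_density(
            analysis, recording.duration, recording.fs, pooled=True
        )
    try:
        amplitude = compute_amplitude(analysis)
    except UndefinedMeasure:
        amplitude = np.nan
    row = recording.metadata.as_dict()
    row["Amplitude"] = amplitude
    row["Density"] = density
    row.update(
        {
            k: v
            for k, v in spectral_measures(recording, channels=channels).items()
            if k in ("Exponent", "Offset", "Power", "PeriodicPower")
        }
    )
    return row
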