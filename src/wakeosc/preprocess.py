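"""Filter chain and fully automated artifact-rejection cascade.

The cascade works on a 3-s segment grid: any (channel, segment) cell whose
amplitude exceeds 500 µV is a *major* artifact, removed by dropping
whichever of the whole channel or the whole segment discards less clean
data; cells whose maximum correlation with neighboring channels falls below
0.3 are *minor* artifacts, thinned iteratively until every channel and every
segment has at most 30% minor cells.  A second pass removes residual
(channel, segment) cells above 140 µV.  Recordings losing more than 25
channels or left with under one minute of data are excluded; otherwise
removed channels are interpolated by spherical splines onto the 123-channel
analysis montage and the data is average referenced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import mne

from .core import Recording
from .spectral import Spectrum, fit_specparam, smooth_spectrum, welch

__all__ = [
    "ArtifactMatrix",
    "RemovalPlan",
    "QCReport",
    "RecordingExcluded",
    "filter_chain",
    "mark_segments",
    "resolve_removals",
    "screen_components",
    "finalize",
    "preprocess_recording",
]

CLEAN, MINOR, MAJOR = 0, 1, 2

SEGMENT_S = 3.0
MAJOR_THRESHOLD_UV = 500.0
SECOND_PASS_THRESHOLD_UV = 140.0
MIN_NEIGHBOR_CORR = 0.3
MAX_MINOR_FRACTION = 0.30
MAX_CHANNELS_REMOVED = 25
MIN_CLEAN_SECONDS = 60.0
TARGET_FS = 250.0


@dataclass
class ArtifactMatrix:
    """Per-(channel, 3-s segment) artifact flags."""

    flags: np.ndarray  # (n_channels, n_segments) of {CLEAN, MINOR, MAJOR}
    window_s: float = SEGMENT_S

    @property
    def n_channels(self) -> int:
        return self.flags.shape[0]

    @property
    def n_segments(self) -> int:
        return self.flags.shape[1]


@dataclass
class RemovalPlan:
    channels: set[int] = field(default_factory=set)
    segments: set[int] = field(default_factory=set)

    @property
    def is_empty(self) -> bool:
        return not self.channels and not self.segments


@dataclass
class QCReport:
    channels_removed: list[str] = field(default_factory=list)
    seconds_removed: float = 0.0
    excluded: bool = False
    reason: str = "none"  # none | too-many-channels | too-short

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channels_removed": self.channels_removed,
                    "seconds_removed": self.seconds_removed,
                    "excluded": self.excluded,
                    "reason": self.reason,
                },
                fh,
                indent=2,
            )


class RecordingExcluded(Exception):
    """Raised when a recording fails the quality thresholds."""

    def __init__(self, report: QCReport):
        super().__init__(f"recording excluded: {report.reason}")
        self.report = report


def _kaiser_highpass(fs: float) -> np.ndarray:
    """FIR high-pass: 0.5 Hz passband edge, 0.25 Hz stopband edge,
    60 dB stopband attenuation (Kaiser design)."""
    from scipy.signal import firwin, kaiserord

    nyq = fs / 2.0
    ntaps, beta = kaiserord(60.0, 0.25 / nyq)
    if ntaps % 2 == 0:
        ntaps += 1
    return firwin(
        ntaps, 0.375 / nyq, window=("kaiser", beta), pass_zero=False
    )


def filter_chain(raw: Recording, line_freq: float = 50.0) -> Recording:
    """Mean-center, 40 Hz low-pass, notch line + harmonics, downsample to
    250 Hz, then 0.5 Hz Kaiser high-pass (zero-phase throughout)."""
    from scipy.signal import filtfilt

    if line_freq not in (50.0, 60.0, 50, 60):
        raise ValueError("line_freq must be 50 or 60 Hz")
    if raw.fs < 500:
        raise ValueError("raw sampling rate must be >= 500 Hz")
    x = raw.signal - raw.signal.mean(axis=1, keepdims=True)
    x = mne.filter.filter_data(x, raw.fs, None, 40.0, verbose="error")
    nyq = raw.fs / 2.0
    notches = np.arange(line_freq, nyq, line_freq)
    if notches.size:
        x = mne.filter.notch_filter(
            x, raw.fs, freqs=notches, notch_widths=2.0, verbose="error"
        )
    if raw.fs != TARGET_FS:
        x = mne.filter.resample(x, down=raw.fs / TARGET_FS, verbose="error")
    taps = _kaiser_highpass(TARGET_FS)
    x = filtfilt(taps, 1.0, x, axis=1)
    return raw.copy(signal=x, fs=TARGET_FS)


def _segment_grid(n_samples: int, fs: float, window_s: float = SEGMENT_S):
    """Non-overlapping half-open [k·w, (k+1)·w) windows; partial tail dropped."""
    seg_len = int(round(window_s * fs))
    n_seg = n_samples // seg_len
    return seg_len, n_seg


def mark_segments(filtered: Recording, n_neighbors: int = 6) -> ArtifactMatrix:
    """Flag (channel, 3-s segment) cells as clean/minor/major.

    Detection runs on an internal 1–40 Hz copy.  Major: any sample above
    500 µV.  Minor: best correlation with the 6 nearest channels below 0.3
    (undefined correlations — e.g., flat channels — count as minor).
    """
    if filtered.montage.positions.size == 0:
        raise ValueError("montage without positions cannot define neighbors")
    det = mne.filter.filter_data(
        filtered.signal, filtered.fs, 1.0, 40.0, verbose="error"
    )
    seg_len, n_seg = _segment_grid(filtered.n_samples, filtered.fs)
    neighbors = filtered.montage.neighbors(k=n_neighbors)
    flags = np.zeros((filtered.n_channels, n_seg), dtype=int)
    for s in range(n_seg):
        seg = det[:, s * seg_len : (s + 1) * seg_len]
        major = np.any(np.abs(seg) > MAJOR_THRESHOLD_UV, axis=1)
        flags[major, s] = MAJOR
        sd = seg.std(axis=1)
        centered = seg - seg.mean(axis=1, keepdims=True)
        for ch in range(filtered.n_channels):
            if flags[ch, s] == MAJOR:
                continue
            nb = neighbors[ch]
            if sd[ch] == 0:
                flags[ch, s] = MINOR
                continue
            valid = nb[sd[nb] > 0]
            if valid.size == 0:
                flags[ch, s] = MINOR
                continue
            corr = centered[valid] @ centered[ch] / (
                seg.shape[1] * sd[valid] * sd[ch]
            )
            if np.max(corr) < MIN_NEIGHBOR_CORR:
                flags[ch, s] = MINOR
    return ArtifactMatrix(flags=flags)


def resolve_removals(matrix: ArtifactMatrix) -> RemovalPlan:
    """Decide which channels and segments to drop.

    Majors are always removed, choosing channel vs segment by whichever
    discards less clean data (ties prefer the segment, preserving
    topography).  Minors are then thinned: repeatedly drop the channel with
    the most minor cells or the segment with the most minor cells —
    whichever count is larger — until every remaining channel and segment
    has at most 30% minor cells.
    """
    flags = matrix.flags
    plan = RemovalPlan()

    def remaining_mask():
        mask = np.ones_like(flags, dtype=bool)
        mask[list(plan.channels), :] = False
        mask[:, list(plan.segments)] = False
        return mask

    # majors: greedy local clean-data-loss comparison
    while True:
        mask = remaining_mask()
        majors = np.argwhere((flags == MAJOR) & mask)
        if majors.size == 0:
            break
        ch, seg = majors[0]
        clean = (flags == CLEAN) & mask
        loss_channel = clean[ch, :].sum()
        loss_segment = clean[:, seg].sum()
        if loss_channel < loss_segment:
            plan.channels.add(int(ch))
        else:
            plan.segments.add(int(seg))

    # minors: iterate until the 30% rule holds everywhere.  Fractions are
    # taken over the original grid so each removal monotonically lowers the
    # remaining counts and the loop cannot cascade.
    while True:
        mask = remaining_mask()
        minor = (flags == MINOR) & mask
        ch_keep = np.array([c for c in range(flags.shape[0]) if c not in plan.channels])
        seg_keep = np.array([s for s in range(flags.shape[1]) if s not in plan.segments])
        if ch_keep.size == 0 or seg_keep.size == 0:
            break
        ch_counts = minor.sum(axis=1)
        seg_counts = minor.sum(axis=0)
        ch_frac = ch_counts[ch_keep] / flags.shape[1]
        seg_frac = seg_counts[seg_keep] / flags.shape[0]
        if ch_frac.max(initial=0) <= MAX_MINOR_FRACTION and (
            seg_frac.max(initial=0) <= MAX_MINOR_FRACTION
        ):
            break
        worst_ch = ch_keep[int(np.argmax(ch_counts[ch_keep]))]
        worst_seg = seg_keep[int(np.argmax(seg_counts[seg_keep]))]
        if ch_counts[worst_ch] > seg_counts[worst_seg]:
            plan.channels.add(int(worst_ch))
        else:
            plan.segments.add(int(worst_seg))
    return plan


def screen_components(
    components: np.ndarray | Spectrum,
    fs: float | None = None,
    labels: list[str] | None = None,
    exponent_threshold: float = 0.5,
    smooth_span_hz: float = 5.0,
) -> np.ndarray:
    """Keep mask for independent components.

    A component is rejected when its label is muscle/eye/heart, or when the
    aperiodic exponent of its 8–30 Hz spectrum (5-Hz smoothed) is shallower
    than 0.5 — near-flat or rising spectra mark non-physiological sources.
    Accepts raw component time courses (Welch spectra are computed with 4-s
    Hanning windows, 50% overlap) or precomputed spectra.
    """
    if isinstance(components, Spectrum):
        spectrum = components
    else:
        components = np.atleast_2d(np.asarray(components, dtype=float))
        if fs is None:
            raise ValueError("fs required with component time courses")
        if components.shape[1] < 4 * fs:
            raise ValueError("component shorter than one Welch window")
        spectrum = welch(components, fs)
    spectrum = smooth_spectrum(spectrum, smooth_span_hz)
    n = spectrum.power.shape[0]
    keep = np.ones(n, dtype=bool)
    reject_labels = {"muscle", "eye", "heart"}
    for i in range(n):
        if labels is not None and labels[i] in reject_labels:
            keep[i] = False
            continue
        fit = fit_specparam(spectrum, fit_range=(8.0, 30.0), channel=i)
        if fit.exponent < exponent_threshold:
            keep[i] = False
    return keep


def _second_pass_matrix(signal: np.ndarray, fs: float) -> ArtifactMatrix:
    seg_len, n_seg = _segment_grid(signal.shape[1], fs)
    flags = np.zeros((signal.shape[0], n_seg), dtype=int)
    for s in range(n_seg):
        seg = signal[:, s * seg_len : (s + 1) * seg_len]
        flags[np.any(np.abs(seg) > SECOND_PASS_THRESHOLD_UV, axis=1), s] = MAJOR
    return ArtifactMatrix(flags=flags)


def _drop_segments(signal: np.ndarray, fs: float, segments: set[int]) -> np.ndarray:
    if not segments:
        return signal
    seg_len, n_seg = _segment_grid(signal.shape[1], fs)
    keep = np.ones(signal.shape[1], dtype=bool)
    for s in segments:
        keep[s * seg_len : (s + 1) * seg_len] = False
    return signal[:, keep]


def finalize(
    recording: Recording, plan: RemovalPlan
) -> tuple[Recording, QCReport]:
    """Apply the removal plan, run the 140 µV second pass, evaluate the
    exclusion rules, interpolate removed channels, and average reference
    on the 123-channel analysis montage.

    Raises
    ------
    RecordingExcluded
        If more than 25 channels were removed or less than 60 s of clean
        data remains.  The exception carries the QC report.
    """
    from .montage import full_analysis_montage

    report = QCReport()
    signal = _drop_segments(recording.signal, recording.fs, plan.segments)
    report.seconds_removed = len(plan.segments) * SEGMENT_S
    removed = set(plan.channels)

    good = [c for c in range(recording.n_channels) if c not in removed]
    # average reference over retained channels before the amplitude pass
    signal = signal - signal[good].mean(axis=0, keepdims=True)

    # second pass: residual >140 µV windows among retained channels
    matrix = _second_pass_matrix(signal[good], recording.fs)
    second = resolve_removals(matrix)
    removed |= {good[c] for c in second.channels}
    signal = _drop_segments(signal, recording.fs, second.segments)
    report.seconds_removed += len(second.segments) * SEGMENT_S

    report.channels_removed = [recording.montage.labels[c] for c in sorted(removed)]
    if len(removed) > MAX_CHANNELS_REMOVED:
        report.excluded, report.reason = True, "too-many-channels"
        raise RecordingExcluded(report)
    if signal.shape[1] / recording.fs < MIN_CLEAN_SECONDS:
        report.excluded, report.reason = True, "too-short"
        raise RecordingExcluded(report)

    # assemble the reference channel, interpolate removed channels by
    # spherical splines, and keep the analysis channels (123 on the full
    # sensor net; proportionally fewer for reduced test montages).  The
    # recording reference Cz starts as zeros and is reconstructed by
    # interpolation like any removed channel — its potential relative to
    # the average reference is not otherwise recoverable.
    full_target = full_analysis_montage()
    available = set(recording.montage.labels) | {"Cz"}
    target = full_target.subset(
        [l for l in full_target.labels if l in available]
    )
    labels = list(recording.montage.labels)
    full = signal.copy()
    bads = [recording.montage.labels[c] for c in sorted(removed)]
    if "Cz" not in labels:
        full = np.vstack([full, np.zeros((1, full.shape[1]))])
        labels = labels + ["Cz"]
        bads = bads + ["Cz"]
    info = mne.create_info(labels, recording.fs, ch_types="eeg", verbose="error")
    raw = mne.io.RawArray(full * 1e-6, info, verbose="error")  # to volts
    std = mne.channels.make_standard_montage("GSN-HydroCel-129")
    raw.set_montage(std, verbose="error")
    raw.info["bads"] = bads
    if raw.info["bads"]:
        raw.interpolate_bads(reset_bads=True, verbose="error")
    raw.pick(target.labels, verbose="error")
    out_signal = raw.get_data() * 1e6
    out_signal -= out_signal.mean(axis=0, keepdims=True)  # final average ref
    out = Recording(
        signal=out_signal,
        fs=recording.fs,
        montage=target,
        metadata=recording.metadata,
    )
    return out, report


def preprocess_recording(
    raw: Recording, line_freq: float = 50.0
) -> tuple[Recording, QCReport]:
    """Full cascade: filter chain, artifact marking, removal resolution,
    second pass, interpolation and referencing."""
    filtered = filter_chain(raw, line_freq)
    matrix = mark_segments(filtered)
    plan = resolve_removals(matrix)
    return finalize(filtered, plan)
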