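"""Cycle-by-cycle oscillation-burst detection.

The signal is narrow-bandpass filtered in overlapping 4-Hz-wide bands
stepping by 2 Hz from 2 to 16 Hz.  Zero-crossings of the narrowband signal
delimit half-cycles; peaks are then located in the broadband (0.5–40 Hz)
signal between those crossings, and a cycle runs from positive peak to
positive peak.  Each cycle gets seven regularity scores in [0, 1], and a
burst is a run of at least MinCycles consecutive cycles that pass every
threshold of one of three a-priori criteria sets.  Amplitude is never used
as a threshold, which keeps burst density and burst amplitude independent
measures: scaling the signal leaves the detected burst set unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import mne

from .core import Recording

__all__ = [
    "CriteriaSet",
    "Burst",
    "DEFAULT_CRITERIA",
    "band_filters",
    "parse_cycles",
    "score_cycles",
    "detect_bursts",
    "detect_recording_bursts",
    "bursts_to_frame",
]

FREQ_MIN, FREQ_MAX = 2.0, 16.0

SCORE_COLUMNS = (
    "period_consistency",
    "amplitude_consistency",
    "flank_consistency",
    "shape_consistency",
    "monotonicity_time",
    "monotonicity_amplitude",
    "reversal_ratio",
)


def band_filters() -> list[tuple[float, float]]:
    """Overlapping narrowband ranges: 4 Hz wide, 2 Hz step, within 2–16 Hz."""
    return [(lo, lo + 4.0) for lo in np.arange(2.0, 13.0, 2.0)]


@dataclass(frozen=True)
class CriteriaSet:
    """Named thresholds on the cycle scores plus a minimum run length."""

    name: str
    min_cycles: int
    thresholds: dict[str, float] = field(default_factory=dict)
    in_band_frequency: bool = False

    def __post_init__(self) -> None:
        if self.min_cycles < 3:
            raise ValueError("MinCycles must be >= 3")
        for key, val in self.thresholds.items():
            if key not in SCORE_COLUMNS:
                raise ValueError(f"unknown score {key!r}")
            if not 0 <= val <= 1:
                raise ValueError("thresholds must lie in [0, 1]")


#: The three a-priori criteria sets. Set 1: many permissive criteria,
#: 4 cycles. Set 2: fewer, intermediate thresholds, 5 cycles. Set 3:
#: strict amplitude monotonicity, 3 cycles.
DEFAULT_CRITERIA = (
    CriteriaSet(
        name="set1",
        min_cycles=4,
        in_band_frequency=True,
        thresholds={
            "period_consistency": 0.5,
            "amplitude_consistency": 0.4,
            "flank_consistency": 0.5,
            "shape_consistency": 0.2,
            "monotonicity_time": 0.4,
            "monotonicity_amplitude": 0.4,
            "reversal_ratio": 0.6,
        },
    ),
    CriteriaSet(
        name="set2",
        min_cycles=5,
        thresholds={
            "period_consistency": 0.6,
            "amplitude_consistency": 0.6,
            "monotonicity_amplitude": 0.6,
            "flank_consistency": 0.6,
        },
    ),
    CriteriaSet(
        name="set3",
        min_cycles=3,
        in_band_frequency=True,
        thresholds={
            "period_consistency": 0.7,
            "flank_consistency": 0.3,
            "monotonicity_amplitude": 0.9,
        },
    ),
)


@dataclass
class Burst:
    """A channel-level run of qualifying cycles."""

    channel: int
    band: tuple[float, float]
    start: int  # sample, 0-based
    end: int  # sample, half-open
    n_cycles: int
    frequency: float  # 1 / mean negative-peak spacing
    mean_amplitude: float  # µV, mean cycle peak-to-peak
    sets: tuple[str, ...]
    neg_peaks: tuple[int, ...] = ()
    cycle_amplitudes: tuple[float, ...] = ()

    @property
    def duration_samples(self) -> int:
        return self.end - self.start

    def duration_s(self, fs: float) -> float:
        return self.duration_samples / fs


def parse_cycles(
    narrowband: np.ndarray,
    broadband: np.ndarray,
    fs: float,
    band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Cycle table: one row per positive-peak-to-positive-peak span.

    Zero-crossings are taken from the narrowband signal; the peaks between
    them are located in the broadband signal, so cycle amplitudes reflect
    the raw waveform rather than the filter output.  With ``band`` given,
    spans whose period lies more than an octave outside the narrowband
    range are discarded — they arise from filter ringing in signal-free
    stretches, not from oscillations the band can represent.
    """
    narrowband = np.asarray(narrowband, dtype=float)
    broadband = np.asarray(broadband, dtype=float)
    if narrowband.shape != broadband.shape:
        raise ValueError("narrowband and broadband signals must be equal length")
    sign = np.sign(narrowband)
    sign[sign == 0] = 1
    changes = np.flatnonzero(np.diff(sign))
    if changes.size < 3:
        return _empty_cycle_frame()
    crossings = changes + 1  # first index on the new side
    rising = crossings[narrowband[crossings] > 0]
    falling = crossings[narrowband[crossings] <= 0]

    # positive peaks: between each rising and next falling crossing
    pos_peaks = []
    for r in rising:
        nxt = falling[falling > r]
        if nxt.size == 0:
            break
        seg = broadband[r : nxt[0]]
        if seg.size:
            p = r + int(np.argmax(seg))
            if _is_local_extremum(broadband, p):
                pos_peaks.append(p)
    rows = []
    for i in range(len(pos_peaks) - 1):
        p0, p1 = pos_peaks[i], pos_peaks[i + 1]
        if p1 <= p0 + 2:
            continue
        inner = broadband[p0 : p1 + 1]
        neg = p0 + int(np.argmin(inner))
        if neg in (p0, p1):
            continue
        amp = (broadband[p0] + broadband[p1]) / 2.0 - broadband[neg]
        if amp <= 0:
            continue  # degenerate span (e.g., silence), not an oscillation
        if band is not None:
            period = (p1 - p0) / fs
            if not (1.0 / (2 * band[1]) <= period <= 2.0 / band[0]):
                continue
        rows.append(
            {
                "start": p0,
                "neg": neg,
                "end": p1,
                "period_s": (p1 - p0) / fs,
                "amplitude": amp,
            }
        )
    if not rows:
        return _empty_cycle_frame()
    frame = pd.DataFrame(rows)
    frame.attrs["fs"] = fs
    frame.attrs["broadband"] = _SignalRef(broadband)
    return frame


def _is_local_extremum(x: np.ndarray, p: int, max_plateau: int = 2) -> bool:
    """True when x[p] is a genuine local extremum rather than a point on a
    plateau (e.g., silence), allowing a 2-sample tie for peaks falling
    between samples."""
    lo = p
    while lo > 0 and x[lo - 1] == x[p]:
        lo -= 1
    hi = p
    while hi < x.size - 1 and x[hi + 1] == x[p]:
        hi += 1
    if hi - lo + 1 > max_plateau:
        return False
    return lo > 0 and hi < x.size - 1


class _SignalRef:
    """Holds the broadband signal on a cycle table without confusing
    pandas metadata comparisons."""

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray):
        self.data = data

    def __eq__(self, other) -> bool:
        return self is other

    def __hash__(self) -> int:
        return id(self)


def _empty_cycle_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["start", "neg", "end", "period_s", "amplitude"]
    )


def _adjacent_ratio(values: np.ndarray, contiguous: np.ndarray) -> np.ndarray:
    """Worst min/max ratio against the temporally contiguous neighbors.

    ``contiguous[i]`` marks whether cycle i+1 directly follows cycle i; a
    neighbor across a gap is not an adjacent cycle of the same oscillation
    and is ignored, like a missing neighbor at the signal edge.
    """
    n = values.size
    out = np.ones(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        pair = np.minimum(values[1:], values[:-1]) / np.maximum(
            values[1:], values[:-1]
        )
    pair = np.nan_to_num(pair, nan=0.0)
    for i in range(n):
        ratios = []
        if i > 0 and contiguous[i - 1]:
            ratios.append(pair[i - 1])
        if i < n - 1 and contiguous[i]:
            ratios.append(pair[i])
        out[i] = min(ratios) if ratios else 1.0
    return out


def _flank_scores(broadband: np.ndarray, row) -> tuple[float, float, float, float]:
    """(flank_consistency, monotonicity_time, monotonicity_amplitude,
    reversal_ratio) for one cycle."""
    start, neg, end = int(row.start), int(row.neg), int(row.end)
    decay = broadband[start : neg + 1]  # descending flank
    rise = broadband[neg : end + 1]  # ascending flank
    t_decay, t_rise = neg - start, end - neg
    flank_consistency = min(t_decay, t_rise) / max(t_decay, t_rise)

    d_decay = np.diff(decay)
    d_rise = np.diff(rise)
    n_flank = d_decay.size + d_rise.size
    good = (d_decay <= 0).sum() + (d_rise >= 0).sum()
    monotonicity_time = good / n_flank

    net = abs(decay[-1] - decay[0]) + abs(rise[-1] - rise[0])
    total = np.abs(d_decay).sum() + np.abs(d_rise).sum()
    monotonicity_amplitude = net / total if total > 0 else 1.0

    reversals = (np.diff(np.sign(d_decay[d_decay != 0])) != 0).sum() + (
        np.diff(np.sign(d_rise[d_rise != 0])) != 0
    ).sum()
    reversal_ratio = 1.0 - reversals / n_flank
    return flank_consistency, monotonicity_time, monotonicity_amplitude, reversal_ratio


def _shape_consistency(
    broadband: np.ndarray, frame: pd.DataFrame, contiguous: np.ndarray
) -> np.ndarray:
    """1 − mean |normalized cycle waveform − mean neighbor waveform|,
    comparing only against temporally contiguous neighbors."""
    n = len(frame)
    grid = np.linspace(0, 1, 32)
    shapes = np.empty((n, grid.size))
    for i, row in enumerate(frame.itertuples()):
        wave = broadband[int(row.start) : int(row.end) + 1]
        x = np.linspace(0, 1, wave.size)
        wave = np.interp(grid, x, wave)
        lo, hi = wave.min(), wave.max()
        shapes[i] = (wave - lo) / (hi - lo) if hi > lo else 0.0
    out = np.ones(n)
    for i in range(n):
        nb = []
        if i > 0 and contiguous[i - 1]:
            nb.append(i - 1)
        if i < n - 1 and contiguous[i]:
            nb.append(i + 1)
        if not nb:
            continue
        ref = shapes[nb].mean(axis=0)
        out[i] = 1.0 - np.mean(np.abs(shapes[i] - ref))
    return out


def score_cycles(frame: pd.DataFrame) -> pd.DataFrame:
    """Attach the seven regularity scores (all in [0, 1]) to a cycle table."""
    frame = frame.copy()
    if frame.empty:
        for col in SCORE_COLUMNS:
            frame[col] = pd.Series(dtype=float)
        return frame
    broadband = frame.attrs["broadband"].data
    periods = frame["period_s"].to_numpy()
    amps = frame["amplitude"].to_numpy()
    contiguous = frame["start"].to_numpy()[1:] == frame["end"].to_numpy()[:-1]
    frame["period_consistency"] = _adjacent_ratio(periods, contiguous)
    frame["amplitude_consistency"] = _adjacent_ratio(amps, contiguous)
    flank = np.array([_flank_scores(broadband, row) for row in frame.itertuples()])
    frame["flank_consistency"] = flank[:, 0]
    frame["monotonicity_time"] = flank[:, 1]
    frame["monotonicity_amplitude"] = flank[:, 2]
    frame["reversal_ratio"] = flank[:, 3]
    frame["shape_consistency"] = _shape_consistency(broadband, frame, contiguous)
    return frame


def _runs(mask: np.ndarray, min_len: int, contiguous: np.ndarray | None = None):
    """Maximal runs of True of at least min_len, as (start, stop) half-open.

    ``contiguous[i]`` says whether element i+1 directly follows element i in
    time; a run cannot span a temporal break.
    """
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                if contiguous is not None and j > i and not contiguous[j - 1]:
                    break
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j if j > i else i + 1
        else:
            i += 1
    return out


def detect_bursts(
    scored: pd.DataFrame,
    fs: float,
    band: tuple[float, float],
    channel: int = 0,
    criteria: tuple[CriteriaSet, ...] = DEFAULT_CRITERIA,
) -> list[Burst]:
    """Runs of >= MinCycles consecutive qualifying cycles, per criteria set,
    unioned across sets and merged when overlapping."""
    if scored.empty:
        return []
    bursts: list[Burst] = []
    freq = 1.0 / scored["period_s"].to_numpy()
    starts = scored["start"].to_numpy()
    ends = scored["end"].to_numpy()
    contiguous = starts[1:] == ends[:-1]
    for cs in criteria:
        mask = np.ones(len(scored), dtype=bool)
        for key, thr in cs.thresholds.items():
            mask &= scored[key].to_numpy() >= thr
        if cs.in_band_frequency:
            mask &= (freq >= band[0]) & (freq <= band[1])
        for i, j in _runs(mask, cs.min_cycles, contiguous):
            rows = scored.iloc[i:j]
            bursts.append(_make_burst(rows, fs, band, channel, (cs.name,)))
    return merge_bursts(bursts, fs)


def _make_burst(
    rows: pd.DataFrame,
    fs: float,
    band: tuple[float, float],
    channel: int,
    sets: tuple[str, ...],
) -> Burst:
    negs = rows["neg"].to_numpy()
    freq = fs / np.mean(np.diff(negs)) if negs.size > 1 else fs / (
        rows["end"].iloc[0] - rows["start"].iloc[0]
    )
    return Burst(
        channel=channel,
        band=band,
        start=int(rows["start"].iloc[0]),
        end=int(rows["end"].iloc[-1]) + 1,
        n_cycles=len(rows),
        frequency=float(freq),
        mean_amplitude=float(rows["amplitude"].mean()),
        sets=sets,
        neg_peaks=tuple(int(v) for v in negs),
        cycle_amplitudes=tuple(float(v) for v in rows["amplitude"]),
    )


def merge_bursts(bursts: list[Burst], fs: float) -> list[Burst]:
    """Merge same-channel bursts that overlap by at least one sample.

    The merged burst's frequency is recomputed from the pooled negative
    peaks, and its cycles are the union of member cycles.
    """
    merged: list[Burst] = []
    for burst in sorted(bursts, key=lambda b: (b.channel, b.start, b.end)):
        last = merged[-1] if merged else None
        if last is not None and burst.channel == last.channel and burst.start < last.end:
            negs = sorted(set(last.neg_peaks) | set(burst.neg_peaks))
            pairs = dict(zip(last.neg_peaks, last.cycle_amplitudes))
            pairs.update(zip(burst.neg_peaks, burst.cycle_amplitudes))
            amps = [pairs[n] for n in negs]
            freq = (
                fs / float(np.mean(np.diff(negs))) if len(negs) > 1 else last.frequency
            )
            merged[-1] = Burst(
                channel=last.channel,
                band=(
                    min(last.band[0], burst.band[0]),
                    max(last.band[1], burst.band[1]),
                ),
                start=min(last.start, burst.start),
                end=max(last.end, burst.end),
                n_cycles=len(negs),
                frequency=freq,
                mean_amplitude=float(np.mean(amps)),
                sets=tuple(sorted(set(last.sets) | set(burst.sets))),
                neg_peaks=tuple(negs),
                cycle_amplitudes=tuple(amps),
            )
        else:
            merged.append(burst)
    return merged


def _narrowband(signal: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    return mne.filter.filter_data(
        signal.astype(float), fs, band[0], band[1], verbose="error"
    )


def detect_recording_bursts(
    recording: Recording,
    criteria: tuple[CriteriaSet, ...] = DEFAULT_CRITERIA,
    channels: list[int] | None = None,
) -> list[Burst]:
    """Detect bursts in every channel of a preprocessed recording.

    The recording itself (already 0.5–40 Hz band-limited by the filter
    chain) serves as the broadband signal for peak localization.
    """
    channels = list(range(recording.n_channels)) if channels is None else channels
    out: list[Burst] = []
    for band in band_filters():
        nb = _narrowband(recording.signal[channels], recording.fs, band)
        for row, ch in enumerate(channels):
            table = parse_cycles(nb[row], recording.signal[ch], recording.fs, band=band)
            if table.empty:
                continue
            scored = score_cycles(table)
            out.extend(
                detect_bursts(scored, recording.fs, band, channel=ch, criteria=criteria)
            )
    # merge across bands within each channel; only 2-16 Hz bursts are kept
    merged = merge_bursts(out, recording.fs)
    return [b for b in merged if FREQ_MIN <= b.frequency <= FREQ_MAX]


def bursts_to_frame(bursts: list[Burst], fs: float) -> pd.DataFrame:
    """One row per burst: channel, start_s, end_s, n_cycles, frequency_hz,
    amplitude_uv, sets."""
    return pd.DataFrame(
        [
            {
                "channel": b.channel,
                "start_s": b.start / fs,
                "end_s": b.end / fs,
                "n_cycles": b.n_cycles,
                "frequency_hz": b.frequency,
                "amplitude_uv": b.mean_amplitude,
                "sets": ",".join(b.sets),
            }
            for b in bursts
        ]
    )
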