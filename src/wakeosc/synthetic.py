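"""Synthetic wake-EEG with known ground truth.

Every downstream stage (artifact rejection, burst detection, spectral
parameterization, mixed-effects statistics) is tested against signals built
here, where the true burst density and amplitude, artifact locations, and
aperiodic parameters are known by construction.

The aperiodic background is synthesized in the frequency domain: the
amplitude spectrum is set from the target power law ``10^offset / f^exponent``
(µV²/Hz, one-sided), phases are randomized, and the signal is obtained by
inverse FFT.  The Welch spectrum of the output therefore follows the target
law exactly in expectation, which gives analytic ground truth for the
spectral fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Recording, RecordingMetadata
from .montage import Montage, make_geodesic_montage

__all__ = [
    "BurstSpec",
    "ArtifactEvent",
    "GroundTruthManifest",
    "CohortParams",
    "generate_aperiodic",
    "insert_bursts",
    "insert_artifacts",
    "simulate_cohort",
]

#: frequency below which the power-law target is clamped (avoids the
#: divergence at DC; the analysis fit range starts at 2 Hz)
_F_CLAMP = 0.5


@dataclass(frozen=True)
class BurstSpec:
    """One planted oscillation burst."""

    channels: tuple[int, ...]
    onset: float  # s
    frequency: float  # Hz
    n_cycles: int
    peak_to_peak: float  # µV
    asymmetry: float = 0.0  # 0 = pure sinusoid; in [0, 1)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.peak_to_peak <= 0:
            raise ValueError("peak_to_peak must be positive")
        if not 0 <= self.asymmetry < 1:
            raise ValueError("asymmetry must be in [0, 1)")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency

    @property
    def offset_end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str  # transient | decorrelate | flat
    channel: int
    start: float  # s
    duration: float  # s

    _KINDS = ("transient", "decorrelate", "flat")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


# band edges used for ground-truth bookkeeping (match burst_metrics)
_BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 11.0), "low-beta": (12.0, 16.0)}


def _band_of(freq: float) -> str:
    for name, (lo, hi) in _BANDS.items():
        if lo <= freq <= hi:
            return name
    if freq < 4:
        return "excluded"
    return "gap"


@dataclass
class GroundTruthManifest:
    """What was planted, and the measures it implies.

    Densities are computed from the burst specifications (100 × summed burst
    duration / recording duration), never from the signal itself.
    """

    duration: float
    n_channels: int
    burst_specs: list[BurstSpec] = field(default_factory=list)
    artifact_events: list[ArtifactEvent] = field(default_factory=list)
    aperiodic_offset: float | None = None
    aperiodic_exponent: float | None = None

    def channel_bursts(self, channel: int) -> list[BurstSpec]:
        return [b for b in self.burst_specs if channel in b.channels]

    def density(self, channel: int | None = None, band: str | None = None) -> float:
        """True burst density in % of recording time.

        ``channel=None`` pools channel-level durations over all channels (so
        the value can exceed 100%); ``band=None`` pools all bands but counts
        each channel's overlapping time once (interval union per channel).
        """
        channels = range(self.n_channels) if channel is None else [channel]
        total = 0.0
        for ch in channels:
            specs = self.channel_bursts(ch)
            if band is not None:
                specs = [b for b in specs if _band_of(b.frequency) == band]
                total += sum(b.duration for b in specs)
            else:
                total += _union_length(
                    [(b.onset, b.offset_end) for b in specs]
                )
        return 100.0 * total / self.duration

    def amplitude(self, channel: int | None = None) -> float:
        """True cycle-weighted mean peak-to-peak amplitude in µV."""
        channels = range(self.n_channels) if channel is None else [channel]
        cycles, weighted = 0, 0.0
        for ch in channels:
            for b in self.channel_bursts(ch):
                cycles += b.n_cycles
                weighted += b.n_cycles * b.peak_to_peak
        if cycles == 0:
            raise ValueError("no bursts planted")
        return weighted / cycles

    def to_json_dict(self) -> dict:
        return {
            "duration": self.duration,
            "n_channels": self.n_channels,
            "aperiodic_offset": self.aperiodic_offset,
            "aperiodic_exponent": self.aperiodic_exponent,
            "burst_specs": [
                {
                    "channels": list(b.channels),
                    "onset": b.onset,
                    "frequency": b.frequency,
                    "n_cycles": b.n_cycles,
                    "peak_to_peak": b.peak_to_peak,
                    "asymmetry": b.asymmetry,
                }
                for b in self.burst_specs
            ],
            "artifact_events": [
                {
                    "kind": a.kind,
                    "channel": a.channel,
                    "start": a.start,
                    "duration": a.duration,
                }
                for a in self.artifact_events
            ],
        }


def _union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total, cur_lo, cur_hi = 0.0, *intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def generate_aperiodic(
    n_channels: int,
    duration_s: float,
    fs: float,
    exponent: float,
    offset: float,
    seed: int,
    montage: Montage | None = None,
    metadata: RecordingMetadata | None = None,
    spatial_smoothing_m: float = 0.06,
) -> Recording:
    """Multichannel 1/f^x background noise with a known Welch spectrum.

    Parameters
    ----------
    exponent
        The x in the 10^offset / f^x one-sided PSD (µV²/Hz); positive means
        power falls with frequency.
    offset
        log10 PSD at 1 Hz.
    spatial_smoothing_m
        Scale of the Gaussian mixing kernel across electrode positions.
        Real EEG is spatially correlated; mixing unit-norm combinations of
        independent sources reproduces that while leaving every channel's
        PSD exactly on the target law.  Set to 0 for independent channels.
    """
    if duration_s < 8:
        raise ValueError("duration_s must be >= 8 s")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.maximum(freqs, _F_CLAMP)
    psd = 10.0**offset / f_eff**exponent  # µV²/Hz, one-sided
    # one-sided periodogram S = 2|X|^2/(fs*N)  =>  |X| = sqrt(S*fs*N/2)
    mag = np.sqrt(psd * fs * n / 2.0)
    mag[0] = 0.0
    if n % 2 == 0:
        mag[-1] /= np.sqrt(2.0)  # Nyquist bin is not doubled
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, mag.size))
    phases[:, 0] = 0.0
    if n % 2 == 0:
        phases[:, -1] = 0.0
    spectrum = mag * np.exp(1j * phases)
    signal = np.fft.irfft(spectrum, n=n, axis=1)
    if montage is None:
        montage = _default_montage(n_channels)
    if spatial_smoothing_m > 0 and n_channels > 1:
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :],
            axis=-1,
        )
        w = np.exp(-(d**2) / (2 * spatial_smoothing_m**2))
        w /= np.linalg.norm(w, axis=1, keepdims=True)  # unit rows keep PSD
        signal = w @ signal
    return Recording(
        signal=signal,
        fs=fs,
        montage=montage,
        metadata=metadata or RecordingMetadata(),
    )


def _default_montage(n_channels: int) -> Montage:
    full = make_geodesic_montage(include_reference=False)
    if n_channels == full.n_channels:
        return full
    if n_channels < full.n_channels:
        return full.subset(full.labels[:n_channels])
    raise ValueError(f"no default montage with {n_channels} channels")


def _burst_waveform(spec: BurstSpec, fs: float) -> np.ndarray:
    """Sampled burst waveform with raised-cosine on/off ramps.

    The ramps span the first and last quarter-cycle — inside the one-cycle
    bound, but short enough that every peak-to-peak cycle of the burst keeps
    the planted amplitude, so the manifest amplitude is exact.
    """
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    theta = 2 * np.pi * spec.frequency * t
    # asymmetry warps the phase, sharpening one flank relative to the other
    wave = np.sin(theta - spec.asymmetry * np.sin(theta))
    span = wave.max() - wave.min()
    wave *= spec.peak_to_peak / span
    ramp_samples = max(int(fs / (4 * spec.frequency)), 1)
    taper = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_samples) / ramp_samples))
    m = min(ramp_samples, n)
    taper[:m] = np.minimum(taper[:m], ramp[:m])
    taper[-m:] = np.minimum(taper[-m:], ramp[:m][::-1])
    return wave * taper


def insert_bursts(
    recording: Recording, burst_specs: Sequence[BurstSpec]
) -> tuple[Recording, GroundTruthManifest]:
    """Superpose oscillation bursts and record ground truth.

    Raises if two specs place bursts of the same frequency band on the same
    channel at overlapping times, because the implied density would be
    ambiguous.
    """
    out = recording.copy()
    manifest = GroundTruthManifest(
        duration=recording.duration, n_channels=recording.n_channels
    )
    for spec in burst_specs:
        if spec.offset_end > recording.duration + 1e-9:
            raise ValueError(f"burst spec {spec} exceeds recording duration")
        if not (2.0 <= spec.frequency <= 16.0):
            raise ValueError("burst frequency outside the detectable 2-16 Hz")
        if max(spec.channels) >= recording.n_channels:
            raise ValueError("burst channel outside recording")
    for i, a in enumerate(burst_specs):
        for b in burst_specs[:i]:
            shared = set(a.channels) & set(b.channels)
            overlap = min(a.offset_end, b.offset_end) - max(a.onset, b.onset)
            if shared and overlap > 0 and _band_of(a.frequency) == _band_of(b.frequency):
                raise ValueError(
                    "overlapping same-band bursts on one channel make the "
                    "ground-truth density ambiguous"
                )
    for spec in burst_specs:
        wave = _burst_waveform(spec, recording.fs)
        i0 = int(round(spec.onset * recording.fs))
        for ch in spec.channels:
            out.signal[ch, i0 : i0 + wave.size] += wave
        manifest.burst_specs.append(spec)
    return out, manifest


def insert_artifacts(
    recording: Recording,
    artifact_events: Sequence[ArtifactEvent],
    seed: int = 0,
) -> tuple[Recording, GroundTruthManifest]:
    """Plant statistical stand-ins for recording artifacts.

    ``transient`` adds a >500 µV spike, ``decorrelate`` replaces a channel
    segment with independent noise, ``flat`` zeroes the channel segment.
    """
    rng = np.random.default_rng(seed)
    out = recording.copy()
    manifest = GroundTruthManifest(
        duration=recording.duration, n_channels=recording.n_channels
    )
    for ev in artifact_events:
        if ev.start + ev.duration > recording.duration + 1e-9:
            raise ValueError(f"artifact event {ev} exceeds recording duration")
        i0 = int(round(ev.start * recording.fs))
        i1 = int(round((ev.start + ev.duration) * recording.fs))
        seg = slice(i0, i1)
        n = i1 - i0
        if ev.kind == "transient":
            # 3 Hz carrier keeps the spike inside the 1-40 Hz detection band
            t = np.arange(n) / recording.fs
            pulse = 700.0 * np.hanning(n) * np.sin(2 * np.pi * 3.0 * t + np.pi / 2)
            out.signal[ev.channel, seg] += pulse
        elif ev.kind == "decorrelate":
            scale = max(np.std(recording.signal), 1.0)
            out.signal[ev.channel, seg] = rng.normal(0, scale, size=n)
        elif ev.kind == "flat":
            out.signal[ev.channel, seg] = 0.0
        manifest.artifact_events.append(ev)
    return out, manifest


@dataclass
class CohortParams:
    """Generative twin of the developmental mixed-effects model.

    Outcome = intercept + β_age·Age + β_time·Time + β_ageXtime·Age·Time
    + β_task·(Task≠oddball) + β_group·ADHD + β_sex·male
    + participant intercept + session intercept + residual,
    with Time coded evening=0 / morning=1.  Effect sizes are in the units of
    the simulated measure (defaults emulate oscillation amplitude in µV).
    """

    n_participants: int = 100
    age_range: tuple[float, float] = (3.5, 24.7)
    sessions_per_participant: int = 2
    intercept: float = 40.0
    beta_age: float = -0.8
    beta_time: float = -4.0
    beta_age_x_time: float = 0.14
    beta_task: float = 1.0
    beta_group: float = -0.5
    beta_sex: float = -1.5
    sd_participant: float = 4.0
    sd_session: float = 1.0
    sd_residual: float = 2.0
    prop_adhd: float = 0.36
    prop_male: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_participant, self.sd_session, self.sd_residual) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")


def simulate_cohort_recordings(
    n_participants: int = 6,
    seed: int = 0,
    n_channels: int = 16,
    duration_s: float = 66.0,
    fs: float = 500.0,
    base_amplitude: float = 45.0,
    beta_age: float = -1.0,
    beta_time: float = -8.0,
) -> list[Recording]:
    """Small raw-EEG cohort for end-to-end smoke runs.

    Each participant contributes one evening and one morning recording on a
    spatially contiguous channel subset; planted burst amplitudes follow a
    linear age and time-of-day model so the downstream mixed-effects fit
    should recover the effect signs.  Channel counts and durations are kept
    small — this exercises plumbing, not statistical power.
    """
    rng = np.random.default_rng(seed)
    full = make_geodesic_montage(include_reference=False)
    # contiguous subset: channels nearest the vertex
    center = full.positions.mean(axis=0)
    order = np.argsort(np.linalg.norm(full.positions - center, axis=1))
    labels = [full.labels[i] for i in sorted(order[:n_channels])]
    montage = full.subset(labels)
    burst_channels = tuple(range(0, n_channels, 2))  # subset survives avg ref
    recordings = []
    for i in range(n_participants):
        age = 5.0 + 20.0 * i / max(n_participants - 1, 1)
        for t_code, time in enumerate(("evening", "morning")):
            amp = base_amplitude + beta_age * age + beta_time * t_code
            specs, t0 = [], 2.0
            while t0 < duration_s - 4.0:
                f = float(rng.uniform(8, 12))
                nc = int(rng.integers(12, 20))
                specs.append(BurstSpec(burst_channels, t0, f, nc, amp))
                t0 += nc / f + float(rng.uniform(1.5, 2.5))
            base = generate_aperiodic(
                n_channels, duration_s, fs, exponent=1.3, offset=0.2,
                seed=int(rng.integers(2**31)), montage=montage,
                metadata=RecordingMetadata(
                    participant=f"P{i:03d}", session="S1", time=time, age=age
                ),
            )
            rec, _ = insert_bursts(base, specs)
            recordings.append(rec)
    return recordings


def simulate_cohort(params: CohortParams, measure: str = "Amplitude") -> pd.DataFrame:
    """Simulate a cohort measure table (one row per recording).

    Each participant contributes every Time level in every session; tasks
    alternate between oddball and a non-reference task so the Task effect is
    identifiable.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(params.n_participants):
        pid = f"P{i:03d}"
        age = rng.uniform(*params.age_range)
        adhd = rng.random() < params.prop_adhd
        male = rng.random() < params.prop_male
        b_part = rng.normal(0, params.sd_participant)
        for s in range(params.sessions_per_participant):
            b_sess = rng.normal(0, params.sd_session)
            for time_code, time in enumerate(("evening", "morning")):
                task = "oddball" if (i + s) % 2 == 0 else "fixation"
                y = (
                    params.intercept
                    + params.beta_age * age
                    + params.beta_time * time_code
                    + params.beta_age_x_time * age * time_code
                    + params.beta_task * (task != "oddball")
                    + params.beta_group * adhd
                    + params.beta_sex * male
                    + b_part
                    + b_sess
                    + rng.normal(0, params.sd_residual)
                )
                rows.append(
                    {
                        "Participant": pid,
                        "Session": f"S{s + 1}",
                        "Task": task,
                        "Time": time,
                        "Age": age,
                        "Group": "ADHD" if adhd else "control",
                        "Sex": "male" if male else "female",
                        measure: y,
                    }
                )
    return pd.DataFrame(rows)
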