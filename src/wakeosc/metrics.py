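"""Scalp-level burst clustering and the two oscillation measures.

Burst *density* is the percentage of recording time occupied by bursts
(summed burst durations over recording duration; pooled over channels it can
exceed 100%).  Burst *amplitude* is the mean negative-to-positive peak
voltage difference over all cycles of all bursts (cycle-weighted).  Bursts
co-occurring across channels — temporal overlap of at least 50% of the
shorter burst and frequencies within 1 Hz — form clusters; cluster-level
density counts each cluster's global span once, which removes the effect of
burst spread across the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bursts import Burst

__all__ = [
    "BurstCluster",
    "BANDS",
    "cluster_bursts",
    "compute_density",
    "compute_amplitude",
    "band_assign",
    "UndefinedMeasure",
]

#: analysis bands with 1 Hz gaps; edges inclusive
BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 11.0), "low-beta": (12.0, 16.0)}

MIN_ANALYSIS_FREQ = 4.0


class UndefinedMeasure(ValueError):
    """Raised when a measure has no defined value (e.g., no bursts)."""


def channel_band_matrix(bursts, n_channels: int, duration_s: float, fs: float):
    """Per-channel × band density and amplitude tables (channel-level
    bursts, as used for topographies)."""
    import pandas as pd

    rows = []
    for ch in range(n_channels):
        mine = [b for b in bursts if b.channel == ch]
        for band_name, band in BANDS.items():
            in_band = [b for b in mine if band[0] <= b.frequency <= band[1]]
            amps = [a for b in in_band for a in b.cycle_amplitudes]
            rows.append(
                {
                    "Channel": ch,
                    "Band": band_name,
                    "Density": compute_density(in_band, duration_s, fs, band=band),
                    "Amplitude": float(np.mean(amps)) if amps else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BurstCluster:
    members: list[Burst]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(b.start for b in self.members),
            max(b.end for b in self.members),
        )

    @property
    def n_channels(self) -> int:
        return len({b.channel for b in self.members})

    @property
    def frequency(self) -> float:
        """Duration-weighted mean of member frequencies."""
        w = np.array([b.duration_samples for b in self.members], dtype=float)
        f = np.array([b.frequency for b in self.members])
        return float(np.sum(w * f) / np.sum(w))

    @property
    def duration_samples(self) -> int:
        lo, hi = self.span
        return hi - lo


def _linked(a: Burst, b: Burst) -> bool:
    overlap = min(a.end, b.end) - max(a.start, b.start)
    shorter = min(a.duration_samples, b.duration_samples)
    return overlap >= 0.5 * shorter and abs(a.frequency - b.frequency) <= 1.0


def cluster_bursts(bursts: list[Burst]) -> list[BurstCluster]:
    """Connected components of the pairwise co-occurrence link graph."""
    g = nx.Graph()
    g.add_nodes_from(range(len(bursts)))
    for i in range(len(bursts)):
        for j in range(i + 1, len(bursts)):
            if _linked(bursts[i], bursts[j]):
                g.add_edge(i, j)
    return [
        BurstCluster(members=[bursts[i] for i in sorted(comp)])
        for comp in sorted(nx.connected_components(g), key=min)
    ]


def compute_density(
    items: list[Burst] | list[BurstCluster],
    duration_s: float,
    fs: float,
    band: tuple[float, float] | None = None,
    pooled: bool = False,
) -> float:
    """Percentage of recording time occupied by bursts.

    With ``band`` given, only items whose frequency lies in the band count;
    ``pooled=True`` admits any analysis frequency (4–16 Hz).  For clusters,
    each cluster contributes its global span once.
    """
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    total = 0
    for item in items:
        freq = item.frequency
        if pooled:
            if freq < MIN_ANALYSIS_FREQ:
                continue
        elif band is not None and not (band[0] <= freq <= band[1]):
            continue
        total += item.duration_samples
    return 100.0 * (total / fs) / duration_s


def compute_amplitude(bursts: list[Burst]) -> float:
    """Cycle-weighted mean peak-to-peak amplitude (µV) over all bursts."""
    amps = [a for b in bursts for a in b.cycle_amplitudes]
    if not amps:
        raise UndefinedMeasure("no bursts: amplitude undefined")
    return float(np.mean(amps))


def band_assign(frequency: float) -> str:
    """theta (4–7), alpha (8–11), low-beta (12–16); open 1 Hz gaps between;
    below 4 Hz excluded from analysis."""
    if frequency < MIN_ANALYSIS_FREQ:
        return "excluded"
    for name, (lo, hi) in BANDS.items():
        if lo <= frequency <= hi:
            return name
    if frequency > 16.0:
        raise ValueError("burst frequency above the 16 Hz detection bound")
    return "gap"
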