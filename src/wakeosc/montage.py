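"""Electrode montage for the 128-channel geodesic sensor net.

The analysis montage drops the external electrodes (E49, E56, E107, E113)
and face electrodes (E126, E127) from the 129 positions (E1–E128 plus the
vertex reference Cz), leaving 123 analysis channels.  A further "edge" set
of 25 inferior channels is flagged so that channel averages of spectral
measures run over the remaining 98 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import mne

#: electrodes outside the skull outline (mastoid/neck leads)
EXTERNAL_ELECTRODES = ("E49", "E56", "E107", "E113")
#: cheek electrodes
FACE_ELECTRODES = ("E126", "E127")

N_ANALYSIS_CHANNELS = 123
N_NONEDGE_CHANNELS = 98


@dataclass
class Montage:
    """Channel labels, 3-D positions (meters) and exclusion flags."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3)
    excluded: frozenset[str] = field(default_factory=frozenset)  # face/external
    edge: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def analysis_labels(self) -> list[str]:
        return [l for l in self.labels if l not in self.excluded]

    @property
    def nonedge_labels(self) -> list[str]:
        return [l for l in self.analysis_labels if l not in self.edge]

    def neighbors(self, k: int = 6) -> dict[int, np.ndarray]:
        """k-nearest channels by 3-D electrode distance, per channel index."""
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return {i: np.argsort(d[i])[:k] for i in range(self.n_channels)}

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(
            labels=list(labels),
            positions=self.positions[idx],
            excluded=frozenset(l for l in self.excluded if l in labels),
            edge=frozenset(l for l in self.edge if l in labels),
        )


def make_geodesic_montage(include_reference: bool = False) -> Montage:
    """Build the 128-channel (optionally +Cz) montage with exclusion flags.

    Positions come from the standard GSN-HydroCel-129 layout.  Edge channels
    are the 25 most inferior (lowest z) of the 123 analysis channels, so the
    non-edge count used for spectral channel averages is exactly 98.
    """
    std = mne.channels.make_standard_montage("GSN-HydroCel-129")
    pos = std.get_positions()["ch_pos"]
    labels = [f"E{i}" for i in range(1, 129)]
    if include_reference:
        labels.append("Cz")
    positions = np.array([pos[l] for l in labels])
    excluded = frozenset(EXTERNAL_ELECTRODES + FACE_ELECTRODES)

    # edge = lowest-z analysis channels; Cz can never be an edge channel
    analysis = [l for l in labels if l not in excluded]
    if "Cz" not in analysis:
        analysis = analysis + ["Cz"]
    z = {l: pos[l][2] for l in analysis}
    n_edge = len(analysis) - N_NONEDGE_CHANNELS
    edge = frozenset(sorted(analysis, key=lambda l: z[l])[:n_edge])
    return Montage(
        labels=labels,
        positions=positions,
        excluded=excluded,
        edge=edge,
    )


def full_analysis_montage() -> Montage:
    """The 123-channel analysis montage (E1–E128 + Cz minus exclusions)."""
    m = make_geodesic_montage(include_reference=True)
    return m.subset([l for l in m.labels if l not in m.excluded])
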