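"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .montage import Montage

TASKS = ("oddball", "go/no-go", "alertness", "fixation")
TIMES = ("evening", "morning")
GROUPS = ("control", "ADHD")
SEXES = ("female", "male")


@dataclass
class RecordingMetadata:
    participant: str = "P000"
    session: str = "S1"
    task: str = "oddball"
    time: str = "evening"
    age: float = 12.0
    group: str = "control"
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.time not in TIMES:
            raise ValueError(f"unknown time {self.time!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    def as_dict(self) -> dict[str, Any]:
        return {
            "Participant": self.participant,
            "Session": self.session,
            "Task": self.task,
            "Time": self.time,
            "Age": self.age,
            "Group": self.group,
            "Sex": self.sex,
        }


@dataclass
class Recording:
    """Multichannel EEG: signal in µV, channels × samples."""

    signal: np.ndarray
    fs: float
    montage: Montage
    metadata: RecordingMetadata = field(default_factory=RecordingMetadata)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    def copy(self, **changes: Any) -> "Recording":
        out = replace(self, **changes)
        if "signal" not in changes:
            out.signal = self.signal.copy()
        return out
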