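"""Core data containers shared across the pipeline.

The montage is the 22-channel subset of the international 10-20 system used
throughout: frontal-polar through occipital rows, recorded against a Cz
reference (Cz itself is therefore not an analysis channel).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: Analysis montage, ordered. All connectivity matrices and graphs index
#: channels in this order unless an explicit channel_names list says otherwise.
MONTAGE_22: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "Oz",
    "O1", "O2",
)

DEFAULT_SFREQ = 250.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class EventSchedule:
    """Stimulus onsets (sample indices) with target/standard labels."""

    onsets: np.ndarray
    labels: np.ndarray  # '<U8' array of {"target", "standard"}
    isi_bounds: tuple[float, float]  # milliseconds

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype="<U8")
        if self.onsets.shape != self.labels.shape:
            raise ValidationError("onsets and labels must have equal length")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")

    @property
    def target_onsets(self) -> np.ndarray:
        return self.onsets[self.labels == "target"]

    @property
    def n_targets(self) -> int:
        return int(np.sum(self.labels == "target"))

    def to_dict(self) -> dict:
        return {
            "onsets": self.onsets.tolist(),
            "labels": self.labels.tolist(),
            "isi_bounds": list(self.isi_bounds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSchedule":
        return cls(
            onsets=np.asarray(d["onsets"]),
            labels=np.asarray(d["labels"]),
            isi_bounds=tuple(d["isi_bounds"]),
        )


@dataclass
class EpochSet:
    """Trials x channels x samples tensor of epoched EEG (microvolts)."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    sampling_rate: float
    trial_labels: np.ndarray = None
    subject_id: str = ""
    group_label: str = ""
    window: tuple[float, float] = (-0.2, 0.8)
    band: str = "wide"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.data.shape[1]} data channels but "
                f"{len(self.channel_names)} channel names"
            )
        n_expected = int(round((self.window[1] - self.window[0]) * self.sampling_rate))
        if self.data.shape[2] != n_expected:
            raise ValidationError(
                f"window {self.window} at {self.sampling_rate} Hz implies "
                f"{n_expected} samples, got {self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("epoch data contains non-finite values")
        if self.trial_labels is None:
            self.trial_labels = np.full(self.data.shape[0], "target", dtype="<U8")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset (half-open window)."""
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, **kw) -> "EpochSet":
        d = dataclasses.asdict(self)
        d.update(kw)
        d["channel_names"] = tuple(d["channel_names"])
        return EpochSet(**d)
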