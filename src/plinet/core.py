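"""Shared domain types: recordings, frequency bands, segment sets, montage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical analysis bands (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Experimental conditions, in within-subject order.
CONDITIONS: tuple[str, ...] = ("rest", "0-back", "2-back")

#: 59-channel extended 10-20 montage (61 electrodes minus the two mastoid
#: reference sites TP9/TP10).
DEFAULT_MONTAGE_59: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

assert len(DEFAULT_MONTAGE_59) == 59


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval in Hz with 0 < low < high."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.high >= fs / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds Nyquist ({fs / 2} Hz)"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def contains(self, freq: float) -> bool:
        return self.low <= freq <= self.high


def band_from_name(name: str) -> BandDefinition:
    """Look up one of the canonical bands by name."""
    try:
        low, high = DEFAULT_BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; known bands: {sorted(DEFAULT_BANDS)}"
        ) from None
    return BandDefinition(name, low, high)


@dataclass
class EEGRecording:
    """A channels x samples matrix (microvolts) with labels and sampling rate."""

    data: np.ndarray
    fs: float
    labels: list[str]
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = [str(lbl) for lbl in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data=data, fs=self.fs, labels=list(self.labels),
                           condition=self.condition)

    def pick(self, labels: list[str]) -> "EEGRecording":
        """Subset channels by label, preserving the requested order."""
        missing = [lbl for lbl in labels if lbl not in self.labels]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.labels.index(lbl) for lbl in labels]
        return EEGRecording(data=self.data[idx], fs=self.fs, labels=list(labels),
                           condition=self.condition)


@dataclass
class SegmentSet:
    """Band-limited 2.5-s analysis segments plus provenance.

    Every segment is a channels x samples array with identical shape; the
    provenance list records the source epoch index of each segment.
    """

    segments: list[np.ndarray]
    fs: float
    labels: list[str]
    band: str | None = None
    condition: str | None = None
    provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        if self.segments:
            shape = self.segments[0].shape
            for k, seg in enumerate(self.segments):
                if seg.ndim != 2 or seg.shape != shape:
                    raise ValueError(f"segment {k} has shape {seg.shape}, expected {shape}")
            if shape[0] != len(self.labels):
                raise ValueError(
                    f"{len(self.labels)} labels for segments with {shape[0]} channels"
                )
        if not self.provenance:
            self.provenance = list(range(len(self.segments)))
        if len(self.provenance) != len(self.segments):
            raise ValueError("provenance length must match segment count")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def segment_duration(self) -> float:
        if not self.segments:
            return 0.0
        return self.segments[0].shape[1] / self.fs
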