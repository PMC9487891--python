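"""Core in-memory containers for the pipeline.

A :class:`Recording` is a continuous multichannel signal; an
:class:`EpochSet` is a stack of fixed-length epochs cut from it.  Both are
thin, validated dataclasses around a numpy array — the field-standard
containers (``mne.io.Raw`` / ``mne.Epochs``) are deliberately not used as
the exchange type so that every stage of the pipeline stays a pure
array-in / array-out function; :mod:`eegtree.io` converts from EDF via mne
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "BandDefinition",
    "DEFAULT_BANDS",
    "BROADBAND",
    "DEFAULT_EYE_CHANNELS",
    "montage_labels",
]

#: Conventional label set of the 128-channel geodesic montage: E1 ... E128.
def montage_labels(n_channels: int = 128) -> list[str]:
    """Return the default channel labels ``["E1", ..., "E<n>"]``."""
    return [f"E{i}" for i in range(1, n_channels + 1)]


#: Default periocular (eye-movement) channels excluded before connectivity
#: analysis on the 128-channel layout.  The montage convention names eight
#: channels at the orbital rim; the list is configurable because layouts vary.
DEFAULT_EYE_CHANNELS: tuple[str, ...] = (
    "E8", "E14", "E21", "E25", "E125", "E126", "E127", "E128",
)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < low < high, "
                f"got [{self.low}, {self.high}]"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


#: The four classical resting-state bands analyzed by the pipeline.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Band label used for unsplit (0.5-30 Hz) data.
BROADBAND = "broadband"


@dataclass
class Recording:
    """Continuous multichannel signal with metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in signal units (µV-like).
    labels
        Unique channel labels, conventionally ``E1 ... E128``.
    rate
        Sampling rate in Hz, > 0.
    subject_id, condition
        Subject tag and recording condition (``"EC"`` eyes closed /
        ``"EO"`` eyes open).
    """

    data: np.ndarray
    labels: list[str]
    rate: float
    subject_id: str = "S0"
    condition: str = "EC"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Fixed-length epoch stack: ``(n_epochs, n_channels, n_samples)``.

    ``band`` records which frequency band the data were filtered into
    (:data:`BROADBAND` before band decomposition); ``rereferenced`` flags
    whether the common-average reference has been applied.
    """

    data: np.ndarray
    labels: list[str]
    rate: float
    epoch_length: float
    band: str = BROADBAND
    rereferenced: bool = False
    subject_id: str = "S0"
    condition: str = "EC"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (epochs x channels x samples)")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count does not match channel axis")
        n_expected = int(round(self.epoch_length * self.rate))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch length {self.epoch_length} s at {self.rate} Hz implies "
                f"{n_expected} samples per epoch, got {self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)
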