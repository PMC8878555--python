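"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TERM = "term"
PRETERM = "preterm"
CHANNEL_NAMES = ("CH1", "CH2", "CH3")

#: Gestational age (completed weeks) below which a delivery is preterm.
PRETERM_WEEK_THRESHOLD = 37.0


class MetadataError(ValueError):
    """Gestational metadata missing or inconsistent."""


def label_from_delivery_week(week: float) -> str:
    """Map gestational age at delivery to a class label (preterm iff < 37 weeks)."""
    if not np.isfinite(week):
        raise MetadataError(f"delivery week is not finite: {week!r}")
    return PRETERM if week < PRETERM_WEEK_THRESHOLD else TERM


@dataclass
class EHGRecord:
    """One pregnancy recording: three derived bipolar channels plus metadata.

    Channels are ordered CH1, CH2, CH3 and expressed in millivolts.
    """

    record_id: str
    channels: np.ndarray  # shape (3, n_samples)
    fs: float
    gestation_week_recording: float | None
    gestation_week_delivery: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise ValueError(
                f"channels must have shape (3, n_samples), got {self.channels.shape}"
            )
        if not np.all(np.isfinite(self.channels)):
            raise ValueError(f"record {self.record_id}: non-finite channel samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.label = label_from_delivery_week(self.gestation_week_delivery)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[CHANNEL_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")


@dataclass(frozen=True)
class SignalWindow:
    """A contiguous slice of one channel, in millivolts.

    ``start_index`` is the 0-based offset of the first sample in the source
    channel; the window covers the half-open interval
    ``[start_index, start_index + len(samples))``.
    """

    samples: np.ndarray
    fs: float
    start_index: int

    def __len__(self) -> int:
        return len(self.samples)
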