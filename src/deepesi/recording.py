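"""Multichannel electrophysiological recording container.

A :class:`Recording` holds a channels x samples matrix in microvolts together
with the sampling rate, channel labels, optional 3-D electrode positions
(head-centred RAS, mm) and the referencing state. Scalp EEG enters
vertex-referenced and is re-referenced to the common average downstream;
intracranial lead contacts enter mastoid-referenced and are recalculated to
bipolar derivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Allowed referencing states.
REFERENCES = ("vertex", "mastoid", "average", "bipolar")


@dataclass
class Recording:
    data: np.ndarray                       # (n_channels, n_samples), µV
    fs: float                              # Hz
    labels: list[str]
    positions: np.ndarray | None = None    # (n_channels, 3), mm
    reference: str = "vertex"
    band: tuple[float, float] | None = None  # set after narrow-band filtering
    seams: tuple[int, ...] = ()            # sample offsets of concatenation seams
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.reference not in REFERENCES:
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced (data not shared)."""
        new = replace(self, **changes)
        if "data" not in changes:
            new.data = self.data.copy()
        if "meta" not in changes:
            new.meta = dict(self.meta)
        return new
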