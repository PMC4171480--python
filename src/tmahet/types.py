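"""Core data containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels on a common pixel grid.

    Channels are float arrays of identical shape with finite, non-negative
    intensities.  ``pixel_size`` is the edge length of one pixel in
    micrometres (``None`` means unknown; areas then stay in px^2).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    image_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def copy(self) -> "MultiChannelImage":
        return MultiChannelImage(
            channels={k: v.copy() for k, v in self.channels.items()},
            pixel_size=self.pixel_size,
            image_id=self.image_id,
            patient_id=self.patient_id,
        )


@dataclass
class CellSegmentation:
    """Paired nuclear and cytoplasmic label maps with matched labels.

    The same positive integer labels one cell's nucleus in
    ``nuclear_labels`` and its cytoplasm in ``cytoplasm_labels``
    (label 0 is background).  Cells whose cytoplasm could not be
    recovered keep their nuclear label and are listed in
    ``empty_cytoplasm``.
    """

    nuclear_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    empty_cytoplasm: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.nuclear_labels.shape != self.cytoplasm_labels.shape:
            raise ValueError("nuclear and cytoplasm label maps differ in shape")
        nuc = set(np.unique(self.nuclear_labels)) - {0}
        cyt = set(np.unique(self.cytoplasm_labels)) - {0}
        if not cyt <= nuc:
            raise ValueError(f"cytoplasm labels {sorted(cyt - nuc)} have no nucleus")
        missing = nuc - cyt - set(self.empty_cytoplasm)
        if missing:
            raise ValueError(
                f"labels {sorted(missing)} lack cytoplasm but are not flagged"
            )
        overlap = (self.nuclear_labels > 0) & (
            self.nuclear_labels == self.cytoplasm_labels
        )
        if overlap.any():
            raise ValueError("nuclear and cytoplasmic regions of one cell overlap")

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of cell labels present in the segmentation."""
        lab = np.unique(self.nuclear_labels)
        return lab[lab > 0]

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days and event indicator."""

    patient_id: str
    time: float
    event: int
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"non-positive follow-up time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 (censored) or 1 (deceased)")
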