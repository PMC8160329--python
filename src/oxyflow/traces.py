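"""Shared time-series containers used across the imaging and probe pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceTrace", "DiameterTrace", "BlockSeries"]


@dataclass
class FluorescenceTrace:
    """Sampled fluorescence of one ROI (or a net/ROI-averaged signal).

    ``normalization`` tracks which representation ``values`` is in:
    ``"raw"`` (arbitrary units), ``"global"`` (min--max normalised over the
    whole recording, range [0, 1]) or ``"baseline"`` (ΔF/F relative to a
    local baseline window).
    """

    values: np.ndarray
    frame_rate: float  # Hz
    roi_id: str = "roi0"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate


@dataclass
class DiameterTrace:
    """Vessel lumen diameter over time, in μm.

    Missing values (frames where no lumen profile peak was found) are NaN.
    """

    values: np.ndarray
    rate: float  # samples per second
    units: str = "um"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass
class BlockSeries:
    """Per-block estimates from a line scan (velocity, haematocrit or flux).

    ``block_centers`` are the block midpoints in seconds; ``quality`` is a
    boolean flag per block (False marks uninformative / degenerate blocks).
    """

    block_centers: np.ndarray
    values: np.ndarray
    block_len: float
    stride: float
    quality: np.ndarray = field(default=None)
    kind: str = ""

    def __post_init__(self) -> None:
        self.block_centers = np.asarray(self.block_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.quality is None:
            self.quality = np.ones(self.values.shape, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=bool)
        if self.stride > self.block_len + 1e-12:
            raise ValueError("stride must not exceed block length")

    def good_values(self) -> np.ndarray:
        return self.values[self.quality]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.block_centers, "value": self.values, "quality": self.quality}
        )
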