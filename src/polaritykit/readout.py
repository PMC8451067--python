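"""Common per-cell polarity readout container."""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


@dataclass(frozen=True)
class PolarityReadout:
    """One cell's polarity as measured by one method.

    magnitude is on the method's raw scale (PCA/Fourier start at 0, Ratio at
    1); magnitude_norm is the dataset-normalized value in [0, 1], filled in
    by tissue-level normalization. angle_deg is axial in (-90, +90] with 0
    along the image x-axis, or None when the method cannot orient the cell
    (degenerate or perfectly uniform signal).
    """

    cell_id: int
    method: str
    magnitude: float
    angle_deg: Optional[float]
    magnitude_norm: Optional[float] = None

    def with_norm(self, value: float) -> "PolarityReadout":
        return replace(self, magnitude_norm=value)
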