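"""Per-pixel tissue compartment labels.

Label convention (shared by the generator, the segmenters and all outputs):
0 = FSR (fat / interlobular stroma), 1 = PE (peri-epithelium),
2 = ILS (intralobular stroma).  EER (epithelium-enriched region) is the
union of PE and ILS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FSR, PE, ILS = 0, 1, 2
LABEL_NAMES = {FSR: "FSR", PE: "PE", ILS: "ILS"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class CompartmentMask:
    """Label map over pixels with {FSR, PE, ILS}; carries the physical
    pixel size so areas convert to mm^2."""

    labels: np.ndarray  # uint8 (rows, cols)
    pixel_size_um: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.isin(np.unique(lab), [FSR, PE, ILS]).all():
            raise ValueError("labels must be in {0=FSR, 1=PE, 2=ILS}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def area_mm2(self, label: int) -> float:
        """Area of one compartment; EER pixels only for PE/ILS."""
        return self.pixel_count(label) * self.pixel_area_mm2

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um * 1e-3) ** 2

    @property
    def eer_mask(self) -> np.ndarray:
        return self.labels != FSR

    def eer_area_mm2(self) -> float:
        return float(np.count_nonzero(self.eer_mask)) * self.pixel_area_mm2

    def label_at(self, row: int, col: int) -> int:
        return int(self.labels[row, col])

    def areas(self) -> dict[str, float]:
        return {LABEL_NAMES[k]: self.area_mm2(k) for k in (FSR, PE, ILS)}
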