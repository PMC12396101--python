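"""Shared section containers.

Darkness convention used throughout the analysis side of the package:
``darkness = 1 - raw/255`` so that 0 is unstained (white) and 1 is the
darkest staining. Raw section images are 8-bit grayscale with non-brain
pixels set to 0 and brain pixels in 1..255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: label values used for segmented sections
LABEL_BACKGROUND = 0
LABEL_GM = 127
LABEL_WM = 255

STAIN_CO = "co"
STAIN_MYELIN = "myelin"


@dataclass
class StainSection:
    """One 2D grayscale stained section."""

    image: np.ndarray            # uint8, 0 = outside brain
    stain: str                   # "co" | "myelin"
    index: int                   # position in the cutting order
    plane: str = "coronal"
    pixel_size_um: float = 25.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("section image must be 2D")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.image > 0


@dataclass
class SegmentedSection:
    """Background/GM/WM label image plus the two GM boundary masks.

    ``outer_boundary`` are GM pixels adjacent (4-connected) to background
    (the pial side); ``inner_boundary`` are GM pixels adjacent to WM.
    """

    labels: np.ndarray           # uint8 in {0, 127, 255}
    outer_boundary: np.ndarray   # bool
    inner_boundary: np.ndarray   # bool
    index: int = 0
    stain: str = STAIN_CO

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == LABEL_GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == LABEL_WM

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == LABEL_BACKGROUND
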