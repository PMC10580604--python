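"""Tissue classes of colorectal H&E histology and their four-class reduction.

The nine patch-level classes follow the standard colorectal tissue taxonomy:
adipose, background, debris, lymphocytes, mucus, smooth muscle, normal colon
mucosa, cancer-associated stroma and colorectal adenocarcinoma epithelium.
For area features the map is reduced to four super-classes: tumor,
lymphocyte, stroma, and other (everything else, including background and
mucus). Background (BACK) is the only class excluded from deep feature
extraction.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "TissueClass",
    "SuperClass",
    "SUPERCLASS_OF",
    "NON_BACKGROUND_CLASSES",
    "DEFAULT_HISTO_TISSUES",
    "to_superclass",
]


class TissueClass(IntEnum):
    """The nine patch tissue classes, in fixed (alphabetical) enum order.

    The integer values double as the label codes used in tissue-map grids
    and as the deterministic tie-break order for majority voting.
    """

    ADI = 0   # adipose
    BACK = 1  # background
    DEB = 2   # debris
    LYM = 3   # lymphocytes
    MUC = 4   # mucus
    MUS = 5   # smooth muscle
    NORM = 6  # normal colon mucosa
    STR = 7   # cancer-associated stroma
    TUM = 8   # colorectal adenocarcinoma epithelium


class SuperClass(IntEnum):
    """Four-class reduction used by the tissue-area stage."""

    OTHER = 0
    TUMOR = 1
    LYMPHOCYTE = 2
    STROMA = 3


#: TUM -> tumor, LYM -> lymphocyte, STR -> stroma, everything else -> other.
SUPERCLASS_OF: dict[TissueClass, SuperClass] = {
    cls: SuperClass.OTHER for cls in TissueClass
}
SUPERCLASS_OF[TissueClass.TUM] = SuperClass.TUMOR
SUPERCLASS_OF[TissueClass.LYM] = SuperClass.LYMPHOCYTE
SUPERCLASS_OF[TissueClass.STR] = SuperClass.STROMA

#: The eight classes entering deep feature extraction (BACK eliminated).
NON_BACKGROUND_CLASSES: tuple[TissueClass, ...] = tuple(
    c for c in TissueClass if c is not TissueClass.BACK
)

#: Default tissue set for the histopathological feature vector, in the fixed
#: concatenation order tumor, lymphocytes, stroma, mucus.
DEFAULT_HISTO_TISSUES: tuple[TissueClass, ...] = (
    TissueClass.TUM,
    TissueClass.LYM,
    TissueClass.STR,
    TissueClass.MUC,
)

_SUPER_LUT = np.array([SUPERCLASS_OF[c] for c in TissueClass], dtype=np.int8)


def to_superclass(labels: np.ndarray) -> np.ndarray:
    """Map a grid of nine-class labels to the four super-class codes.

    Shape is preserved; cell counts are preserved (every cell maps to
    exactly one super-class).
    """
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= len(TissueClass)):
        raise ValueError("labels outside the valid tissue-class range 0..8")
    return _SUPER_LUT[labels]
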