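"""The five tissue-area features of a four-class tissue map.

All areas are in patch-count units. The tumor and stroma masks are closed
with a 5x5 rectangular structuring element before measurement, so gaps the
classifier split inappropriately count toward area. "Inside tumor" means
within the hole-filled closed tumor region; "around tumor" means within a
Chebyshev band (default width 2 patches) outside that region. The
around/inside ratio is add-one smoothed: (around + 1) / (inside + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import MorphConfig, closing, connected_components, fill_holes
from .tissue import SuperClass, to_superclass

__all__ = [
    "AreaFeatures",
    "BandConfig",
    "max_tumor_area",
    "lymphocyte_partition",
    "around_inside_ratio",
    "total_stroma_area",
    "extract_area_features",
]


@dataclass(frozen=True)
class BandConfig:
    """Chebyshev width (in patches) of the "around tumor" band."""

    around_band_width: int = 2

    def __post_init__(self) -> None:
        if self.around_band_width < 1:
            raise ValueError("around_band_width must be >= 1")


@dataclass(frozen=True)
class AreaFeatures:
    """The five tissue-area features of one slide."""

    max_tumor_area: int
    lymphocyte_inside_tumor: int
    lymphocyte_around_tumor: int
    around_inside_ratio: float
    total_stroma_area: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.max_tumor_area,
                self.lymphocyte_inside_tumor,
                self.lymphocyte_around_tumor,
                self.around_inside_ratio,
                self.total_stroma_area,
            ],
            dtype=float,
        )

    names = (
        "max_tumor_area",
        "lymphocyte_inside_tumor",
        "lymphocyte_around_tumor",
        "around_inside_ratio",
        "total_stroma_area",
    )


def _super_map(tissue_map: np.ndarray, superclass_input: bool) -> np.ndarray:
    m = np.asarray(tissue_map)
    if superclass_input:
        if m.size and (m.min() < 0 or m.max() >= len(SuperClass)):
            raise ValueError("four-class map values must be in 0..3")
        return m
    return to_superclass(m)


def _mask(super_map: np.ndarray, cls: SuperClass) -> np.ndarray:
    return (super_map == cls).astype(np.uint8)


def max_tumor_area(
    tissue_map: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    superclass_input: bool = False,
) -> int:
    """Area of the largest tumor component after 5x5 closing (0 if none).

    The area is measured on the closed mask, so gap cells filled by closing
    count toward the area. Maps are nine-class by default; pass
    superclass_input=True for an already-reduced four-class map.
    """
    sm = _super_map(tissue_map, superclass_input)
    closed = closing(_mask(sm, SuperClass.TUMOR), morph)
    return connected_components(closed, morph).max_area


def tumor_region(
    tissue_map: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    superclass_input: bool = False,
) -> np.ndarray:
    """The hole-filled closed tumor region used for the inside/around split."""
    sm = _super_map(tissue_map, superclass_input)
    return fill_holes(closing(_mask(sm, SuperClass.TUMOR), morph), morph)


def lymphocyte_partition(
    tissue_map: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    band: BandConfig = BandConfig(),
    superclass_input: bool = False,
) -> tuple[int, int]:
    """Counts of lymphocyte patches inside vs. around the tumor region.

    inside: lymphocyte cells within the hole-filled closed tumor region;
    around: lymphocyte cells within Chebyshev distance <= band width of the
    region and not inside. The two sets are disjoint by construction.
    """
    sm = _super_map(tissue_map, superclass_input)
    lym = _mask(sm, SuperClass.LYMPHOCYTE).astype(bool)
    region = tumor_region(tissue_map, morph, superclass_input).astype(bool)
    w = band.around_band_width
    band_struct = np.ones((2 * w + 1, 2 * w + 1), dtype=bool)
    banded = ndimage.binary_dilation(region, structure=band_struct, border_value=0)
    inside = int((lym & region).sum())
    around = int((lym & banded & ~region).sum())
    return inside, around


def around_inside_ratio(inside: int, around: int) -> float:
    """Add-one smoothed ratio (around + 1) / (inside + 1)."""
    if inside < 0 or around < 0:
        raise ValueError("counts must be non-negative")
    return (around + 1) / (inside + 1)


def total_stroma_area(
    tissue_map: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    superclass_input: bool = False,
) -> int:
    """Total stroma area (all components) after 5x5 closing."""
    sm = _super_map(tissue_map, superclass_input)
    return int(closing(_mask(sm, SuperClass.STROMA), morph).sum())


def extract_area_features(
    tissue_map: np.ndarray,
    morph: MorphConfig = MorphConfig(),
    band: BandConfig = BandConfig(),
    superclass_input: bool = False,
) -> AreaFeatures:
    """Compute all five tissue-area features of one map."""
    inside, around = lymphocyte_partition(tissue_map, morph, band, superclass_input)
    return AreaFeatures(
        max_tumor_area=max_tumor_area(tissue_map, morph, superclass_input),
        lymphocyte_inside_tumor=inside,
        lymphocyte_around_tumor=around,
        around_inside_ratio=around_inside_ratio(inside, around),
        total_stroma_area=total_stroma_area(tissue_map, morph, superclass_input),
    )
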