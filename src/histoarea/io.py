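"""Reading and writing of tissue maps, masks, features and survival tables.

Coordinates are 0-based, row-major (row, col). Tissue maps travel as CSV
integer grids or indexed PNGs whose palette index equals the tissue-class
code; masks as 0/1 CSV grids or 1-bit PNGs. Every CSV written by the
pipeline carries a provenance comment line (# key=value) with the run's
config hash and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .tissue import TissueClass

__all__ = [
    "write_tissue_map_csv",
    "read_tissue_map_csv",
    "write_tissue_map_png",
    "read_tissue_map_png",
    "write_mask_csv",
    "read_mask_csv",
    "write_survival_csv",
    "read_survival_csv",
    "write_ground_truth_json",
    "write_frame_csv",
]

# display palette, one RGB triple per tissue-class code
_PALETTE = [
    (235, 225, 235),  # ADI
    (255, 255, 255),  # BACK
    (150, 110, 140),  # DEB
    (80, 40, 200),    # LYM
    (200, 210, 230),  # MUC
    (190, 120, 160),  # MUS
    (170, 220, 170),  # NORM
    (255, 180, 80),   # STR
    (200, 40, 40),    # TUM
]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_tissue_map_csv(
    path: str | Path, labels: np.ndarray, provenance: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("# rows are map rows; values are TissueClass codes 0..8\n")
        np.savetxt(fh, np.asarray(labels, dtype=int), fmt="%d", delimiter=",")


def read_tissue_map_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, delimiter=",", comments="#", ndmin=2)


def write_tissue_map_png(path: str | Path, labels: np.ndarray, color: bool = False) -> None:
    """Write an indexed PNG (palette index = class code); with color=True the
    palette carries the display colors used for visual maps."""
    labels = np.asarray(labels, dtype=np.uint8)
    img = Image.fromarray(labels, mode="P")
    palette = []
    for code in range(len(TissueClass)):
        palette.extend(_PALETTE[code] if color else (code, code, code))
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def read_tissue_map_png(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError("expected an indexed (palette) PNG tissue map")
    return np.asarray(img, dtype=np.int8)


def write_mask_csv(path: str | Path, mask: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d", delimiter=",")


def read_mask_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.uint8, delimiter=",", comments="#", ndmin=2)


def write_survival_csv(
    path: str | Path, survival: pd.DataFrame, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        survival.to_csv(fh, index=False)


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    required = {"patient_id", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns {sorted(missing)}")
    return frame


def write_ground_truth_json(path: str | Path, truths: list) -> None:
    payload = [
        {
            "tumor_areas": t.tumor_areas,
            "lym_inside": t.lym_inside,
            "lym_around": t.lym_around,
            "stroma_area": t.stroma_area,
            "log_hazard": t.log_hazard,
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_frame_csv(
    path: str | Path, frame: pd.DataFrame, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, index=False)
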