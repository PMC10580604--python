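"""Patch sampling, patch classification and tissue-map assembly.

A whole slide is treated as a rectangular grid of non-overlapping patches
(0-based, row-major (row, col) coordinates). A fixed fraction of patch
positions (default 5%) is sampled uniformly without replacement for deep
feature extraction, while the full grid is classified block by block to
build the tissue map. The desk-scale patch classifier is multinomial
logistic regression on raw pixels (cross-entropy, seeded); an oracle
classifier backed by generator ground truth is provided for tests and for
runs that skip classifier training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .tissue import TissueClass

__all__ = [
    "SamplingConfig",
    "PatchRecord",
    "sample_positions",
    "sample_patches",
    "majority_label",
    "PatchClassifier",
    "OracleClassifier",
    "train_patch_classifier",
    "build_tissue_map",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Patch sampling settings: ratio in (0, 1] (default 5%), seed,
    and whether to sample with replacement (default without)."""

    sampling_ratio: float = 0.05
    seed: int = 0
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_ratio <= 1.0:
            raise ValueError("sampling_ratio must be in (0, 1]")


@dataclass
class PatchRecord:
    """One sampled patch: identity, grid position, pixels and label."""

    patient_id: str
    slide_id: str
    row: int
    col: int
    pixels: np.ndarray | None = None
    tissue_class: TissueClass | None = None
    confidence: float | None = None


def _sample_count(n_positions: int, ratio: float) -> int:
    # round half up, floored at one patch
    return max(1, int(math.floor(ratio * n_positions + 0.5)))


def sample_positions(
    positions: Sequence[tuple[int, int]] | np.ndarray, cfg: SamplingConfig
) -> list[tuple[int, int]]:
    """Sample max(1, round(ratio * N)) positions uniformly.

    Without replacement by default; deterministic under cfg.seed.
    """
    positions = list(map(tuple, positions))
    if not positions:
        raise ValueError("patch source is empty")
    k = _sample_count(len(positions), cfg.sampling_ratio)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(positions), size=k, replace=cfg.with_replacement)
    return [positions[i] for i in np.sort(idx)]


def sample_patches(
    patch_source: dict[tuple[int, int], np.ndarray] | np.ndarray,
    cfg: SamplingConfig,
    patient_id: str = "",
    slide_id: str = "",
) -> list[PatchRecord]:
    """Sample patches from a slide.

    patch_source is either a mapping (row, col) -> pixel array or a 4-D
    array indexed [row, col, :, :(, :)] over the full grid.
    """
    if isinstance(patch_source, np.ndarray):
        rows, cols = patch_source.shape[:2]
        positions = [(r, c) for r in range(rows) for c in range(cols)]
        getter = lambda rc: patch_source[rc]  # noqa: E731
    else:
        positions = sorted(patch_source)
        getter = patch_source.__getitem__
    chosen = sample_positions(positions, cfg)
    return [
        PatchRecord(patient_id, slide_id, r, c, pixels=np.asarray(getter((r, c))))
        for r, c in chosen
    ]


def majority_label(patch_region: np.ndarray | Iterable[int]) -> TissueClass:
    """Label of the class covering the largest area of a patch region.

    Ties break toward the earlier class in TissueClass enum order.
    """
    region = np.asarray(list(patch_region) if not isinstance(patch_region, np.ndarray) else patch_region)
    if region.size == 0:
        raise ValueError("patch region is empty")
    counts = np.bincount(region.ravel().astype(int), minlength=len(TissueClass))
    return TissueClass(int(np.argmax(counts)))


class Classifier(Protocol):
    def predict(self, patch: np.ndarray) -> tuple[TissueClass, float]: ...


def _flatten(patches: np.ndarray) -> np.ndarray:
    x = np.asarray(patches, dtype=float)
    return x.reshape(x.shape[0], -1)


@dataclass
class PatchClassifier:
    """Multinomial logistic-regression patch classifier.

    predict returns (class, confidence) where confidence is the softmax
    probability of the arg-max class.
    """

    scaler: StandardScaler
    model: LogisticRegression

    def predict(self, patch: np.ndarray) -> tuple[TissueClass, float]:
        cls, conf = self.predict_batch(np.asarray(patch)[None])
        return cls[0], float(conf[0])

    def predict_batch(self, patches: np.ndarray) -> tuple[list[TissueClass], np.ndarray]:
        x = self.scaler.transform(_flatten(patches))
        proba = self.model.predict_proba(x)
        idx = proba.argmax(axis=1)
        labels = [TissueClass(int(self.model.classes_[i])) for i in idx]
        return labels, proba[np.arange(len(idx)), idx]


@dataclass
class OracleClassifier:
    """Classifier backed by a known label grid; confidence is always 1.

    Used to decouple downstream stages from classifier quality in tests and
    synthetic runs.
    """

    truth: np.ndarray

    def predict_position(self, row: int, col: int) -> tuple[TissueClass, float]:
        return TissueClass(int(self.truth[row, col])), 1.0


def train_patch_classifier(
    patches: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
) -> PatchClassifier:
    """Fit the desk-scale patch classifier with cross-entropy loss.

    patches: (n, edge, edge, 3) array; labels: TissueClass codes.
    Deterministic under seed. Raises on fewer than two classes.
    """
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    x = _flatten(patches)
    scaler = StandardScaler().fit(x)
    model = LogisticRegression(max_iter=max_iter, random_state=seed, C=1.0)
    model.fit(scaler.transform(x), y)
    return PatchClassifier(scaler, model)


def build_tissue_map(
    patch_grid: dict[tuple[int, int], np.ndarray] | np.ndarray,
    classifier,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Classify every grid position and assemble the label matrix.

    patch_grid is a complete mapping (row, col) -> pixels (shape required),
    a 4/5-D array over the grid, or — with an OracleClassifier — None pixels
    are tolerated since labels come from the stored truth. Missing positions
    raise an error naming them.
    """
    if isinstance(classifier, OracleClassifier):
        return np.asarray(classifier.truth, dtype=np.int8).copy()

    if isinstance(patch_grid, np.ndarray):
        rows, cols = patch_grid.shape[:2]
        getter = lambda rc: patch_grid[rc]  # noqa: E731
    else:
        if shape is None:
            raise ValueError("shape is required for a mapping patch grid")
        rows, cols = shape
        missing = [
            (r, c)
            for r in range(rows)
            for c in range(cols)
            if (r, c) not in patch_grid
        ]
        if missing:
            raise ValueError(f"missing patches at positions {missing[:10]}")
        getter = patch_grid.__getitem__

    out = np.zeros((rows, cols), dtype=np.int8)
    batch = np.stack([getter((r, c)) for r in range(rows) for c in range(cols)])
    if hasattr(classifier, "predict_batch"):
        labels, _ = classifier.predict_batch(batch)
    else:
        labels = [classifier.predict(p)[0] for p in batch]
    out.ravel()[:] = np.array([int(l) for l in labels], dtype=np.int8)
    return out
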