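"""Synthetic cohort generator: tissue maps, patch textures and survival times.

Emulates the structure of a whole-slide-image survival cohort so the whole
pipeline is exercisable offline with known ground truth:

* per-patient tissue maps — 2-D grids of nine-class labels with planted
  tumor blobs (solid squares), lymphocytes inside and in a ring around the
  tumors, and solid stroma rectangles;
* per-class patch textures (mean color + Gaussian noise + optional stripes)
  learnable by a small classifier;
* survival times from an exponential proportional-hazards model whose
  log-hazard is a linear function of the standardized planted area features,
  with independent uniform censoring calibrated to a target rate.

Planted components are kept at Chebyshev distance >= 8 from each other so a
5x5 morphological closing acts on each component in isolation: the recorded
ground-truth areas then coincide exactly with what the area-feature
extractor measures. Lymphocytes planted inside a tumor sit strictly in its
interior within 2 cells of the boundary, so closing re-fills them and the
tumor component keeps its full square area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tissue import TissueClass

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_tissue_map",
    "generate_patch_images",
    "generate_survival",
    "generate_cohort",
    "AREA_FEATURE_NAMES",
]

#: Order of the planted area features in hazard_betas and feature matrices.
AREA_FEATURE_NAMES = (
    "max_tumor_area",
    "lymphocyte_inside_tumor",
    "lymphocyte_around_tumor",
    "around_inside_ratio",
    "total_stroma_area",
)

#: Minimum Chebyshev distance between planted components; 8 guarantees that
#: dilation by 2 (half of a 5x5 element) never bridges two components.
MIN_SEPARATION = 8

#: Width of the lymphocyte ring around tumors, in patches (Chebyshev).
AROUND_BAND = 2

# Per-class texture style: mean RGB, noise sd, stripe (amplitude, period).
_CLASS_STYLE: dict[TissueClass, tuple[tuple[int, int, int], float, float, int]] = {
    TissueClass.ADI: ((235, 225, 235), 12.0, 0.0, 8),
    TissueClass.BACK: ((245, 245, 245), 4.0, 0.0, 8),
    TissueClass.DEB: ((150, 110, 140), 25.0, 0.0, 8),
    TissueClass.LYM: ((90, 60, 160), 15.0, 0.0, 8),
    TissueClass.MUC: ((200, 210, 230), 10.0, 20.0, 6),
    TissueClass.MUS: ((190, 120, 160), 12.0, 25.0, 10),
    TissueClass.NORM: ((170, 140, 190), 14.0, 0.0, 8),
    TissueClass.STR: ((210, 160, 200), 12.0, 30.0, 4),
    TissueClass.TUM: ((140, 80, 150), 18.0, 0.0, 8),
}

# Background fill mixture over classes that never carry planted signal.
_FILL_CLASSES = np.array(
    [TissueClass.NORM, TissueClass.ADI, TissueClass.MUS, TissueClass.DEB,
     TissueClass.MUC, TissueClass.BACK],
    dtype=np.int8,
)
_FILL_PROBS = np.array([0.60, 0.10, 0.10, 0.08, 0.07, 0.05])


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    tumor_blobs: explicit list of (row, col, radius) squares shared by all
        patients, or None to draw 1-3 blobs with radius 1-5 per patient.
        radius r plants a solid (2r+1) x (2r+1) square; r = 0 is a single
        cell.
    hazard_betas: coefficients linking the standardized planted area
        features (order AREA_FEATURE_NAMES) to the log-hazard.
    hazard_texture_scale: optional brightness shift per unit log-hazard
        applied to that patient's patch textures, so deep extractors can
        recover the signal from pixels.
    """

    n_patients: int = 60
    map_rows: int = 48
    map_cols: int = 48
    tumor_blobs: tuple[tuple[int, int, int], ...] | None = None
    lym_inside_rate: float = 0.15
    lym_around_rate: float = 0.25
    stroma_fraction: float = 0.08
    patch_pixels: int = 32
    hazard_betas: tuple[float, ...] = (0.8, 0.3, -0.3, -0.4, 0.4)
    hazard_texture_scale: float = 0.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.map_rows < 2 or self.map_cols < 2:
            raise ValueError("map dimensions must be >= 2")
        for p, name in [
            (self.lym_inside_rate, "lym_inside_rate"),
            (self.lym_around_rate, "lym_around_rate"),
            (self.stroma_fraction, "stroma_fraction"),
            (self.censor_rate, "censor_rate"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.patch_pixels < 8:
            raise ValueError("patch_pixels must be >= 8")
        if len(self.hazard_betas) != len(AREA_FEATURE_NAMES):
            raise ValueError(
                f"hazard_betas must have {len(AREA_FEATURE_NAMES)} entries"
            )
        if not np.all(np.isfinite(self.hazard_betas)):
            raise ValueError("hazard_betas must be finite")
        if self.tumor_blobs is not None:
            max_r = max((r for _, _, r in self.tumor_blobs), default=0)
            if any(r < 0 for _, _, r in self.tumor_blobs):
                raise ValueError("blob radius must be >= 0")
            if min(self.map_rows, self.map_cols) < 2 * max_r:
                raise ValueError("map dims must be >= 2 x max blob radius")
            for row, col, r in self.tumor_blobs:
                if not (r <= row < self.map_rows - r and r <= col < self.map_cols - r):
                    raise ValueError(
                        f"blob at ({row},{col}) radius {r} out of grid bounds"
                    )
            squares = [
                (row - r, row + r, col - r, col + r)
                for row, col, r in self.tumor_blobs
            ]
            for i in range(len(squares)):
                for j in range(i + 1, len(squares)):
                    if _chebyshev_gap(squares[i], squares[j]) < MIN_SEPARATION:
                        raise ValueError(
                            "tumor blobs closer than the minimum separation "
                            f"({MIN_SEPARATION} patches); ground truth would "
                            "not match the morphology-based extractor"
                        )


def _chebyshev_gap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> int:
    """Chebyshev distance between two axis-aligned boxes (r0,r1,c0,c1)."""
    dr = max(a[0] - b[1], b[0] - a[1], 0)
    dc = max(a[2] - b[3], b[2] - a[3], 0)
    return max(dr, dc)


@dataclass
class GroundTruth:
    """Planted quantities for one patient, exact recounts of the emitted map."""

    tumor_areas: list[int] = field(default_factory=list)
    lym_inside: int = 0
    lym_around: int = 0
    stroma_area: int = 0
    log_hazard: float = 0.0

    @property
    def max_tumor_area(self) -> int:
        return max(self.tumor_areas, default=0)

    @property
    def around_inside_ratio(self) -> float:
        return (self.lym_around + 1) / (self.lym_inside + 1)

    def feature_vector(self) -> np.ndarray:
        """Planted area features in AREA_FEATURE_NAMES order."""
        return np.array(
            [
                self.max_tumor_area,
                self.lym_inside,
                self.lym_around,
                self.around_inside_ratio,
                self.stroma_area,
            ],
            dtype=float,
        )


def _patient_rng(cfg: SyntheticCohortConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((cfg.seed, stream, patient_index))
    )


def _random_blobs(
    cfg: SyntheticCohortConfig, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    n_blobs = int(rng.integers(1, 4))
    blobs: list[tuple[int, int, int]] = []
    boxes: list[tuple[int, int, int, int]] = []
    max_r = min(5, (min(cfg.map_rows, cfg.map_cols) - 1) // 2)
    for _ in range(n_blobs):
        r = int(rng.integers(1, max_r + 1)) if max_r >= 1 else 0
        for _attempt in range(200):
            row = int(rng.integers(r, cfg.map_rows - r))
            col = int(rng.integers(r, cfg.map_cols - r))
            box = (row - r, row + r, col - r, col + r)
            if all(_chebyshev_gap(box, b) >= MIN_SEPARATION for b in boxes):
                blobs.append((row, col, r))
                boxes.append(box)
                break
    return blobs


def generate_tissue_map(
    cfg: SyntheticCohortConfig, patient_index: int
) -> tuple[np.ndarray, GroundTruth]:
    """Build one patient's nine-class tissue map and its exact ground truth.

    Deterministic in (cfg.seed, patient_index).
    """
    if not 0 <= patient_index < cfg.n_patients:
        raise ValueError("patient_index out of range")
    rng = _patient_rng(cfg, patient_index, stream=1)
    rows, cols = cfg.map_rows, cfg.map_cols
    labels = np.full((rows, cols), TissueClass.NORM, dtype=np.int8)
    truth = GroundTruth()

    blobs = (
        list(cfg.tumor_blobs)
        if cfg.tumor_blobs is not None
        else _random_blobs(cfg, rng)
    )
    boxes = [(row - r, row + r, col - r, col + r) for row, col, r in blobs]

    # occupancy guard: tumor squares plus their around-band, so stroma never
    # lands inside the lymphocyte ring of any tumor
    reserved = np.zeros((rows, cols), dtype=bool)

    for (row, col, r), (r0, r1, c0, c1) in zip(blobs, boxes):
        labels[r0 : r1 + 1, c0 : c1 + 1] = TissueClass.TUM
        truth.tumor_areas.append((2 * r + 1) ** 2)
        g0, g1 = max(r0 - AROUND_BAND, 0), min(r1 + AROUND_BAND, rows - 1)
        h0, h1 = max(c0 - AROUND_BAND, 0), min(c1 + AROUND_BAND, cols - 1)
        reserved[g0 : g1 + 1, h0 : h1 + 1] = True

        # lymphocytes inside: strict interior cells within 2 of the square
        # boundary (so closing always re-fills the holes they punch)
        if r >= 1:
            rr, cc = np.meshgrid(
                np.arange(r0 + 1, r1), np.arange(c0 + 1, c1), indexing="ij"
            )
            if rr.size:
                depth = np.minimum.reduce(
                    [rr - r0, r1 - rr, cc - c0, c1 - cc]
                )
                ok = depth <= AROUND_BAND
                hit = (rng.random(rr.shape) < cfg.lym_inside_rate) & ok
                labels[rr[hit], cc[hit]] = TissueClass.LYM
                truth.lym_inside += int(hit.sum())

        # lymphocytes around: ring at Chebyshev distance 1..AROUND_BAND
        rr, cc = np.meshgrid(
            np.arange(g0, g1 + 1), np.arange(h0, h1 + 1), indexing="ij"
        )
        in_square = (rr >= r0) & (rr <= r1) & (cc >= c0) & (cc <= c1)
        ring = ~in_square
        hit = (rng.random(rr.shape) < cfg.lym_around_rate) & ring
        labels[rr[hit], cc[hit]] = TissueClass.LYM
        truth.lym_around += int(hit.sum())

    # stroma: solid rectangles, mutually separated, clear of tumors + rings
    target = int(round(cfg.stroma_fraction * rows * cols))
    stroma_boxes: list[tuple[int, int, int, int]] = []
    budget = 400
    while truth.stroma_area < target and budget > 0:
        budget -= 1
        h = int(rng.integers(2, 7))
        w = int(rng.integers(2, 7))
        if h > rows or w > cols:
            continue
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        box = (r0, r0 + h - 1, c0, c0 + w - 1)
        if reserved[r0 : r0 + h, c0 : c0 + w].any():
            continue
        if any(_chebyshev_gap(box, b) < MIN_SEPARATION for b in stroma_boxes):
            continue
        labels[r0 : r0 + h, c0 : c0 + w] = TissueClass.STR
        stroma_boxes.append(box)
        truth.stroma_area += h * w

    # fill remaining NORM cells with a fixed background mixture (never LYM,
    # TUM or STR, which carry planted signal)
    free = labels == TissueClass.NORM
    n_free = int(free.sum())
    if n_free:
        fill = rng.choice(_FILL_CLASSES, size=n_free, p=_FILL_PROBS)
        labels[free] = fill

    return labels, truth


def generate_patch_images(
    tissue_class: TissueClass,
    n: int,
    edge: int,
    seed: int,
    brightness_shift: float = 0.0,
) -> np.ndarray:
    """Draw n RGB patch textures of one tissue class, shape (n, edge, edge, 3).

    Each class has a distinct mean color, noise scale and optional stripe
    pattern, so classes are separable by a small classifier. Deterministic
    under seed. brightness_shift adds a constant to all channels before
    clipping (used to encode patient-level hazard in pixel space).
    """
    tissue_class = TissueClass(tissue_class)
    if n < 1:
        raise ValueError("n must be >= 1")
    if edge < 8:
        raise ValueError("edge must be >= 8")
    mean, sd, stripe_amp, stripe_period = _CLASS_STYLE[tissue_class]
    rng = np.random.default_rng(np.random.SeedSequence((int(tissue_class), seed)))
    img = np.tile(np.array(mean, dtype=float), (n, edge, edge, 1))
    img += rng.normal(0.0, sd, size=img.shape)
    if stripe_amp > 0:
        x = np.arange(edge)
        phase = rng.uniform(0, 2 * np.pi, size=n)
        stripes = stripe_amp * np.sin(
            2 * np.pi * x[None, :] / stripe_period + phase[:, None]
        )
        img += stripes[:, None, :, None]
    img += brightness_shift
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_survival(
    truths: list[GroundTruth],
    betas: np.ndarray | tuple[float, ...],
    censor_rate: float,
    seed: int,
    baseline_rate: float = 1.0,
) -> pd.DataFrame:
    """Draw survival records from an exponential proportional-hazards model.

    Log-hazard = betas . z-scored planted area features (+ log baseline
    rate). Censoring times are i.i.d. Uniform(0, c) with c solved so the
    expected censored fraction equals censor_rate. Each truth's log_hazard
    field is filled in. Returns a DataFrame (patient_id, time, event) with
    event 1 = death observed, 0 = censored.
    """
    betas = np.asarray(betas, dtype=float)
    if not np.all(np.isfinite(betas)):
        raise ValueError("betas must be finite")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be in [0, 1]")
    n = len(truths)
    X = np.array([t.feature_vector() for t in truths])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    lp = (X - mu) / sd @ betas
    for t, h in zip(truths, lp):
        t.log_hazard = float(h)
    rates = baseline_rate * np.exp(lp)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    event_times = rng.exponential(1.0 / rates)

    if censor_rate == 0.0:
        times, events = event_times, np.ones(n, dtype=int)
    else:
        if censor_rate == 1.0:
            c = 1e-9 / rates.max()
        else:

            def expected_censored(c: float) -> float:
                lc = rates * c
                return float(np.mean(-np.expm1(-lc) / lc) - censor_rate)

            lo, hi = 1e-12 / rates.max(), 1e12 / rates.min()
            c = brentq(expected_censored, lo, hi, xtol=1e-12, rtol=1e-10)
        censor_times = rng.uniform(0.0, c, size=n)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time": times,
            "event": events,
        }
    )


@dataclass
class SyntheticCohort:
    """One fully generated cohort: maps, ground truth and survival records."""

    config: SyntheticCohortConfig
    tissue_maps: list[np.ndarray]
    truths: list[GroundTruth]
    survival: pd.DataFrame

    def patient_ids(self) -> list[str]:
        return list(self.survival["patient_id"])

    def patch_images(
        self, patient_index: int, tissue_class: TissueClass, n: int, seed_offset: int = 0
    ) -> np.ndarray:
        """Patch textures for one patient, brightness-shifted by hazard if
        the config's hazard_texture_scale is non-zero."""
        cfg = self.config
        shift = cfg.hazard_texture_scale * self.truths[patient_index].log_hazard
        seed = int(
            np.random.SeedSequence(
                (cfg.seed, 3, patient_index, seed_offset)
            ).generate_state(1)[0] % (2**31)
        )
        return generate_patch_images(
            tissue_class, n, cfg.patch_pixels, seed, brightness_shift=shift
        )


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate the full cohort: one map per patient plus survival records."""
    maps, truths = [], []
    for i in range(cfg.n_patients):
        m, t = generate_tissue_map(cfg, i)
        maps.append(m)
        truths.append(t)
    survival = generate_survival(truths, cfg.hazard_betas, cfg.censor_rate, cfg.seed)
    return SyntheticCohort(cfg, maps, truths, survival)
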