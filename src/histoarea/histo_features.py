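"""Per-tissue deep Cox feature extraction and aggregation.

One extractor network is trained per tissue type on the patches of that
tissue, each patch inheriting its patient's overall-survival label
(time, event). The 32-unit hidden layer is the per-patch feature. Per-slide
tissue features are the patch-mean feature scaled by the tissue's share of
all sampled non-background patches, and the per-tissue vectors are
concatenated in the fixed order tumor, lymphocytes, stroma, mucus to the
4 x 32 = 128-dimensional histopathological vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._convnet import ConvSurvNet, cox_partial_nll, cox_partial_nll_grad
from .tissue import DEFAULT_HISTO_TISSUES, NON_BACKGROUND_CLASSES, TissueClass

__all__ = [
    "DeepConvSurvConfig",
    "cox_partial_nll",
    "cox_partial_nll_grad",
    "train_tissue_extractor",
    "aggregate_tissue",
    "concat_histo",
    "enumerate_tissue_subsets",
    "tissue_combination_search",
    "FEATURE_WIDTH",
]

FEATURE_WIDTH = 32


@dataclass(frozen=True)
class DeepConvSurvConfig:
    """Training settings for one per-tissue extractor.

    input_edge defaults to the desk-scale 32 pixels; conv_channels describe
    the strided 3x3 conv stack. feature_width stays 32 unless changed
    consistently pipeline-wide.
    """

    input_edge: int = 32
    conv_channels: tuple[int, ...] = (8, 16, 32)
    feature_width: int = FEATURE_WIDTH
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int | None = None
    seed: int = 0


def train_tissue_extractor(
    patches: np.ndarray,
    patient_ids: Sequence[str],
    survival: pd.DataFrame,
    cfg: DeepConvSurvConfig = DeepConvSurvConfig(),
) -> ConvSurvNet:
    """Train the extractor for one tissue type.

    Every patch carries its patient's (time, event) from the survival table
    (columns patient_id, time, event). Requires at least two patients and
    one observed event. Deterministic under cfg.seed.
    """
    patches = np.asarray(patches)
    patient_ids = list(patient_ids)
    if len(patches) != len(patient_ids):
        raise ValueError("patches and patient_ids must align")
    surv = survival.set_index("patient_id")
    unknown = set(patient_ids) - set(surv.index)
    if unknown:
        raise ValueError(f"patients without survival records: {sorted(unknown)[:5]}")
    if len(set(patient_ids)) < 2:
        raise ValueError("at least two patients are required")
    times = surv.loc[patient_ids, "time"].to_numpy(dtype=float)
    events = surv.loc[patient_ids, "event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("all-censored input: partial likelihood undefined")
    net = ConvSurvNet(
        input_edge=cfg.input_edge,
        channels=cfg.conv_channels,
        feature_width=cfg.feature_width,
        lr=cfg.learning_rate,
        seed=cfg.seed,
    )
    net.fit(patches, times, events, epochs=cfg.epochs, batch_size=cfg.batch_size)
    return net


def aggregate_tissue(
    patch_features: np.ndarray, n_tissue: int, n_total: int, width: int = FEATURE_WIDTH
) -> np.ndarray:
    """Weighted patch-mean feature of one tissue on one slide.

    weight = n_tissue / n_total, where n_total counts all sampled
    non-background patches of the slide. Returns the zero vector when the
    tissue has no patches.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_tissue < 0 or n_tissue > n_total:
        raise ValueError("n_tissue must be in [0, n_total]")
    if n_tissue == 0:
        return np.zeros(width)
    feats = np.asarray(patch_features, dtype=float)
    if feats.ndim != 2 or len(feats) != n_tissue:
        raise ValueError("patch_features must be (n_tissue, width)")
    return (n_tissue / n_total) * feats.mean(axis=0)


def concat_histo(
    tissue_vectors: Mapping[TissueClass, np.ndarray],
    tissues: Sequence[TissueClass] = DEFAULT_HISTO_TISSUES,
    width: int = FEATURE_WIDTH,
) -> np.ndarray:
    """Concatenate per-tissue vectors in fixed tissue order.

    All tissues in `tissues` must be present (zero vectors allowed); every
    vector must have the configured width. Default order TUM, LYM, STR, MUC
    gives the 128-dimensional histopathological vector.
    """
    blocks = []
    for t in tissues:
        if t not in tissue_vectors:
            raise ValueError(f"missing vector for tissue {TissueClass(t).name}")
        v = np.asarray(tissue_vectors[t], dtype=float).ravel()
        if v.shape != (width,):
            raise ValueError(
                f"tissue {TissueClass(t).name} vector has width {v.size}, "
                f"expected {width}"
            )
        blocks.append(v)
    return np.concatenate(blocks)


def enumerate_tissue_subsets(
    classes: Sequence[TissueClass] = NON_BACKGROUND_CLASSES,
) -> list[tuple[TissueClass, ...]]:
    """All non-empty subsets of the given tissue classes (2^k - 1 of them),
    ordered by size then enum order."""
    classes = list(classes)
    out: list[tuple[TissueClass, ...]] = []
    for k in range(1, len(classes) + 1):
        out.extend(combinations(classes, k))
    return out


def tissue_combination_search(
    tissue_features: Mapping[TissueClass, np.ndarray],
    survival: pd.DataFrame,
    model_names: Sequence[str],
    cv_seed: int = 0,
    k_folds: int = 5,
    subsets: Sequence[tuple[TissueClass, ...]] | None = None,
) -> pd.DataFrame:
    """Cross-validated C-index for every tissue subset and model.

    tissue_features maps each tissue to an (n_patients, 32) matrix aligned
    with the survival table rows. By default all 2^k - 1 non-empty subsets
    of the provided tissues are evaluated (255 for the eight non-background
    classes); a sub-lattice can be passed explicitly. Returns a long-format
    table (subset, model, mean_cindex, std_cindex) sorted by mean C-index.
    """
    from .survival_eval import cross_validate  # deferred: avoids cycle

    tissues = sorted(tissue_features, key=int)
    if subsets is None:
        subsets = enumerate_tissue_subsets(tissues)
    rows = []
    for subset in subsets:
        X = np.hstack([np.asarray(tissue_features[t], dtype=float) for t in subset])
        results = cross_validate(
            X, survival, model_names=model_names, k=k_folds, seed=cv_seed
        )
        label = "+".join(TissueClass(t).name for t in subset)
        for res in results:
            rows.append(
                {
                    "subset": label,
                    "n_tissues": len(subset),
                    "model": res.model_name,
                    "mean_cindex": res.mean,
                    "std_cindex": res.std,
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values("mean_cindex", ascending=False).reset_index(drop=True)
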