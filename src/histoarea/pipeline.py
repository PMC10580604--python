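"""End-to-end orchestration: cohort -> tissue maps -> area features ->
deep features -> discretize -> merge -> cross-validated survival models.

A run is driven by one RunConfig (YAML/JSON-loadable). A single global seed
fans out to per-stage seeds through named substreams, so each stage is
independently reproducible; every artifact CSV carries the config hash and
the global seed as provenance comments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .area_features import AreaFeatures, BandConfig, extract_area_features
from .histo_features import (
    DeepConvSurvConfig,
    aggregate_tissue,
    concat_histo,
    train_tissue_extractor,
)
from .morphology import MorphConfig
from .survival_eval import (
    MODEL_NAMES,
    CVResult,
    cross_validate,
    kaplan_meier,
    logrank_test,
    maxstat_cutoff,
    discretize,
)
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort
from .tissue import DEFAULT_HISTO_TISSUES, TissueClass
from .tissue_map import (
    OracleClassifier,
    SamplingConfig,
    build_tissue_map,
    sample_positions,
    train_patch_classifier,
)
from .synthetic import generate_patch_images

__all__ = ["RunConfig", "RunReport", "run_pipeline", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    """A stage failure annotated with the stage name and offending subject."""

    def __init__(self, stage: str, subject: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for {subject}: {original}")
        self.stage = stage
        self.subject = subject
        self.original = original


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    output_dir: str = "runs/latest"
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    maps_dir: str | None = None  # load per-patient map CSVs instead of generating
    survival_csv: str | None = None  # load survival table instead of generating
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    band: BandConfig = field(default_factory=BandConfig)
    deep: DeepConvSurvConfig = field(default_factory=DeepConvSurvConfig)
    tissues: tuple[TissueClass, ...] = DEFAULT_HISTO_TISSUES
    classifier: str = "oracle"  # "oracle" | "trained"
    classifier_patches_per_class: int = 150
    model_names: tuple[str, ...] = MODEL_NAMES
    k_folds: int = 5
    cutoff_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("tissue set must be non-empty")
        self.tissues = tuple(TissueClass(t) for t in self.tissues)
        if TissueClass.BACK in self.tissues:
            raise ValueError("tissue set must exclude BACK")
        if self.classifier not in ("oracle", "trained"):
            raise ValueError("classifier must be 'oracle' or 'trained'")
        unknown = set(self.model_names) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        if (self.maps_dir is None) != (self.survival_csv is None):
            raise ValueError("maps_dir and survival_csv must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in [
            ("cohort", SyntheticCohortConfig),
            ("sampling", SamplingConfig),
            ("morph", MorphConfig),
            ("band", BandConfig),
            ("deep", DeepConvSurvConfig),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                sect = dict(kwargs[key])
                for tkey in ("tumor_blobs", "hazard_betas", "conv_channels"):
                    if tkey in sect and sect[tkey] is not None:
                        sect[tkey] = tuple(
                            tuple(v) if isinstance(v, list) else v for v in sect[tkey]
                        )
                kwargs[key] = sub(**sect)
        if "tissues" in kwargs:
            kwargs["tissues"] = tuple(
                TissueClass[t] if isinstance(t, str) else TissueClass(t)
                for t in kwargs["tissues"]
            )
        if "model_names" in kwargs:
            kwargs["model_names"] = tuple(kwargs["model_names"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunReport:
    """Everything a run produced, plus provenance."""

    config_hash: str
    seed: int
    n_patients: int
    area_features: pd.DataFrame
    histo_features: pd.DataFrame
    merged_width: int
    cutoffs: dict[str, dict]
    cv_results: list[CVResult]
    output_dir: str

    def cv_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"model": r.model_name, "mean_cindex": r.mean, "std_cindex": r.std}
                for r in self.cv_results
            ]
        )


def _load_cohort(cfg: RunConfig) -> SyntheticCohort:
    if cfg.maps_dir is None:
        return generate_cohort(cfg.cohort)
    maps_dir = Path(cfg.maps_dir)
    surv_path = Path(cfg.survival_csv)
    if not surv_path.exists():
        raise FileNotFoundError(f"survival CSV not found: {surv_path}")
    if not maps_dir.is_dir():
        raise FileNotFoundError(f"maps directory not found: {maps_dir}")
    survival = hio.read_survival_csv(surv_path)
    maps = []
    for pid in survival["patient_id"]:
        p = maps_dir / f"{pid}.csv"
        if not p.exists():
            raise FileNotFoundError(f"tissue map not found for patient {pid}: {p}")
        maps.append(hio.read_tissue_map_csv(p))
    cohort_cfg = cfg.cohort
    from .synthetic import GroundTruth

    truths = [GroundTruth() for _ in maps]
    return SyntheticCohort(cohort_cfg, maps, truths, survival)


def _classify_maps(cfg: RunConfig, cohort: SyntheticCohort) -> list[np.ndarray]:
    """Tissue maps as seen by the pipeline: ground-truth grids under the
    oracle classifier, or re-classified patch textures under 'trained'."""
    if cfg.classifier == "oracle":
        return [
            build_tissue_map(None, OracleClassifier(m)) for m in cohort.tissue_maps
        ]
    seed = cfg.stage_seed("classifier")
    per_class = cfg.classifier_patches_per_class
    edge = cfg.cohort.patch_pixels
    xs, ys = [], []
    for cls in TissueClass:
        xs.append(generate_patch_images(cls, per_class, edge, seed + int(cls)))
        ys.extend([int(cls)] * per_class)
    clf = train_patch_classifier(np.concatenate(xs), ys, seed=seed)
    out = []
    for i, m in enumerate(cohort.tissue_maps):
        rows, cols = m.shape
        flat_classes = m.ravel()
        patches = np.empty((rows * cols, edge, edge, 3), dtype=np.uint8)
        for cls in np.unique(flat_classes):
            pos = np.flatnonzero(flat_classes == cls)
            patches[pos] = generate_patch_images(
                TissueClass(int(cls)), len(pos), edge, seed + 1000 + i
            )
        labels, _ = clf.predict_batch(patches)
        out.append(np.array([int(l) for l in labels], dtype=np.int8).reshape(rows, cols))
    return out


def _deep_features(
    cfg: RunConfig, cohort: SyntheticCohort, maps: list[np.ndarray]
) -> pd.DataFrame:
    """Sample patches, train one extractor per tissue, aggregate per patient."""
    rng_seed = cfg.stage_seed("sampling")
    ids = cohort.patient_ids()
    width = cfg.deep.feature_width
    # per-patient sampled patch classes and images, grouped by tissue
    sampled: dict[TissueClass, list[tuple[int, np.ndarray]]] = {
        t: [] for t in cfg.tissues
    }
    n_nonback = np.zeros(len(ids), dtype=int)
    n_per_tissue = {t: np.zeros(len(ids), dtype=int) for t in cfg.tissues}
    for i, m in enumerate(maps):
        rows, cols = m.shape
        positions = [(r, c) for r in range(rows) for c in range(cols)]
        scfg = SamplingConfig(
            sampling_ratio=cfg.sampling.sampling_ratio,
            seed=rng_seed + i,
            with_replacement=cfg.sampling.with_replacement,
        )
        chosen = sample_positions(positions, scfg)
        classes = [TissueClass(int(m[r, c])) for r, c in chosen]
        n_nonback[i] = sum(1 for c in classes if c is not TissueClass.BACK)
        for t in cfg.tissues:
            k = sum(1 for c in classes if c is t)
            if k:
                imgs = cohort.patch_images(i, t, k, seed_offset=int(t))
                sampled[t].append((i, imgs))
                n_per_tissue[t][i] = k

    # train one extractor per tissue on all its patches across patients
    extractors: dict[TissueClass, object] = {}
    for t in cfg.tissues:
        chunks = sampled[t]
        if not chunks:
            extractors[t] = None
            continue
        patches = np.concatenate([imgs for _, imgs in chunks])
        pids = sum(
            ([ids[i]] * len(imgs) for i, imgs in chunks), []
        )
        deep_cfg = DeepConvSurvConfig(
            input_edge=cfg.cohort.patch_pixels,
            conv_channels=cfg.deep.conv_channels,
            feature_width=width,
            learning_rate=cfg.deep.learning_rate,
            epochs=cfg.deep.epochs,
            batch_size=cfg.deep.batch_size,
            seed=cfg.stage_seed(f"extractor:{t.name}"),
        )
        try:
            extractors[t] = train_tissue_extractor(
                patches, pids, cohort.survival, deep_cfg
            )
        except ValueError as exc:
            raise PipelineStageError("deep-features", f"tissue {t.name}", exc)

    # aggregate per patient
    rows_out = []
    for i, pid in enumerate(ids):
        vectors: dict[TissueClass, np.ndarray] = {}
        for t in cfg.tissues:
            n_t = int(n_per_tissue[t][i])
            if n_t == 0 or extractors[t] is None:
                vectors[t] = np.zeros(width)
                continue
            imgs = next(imgs for j, imgs in sampled[t] if j == i)
            feats = extractors[t].features(imgs)
            vectors[t] = aggregate_tissue(
                feats, n_t, max(int(n_nonback[i]), 1), width=width
            )
        vec = concat_histo(vectors, tissues=cfg.tissues, width=width)
        rows_out.append([pid, *vec])
    cols = ["patient_id"] + [
        f"{t.name}_f{j:02d}" for t in cfg.tissues for j in range(width)
    ]
    return pd.DataFrame(rows_out, columns=cols)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to cfg.output_dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    prov = {"config_hash": chash, "seed": cfg.seed}

    try:
        cohort = _load_cohort(cfg)
    except (OSError, ValueError) as exc:
        raise PipelineStageError("load-cohort", "cohort", exc)

    try:
        maps = _classify_maps(cfg, cohort)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("classify", "cohort", exc)

    # area features
    area_rows = []
    for pid, m in zip(cohort.patient_ids(), maps):
        try:
            feats = extract_area_features(m, cfg.morph, cfg.band)
        except Exception as exc:
            raise PipelineStageError("area-features", f"patient {pid}", exc)
        area_rows.append([pid, *feats.as_array()])
    area_df = pd.DataFrame(area_rows, columns=["patient_id", *AreaFeatures.names])

    # deep features
    histo_df = _deep_features(cfg, cohort, maps)

    survival = cohort.survival
    # whole-cohort cutoffs with KM / log-rank reporting (the CV below
    # re-selects cutoffs per training fold; these are for the run report)
    cutoffs: dict[str, dict] = {}
    for name in AreaFeatures.names:
        values = area_df[name].to_numpy(dtype=float)
        try:
            cut = maxstat_cutoff(
                values,
                survival,
                feature_name=name,
                n_permutations=cfg.cutoff_permutations,
                seed=cfg.stage_seed(f"maxstat:{name}"),
            )
            groups = discretize(values, cut.cutoff)
            chi2, p_lr = logrank_test(groups, survival)
            cutoffs[name] = {
                "cutoff": cut.cutoff,
                "statistic": cut.statistic,
                "p_permutation": cut.p_value,
                "p_logrank": p_lr,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
            }
        except ValueError as exc:
            cutoffs[name] = {"error": str(exc)}

    # merged features and cross-validation (cutoffs re-selected per fold)
    histo_mat = histo_df.drop(columns="patient_id").to_numpy(dtype=float)
    area_mat = area_df.drop(columns="patient_id").to_numpy(dtype=float)
    merged = np.hstack([histo_mat, area_mat])
    area_cols = list(range(histo_mat.shape[1], merged.shape[1]))
    try:
        cv_results = cross_validate(
            merged,
            survival,
            model_names=cfg.model_names,
            k=cfg.k_folds,
            seed=cfg.stage_seed("cv"),
            area_cols=area_cols,
        )
    except ValueError as exc:
        raise PipelineStageError("evaluate", "cohort", exc)

    # artifacts
    hio.write_frame_csv(out / "area_features.csv", area_df, prov)
    hio.write_frame_csv(out / "histo_features.csv", histo_df, prov)
    hio.write_survival_csv(out / "survival.csv", survival, prov)
    (out / "cutoffs.json").write_text(json.dumps({**prov, "cutoffs": cutoffs}, indent=1))
    km = kaplan_meier(survival)
    hio.write_frame_csv(out / "kaplan_meier.csv", km, prov)
    report = RunReport(
        config_hash=chash,
        seed=cfg.seed,
        n_patients=len(survival),
        area_features=area_df,
        histo_features=histo_df,
        merged_width=merged.shape[1],
        cutoffs=cutoffs,
        cv_results=cv_results,
        output_dir=str(out),
    )
    hio.write_frame_csv(out / "cv_results.csv", report.cv_summary(), prov)
    (out / "config.json").write_text(
        json.dumps({**prov, "config": asdict(cfg)}, indent=1, default=str)
    )
    return report
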