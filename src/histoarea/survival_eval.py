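"""Survival evaluation: concordance index, Kaplan-Meier, log-rank,
maximally selected rank statistics, feature discretization and the six
cross-validated survival models.

The concordance index is implemented literally as

    C = #{(i, j): i uncensored, T_j > T_i, R_i > R_j}
        / #{(i, j): i uncensored, T_j > T_i}

with strict inequalities (ties earn no credit); the common Harrell variant
with 0.5 credit for risk ties is available behind a flag. Cutpoints for the
tissue-area features are chosen by maximally selected rank statistics: the
cutoff maximizing the absolute standardized two-group log-rank statistic
over all admissible splits, with a permutation p-value for the maximal
statistic (multiplicity-honest null). Features are binarized strictly
(1 iff value > cutoff). The six survival models — LASSO-Cox, RIDGE-Cox,
EN-Cox, survival SVM, random survival forest and gradient-boosted
regression trees — are fitted through scikit-survival with fixed,
overridable hyperparameters, and evaluated by patient-level, event-
stratified fivefold cross-validation in which cutoffs and model fits use
training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CutoffResult",
    "CVResult",
    "concordance_index",
    "kaplan_meier",
    "logrank_test",
    "maxstat_cutoff",
    "discretize",
    "merge_features",
    "fit_survival_model",
    "cross_validate",
    "MODEL_NAMES",
    "records_from_frame",
]

MODEL_NAMES = ("lasso_cox", "ridge_cox", "en_cox", "ssvm", "rsf", "gbrt")


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's observed time and event indicator (1 = death)."""

    patient_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_from_frame(frame: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(str(r.patient_id), float(r.time), int(r.event))
        for r in frame.itertuples()
    ]


def _times_events(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        t = records["time"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=int)
    else:
        t = np.array([r.time for r in records], dtype=float)
        e = np.array([r.event for r in records], dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


def concordance_index(records, risks, tie_credit: bool = False) -> float:
    """Concordance between survival times and predicted risks.

    For every ordered pair with i uncensored and T_j > T_i, the pair is
    concordant when R_i > R_j. With tie_credit=True, risk ties count 0.5
    (Harrell's variant); by default they count 0. Raises when no comparable
    pair exists.
    """
    t, e = _times_events(records)
    r = np.asarray(risks, dtype=float).ravel()
    if r.shape != t.shape:
        raise ValueError("risks must align with records")
    if not np.isfinite(r).all():
        raise ValueError("risks must be finite")
    unc = e == 1
    # comparable[i, j] = i uncensored and T_j > T_i
    comparable = unc[:, None] & (t[None, :] > t[:, None])
    den = int(comparable.sum())
    if den == 0:
        raise ValueError("no comparable pair")
    conc = comparable & (r[:, None] > r[None, :])
    num = float(conc.sum())
    if tie_credit:
        num += 0.5 * float((comparable & (r[:, None] == r[None, :])).sum())
    return num / den


def kaplan_meier(records) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table (time, n_at_risk, n_events, survival); the curve
    is right-continuous and starts at S(0) = 1.
    """
    t, e = _times_events(records)
    if len(t) == 0:
        raise ValueError("at least one record is required")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n = len(t)
    rows = []
    s = 1.0
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        if d:
            s *= 1.0 - d / at_risk
        rows.append({"time": u, "n_at_risk": at_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows)


def _logrank_terms(t: np.ndarray, e: np.ndarray, g: np.ndarray):
    """Observed-minus-expected and hypergeometric variance for group 1."""
    event_times = np.unique(t[e == 1])
    U = 0.0
    V = 0.0
    for u in event_times:
        at_risk = t >= u
        n_i = at_risk.sum()
        n1_i = (at_risk & g).sum()
        d_i = ((t == u) & (e == 1)).sum()
        d1_i = ((t == u) & (e == 1) & g).sum()
        U += d1_i - d_i * n1_i / n_i
        if n_i > 1:
            V += d_i * (n1_i / n_i) * (1 - n1_i / n_i) * (n_i - d_i) / (n_i - 1)
    return U, V


def logrank_test(groups, records) -> tuple[float, float]:
    """Two-group log-rank test.

    groups: binary labels aligned with records. Returns the chi-square
    statistic (1 df) and its p-value.
    """
    t, e = _times_events(records)
    g = np.asarray(groups).ravel().astype(bool)
    if g.shape != t.shape:
        raise ValueError("groups must align with records")
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    U, V = _logrank_terms(t, e, g)
    if V == 0:
        return 0.0, 1.0
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class CutoffResult:
    """Maximally selected rank statistic for one feature."""

    feature_name: str
    cutoff: float
    statistic: float  # |standardized log-rank| at the selected cutoff
    p_value: float
    n_low: int  # values <= cutoff
    n_high: int  # values > cutoff


def _maxstat_scan(
    x: np.ndarray, t: np.ndarray, e: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """|standardized log-rank statistic| for the split x > c, per candidate.

    Vectorized over candidates: for each unique event time the group-1 risk
    and event counts are computed for all candidate splits at once.
    """
    order = np.argsort(t, kind="stable")
    t_s, e_s = t[order], e[order]
    G = x[order, None] > candidates[None, :]  # (n, n_candidates), time-sorted
    n = len(t_s)
    # suffix[i] = group-1 count of the risk set {j: t_j >= t_s[i]} when i is
    # the first index of its tie block
    suffix = np.cumsum(G[::-1], axis=0)[::-1].astype(float)
    # tie-block starts and per-block event counts
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    ends = np.r_[starts[1:], n]
    U = np.zeros(len(candidates))
    V = np.zeros(len(candidates))
    for f, l in zip(starts, ends):
        block_events = e_s[f:l] == 1
        d_i = int(block_events.sum())
        if d_i == 0:
            continue
        n_i = n - f
        n1 = suffix[f]
        d1 = G[f:l][block_events].sum(axis=0).astype(float)
        p1 = n1 / n_i
        U += d1 - d_i * p1
        if n_i > 1:
            V += d_i * p1 * (1 - p1) * (n_i - d_i) / (n_i - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, np.abs(U) / np.sqrt(V), 0.0)
    return z


def maxstat_cutoff(
    values,
    records,
    feature_name: str = "feature",
    min_prop: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CutoffResult:
    """Cutpoint maximizing the absolute standardized log-rank statistic.

    Candidate cutoffs are the observed values whose split x > c leaves at
    least ceil(min_prop * n) patients on each side. The p-value is the
    permutation tail probability of the maximal statistic under random
    reassignment of feature values to outcomes (n_permutations = 0 skips
    it and reports p = NaN). Raises for constant features and when no
    admissible cutoff exists.
    """
    x = np.asarray(values, dtype=float).ravel()
    t, e = _times_events(records)
    if x.shape != t.shape:
        raise ValueError("values must align with records")
    if e.sum() == 0:
        raise ValueError("at least one event is required")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("constant feature: no cutoff exists")
    n = len(x)
    min_size = int(np.ceil(min_prop * n))
    n_high = (x[:, None] > uniq[None, :]).sum(axis=0)
    admissible = (n_high >= min_size) & (n - n_high >= min_size)
    candidates = uniq[admissible]
    if len(candidates) == 0:
        raise ValueError("no admissible cutoff under the minimal proportion")

    z = _maxstat_scan(x, t, e, candidates)
    best = int(np.argmax(z))
    cutoff = float(candidates[best])
    observed = float(z[best])

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            xp = x[rng.permutation(n)]
            zp = _maxstat_scan(xp, t, e, candidates)
            if zp.max() >= observed:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    else:
        p = float("nan")

    n_hi = int((x > cutoff).sum())
    return CutoffResult(feature_name, cutoff, observed, p, n - n_hi, n_hi)


def discretize(values, cutoff: float) -> np.ndarray:
    """Binarize strictly: 1 iff value > cutoff."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all() or not np.isfinite(cutoff):
        raise ValueError("inputs must be finite")
    return (v > cutoff).astype(int)


def merge_features(histo: np.ndarray, area_binary: np.ndarray) -> np.ndarray:
    """Concatenate the histopathological block (width 128) with the five
    discretized area features into the 133-wide merged vector.

    Accepts either single vectors or (n, width) matrices.
    """
    h = np.asarray(histo, dtype=float)
    a = np.asarray(area_binary, dtype=float)
    single = h.ndim == 1
    if single:
        h, a = h[None], a[None]
    if h.shape[1] != 128:
        raise ValueError(f"histo block must have width 128, got {h.shape[1]}")
    if a.shape[1] != 5:
        raise ValueError(f"area block must have width 5, got {a.shape[1]}")
    if h.shape[0] != a.shape[0]:
        raise ValueError("histo and area blocks must align")
    out = np.hstack([h, a])
    return out[0] if single else out


# ---------------------------------------------------------------------------
# the six survival models
# ---------------------------------------------------------------------------

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "lasso_cox": {"alpha": 0.1},
    "ridge_cox": {"alpha": 1.0},
    "en_cox": {"alpha": 0.1, "l1_ratio": 0.5},
    "ssvm": {"alpha": 1.0, "max_iter": 100},
    "rsf": {"n_estimators": 100, "min_samples_leaf": 3},
    "gbrt": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2},
}


@dataclass
class FittedSurvivalModel:
    """A fitted model exposing predict_risk with higher = worse.

    Orientation is normalized at fit time: if the training-set concordance
    of raw predictions is below 0.5 the sign is flipped.
    """

    name: str
    estimator: object
    mean_: np.ndarray
    scale_: np.ndarray
    sign: float = 1.0

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self.sign * np.asarray(self.estimator.predict(Xs), dtype=float)


def _surv_y(t: np.ndarray, e: np.ndarray):
    from sksurv.util import Surv

    return Surv.from_arrays(e.astype(bool), t)


def fit_survival_model(
    name: str,
    X: np.ndarray,
    records,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> FittedSurvivalModel:
    """Fit one of the six survival models on (X, records).

    Features are z-scored internally (constant columns pass through).
    Unknown names and degenerate inputs (fewer than two patients, no
    events) raise.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    t, e = _times_events(records)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(t):
        raise ValueError("X must be (n_patients, n_features) aligned with records")
    if len(t) < 2 or e.sum() == 0:
        raise ValueError("degenerate input: need >= 2 patients and >= 1 event")
    hp = dict(DEFAULT_HYPERPARAMS[name])
    if hyperparams:
        hp.update(hyperparams)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    y = _surv_y(t, e)

    if name == "lasso_cox":
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[hp["alpha"]])
    elif name == "ridge_cox":
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        est = CoxPHSurvivalAnalysis(alpha=hp["alpha"])
    elif name == "en_cox":
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        est = CoxnetSurvivalAnalysis(l1_ratio=hp["l1_ratio"], alphas=[hp["alpha"]])
    elif name == "ssvm":
        from sksurv.svm import FastSurvivalSVM

        est = FastSurvivalSVM(
            alpha=hp["alpha"], max_iter=hp["max_iter"], random_state=seed
        )
    elif name == "rsf":
        from sksurv.ensemble import RandomSurvivalForest

        est = RandomSurvivalForest(
            n_estimators=hp["n_estimators"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
        )
    else:  # gbrt
        from sksurv.ensemble import GradientBoostingSurvivalAnalysis

        est = GradientBoostingSurvivalAnalysis(
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            max_depth=hp["max_depth"],
            random_state=seed,
        )

    if name in ("lasso_cox", "en_cox"):
        # the coordinate-descent Coxnet solver can overflow when the penalty
        # is too weak for near-separable data; escalate alpha geometrically
        alpha = hp["alpha"]
        for _ in range(6):
            try:
                est.set_params(alphas=[alpha])
                est.fit(Xs, y)
                break
            except ArithmeticError:
                alpha *= 10.0
        else:
            raise ArithmeticError(
                f"{name}: Coxnet failed to converge even at alpha={alpha:g}"
            )
    else:
        est.fit(Xs, y)
    model = FittedSurvivalModel(name, est, mean, scale)
    try:
        c_train = concordance_index(records, model.predict_risk(X), tie_credit=True)
        if c_train < 0.5:
            model.sign = -1.0
    except ValueError:
        pass  # no comparable pair in training data; keep native orientation
    return model


@dataclass(frozen=True)
class CVResult:
    """Cross-validated C-index summary for one model."""

    model_name: str
    fold_cindices: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_cindices))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_cindices, ddof=1))


def _stratified_folds(
    e: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Patient-level folds stratified by event indicator."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (1, 0):
        idx = np.flatnonzero(e == label)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    X: np.ndarray,
    survival: pd.DataFrame,
    model_names: Sequence[str] = MODEL_NAMES,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict[str, dict] | None = None,
    area_cols: Sequence[int] | None = None,
    tie_credit: bool = False,
    return_details: bool = False,
):
    """k-fold cross-validated concordance per model.

    Folds are split at the patient level and stratified by event indicator;
    deterministic under seed. When area_cols names continuous columns of X,
    each training fold selects their maximally-selected-rank cutoffs and
    binarizes both folds with the training cutoffs — test-fold information
    never enters cutoff selection or model fitting. Raises when a training
    fold has no events.
    """
    X = np.asarray(X, dtype=float)
    t, e = _times_events(survival)
    n = len(t)
    if n < k:
        raise ValueError("need at least k patients")
    if isinstance(survival, pd.DataFrame) and survival["patient_id"].duplicated().any():
        raise ValueError("survival table must have one row per patient")
    folds = _stratified_folds(e, k, seed)
    per_model: dict[str, list[float]] = {m: [] for m in model_names}
    details: list[dict] = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if e[train_idx].sum() == 0:
            raise ValueError(f"fold {fold_id}: training fold has no events")
        train_surv = survival.iloc[train_idx]
        test_surv = survival.iloc[test_idx]
        X_train = X[train_idx].copy()
        X_test = X[test_idx].copy()
        fold_cutoffs: dict[int, float] = {}
        if area_cols:
            for col in area_cols:
                try:
                    cut = maxstat_cutoff(
                        X_train[:, col],
                        train_surv,
                        n_permutations=0,
                        seed=seed,
                    ).cutoff
                except ValueError:
                    cut = float(np.median(X_train[:, col]))
                fold_cutoffs[col] = cut
                X_train[:, col] = discretize(X_train[:, col], cut)
                X_test[:, col] = discretize(X_test[:, col], cut)
        details.append(
            {"fold": fold_id, "test_idx": test_idx, "cutoffs": fold_cutoffs}
        )
        for m in model_names:
            hp = (hyperparams or {}).get(m)
            model = fit_survival_model(m, X_train, train_surv, hp, seed=seed)
            risks = model.predict_risk(X_test)
            per_model[m].append(
                concordance_index(test_surv, risks, tie_credit=tie_credit)
            )
    results = [CVResult(m, tuple(per_model[m])) for m in model_names]
    if return_details:
        return results, details
    return results
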