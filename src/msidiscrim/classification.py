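"""Cancer-vs-epithelium spectral classification.

Multiple random validation (stratified 50/50 splits, minority-size
downsampling of the training pool), forward stepwise logistic regression
guided by BIC, run-aggregated feature scoring, knee-rule signature sizing
with a plateau advance, validation metrics, probability maps and
signature-feature correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import FeatureTable, RoiMask, ValidationError

_RIDGE = 1e-8  # IRLS jitter so separable data cannot blow up coefficients


@dataclass
class ValidationMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    weighted_accuracy: float
    precision: float
    f_measure: float

    def __post_init__(self) -> None:
        assert abs(
            self.weighted_accuracy - (self.sensitivity + self.specificity) / 2.0
        ) < 1e-9, "weighted accuracy must be the mean of sensitivity/specificity"
        if self.precision + self.sensitivity > 0:
            f = (
                2.0 * self.precision * self.sensitivity
                / (self.precision + self.sensitivity)
            )
            assert abs(self.f_measure - f) < 1e-9

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "weighted_accuracy": self.weighted_accuracy,
            "precision": self.precision,
            "f_measure": self.f_measure,
        }


@dataclass
class ValidationRun:
    iteration: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    signature: list[int]  # component indices, selection order = importance
    test_metrics: ValidationMetrics


@dataclass
class FeatureScore:
    component_id: float
    component_index: int
    score: float
    rank: int


@dataclass
class ClassifierModel:
    component_indices: list[int]
    component_ids: list[float]
    coefficients: np.ndarray
    intercept: float
    seed: int = 0
    n_iterations: int = 0

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        x = table.abundances[self.component_indices].T
        z = x @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "component_indices": list(map(int, self.component_indices)),
                    "component_ids": list(map(float, self.component_ids)),
                    "coefficients": self.coefficients.tolist(),
                    "intercept": float(self.intercept),
                    "seed": self.seed,
                    "n_iterations": self.n_iterations,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["component_indices"], d["component_ids"],
            np.array(d["coefficients"]), d["intercept"],
            d.get("seed", 0), d.get("n_iterations", 0),
        )


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------


def _fit_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 60) -> tuple[np.ndarray, float]:
    """Ridge-jittered IRLS; returns (beta including intercept, log-likelihood)."""
    n, k = x.shape
    xa = np.column_stack([np.ones(n), x])
    beta = np.zeros(k + 1)
    for _ in range(max_iter):
        z = xa @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = xa.T @ (y - p) - _RIDGE * beta
        hess = (xa * w[:, None]).T @ xa + _RIDGE * np.eye(k + 1)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    z = xa @ beta
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return beta, ll


def _bic(ll: float, k_params: int, n: int) -> float:
    return -2.0 * ll + k_params * np.log(n)


def _stepwise_bic(x: np.ndarray, y: np.ndarray, max_features: int = 25) -> list[int]:
    """Forward selection: greedily add the feature that lowers BIC most."""
    n, n_feat = x.shape
    chosen: list[int] = []
    _, ll0 = _fit_logistic(np.empty((n, 0)), y)
    best_bic = _bic(ll0, 1, n)
    remaining = list(range(n_feat))
    while remaining and len(chosen) < max_features:
        cand_bic, cand_f = None, None
        for f in remaining:
            cols = chosen + [f]
            _, ll = _fit_logistic(x[:, cols], y)
            b = _bic(ll, len(cols) + 1, n)
            if cand_bic is None or b < cand_bic:
                cand_bic, cand_f = b, f
        if cand_bic >= best_bic:
            break
        best_bic = cand_bic
        chosen.append(cand_f)
        remaining.remove(cand_f)
    return chosen


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ValidationMetrics:
    """All values in percent.  Positive class = cancer = 1."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both classes must be present")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    f = 2.0 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return ValidationMetrics(sens, spec, acc, (sens + spec) / 2.0, prec, f)


def weighted_accuracy(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy from sensitivity and specificity (all in %)."""
    return (sensitivity + specificity) / 2.0


# ---------------------------------------------------------------------------
# multiple random validation
# ---------------------------------------------------------------------------


def _labels_to_binary(mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    assigned = np.flatnonzero(mask.labels != "unassigned")
    y = (mask.labels[assigned] == "cancer").astype(float)
    return assigned, y


def run_random_validation(
    table: FeatureTable,
    mask: RoiMask,
    n_iter: int = 50,
    seed: int = 0,
    max_features: int = 25,
) -> list[ValidationRun]:
    """Stratified 50/50 split, minority-size downsampling of the training
    pool, forward stepwise BIC logistic selection, metrics on the untouched
    test half.  Iteration seeds derive from the master seed."""
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    assigned, y = _labels_to_binary(mask)
    pos = assigned[y == 1]
    neg = assigned[y == 0]
    if min(pos.size, neg.size) < 10:
        raise ValidationError("minority class has fewer than 10 pixels")
    x_all = table.abundances.T
    is_cancer = mask.labels == "cancer"
    master = np.random.default_rng(seed)
    runs: list[ValidationRun] = []
    for it in range(n_iter):
        rng = np.random.default_rng(master.integers(2**63))
        tr_parts, te_parts = [], []
        for grp in (pos, neg):
            perm = rng.permutation(grp)
            half = grp.size // 2
            tr_parts.append(perm[:half])
            te_parts.append(perm[half:])
        train = np.concatenate(tr_parts)
        test = np.concatenate(te_parts)
        # downsample the training pool to the minority class size
        tr_pos = train[is_cancer[train]]
        tr_neg = train[~is_cancer[train]]
        m = min(tr_pos.size, tr_neg.size)
        tr_bal = np.concatenate(
            [rng.permutation(tr_pos)[:m], rng.permutation(tr_neg)[:m]]
        )
        sig = _stepwise_bic(
            x_all[tr_bal], is_cancer[tr_bal].astype(float), max_features
        )
        if sig:
            beta, _ = _fit_logistic(
                x_all[tr_bal][:, sig], is_cancer[tr_bal].astype(float)
            )
            z = x_all[test][:, sig] @ beta[1:] + beta[0]
        else:
            z = np.zeros(test.size)
        pred = z >= 0.0  # probability 0.5 threshold
        metrics = compute_metrics(is_cancer[test], pred)
        runs.append(ValidationRun(it, train, test, sig, metrics))
    return runs


def score_and_rank_features(
    runs: list[ValidationRun], table: FeatureTable
) -> list[FeatureScore]:
    """score(f) = sum over runs containing f of
    (test weighted accuracy as a fraction) * (L - pos + 1) / L.

    Rank descending, ties broken by ascending component m/z."""
    if not runs:
        raise ValidationError("no validation runs")
    scores = np.zeros(table.n_components)
    for run in runs:
        wacc = run.test_metrics.weighted_accuracy / 100.0
        L = len(run.signature)
        for pos, f in enumerate(run.signature):
            scores[f] += wacc * (L - pos) / L
    order = np.lexsort((table.component_ids, -scores))
    return [
        FeatureScore(
            component_id=float(table.component_ids[f]),
            component_index=int(f),
            score=float(scores[f]),
            rank=r,
        )
        for r, f in enumerate(order)
    ]


def _knee_index(values: np.ndarray) -> int:
    """0-based index of the knee: max distance to the chord, restricted to
    points on or above the chord of a decreasing curve.  Flat or 1-point
    curves give index 0."""
    v = np.asarray(values, dtype=float)
    k = v.size
    if k < 3 or np.allclose(v, v[0]):
        return 0
    xs = np.arange(k, dtype=float)
    dx, dy = xs[-1] - xs[0], v[-1] - v[0]
    norm = np.hypot(dx, dy)
    # signed cross product; points above the chord of a decreasing curve
    # have positive value
    cross = (dx * (v - v[0]) - dy * (xs - xs[0])) / norm
    above = cross > 0
    if not np.any(above):
        return 0
    return int(np.argmax(np.where(above, cross, -np.inf)))


def select_signature(
    scores: list[FeatureScore],
    runs: list[ValidationRun],
    table: FeatureTable,
    mask: RoiMask,
    seed: int = 0,
    plateau_tol: float = 0.5,
    max_k: int | None = None,
) -> list[int]:
    """Signature size from the knee of the score curve, advanced to the
    plateau of the top-k performance curve when that is larger."""
    if not scores:
        raise ValidationError("empty score list")
    svals = np.array([s.score for s in scores])
    nonzero = int(np.sum(svals > 0))
    if nonzero == 0:
        return [scores[0].component_index]
    knee_k = _knee_index(svals[: max(nonzero, 2)]) + 1
    k_cap = max_k or min(nonzero, 30)
    perf = _topk_performance(scores, table, mask, k_cap, seed)
    plateau_k = int(np.argmax(perf >= perf.max() - plateau_tol)) + 1
    k = max(knee_k, plateau_k)
    k = min(k, k_cap)
    return [s.component_index for s in scores[:k]]


def _topk_performance(
    scores: list[FeatureScore],
    table: FeatureTable,
    mask: RoiMask,
    k_cap: int,
    seed: int,
) -> np.ndarray:
    """Weighted accuracy of a classifier retrained on the top-k features,
    for k = 1..k_cap, on a fixed stratified split."""
    rng = np.random.default_rng(seed)
    assigned, y = _labels_to_binary(mask)
    pos, neg = assigned[y == 1], assigned[y == 0]
    tr_parts, te_parts = [], []
    for grp in (pos, neg):
        perm = rng.permutation(grp)
        half = grp.size // 2
        tr_parts.append(perm[:half])
        te_parts.append(perm[half:])
    train, test = np.concatenate(tr_parts), np.concatenate(te_parts)
    is_cancer = mask.labels == "cancer"
    tr_pos, tr_neg = train[is_cancer[train]], train[~is_cancer[train]]
    m = min(tr_pos.size, tr_neg.size)
    tr_bal = np.concatenate([rng.permutation(tr_pos)[:m], rng.permutation(tr_neg)[:m]])
    x_all = table.abundances.T
    out = np.empty(k_cap)
    for k in range(1, k_cap + 1):
        cols = [s.component_index for s in scores[:k]]
        beta, _ = _fit_logistic(x_all[tr_bal][:, cols], is_cancer[tr_bal].astype(float))
        pred = x_all[test][:, cols] @ beta[1:] + beta[0] >= 0
        out[k - 1] = compute_metrics(is_cancer[test], pred).weighted_accuracy
    return out


def train_classifier(
    table: FeatureTable,
    mask: RoiMask,
    n_iter: int = 50,
    seed: int = 0,
    max_features: int = 25,
) -> tuple[ClassifierModel, list[ValidationRun], list[FeatureScore]]:
    """Full training protocol: random validation, scoring, signature
    selection, final fit on the downsampled full training pool."""
    runs = run_random_validation(table, mask, n_iter, seed, max_features)
    scores = score_and_rank_features(runs, table)
    signature = select_signature(scores, runs, table, mask, seed=seed)
    rng = np.random.default_rng(seed + 1)
    assigned, y = _labels_to_binary(mask)
    pos, neg = assigned[y == 1], assigned[y == 0]
    m = min(pos.size, neg.size)
    bal = np.concatenate([rng.permutation(pos)[:m], rng.permutation(neg)[:m]])
    is_cancer = mask.labels == "cancer"
    beta, _ = _fit_logistic(
        table.abundances.T[bal][:, signature], is_cancer[bal].astype(float)
    )
    model = ClassifierModel(
        component_indices=signature,
        component_ids=[float(table.component_ids[f]) for f in signature],
        coefficients=beta[1:],
        intercept=float(beta[0]),
        seed=seed,
        n_iterations=n_iter,
    )
    return model, runs, scores


def evaluate_classifier(
    model: ClassifierModel,
    table: FeatureTable,
    mask: RoiMask,
    threshold: float = 0.5,
) -> ValidationMetrics:
    """Metrics of thresholded logistic probabilities on labelled pixels."""
    mask.require_two_groups()
    assigned = np.flatnonzero(mask.labels != "unassigned")
    proba = model.predict_proba(table)[assigned]
    y_true = mask.labels[assigned] == "cancer"
    return compute_metrics(y_true, proba >= threshold)


def probability_map(
    model: ClassifierModel,
    table: FeatureTable,
    coords: np.ndarray,
    mask: RoiMask | None = None,
) -> np.ndarray:
    """Cancer probability arranged on the raster grid; pixels without data
    (or unassigned, when a mask is given) are NaN."""
    proba = model.predict_proba(table)
    coords = np.asarray(coords, dtype=int)
    ny, nx = coords[:, 1].max() + 1, coords[:, 0].max() + 1
    img = np.full((ny, nx), np.nan)
    for p, (x, y) in enumerate(coords):
        if mask is not None and mask.labels[p] == "unassigned":
            continue
        img[y, x] = proba[p]
    return img


def feature_correlations(
    table: FeatureTable,
    signature: list[int],
    alpha: float = 0.05,
    min_effect: float = 0.5,
) -> pd.DataFrame:
    """Pairwise Pearson r between signature features with BH-adjusted p;
    ``reported`` marks pairs passing both the p and |r| thresholds."""
    if len(signature) < 2:
        raise ValidationError("signature must contain >= 2 features")
    rows = []
    for i in range(len(signature)):
        for j in range(i + 1, len(signature)):
            a = table.abundances[signature[i]]
            b = table.abundances[signature[j]]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rows.append((signature[i], signature[j], np.nan, np.nan))
                continue
            r, p = stats.pearsonr(a, b)
            rows.append((signature[i], signature[j], r, p))
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    valid = df["p"].notna()
    p_adj = np.full(len(df), np.nan)
    if valid.any():
        _, adj, _, _ = multipletests(df.loc[valid, "p"], method="fdr_bh")
        p_adj[valid.to_numpy()] = adj
    df["p_adj"] = p_adj
    df["reported"] = (df["p_adj"] < alpha) & (df["r"].abs() >= min_effect)
    return df
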