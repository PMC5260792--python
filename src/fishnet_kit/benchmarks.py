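"""Evaluation machinery: precision/recall, overlap, stability, CV, FPR.

Stability resampling draws ``size`` samples per class without replacement,
re-runs a selection method and records the binary selection vector per round;
the headline scalar is the mean pairwise Jaccard similarity between the
rounds' selection sets.  Cross-validation splits samples (stratified) into a
selection half, a training quarter and a validation quarter, selects
complexes on the first, and classifies the validation quarter with a
deterministic Gaussian naive Bayes trained on the constituent-protein
expressions of the selected complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ComplexSet, ValidationError
from .registry import resolve_method


# ---------------------------------------------------------------------------
# precision / recall / overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRSummary:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


def precision_recall_f(selected, truth: Mapping[str, bool]) -> PRSummary:
    """Precision, recall and F against complex-level ground truth.

    ``truth`` maps complex_id -> True when differential.  Degenerate 0/0
    ratios are defined as 0.
    """
    selected = set(selected)
    unknown = [cid for cid in selected if cid not in truth]
    if unknown:
        raise ValidationError(f"selected complexes without truth label: {sorted(unknown)}")
    differential = {cid for cid, is_diff in truth.items() if is_diff}
    tp = len(selected & differential)
    fp = len(selected - differential)
    fn = len(differential - selected)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PRSummary(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_score=f)


def set_overlap(t1, t2, mode: str = "jaccard") -> float:
    """|T1 n T2| / |T1 u T2| (jaccard) or / min(|T1|, |T2|) (min_normalized).

    Two empty sets overlap perfectly by convention (1.0).
    """
    t1, t2 = set(t1), set(t2)
    if mode not in ("jaccard", "min_normalized"):
        raise ValidationError(f"unknown overlap mode {mode!r}")
    if not t1 and not t2:
        return 1.0
    inter = len(t1 & t2)
    if mode == "jaccard":
        return inter / len(t1 | t2)
    denom = min(len(t1), len(t2))
    return inter / denom if denom else 0.0


# ---------------------------------------------------------------------------
# stability resampling
# ---------------------------------------------------------------------------

@dataclass
class StabilityMatrix:
    """Rounds x complexes binary selection matrix with its provenance."""

    data: pd.DataFrame
    size: int
    method: str
    reps: int
    seed: int | None


def mean_pairwise_jaccard(binary: pd.DataFrame) -> float:
    """Mean Jaccard similarity over all round pairs (empty pairs count 1)."""
    M = binary.to_numpy(dtype=float)
    r = M.shape[0]
    if r < 2:
        return float("nan")
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / union, 1.0)
    iu = np.triu_indices(r, k=1)
    return float(J[iu].mean())


def stability_summary(sm: StabilityMatrix) -> dict:
    """Row sums, per-complex selection frequencies and mean pairwise Jaccard."""
    data = sm.data
    return {
        "size": sm.size,
        "method": sm.method,
        "reps": sm.reps,
        "selected_per_round": data.sum(axis=1).tolist(),
        "selection_frequency": (data.sum(axis=0) / max(len(data), 1)).to_dict(),
        "mean_pairwise_jaccard": mean_pairwise_jaccard(data),
    }


def stability_resampling(
    matrix: pd.DataFrame,
    classes: pd.Series,
    complexes: ComplexSet,
    method: str | Callable,
    sizes: Sequence[int] = (4, 6, 8),
    reps: int = 1000,
    seed: int | None = None,
    method_params: dict | None = None,
) -> dict[int, StabilityMatrix]:
    """Per resampling size, a binary rounds x complexes selection matrix.

    Each round draws ``size`` samples per class (without replacement), runs
    the method and records which complexes it selects.
    """
    run = resolve_method(method, **(method_params or {}))
    name = method if isinstance(method, str) else getattr(method, "__name__", "callable")
    labels = sorted(pd.Series(classes).unique())
    cols_by_class = {lab: [s for s in matrix.columns if classes[s] == lab] for lab in labels}
    out: dict[int, StabilityMatrix] = {}
    ss = np.random.SeedSequence(seed)
    for size, child in zip(sizes, ss.spawn(len(sizes))):
        for lab in labels:
            if size > len(cols_by_class[lab]):
                raise ValidationError(
                    f"resampling size {size} exceeds class {lab!r} size {len(cols_by_class[lab])}"
                )
        rng = np.random.default_rng(child)
        rows = np.zeros((reps, len(complexes)), dtype=int)
        ids = complexes.ids()
        col_of = {cid: i for i, cid in enumerate(ids)}
        for r in range(reps):
            picked: list[str] = []
            for lab in labels:
                cols = cols_by_class[lab]
                picked.extend(cols[i] for i in rng.choice(len(cols), size=size, replace=False))
            sub = matrix[picked]
            res = run(sub, classes[picked], complexes)
            for cid in res.loc[res["selected"], "complex_id"]:
                rows[r, col_of[cid]] = 1
        out[size] = StabilityMatrix(
            data=pd.DataFrame(rows, columns=ids), size=size, method=str(name), reps=reps, seed=seed
        )
    return out


# ---------------------------------------------------------------------------
# deterministic Gaussian naive Bayes
# ---------------------------------------------------------------------------

def naive_bayes_fit_predict(
    train_features, train_labels, test_features, var_smoothing: float = 1e-2
) -> np.ndarray:
    """Gaussian naive Bayes with deterministic tie-breaking.

    Per class and feature, mean and (ML) variance are estimated from the
    training rows; variances are floored at ``var_smoothing`` * (global
    feature variance + 1).  With the quarter-sized training sets used in the
    cross-validation protocol (two or three samples per class), discrete
    count features are frequently near-constant within a class; a substantial
    floor keeps a single such feature from dominating the posterior.
    Features constant across the whole training set are skipped.  Prediction
    is argmax of log-prior plus summed log-likelihood; exact ties go to the
    lexicographically smaller class label.
    """
    X = np.asarray(train_features, dtype=float)
    T = np.asarray(test_features, dtype=float)
    y = np.asarray([str(v) for v in train_labels])
    if X.ndim != 2 or T.ndim != 2 or X.shape[1] != T.shape[1]:
        raise ValidationError("train and test features must be 2-D with identical columns")
    labels = sorted(set(y))
    if any((y == lab).sum() < 1 for lab in labels):
        raise ValidationError("each class needs at least one training sample")
    global_var = X.var(axis=0)
    keep = global_var > 0
    floor = var_smoothing * (global_var + 1.0)
    log_post = np.zeros((T.shape[0], len(labels)))
    n = len(y)
    for k, lab in enumerate(labels):
        rows = X[y == lab]
        prior = len(rows) / n
        mu = rows.mean(axis=0)
        var = np.maximum(rows.var(axis=0), floor)
        ll = -0.5 * (np.log(2 * np.pi * var[keep]) + (T[:, keep] - mu[keep]) ** 2 / var[keep])
        log_post[:, k] = np.log(prior) + ll.sum(axis=1)
    # argmax returns the first (lexicographically smallest) label on ties
    return np.asarray(labels, dtype=object)[np.argmax(log_post, axis=1)]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVRecord:
    repetition: int
    scenario: str
    accuracy: float
    n_selected_complexes: int
    fallback: bool


def _majority(labels: Sequence[str]) -> str:
    counts = pd.Series(list(labels)).value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def cross_validate(
    matrix: pd.DataFrame,
    classes: pd.Series,
    complexes: ComplexSet,
    method: str | Callable,
    reps: int = 1000,
    seed: int | None = None,
    scenario: str = "real",
    method_params: dict | None = None,
) -> pd.DataFrame:
    """Selection-then-classification CV, repeated with random stratified splits.

    Per repetition: (optionally) shuffle labels; per class reserve a quarter
    for validation, a quarter for training and the rest for feature
    selection; run the method on the selection part; featurize samples by the
    expressions of proteins inside selected complexes; fit the deterministic
    naive Bayes on the training quarter and score the validation quarter.
    When no complex is selected the majority training class is predicted
    (recorded as ``fallback``).
    """
    if scenario not in ("real", "shuffled"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    run = resolve_method(method, **(method_params or {}))
    labels = sorted(pd.Series(classes).unique())
    for lab in labels:
        if (classes == lab).sum() < 4:
            raise ValidationError("cross-validation needs at least 4 samples per class")
    ss = np.random.SeedSequence(seed)
    records: list[CVRecord] = []
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        work = classes.copy()
        if scenario == "shuffled":
            vals = work.to_numpy(copy=True)
            work = pd.Series(vals[rng.permutation(len(vals))], index=work.index)
        sel_cols: list[str] = []
        train_cols: list[str] = []
        val_cols: list[str] = []
        for lab in labels:
            cols = [s for s in matrix.columns if work[s] == lab]
            q = len(cols) // 4
            if q < 1:
                raise ValidationError("a class quarter is empty; need >= 4 samples per class")
            order = [cols[i] for i in rng.permutation(len(cols))]
            val_cols.extend(order[:q])
            train_cols.extend(order[q : 2 * q])
            sel_cols.extend(order[2 * q :])
        res = run(matrix[sel_cols], work[sel_cols], complexes)
        picked = list(res.loc[res["selected"], "complex_id"])
        present = set(matrix.index)
        proteins = sorted(
            {m for cid in picked for m in complexes.members(cid) if m in present}
        )
        truth_val = work[val_cols].to_numpy()
        if proteins:
            preds = naive_bayes_fit_predict(
                matrix.loc[proteins, train_cols].T.to_numpy(),
                work[train_cols].to_numpy(),
                matrix.loc[proteins, val_cols].T.to_numpy(),
            )
            fallback = False
        else:
            preds = np.asarray([_majority(work[train_cols])] * len(val_cols), dtype=object)
            fallback = True
        acc = float(np.mean(preds == truth_val))
        records.append(CVRecord(rep, scenario, acc, len(picked), fallback))
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# false-positive evaluation on pseudo-classes
# ---------------------------------------------------------------------------

def false_positive_eval(
    matrix: pd.DataFrame,
    complexes: ComplexSet,
    method: str | Callable,
    reps: int = 100,
    seed: int | None = None,
    method_params: dict | None = None,
) -> pd.DataFrame:
    """Null selection rates from random halvings of one-class samples.

    The matrix should contain samples of a single condition; per round they
    are split randomly into two pseudo-classes and the method's selection
    fraction is recorded.  An odd sample count is reduced to the largest
    even subset (the last column is dropped).
    """
    run = resolve_method(method, **(method_params or {}))
    cols = list(matrix.columns)
    if len(cols) % 2 == 1:
        cols = cols[:-1]
    if len(cols) < 4:
        raise ValidationError("false-positive evaluation needs at least 4 samples")
    sub = matrix[cols]
    half = len(cols) // 2
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(cols))
        labels = np.empty(len(cols), dtype=object)
        labels[perm[:half]] = "pseudo_a"
        labels[perm[half:]] = "pseudo_b"
        res = run(sub, pd.Series(labels, index=cols), complexes)
        n_sel = int(res["selected"].sum())
        rows.append(
            {"round": rep, "n_selected": n_sel, "rate": n_sel / len(res) if len(res) else 0.0}
        )
    return pd.DataFrame(rows)
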