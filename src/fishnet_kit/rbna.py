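"""Rank-based network comparators: QPSP, SNET, FSNET and PFSNET.

All four convert per-sample abundance ranks into weights (``fs``), then test
complex-level summaries of those weights between two classes:

QPSP
    Per sample, the hit-rate of complex C is the weight-sum of its members
    divided by the number of members measured in the screen; hit-rates are
    compared between classes with the pooled-variance two-sample t (two-sided).
SNET / FSNET
    beta(g, C_j) is the class-average weight of protein g;
    score(S, p, C_j) = sum_{g in S} fs(g, p) * beta(g, C_j).  For each
    weighting direction, scores of the weighting class are compared against
    the other class with a Welch t-test, significant in the upper 5% tail.
    SNET uses binary weights, FSNET the fractional fuzzy weights.
PFSNET
    delta(S, p) = score(S, p, X) - score(S, p, Y) over all samples p in
    X union Y; a one-sample t (mean / standard error, |Z|-1 df) tests the
    upper tail, once per direction.

Directional methods report one row per complex carrying both one-sided
p-values (``p_up_class1``, ``p_up_class2``); ``p_value`` is their minimum and
``selected`` is the union-over-directions rule at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .base import BaseComplexSelector, coerce_classes
from .data_io import ComplexSet, ValidationError
from .weighting import WeightScheme, compute_weights

TINY_P = float(np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: float


def two_sample_t(xs, ys, welch: bool = False) -> TTestResult:
    """Two-sample t statistic, pooled-variance by default, two-sided p.

    ``welch=True`` uses per-class variances with Welch-Satterthwaite degrees
    of freedom.  Zero variance with equal means gives t=0, p=1; zero variance
    with unequal means gives the minimum representable p.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValidationError("two_sample_t needs at least 2 observations per group")
    t, p, df = _t_arrays(xs[None, :], ys[None, :], welch=welch, one_sided=False)
    return TTestResult(float(t[0]), float(p[0]), float(df[0]))


def _t_arrays(
    X: np.ndarray, Y: np.ndarray, welch: bool, one_sided: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise t-tests for stacked observations (rows = complexes)."""
    m, n = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    diff = mx - my
    if welch:
        se2 = vx / m + vy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (vx**2 / (m**2 * (m - 1)) + vy**2 / (n**2 * (n - 1)))
    else:
        sp2 = ((m - 1) * vx + (n - 1) * vy) / (m + n - 2)
        se2 = sp2 * (1.0 / m + 1.0 / n)
        df = np.full_like(se2, float(m + n - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    degenerate = se2 <= 0
    t_degen = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(degenerate, t_degen, t)
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    if one_sided:
        p = stats.t.sf(t, df)
        p = np.where(degenerate, np.where(diff == 0, 1.0, np.where(diff > 0, TINY_P, 1.0)), p)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(degenerate, np.where(diff == 0, 1.0, TINY_P), p)
    return t, np.clip(p, 0.0, 1.0), df


# ---------------------------------------------------------------------------
# QPSP primitives
# ---------------------------------------------------------------------------

def qpsp_hit_rates(weights: pd.DataFrame, complexes: ComplexSet) -> pd.DataFrame:
    """Hit-rate H(S, C) = weight-sum of measured members / number measured.

    ``weights`` is a proteins x samples fractional fuzzy weight table; the
    result is a complexes x samples table of hit-rates in [0, 1].
    """
    present = set(weights.index)
    pos = {p: i for i, p in enumerate(weights.index)}
    W = weights.to_numpy(dtype=float)
    rows = []
    for cid in complexes:
        members = [pos[m] for m in complexes.members(cid) if m in present]
        if not members:
            raise ValidationError(f"complex {cid!r} has no member measured in the matrix")
        rows.append(W[members].sum(axis=0) / len(members))
    return pd.DataFrame(rows, index=complexes.ids(), columns=weights.columns)


# ---------------------------------------------------------------------------
# SNET-family primitives
# ---------------------------------------------------------------------------

def snet_beta(weights: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """beta(g, C) = class-average weight of g (proportion for binary weights)."""
    labels = sorted(pd.Series(classes).unique())
    out = {}
    for lab in labels:
        cols = [s for s in weights.columns if classes[s] == lab]
        out[lab] = weights[cols].mean(axis=1)
    return pd.DataFrame(out)


def snet_score(
    members, sample_id: str, weights: pd.DataFrame, beta: pd.DataFrame, weighting_class: str
) -> float:
    """score(S, p, C_j) = sum over measured members of fs(g, p) * beta(g, C_j)."""
    present = [m for m in members if m in weights.index]
    if not present:
        return 0.0
    fs = weights.loc[present, sample_id].to_numpy(dtype=float)
    b = beta.loc[present, weighting_class].to_numpy(dtype=float)
    return float((fs * b).sum())


def _score_matrix(M: np.ndarray, W: np.ndarray, beta_col: np.ndarray) -> np.ndarray:
    """Complexes x samples score table: M @ (W * beta[:, None])."""
    return M.astype(float) @ (W * beta_col[:, None])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class QPSP(BaseComplexSelector):
    """Hit-rate signature profiling with a pooled-variance two-sample t-test."""

    method_name = "qpsp"

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        alpha1: float = 0.10,
        alpha2: float = 0.20,
        n_bins: int = 4,
        min_identified: int = 3,
        protein_ids=None,
    ):
        super().__init__(complexes=complexes, alpha=alpha, min_identified=min_identified, protein_ids=protein_ids)
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_bins = n_bins

    def _scheme(self) -> WeightScheme:
        return WeightScheme("fuzzy_fractional", self.alpha1, self.alpha2, self.n_bins)

    def _run(self, matrix, classes, complexes):
        labels, idx1, idx2 = self._class_columns(matrix, classes)
        weights = compute_weights(matrix, self._scheme())
        H = qpsp_hit_rates(weights, complexes).to_numpy()
        t, p, _ = _t_arrays(H[:, idx1], H[:, idx2], welch=False, one_sided=False)
        direction = np.where(t > 0, "up_in_class1", np.where(t < 0, "up_in_class2", "none"))
        return self._assemble(complexes, t, p, direction, p < self.alpha, class_labels=labels)


class SNet(BaseComplexSelector):
    """SNET/FSNET: class-weighted complex scores, one-sided Welch t, both
    weighting directions unioned.  ``fuzzy=False`` is SNET (binary weights),
    ``fuzzy=True`` is FSNET (fractional fuzzy weights)."""

    method_name = "snet"

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        fuzzy: bool = False,
        alpha1: float = 0.10,
        alpha2: float = 0.20,
        n_bins: int = 4,
        min_identified: int = 3,
        protein_ids=None,
    ):
        super().__init__(complexes=complexes, alpha=alpha, min_identified=min_identified, protein_ids=protein_ids)
        self.fuzzy = fuzzy
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_bins = n_bins

    def _scheme(self) -> WeightScheme:
        name = "fuzzy_fractional" if self.fuzzy else "binary"
        return WeightScheme(name, self.alpha1, self.alpha2, self.n_bins)

    def _run(self, matrix, classes, complexes):
        labels, idx1, idx2 = self._class_columns(matrix, classes)
        weights = compute_weights(matrix, self._scheme())
        W = weights.to_numpy()
        M = self._membership(matrix, complexes)
        beta = snet_beta(weights, classes)
        ps, ts = [], []
        for lab, own_idx, other_idx in ((labels[0], idx1, idx2), (labels[1], idx2, idx1)):
            S = _score_matrix(M, W, beta[lab].to_numpy())
            t, p, _ = _t_arrays(S[:, own_idx], S[:, other_idx], welch=True, one_sided=True)
            ts.append(t)
            ps.append(p)
        return _directional_results(self, complexes, labels, ts, ps, self.alpha)


class FSNet(SNet):
    """FSNET: SNET with fractional fuzzy weights."""

    method_name = "fsnet"

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        alpha1: float = 0.10,
        alpha2: float = 0.20,
        n_bins: int = 4,
        min_identified: int = 3,
        protein_ids=None,
    ):
        super().__init__(
            complexes=complexes, alpha=alpha, fuzzy=True, alpha1=alpha1, alpha2=alpha2,
            n_bins=n_bins, min_identified=min_identified, protein_ids=protein_ids,
        )

    # fuzzy stays a constructor-fixed True; exclude it from get_params so
    # sklearn.clone can reconstruct the subclass
    def get_params(self, deep=True):
        params = super().get_params(deep=deep)
        params.pop("fuzzy", None)
        return params


class PFSNet(BaseComplexSelector):
    """Paired FSNET: per-sample score differences tested with a one-sample t."""

    method_name = "pfsnet"
    _min_per_class = 1  # needs >= 3 samples overall, checked in _run

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        alpha1: float = 0.10,
        alpha2: float = 0.20,
        n_bins: int = 4,
        min_identified: int = 3,
        protein_ids=None,
    ):
        super().__init__(complexes=complexes, alpha=alpha, min_identified=min_identified, protein_ids=protein_ids)
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_bins = n_bins

    def _scheme(self) -> WeightScheme:
        return WeightScheme("fuzzy_fractional", self.alpha1, self.alpha2, self.n_bins)

    def _run(self, matrix, classes, complexes):
        nz = matrix.shape[1]
        if nz < 3:
            raise ValidationError("PFSNET needs at least 3 samples in total")
        labels, _, _ = self._class_columns(matrix, classes)
        weights = compute_weights(matrix, self._scheme())
        W = weights.to_numpy()
        M = self._membership(matrix, complexes)
        beta = snet_beta(weights, classes)
        delta = _score_matrix(M, W, beta[labels[0]].to_numpy()) - _score_matrix(
            M, W, beta[labels[1]].to_numpy()
        )
        mean = delta.mean(axis=1)
        sd = delta.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = mean / (sd / np.sqrt(nz))
        degenerate = sd == 0
        t1 = np.where(degenerate, np.where(mean == 0, 0.0, np.where(mean > 0, np.inf, -np.inf)), t1)
        df = nz - 1
        p1 = np.where(
            degenerate, np.where(mean == 0, 1.0, np.where(mean > 0, TINY_P, 1.0)),
            stats.t.sf(t1, df),
        )
        p2 = np.where(
            degenerate, np.where(mean == 0, 1.0, np.where(mean < 0, TINY_P, 1.0)),
            stats.t.sf(-t1, df),
        )
        return _directional_results(self, complexes, labels, [t1, -t1], [p1, p2], self.alpha)


def _directional_results(est, complexes, labels, ts, ps, alpha) -> pd.DataFrame:
    """Fold per-direction one-sided tests into one row per complex."""
    p1, p2 = np.clip(ps[0], 0, 1), np.clip(ps[1], 0, 1)
    pick2 = p2 < p1
    p = np.where(pick2, p2, p1)
    t = np.where(pick2, ts[1], ts[0])
    direction = np.where(p1 < p2, "up_in_class1", np.where(p2 < p1, "up_in_class2", "none"))
    selected = p < alpha
    return est._assemble(
        complexes, t, p, direction, selected,
        extra={"p_up_class1": p1, "p_up_class2": p2}, class_labels=labels,
    )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def qpsp_test(matrix, classes, complexes, alpha=0.05, alpha1=0.10, alpha2=0.20,
              n_bins=4, min_identified=3) -> pd.DataFrame:
    classes = coerce_classes(matrix, classes)
    est = QPSP(complexes=complexes, alpha=alpha, alpha1=alpha1, alpha2=alpha2,
               n_bins=n_bins, min_identified=min_identified)
    est.fit(matrix.T, classes.to_numpy())
    return est.results_


def snet_family_test(matrix, classes, complexes, variant="snet", alpha=0.05,
                     alpha1=0.10, alpha2=0.20, n_bins=4, min_identified=3) -> pd.DataFrame:
    """SNET (binary weights) or FSNET (fuzzy weights) selection."""
    if variant not in ("snet", "fsnet"):
        raise ValidationError(f"unknown variant {variant!r}")
    classes = coerce_classes(matrix, classes)
    cls = FSNet if variant == "fsnet" else SNet
    est = cls(complexes=complexes, alpha=alpha, alpha1=alpha1, alpha2=alpha2,
              n_bins=n_bins, min_identified=min_identified)
    est.fit(matrix.T, classes.to_numpy())
    return est.results_


def pfsnet_test(matrix, classes, complexes, alpha=0.05, alpha1=0.10, alpha2=0.20,
                n_bins=4, min_identified=3) -> pd.DataFrame:
    classes = coerce_classes(matrix, classes)
    est = PFSNet(complexes=complexes, alpha=alpha, alpha1=alpha1, alpha2=alpha2,
                 n_bins=n_bins, min_identified=min_identified)
    est.fit(matrix.T, classes.to_numpy())
    return est.results_
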