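"""Classical comparators: hypergeometric enrichment and KS-based set testing.

Hypergeometric enrichment (HE) is the two-stage over-representation test:
per-protein two-sample t-tests produce a differential list, then each complex
is scored by the upper hypergeometric tail of its overlap with that list.

The KS comparator ("GSEA" in the direct-group sense) ranks all proteins by a
class-contrast score and compares the rank distribution of in-complex
proteins (D) against out-of-complex proteins (D') with a two-sample
Kolmogorov-Smirnov statistic; a complex is selected when
KS >= c(alpha) * sqrt((|D|+|D'|)/(|D|*|D'|)), with c(0.05) = 1.36.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .base import BaseComplexSelector, coerce_classes
from .data_io import ComplexSet, ValidationError

KS_CRITICAL_05 = 1.36  # critical multiplier c(alpha) at alpha = 0.05


# ---------------------------------------------------------------------------
# exact hypergeometric tail
# ---------------------------------------------------------------------------

def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


@dataclass(frozen=True)
class HypergeomParams:
    """Universe size N, complex size B, differential-list size n, overlap b."""

    N: int
    B: int
    n: int
    b: int

    def validate(self) -> None:
        if min(self.N, self.B, self.n, self.b) < 0:
            raise ValidationError("hypergeometric parameters must be non-negative")
        if self.B > self.N or self.n > self.N:
            raise ValidationError("B and n cannot exceed N")
        if self.b > min(self.n, self.B):
            raise ValidationError(f"overlap b={self.b} exceeds min(n, B)={min(self.n, self.B)}")


def hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """P(X >= b) for the overlap X of a size-B complex with a size-n list.

    Computed as sum_{i=b}^{min(n,B)} C(n,i) C(N-n,B-i) / C(N,B) in
    log-gamma space; returns a value in (0, 1].
    """
    HypergeomParams(N, B, n, b).validate()
    if b == 0:
        return 1.0
    hi = min(n, B)
    lo = max(b, B - (N - n))  # terms below lo have C(N-n, B-i) = 0
    log_denom = _log_comb(N, B)
    log_terms = [_log_comb(n, i) + _log_comb(N - n, B - i) - log_denom for i in range(lo, hi + 1)]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    p = math.exp(m) * math.fsum(math.exp(t - m) for t in log_terms)
    return min(1.0, p)


def protein_t_table(
    matrix: pd.DataFrame, classes: pd.Series, equal_var: bool = False
) -> pd.DataFrame:
    """Per-protein two-sample t between the two classes (Welch by default).

    Proteins with zero variance in both classes and equal means get t=0, p=1.
    Returns a DataFrame with columns ``t`` (class1 minus class2) and ``p``.
    """
    labels = sorted(classes.unique())
    idx1 = np.asarray([classes[s] == labels[0] for s in matrix.columns], dtype=bool)
    a = matrix.to_numpy(dtype=float)[:, idx1]
    b = matrix.to_numpy(dtype=float)[:, ~idx1]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each class needs at least 2 samples for a t-test")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant proteins trigger scipy's near-identical-data warning; the
        # resulting nan statistics are mapped to t=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    p[~np.isfinite(p)] = 1.0
    return pd.DataFrame({"t": t, "p": p}, index=matrix.index)


# ---------------------------------------------------------------------------
# KS statistic for two rank samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """Two-sample KS statistic with the printed rejection threshold."""

    ks: float
    threshold: float
    significant: bool
    n_in: int
    n_out: int
    p_value: float  # asymptotic Kolmogorov p, reference only


def ks_statistic(in_set_values, out_set_values, alpha: float = 0.05) -> KSResult:
    """max_x |ECDF_D(x) - ECDF_D'(x)| with threshold c(alpha)*sqrt((m+n)/(m n)).

    ECDFs are normalized fractions.  c(0.05) is the printed constant 1.36;
    other alpha levels use the inverse Kolmogorov distribution.
    """
    d = np.sort(np.asarray(in_set_values, dtype=float))
    dp = np.sort(np.asarray(out_set_values, dtype=float))
    m, n = len(d), len(dp)
    if m == 0 or n == 0:
        raise ValidationError("both rank sets must be non-empty")
    grid = np.concatenate([d, dp])
    f1 = np.searchsorted(d, grid, side="right") / m
    f2 = np.searchsorted(dp, grid, side="right") / n
    ks = float(np.max(np.abs(f1 - f2)))
    c = KS_CRITICAL_05 if alpha == 0.05 else float(special.kolmogi(alpha))
    threshold = c * math.sqrt((m + n) / (m * n))
    en = math.sqrt(m * n / (m + n))
    p = float(special.kolmogorov(en * ks))
    return KSResult(ks=ks, threshold=threshold, significant=ks >= threshold, n_in=m, n_out=n, p_value=p)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class HypergeomEnrichment(BaseComplexSelector):
    """Two-stage hypergeometric enrichment over protein complexes.

    Stage 1: per-protein two-sample t-test (Welch unless ``equal_var``);
    proteins with p < ``t_alpha`` form the differential list.  Stage 2: the
    upper hypergeometric tail of each complex's overlap with that list.
    ``fdr='bh'`` optionally applies Benjamini-Hochberg to the stage-2
    p-values before selection (off by default).
    """

    method_name = "he"

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        t_alpha: float = 0.05,
        equal_var: bool = False,
        fdr: str | None = None,
        min_identified: int = 3,
        protein_ids=None,
    ):
        super().__init__(complexes=complexes, alpha=alpha, min_identified=min_identified, protein_ids=protein_ids)
        self.t_alpha = t_alpha
        self.equal_var = equal_var
        self.fdr = fdr

    def _run(self, matrix, classes, complexes):
        labels = sorted(classes.unique())
        ttab = protein_t_table(matrix, classes, equal_var=self.equal_var)
        diff = set(ttab.index[ttab["p"] < self.t_alpha])
        N = matrix.shape[0]
        n = len(diff)
        present = set(matrix.index)
        stat, pvals = [], []
        for cid in complexes:
            members = [m for m in complexes.members(cid) if m in present]
            B = len(members)
            b = sum(1 for m in members if m in diff)
            stat.append(float(b))
            pvals.append(hypergeom_tail(N, B, n, b))
        pvals = np.asarray(pvals)
        adj = stats.false_discovery_control(pvals) if self.fdr == "bh" and len(pvals) else pvals
        selected = adj < self.alpha
        self.n_differential_proteins_ = n
        return self._assemble(
            complexes, np.asarray(stat), pvals, ["none"] * len(complexes), selected,
            class_labels=labels,
        )


class KSEnrichment(BaseComplexSelector):
    """Direct-group KS test of in-complex vs out-of-complex contrast ranks.

    Proteins are ranked by the signed Welch t-statistic (class1 minus class2,
    rank 1 = largest); the paper leaves the ranking score unstated, so this
    choice is documented and deliberate.  Selection follows the printed
    threshold rule; ``p_value`` is the asymptotic Kolmogorov p for reference.
    """

    method_name = "gsea"

    def _run(self, matrix, classes, complexes):
        labels = sorted(classes.unique())
        ttab = protein_t_table(matrix, classes, equal_var=False)
        ids = matrix.index.to_numpy(dtype=str)
        order = np.lexsort((ids, -ttab["t"].to_numpy()))
        ranks = np.empty(len(ids), dtype=float)
        ranks[order] = np.arange(1, len(ids) + 1)
        rank_of = pd.Series(ranks, index=matrix.index)
        present = set(matrix.index)
        stat, pvals, selected = [], [], []
        for cid in complexes:
            members = [m for m in complexes.members(cid) if m in present]
            in_mask = rank_of.index.isin(members)
            if in_mask.all():
                raise ValidationError(
                    f"complex {cid!r} covers every matrix protein; out-set is empty"
                )
            res = ks_statistic(rank_of[in_mask], rank_of[~in_mask], alpha=self.alpha)
            stat.append(res.ks)
            pvals.append(res.p_value)
            selected.append(res.significant)
        return self._assemble(
            complexes, np.asarray(stat), np.asarray(pvals), ["none"] * len(complexes),
            np.asarray(selected), class_labels=labels,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def he_test(
    matrix: pd.DataFrame,
    classes,
    complexes: ComplexSet,
    t_alpha: float = 0.05,
    alpha: float = 0.05,
    equal_var: bool = False,
    fdr: str | None = None,
    min_identified: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment on a proteins x samples matrix."""
    classes = coerce_classes(matrix, classes)
    est = HypergeomEnrichment(
        complexes=complexes, alpha=alpha, t_alpha=t_alpha, equal_var=equal_var,
        fdr=fdr, min_identified=min_identified,
    )
    est.fit(matrix.T, classes.to_numpy())
    return est.results_


def gsea_test(
    matrix: pd.DataFrame,
    classes,
    complexes: ComplexSet,
    alpha: float = 0.05,
    min_identified: int = 3,
) -> pd.DataFrame:
    """KS-based direct-group complex test on a proteins x samples matrix."""
    classes = coerce_classes(matrix, classes)
    est = KSEnrichment(complexes=complexes, alpha=alpha, min_identified=min_identified)
    est.fit(matrix.T, classes.to_numpy())
    return est.results_
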