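"""Fuzzy-FishNET: integer rank weights pooled into a one-sided Fisher test.

The method replaces hypergeometric enrichment's t-test pre-selection with a
rank-derived weight per protein per sample (integer fuzzy scheme 5..0), pools
the weights per class into a 2x2 contingency table

                    in complex S    not in complex S
    class J samples      a                b
    class K samples      c                d

and scores the complex with the one-sided Fisher exact tail
P(first cell >= a | marginals).  Both class orientations are tested and a
complex is selected when either one-sided p falls below alpha.  The ablation
FishNET removes the rank tiers while holding coverage fixed: uniform weight 1
across the whole considered region (the top alpha2 fraction), 0 elsewhere, on
the identical code path, isolating the contribution of fuzzification.

The integer weight units are part of the method definition: the exact test
treats weight sums as pseudo-counts, so rescaling the scheme changes
p-values.  Fractional weights are rejected rather than rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import BaseComplexSelector, coerce_classes
from .data_io import ComplexSet, ValidationError
from .rbna import _directional_results
from .weighting import WeightScheme, compute_weights


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of pooled weight counts; rows are classes J and K."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p: tables with the same marginals, first cell >= a.

    The point probability of a table is the hypergeometric
    C(a+b, k) C(c+d, m-k) / C(n, m) with m = a+c; the tail sums k = a .. kmax
    in log-gamma space.  Returns a value in (0, 1].
    """
    table = ContingencyTable(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        return 1.0
    r1, r2, m = a + b, c + d, a + c
    if a <= max(0, m - r2):
        return 1.0  # a at its minimum given the marginals: the tail is everything
    kmax = min(r1, m)
    log_denom = _log_comb(n, m)
    log_terms = [
        _log_comb(r1, k) + _log_comb(r2, m - k) - log_denom for k in range(a, kmax + 1)
    ]
    if not log_terms:
        return 0.0
    mx = max(log_terms)
    p = math.exp(mx) * math.fsum(math.exp(t - mx) for t in log_terms)
    return min(1.0, p)


def _integer_weight_values(weights: pd.DataFrame) -> np.ndarray:
    vals = weights.to_numpy(dtype=float)
    rounded = np.rint(vals)
    if not np.allclose(vals, rounded, atol=1e-9):
        raise ValidationError(
            "contingency pooling requires integer-valued weights; "
            "use the fuzzy_integer or binary scheme, not fuzzy_fractional"
        )
    return rounded.astype(np.int64)


def ff_contingency(
    weights: pd.DataFrame, classes: pd.Series, members, j_class: str | None = None
) -> ContingencyTable:
    """Pool integer weights into the 2x2 table for one complex.

    Row J (cells a, b) is ``j_class`` (default: the lexicographically smaller
    label); a/c are the weight sums over complex members, b/d over all other
    matrix proteins.
    """
    W = _integer_weight_values(weights)
    labels = sorted(pd.Series(classes).unique())
    if j_class is None:
        j_class = labels[0]
    if j_class not in labels:
        raise ValidationError(f"unknown class {j_class!r}")
    idx_j = np.asarray([classes[s] == j_class for s in weights.columns], dtype=bool)
    in_mask = weights.index.isin(list(members))
    a = int(W[np.ix_(in_mask, idx_j)].sum())
    b = int(W[np.ix_(~in_mask, idx_j)].sum())
    c = int(W[np.ix_(in_mask, ~idx_j)].sum())
    d = int(W[np.ix_(~in_mask, ~idx_j)].sum())
    return ContingencyTable(a, b, c, d)


class FishNet(BaseComplexSelector):
    """Fuzzy-FishNET selector (``fuzzy=True``) and its unweighted ablation.

    With ``fuzzy=True`` proteins get integer weights 5..0 by rank percentile;
    with ``fuzzy=False`` every protein in the considered region (the top
    ``alpha2`` fraction) gets uniform weight 1 and everything else 0, so the
    two variants see the same proteins and differ only in the rank tiers.
    Each complex is tested in both class orientations with the one-sided
    Fisher exact tail; ``selected`` is the union at level alpha.
    """

    method_name = "ffishnet"
    _min_per_class = 1

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        fuzzy: bool = True,
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
        if self.fuzzy:
            return WeightScheme("fuzzy_integer", self.alpha1, self.alpha2, self.n_bins)
        # unweighted ablation: same coverage as the fuzzy scheme, no tiers
        return WeightScheme("binary", self.alpha2, self.alpha2, self.n_bins)

    def _run(self, matrix, classes, complexes):
        labels, idx1, idx2 = self._class_columns(matrix, classes)
        weights = compute_weights(matrix, self._scheme())
        W = _integer_weight_values(weights)
        M = self._membership(matrix, complexes)
        s1 = W[:, idx1].sum(axis=1)  # per-protein weight mass, class 1
        s2 = W[:, idx2].sum(axis=1)
        tot1, tot2 = int(s1.sum()), int(s2.sum())
        a_vec = M.astype(np.int64) @ s1
        c_vec = M.astype(np.int64) @ s2
        p1 = np.empty(len(a_vec))
        p2 = np.empty(len(a_vec))
        stat1 = np.empty(len(a_vec))
        for i, (a, c) in enumerate(zip(a_vec, c_vec)):
            a, c = int(a), int(c)
            b, d = tot1 - a, tot2 - c
            p1[i] = fisher_tail(a, b, c, d)
            p2[i] = fisher_tail(c, d, a, b)
            stat1[i] = float(a)
        self.method_name = "ffishnet" if self.fuzzy else "fishnet"
        return _directional_results(self, complexes, labels, [stat1, c_vec.astype(float)], [p1, p2], self.alpha)


def fishnet_test(
    matrix: pd.DataFrame,
    classes,
    complexes: ComplexSet,
    fuzzy: bool = True,
    alpha: float = 0.05,
    alpha1: float = 0.10,
    alpha2: float = 0.20,
    n_bins: int = 4,
    min_identified: int = 3,
) -> pd.DataFrame:
    """Fuzzy-FishNET (or, with ``fuzzy=False``, unweighted FishNET)."""
    classes = coerce_classes(matrix, classes)
    est = FishNet(complexes=complexes, alpha=alpha, fuzzy=fuzzy, alpha1=alpha1,
                  alpha2=alpha2, n_bins=n_bins, min_identified=min_identified)
    est.fit(matrix.T, classes.to_numpy())
    return est.results_
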