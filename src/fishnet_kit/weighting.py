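"""Per-sample rank percentiles and the three rank-weight schemes.

Every method in this package starts from the same primitive: within each
sample, proteins are ranked by abundance and the top-ranked fraction receives
a weight.  Three schemes are used:

``binary``
    1 for proteins in the top ``alpha1`` fraction, 0 otherwise (SNET).
``fuzzy_fractional``
    1 for the top ``alpha1`` fraction; the band (alpha1, alpha2] is divided
    into ``n_bins`` equal-width bins weighted 0.8, 0.6, 0.4, 0.2 with the
    defaults (QPSP, FSNET, PFSNET); 0 below the top ``alpha2`` fraction.
``fuzzy_integer``
    Same bands with integer weights 5, 4, 3, 2, 1, 0 (Fuzzy-FishNET); the
    integer units matter because downstream they are summed as pseudo-counts
    in an exact test.

Rank conventions
----------------
Only proteins with positive abundance in a sample compete for ranks: an
unobserved protein (value 0) is placed at percentile 1.0 and always weighs 0.
Percentile = ordinal rank (1 = most abundant) / number of positive proteins
in the sample, so "top 10%" means percentile <= 0.10.  Ties are broken by
protein ID (ascending), which makes every weight matrix deterministic across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ValidationError

_EPS = 1e-9

SCHEME_NAMES = ("binary", "fuzzy_fractional", "fuzzy_integer")


@dataclass(frozen=True)
class WeightScheme:
    """A named rank-weighting scheme with its percentile cut-offs."""

    name: str
    alpha1: float = 0.10
    alpha2: float = 0.20
    n_bins: int = 4

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValidationError(f"unknown weight scheme {self.name!r}")
        if not (0 < self.alpha1 <= self.alpha2 <= 1):
            raise ValidationError(
                f"need 0 < alpha1 <= alpha2 <= 1, got alpha1={self.alpha1}, alpha2={self.alpha2}"
            )
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")

    @property
    def top_weight(self) -> float:
        if self.name == "fuzzy_integer":
            return float(self.n_bins + 1)
        return 1.0

    def weight_for_percentile(self, percentile: float) -> float:
        """Scalar weight for one percentile value (reference implementation)."""
        return float(
            assign_weights(pd.DataFrame([[percentile]], index=["g"], columns=["s"]), self).iat[0, 0]
        )


def percentile_ranks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank percentiles, most abundant first.

    Within each sample, proteins with positive values get percentile
    rank/n_positive (rank 1 = most abundant, ties broken by protein ID);
    proteins with value 0 get percentile 1.0.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("expression matrix is empty")
    values = matrix.to_numpy(dtype=float)
    ids = matrix.index.to_numpy(dtype=str)
    out = np.ones_like(values, dtype=float)
    for j, sample in enumerate(matrix.columns):
        v = values[:, j]
        n_pos = int((v > 0).sum())
        if n_pos == 0:
            raise ValidationError(f"sample {sample!r} has no positive abundances")
        order = np.lexsort((ids, -v))  # value descending, protein ID ascending on ties
        order = order[v[order] > 0]
        out[order, j] = np.arange(1, n_pos + 1, dtype=float) / n_pos
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def assign_weights(ranks: pd.DataFrame, scheme: WeightScheme) -> pd.DataFrame:
    """Map percentile ranks to weights under ``scheme``.

    The top region is [0, alpha1]; the fuzzy band (alpha1, alpha2] is split
    into ``n_bins`` half-open equal-width bins with descending weights; beyond
    alpha2 the weight is 0.  The binary scheme ignores alpha2.
    """
    p = ranks.to_numpy(dtype=float)
    top = p <= scheme.alpha1 + _EPS
    w = np.zeros_like(p)
    if scheme.name == "binary":
        w[top] = 1.0
    else:
        full = scheme.n_bins + 1
        w[top] = full
        if scheme.alpha2 > scheme.alpha1:
            mid = (~top) & (p <= scheme.alpha2 + _EPS)
            width = (scheme.alpha2 - scheme.alpha1) / scheme.n_bins
            bin_idx = np.ceil((p - scheme.alpha1) / width - _EPS)
            bin_idx = np.clip(bin_idx, 1, scheme.n_bins)
            w = np.where(mid, full - bin_idx, w)
        if scheme.name == "fuzzy_fractional":
            w = w / full
    return pd.DataFrame(w, index=ranks.index, columns=ranks.columns)


def compute_weights(matrix: pd.DataFrame, scheme: WeightScheme) -> pd.DataFrame:
    """Convenience: percentile ranks then weights in one step."""
    return assign_weights(percentile_ranks(matrix), scheme)
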