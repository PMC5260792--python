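"""Shared scaffolding for the complex-selection estimators.

All seven methods are exposed as scikit-learn style selectors: ``fit(X, y)``
takes a samples x proteins table (a DataFrame whose columns are protein IDs,
or an ndarray plus a ``protein_ids`` constructor argument) and two-class
labels ``y``; the fitted estimator carries a per-complex result table and a
boolean feature support mask (proteins belonging to at least one selected
complex), so it composes with sklearn pipelines as a feature-selection step.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import (
    ComplexSet,
    ValidationError,
    filter_complexes,
    validate_expression_matrix,
    validate_sample_classes,
)

DIRECTIONS = ("up_in_class1", "up_in_class2", "none")


class BaseComplexSelector(BaseEstimator):
    """Base class: input coercion, complex filtering, support computation.

    Subclasses implement ``_run(matrix, classes, complexes)`` returning a
    result DataFrame with at least the canonical columns (complex_id, method,
    statistic, p_value, direction, selected).  ``class1`` is always the
    lexicographically smaller label.
    """

    method_name = "base"
    _min_per_class = 2

    def __init__(
        self,
        complexes: ComplexSet | None = None,
        alpha: float = 0.05,
        min_identified: int = 3,
        protein_ids: Sequence[str] | None = None,
    ):
        self.complexes = complexes
        self.alpha = alpha
        self.min_identified = min_identified
        self.protein_ids = protein_ids

    # -- plumbing ----------------------------------------------------------

    def _coerce(self, X, y) -> tuple[pd.DataFrame, pd.Series]:
        if isinstance(X, pd.DataFrame):
            matrix = X.T
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValidationError("X must be 2-dimensional (samples x proteins)")
            if self.protein_ids is not None:
                if len(self.protein_ids) != X.shape[1]:
                    raise ValidationError("protein_ids length does not match X columns")
                index = [str(p) for p in self.protein_ids]
            else:
                index = [f"P{i}" for i in range(X.shape[1])]
            matrix = pd.DataFrame(
                X.T, index=index, columns=[f"S{i}" for i in range(X.shape[0])]
            )
        matrix = validate_expression_matrix(matrix)
        y = np.asarray(y)
        if len(y) != matrix.shape[1]:
            raise ValidationError(
                f"y has {len(y)} labels for {matrix.shape[1]} samples"
            )
        classes = pd.Series([str(v) for v in y], index=matrix.columns, name="class")
        validate_sample_classes(classes, min_per_class=self._min_per_class)
        return matrix, classes

    def fit(self, X, y):
        """Run the complex-level test and derive the protein support mask."""
        if self.complexes is None:
            raise ValidationError(f"{type(self).__name__} requires a ComplexSet")
        matrix, classes = self._coerce(X, y)
        filtered = filter_complexes(self.complexes, matrix, self.min_identified)
        self.classes_ = sorted(classes.unique())
        self.complex_set_ = filtered
        self.results_ = self._run(matrix, classes, filtered)
        sel = self.results_.loc[self.results_["selected"], "complex_id"]
        self.selected_complexes_ = list(sel)
        present = set(matrix.index)
        selected_proteins: set[str] = set()
        for cid in self.selected_complexes_:
            selected_proteins.update(m for m in filtered.members(cid) if m in present)
        self.selected_proteins_ = sorted(selected_proteins)
        feature_names = list(matrix.index)
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = len(feature_names)
        self.support_ = np.array([p in selected_proteins for p in feature_names], dtype=bool)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "results_"):
            raise ValidationError(f"{type(self).__name__} is not fitted")

    def get_support(self, indices: bool = False):
        self._check_fitted()
        return np.flatnonzero(self.support_) if indices else self.support_.copy()

    def transform(self, X):
        """Restrict X to proteins inside the selected complexes."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            keep = [c for c, s in zip(self.feature_names_in_, self.support_) if s]
            return X.loc[:, keep]
        X = np.asarray(X)
        return X[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    # -- to implement ------------------------------------------------------

    def _run(self, matrix: pd.DataFrame, classes: pd.Series, complexes: ComplexSet) -> pd.DataFrame:
        raise NotImplementedError

    # -- helpers for subclasses --------------------------------------------

    @staticmethod
    def _class_columns(matrix: pd.DataFrame, classes: pd.Series) -> tuple[list[str], np.ndarray, np.ndarray]:
        labels = sorted(classes.unique())
        idx1 = np.asarray([classes[s] == labels[0] for s in matrix.columns], dtype=bool)
        return labels, idx1, ~idx1

    @staticmethod
    def _membership(matrix: pd.DataFrame, complexes: ComplexSet) -> np.ndarray:
        """Boolean complexes x proteins membership over matrix rows."""
        pos = {p: i for i, p in enumerate(matrix.index)}
        M = np.zeros((len(complexes), matrix.shape[0]), dtype=bool)
        for k, cid in enumerate(complexes):
            for m in complexes.members(cid):
                i = pos.get(m)
                if i is not None:
                    M[k, i] = True
        return M

    def _assemble(
        self,
        complexes: ComplexSet,
        statistic: np.ndarray,
        p_value: np.ndarray,
        direction: Sequence[str],
        selected: np.ndarray,
        extra: dict[str, np.ndarray] | None = None,
        class_labels: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "complex_id": complexes.ids(),
                "method": self.method_name,
                "statistic": np.asarray(statistic, dtype=float),
                "p_value": np.clip(np.asarray(p_value, dtype=float), 0.0, 1.0),
                "direction": list(direction),
                "selected": np.asarray(selected, dtype=bool),
            }
        )
        if extra:
            for k, v in extra.items():
                df[k] = v
        if class_labels is not None:
            df.attrs["class1"], df.attrs["class2"] = class_labels
        return df


def coerce_classes(matrix: pd.DataFrame, classes) -> pd.Series:
    """Align a labels mapping/sequence with the matrix sample columns."""
    if isinstance(classes, pd.Series):
        missing = [s for s in matrix.columns if s not in classes.index]
        if missing:
            raise ValidationError(f"samples without class label: {missing}")
        return classes.reindex(matrix.columns).astype(str)
    if isinstance(classes, dict):
        return coerce_classes(matrix, pd.Series(classes))
    classes = list(classes)
    if len(classes) != matrix.shape[1]:
        raise ValidationError("class labels do not match number of samples")
    return pd.Series([str(c) for c in classes], index=matrix.columns, name="class")
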