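"""Readers, writers and structural validation for the three input kinds.

File formats
------------
Expression matrix
    Tab-separated, header row of sample IDs, first column of protein IDs,
    non-negative numeric cells (spectral counts or any abundance proxy).
Sample labels
    Two-column TSV ``sample_id <tab> class``; a header line
    ``sample_id\tclass`` is accepted and skipped.  Exactly two distinct
    class labels are allowed.
Complex sets
    GMT: one set per line, tab-separated fields ``name``, ``description``,
    then one or more member protein IDs.
Results
    TSV with columns ``complex_id``, ``method``, ``statistic``, ``p_value``,
    ``direction``, ``selected``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

RESULT_COLUMNS = ["complex_id", "method", "statistic", "p_value", "direction", "selected"]


class ValidationError(ValueError):
    """An input file or in-memory object violates a structural invariant."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the protein x sample invariants and return the matrix as float64.

    Invariants: unique protein and sample IDs, all values finite and >= 0,
    at least two samples.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise ValidationError("expression matrix must be a pandas DataFrame")
    dup_p = _duplicates(list(map(str, matrix.index)))
    if dup_p:
        raise ValidationError(f"duplicate protein IDs: {dup_p}")
    dup_s = _duplicates(list(map(str, matrix.columns)))
    if dup_s:
        raise ValidationError(f"duplicate sample IDs: {dup_s}")
    if matrix.shape[1] < 2:
        raise ValidationError("expression matrix needs at least 2 samples")
    try:
        values = matrix.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric value in expression matrix: {exc}") from exc
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite value at protein {matrix.index[i]!r}, sample {matrix.columns[j]!r}"
        )
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative value {values[i, j]} at protein {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    out = matrix.astype(float)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read and validate a protein x sample TSV; preserves row/column order."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
    if len(header) < 2:
        raise ValidationError(f"{path}: header must contain at least one sample ID")
    sample_ids = [str(s) for s in header[1:]]
    dup_s = _duplicates(sample_ids)
    if dup_s:
        raise ValidationError(f"{path}: duplicate sample IDs: {dup_s}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, skiprows=1, header=None)
    df.columns = sample_ids
    df.index = df.index.astype(str)
    dup_p = _duplicates(list(df.index))
    if dup_p:
        raise ValidationError(f"{path}: duplicate protein IDs: {dup_p}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at protein "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at protein {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return validate_expression_matrix(numeric)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id")


# ---------------------------------------------------------------------------
# sample classes
# ---------------------------------------------------------------------------

def validate_sample_classes(
    classes: pd.Series,
    matrix: pd.DataFrame | None = None,
    min_per_class: int = 1,
) -> pd.Series:
    """Check the two-class invariant; optionally check coverage of a matrix."""
    classes = pd.Series(classes).astype(str)
    classes.index = classes.index.astype(str)
    labels = sorted(classes.unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two class labels required, got {labels}")
    for lab in labels:
        n = int((classes == lab).sum())
        if n < min_per_class:
            raise ValidationError(
                f"class {lab!r} has {n} samples; at least {min_per_class} required"
            )
    if matrix is not None:
        missing = [s for s in matrix.columns if s not in classes.index]
        if missing:
            raise ValidationError(f"samples without class label: {missing}")
        classes = classes.reindex(matrix.columns)
    return classes


def read_sample_classes(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id <tab> class`` TSV into a Series."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            if lineno == 1 and parts == ["sample_id", "class"]:
                continue
            rows.append((parts[0], parts[1]))
    if not rows:
        raise ValidationError(f"{path}: no sample labels found")
    ids = [r[0] for r in rows]
    dup = _duplicates(ids)
    if dup:
        raise ValidationError(f"{path}: duplicate sample IDs: {dup}")
    return pd.Series({s: c for s, c in rows}, name="class").reindex(ids)


def write_sample_classes(classes: pd.Series, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tclass\n")
        for s, c in classes.items():
            fh.write(f"{s}\t{c}\n")


# ---------------------------------------------------------------------------
# complex sets
# ---------------------------------------------------------------------------

@dataclass
class ComplexSet:
    """Named protein groups with optional ground-truth differential flags.

    ``complexes`` maps complex_id -> ordered, deduplicated member list.
    ``truth`` (optional) maps complex_id -> True for differential complexes.
    """

    complexes: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    truth: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if not members:
                raise ValidationError(f"complex {cid!r} has no members")
            if len(set(members)) != len(members):
                self.complexes[cid] = list(dict.fromkeys(members))

    def ids(self) -> list[str]:
        return list(self.complexes)

    def members(self, cid: str) -> list[str]:
        return self.complexes[cid]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.complexes)

    def __contains__(self, cid: str) -> bool:
        return cid in self.complexes

    def subset(self, ids: Iterable[str]) -> "ComplexSet":
        ids = list(ids)
        return ComplexSet(
            complexes={cid: list(self.complexes[cid]) for cid in ids},
            descriptions={cid: self.descriptions.get(cid, "") for cid in ids},
            truth=None if self.truth is None else {cid: self.truth[cid] for cid in ids if cid in self.truth},
        )


def read_complexes_gmt(path: str | Path) -> ComplexSet:
    """Parse a GMT file: ``name<tab>description<tab>member...`` per line."""
    path = Path(path)
    complexes: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: complex {name!r} has an empty member list")
            if name in complexes:
                raise ValidationError(f"{path}:{lineno}: duplicate complex ID {name!r}")
            complexes[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return ComplexSet(complexes=complexes, descriptions=descriptions)


def write_complexes_gmt(complexes: ComplexSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for cid in complexes:
            desc = complexes.descriptions.get(cid, "")
            fh.write("\t".join([cid, desc, *complexes.members(cid)]) + "\n")


def read_complex_truth(path: str | Path) -> dict[str, bool]:
    """Read a ``complex_id <tab> differential|non_differential`` TSV."""
    truth: dict[str, bool] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if parts == ["complex_id", "status"]:
                continue
            if len(parts) != 2 or parts[1] not in ("differential", "non_differential"):
                raise ValidationError(f"{path}:{lineno}: malformed truth line {line!r}")
            truth[parts[0]] = parts[1] == "differential"
    return truth


def write_complex_truth(truth: Mapping[str, bool], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("complex_id\tstatus\n")
        for cid, is_diff in truth.items():
            fh.write(f"{cid}\t{'differential' if is_diff else 'non_differential'}\n")


def filter_complexes(
    complexes: ComplexSet, matrix: pd.DataFrame, min_identified: int = 3
) -> ComplexSet:
    """Keep complexes with >= ``min_identified`` members present in the matrix.

    A protein counts as identified when it is a row of the matrix, regardless
    of zero counts in individual samples.  Truth labels are carried through.
    """
    if min_identified < 1:
        raise ValidationError("min_identified must be >= 1")
    present = set(map(str, matrix.index))
    keep = [
        cid
        for cid in complexes
        if sum(1 for m in complexes.members(cid) if m in present) >= min_identified
    ]
    return complexes.subset(keep)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical six-column result table as TSV."""
    results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: result table missing columns {missing}")
    return df
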