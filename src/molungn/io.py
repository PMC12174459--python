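"""Tabular I/O and sample alignment for multi-omics feature matrices.

The canonical on-disk format is a CSV whose header row carries feature names
and whose first column carries sample identifiers (TSV accepted via ``sep``).
Missing cells are kept as NaN — they are *recorded*, never silently imputed;
the preprocessing stage decides what to do with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsView",
    "LabelSet",
    "FormatError",
    "AlignmentError",
    "read_view",
    "write_view",
    "read_labels",
    "write_labels",
    "align_views",
    "read_mapping",
]


class FormatError(ValueError):
    """A file violates the tabular contract (duplicates, bad cells)."""


class AlignmentError(ValueError):
    """Views and labels cannot be brought onto a common sample set."""


@dataclass
class OmicsView:
    """One omics modality: an n-samples x p-features value matrix.

    ``values`` is float64; NaN marks a missing (not yet imputed) entry.
    """

    view_name: str
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            dup = _first_duplicate(self.feature_names)
            raise FormatError(f"duplicate feature name: {dup!r}")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, view_name: str) -> "OmicsView":
        return cls(view_name, list(df.index.astype(str)),
                   list(df.columns.astype(str)),
                   df.to_numpy(dtype=np.float64))

    def subset_samples(self, ids: Sequence[str]) -> "OmicsView":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return OmicsView(self.view_name, list(ids), list(self.feature_names),
                         self.values[idx])

    def subset_features(self, names: Sequence[str]) -> "OmicsView":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        idx = [pos[f] for f in names]
        return OmicsView(self.view_name, list(self.sample_ids), list(names),
                         self.values[:, idx])


@dataclass
class LabelSet:
    """Sample -> class-code assignment with stable, sorted class names."""

    sample_ids: list[str]
    class_codes: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_codes = np.asarray(self.class_codes, dtype=np.int64)
        self.class_names = [str(c) for c in self.class_names]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample id: {_first_duplicate(self.sample_ids)!r}")
        if len(self.class_codes) != len(self.sample_ids):
            raise FormatError("one class code per sample id required")
        if self.C < 2:
            raise FormatError("C must be >= 2 (at least two distinct classes)")
        if self.class_codes.min(initial=0) < 0 or \
                self.class_codes.max(initial=0) >= self.C:
            raise FormatError("class codes must lie in [0, C)")

    @property
    def C(self) -> int:
        return len(self.class_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_series(self) -> pd.Series:
        names = np.asarray(self.class_names, dtype=object)
        return pd.Series(names[self.class_codes], index=self.sample_ids,
                         name="label")

    @classmethod
    def from_series(cls, s: pd.Series) -> "LabelSet":
        names = sorted(set(str(v) for v in s))
        code = {name: i for i, name in enumerate(names)}
        return cls(list(s.index.astype(str)),
                   np.array([code[str(v)] for v in s], dtype=np.int64), names)

    def subset(self, ids: Sequence[str]) -> "LabelSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return LabelSet(list(ids), self.class_codes[idx], list(self.class_names))


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""  # pragma: no cover


# -- readers / writers -------------------------------------------------------

def read_view(path, view_name: str, sep: str = ",") -> OmicsView:
    """Read a feature matrix; empty cells become NaN, junk cells raise."""
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers; check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise FormatError(f"{path.name}: duplicate feature name {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate sample id {dup!r}")
    df.columns = header
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=np.float64)
    empty = np.vectorize(lambda c: str(c).strip() == "", otypes=[bool])(raw)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]).replace("", np.nan),
                            errors="coerce").to_numpy()
        bad = np.isnan(col) & ~empty[:, j]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path.name}: non-numeric cell {raw[i, j]!r} at sample "
                f"{df.index[i]!r}, feature {df.columns[j]!r}")
        values[:, j] = col
    return OmicsView(view_name, list(df.index.astype(str)),
                     list(df.columns.astype(str)), values)


def write_view(view: OmicsView, path, sep: str = ",") -> None:
    """Write in the canonical dialect; NaN renders as an empty cell."""
    view.to_frame().to_csv(path, sep=sep, na_rep="")


def read_labels(path, sep: str = ",") -> LabelSet:
    """Two-column table sample_id,label; codes follow sorted label order."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise FormatError(f"{Path(path).name}: expected two columns, "
                          f"got {df.shape[1]}")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    return LabelSet.from_series(s)


def write_labels(labels: LabelSet, path, sep: str = ",") -> None:
    df = labels.to_series().rename_axis("sample_id").reset_index()
    df.to_csv(path, sep=sep, index=False)


def read_mapping(path, sep: str = "\t") -> dict[str, str]:
    """Two-column feature-renaming table (e.g. CpG site -> gene symbol)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise FormatError(f"{Path(path).name}: mapping needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# -- alignment ----------------------------------------------------------------

def align_views(views: Sequence[OmicsView],
                labels: LabelSet) -> tuple[list[OmicsView], LabelSet]:
    """Restrict all views and labels to their common samples.

    Samples absent from any view or from the labels are dropped (the dropped
    set is logged).  The canonical sample order after alignment is the
    lexicographic sort of the surviving identifiers, which removes any
    dependence on input row order.
    """
    if not views:
        raise AlignmentError("need at least one view")
    common = set(labels.sample_ids)
    for v in views:
        common &= set(v.sample_ids)
    if not common:
        raise AlignmentError("no sample id is shared by all views and labels")
    order = sorted(common)
    universe = set(labels.sample_ids).union(*(set(v.sample_ids) for v in views))
    dropped = sorted(universe - common)
    if dropped:
        logger.info("align_views: dropped %d sample(s): %s",
                    len(dropped), ", ".join(dropped[:10]) +
                    ("..." if len(dropped) > 10 else ""))
    return [v.subset_samples(order) for v in views], labels.subset(order)
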