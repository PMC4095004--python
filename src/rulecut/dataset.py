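"""Expression cohort container and delimited-text I/O.

The canonical layout is samples in rows, features (probe sets) in columns,
with non-negative continuous intensities on a MAS5-like scale.  Microarray
exports frequently ship transposed (probes in rows); `read_expression_table`
takes an orientation flag for those.  Labels and survival annotations live
in separate small tables keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with class labels.

    Attributes
    ----------
    sample_ids, feature_ids : lists of unique identifiers.
    values : float ndarray of shape (n, d); no missing entries allowed.
    labels : optional per-sample class names (length n, vocabulary size >= 2
        once present).
    survival_time, survival_event : optional per-sample time-to-event in
        years (>= 0) and event indicator (1 = event, 0 = censored).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: list[str] | None = None
    survival_time: np.ndarray | None = None
    survival_event: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("dataset needs at least one sample and one feature")
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError("identifier lists do not match matrix shape")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} identifiers: {list(dupes[:5])}")
        if np.isnan(self.values).any():
            i, j = map(int, np.argwhere(np.isnan(self.values))[0])
            raise ValueError(
                f"missing value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}")
        if self.labels is not None:
            self.labels = [str(y) for y in self.labels]
            if len(self.labels) != n:
                raise ValueError("labels length does not match sample count")
        if self.survival_time is not None:
            self.survival_time = np.asarray(self.survival_time, dtype=float)
            self.survival_event = np.asarray(self.survival_event, dtype=int)
            if self.survival_time.shape != (n,) or self.survival_event.shape != (n,):
                raise ValueError("survival columns do not match sample count")
            if (self.survival_time < 0).any():
                raise ValueError("negative survival time")
            if not np.isin(self.survival_event, (0, 1)).all():
                raise ValueError("event indicator must be 0/1")

    # -- basic shape -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def class_names(self) -> tuple[str, ...]:
        """Label vocabulary in order of first appearance."""
        if self.labels is None:
            return ()
        seen: list[str] = []
        for y in self.labels:
            if y not in seen:
                seen.append(y)
        return tuple(seen)

    def feature_index(self, feature: str) -> int:
        try:
            return self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"feature {feature!r} not in dataset") from None

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.feature_index(feature)]

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.feature_ids, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx],
            [self.labels[i] for i in idx] if self.labels is not None else None,
            self.survival_time[idx] if self.survival_time is not None else None,
            self.survival_event[idx] if self.survival_event is not None else None,
        )

    def with_labels(self, labels: Sequence[str]) -> "ExpressionDataset":
        return replace(self, labels=list(labels))


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    # engine="python" + sep=None sniffs the delimiter
    return pd.read_csv(path, sep=delimiter, index_col=0,
                       engine="python" if delimiter is None else "c")


def read_expression_table(path, probes_in_rows: bool = False,
                          delimiter: str | None = None) -> ExpressionDataset:
    """Load a delimited expression matrix into canonical orientation.

    Parameters
    ----------
    path : delimited text file with a header row and an identifier column.
    probes_in_rows : set True for transposed exports (features in rows).
    delimiter : explicit delimiter; sniffed when None.
    """
    df = _read_table(path, delimiter)
    if probes_in_rows:
        df = df.T
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric cell at row {df.index[bad.argmax()]!r}, "
                    f"column {col!r} in {path}") from None
        raise
    return ExpressionDataset(list(df.index), list(df.columns), values)


def read_labels(path, delimiter: str | None = None) -> pd.Series:
    """Two-column labels file (sample_id, class) -> Series indexed by sample."""
    df = _read_table(path, delimiter)
    if df.shape[1] != 1:
        raise ValueError(f"labels file {path} must have exactly two columns")
    return df.iloc[:, 0].astype(str)


def read_survival(path, delimiter: str | None = None) -> pd.DataFrame:
    """Three-column survival file (sample_id, time, event) -> DataFrame."""
    df = _read_table(path, delimiter)
    if df.shape[1] != 2:
        raise ValueError(f"survival file {path} must have exactly three columns")
    df.columns = ["time", "event"]
    return df.astype({"time": float, "event": int})


def attach_labels(dataset: ExpressionDataset, labels: pd.Series) -> ExpressionDataset:
    """Align a labels Series to the dataset's samples and attach it."""
    missing = [s for s in dataset.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    return dataset.with_labels([labels[s] for s in dataset.sample_ids])


def attach_survival(dataset: ExpressionDataset, surv: pd.DataFrame) -> ExpressionDataset:
    missing = [s for s in dataset.sample_ids if s not in surv.index]
    if missing:
        raise ValueError(f"samples without survival data: {missing[:5]}")
    surv = surv.loc[dataset.sample_ids]
    return replace(dataset, survival_time=surv["time"].to_numpy(),
                   survival_event=surv["event"].to_numpy())


def write_expression_table(dataset: ExpressionDataset, path, sep: str = "\t") -> None:
    dataset.to_frame().to_csv(path, sep=sep)


def write_labels(dataset: ExpressionDataset, path, sep: str = "\t") -> None:
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    pd.Series(dataset.labels, index=dataset.sample_ids, name="class") \
        .rename_axis("sample_id").to_csv(path, sep=sep)


def write_survival(dataset: ExpressionDataset, path, sep: str = "\t") -> None:
    if dataset.survival_time is None:
        raise ValueError("dataset has no survival annotations")
    pd.DataFrame({"time": dataset.survival_time, "event": dataset.survival_event},
                 index=dataset.sample_ids).rename_axis("sample_id").to_csv(path, sep=sep)
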