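"""Labeled fixed-length accelerometer segment datasets.

A *segment* is a block of consecutive accelerometer samples treated as one
classification unit and labeled with the behavior observed while it was
recorded.  Datasets are stored wide: one row per segment, samples interleaved
per axis (``x, y, z, x, y, z, ...`` for triaxial data) with the behavior label
in the trailing column.  This module reads, writes, validates and converts
between that layout and the two raw-stream layouts common on biologging
trackers: a headerless interleaved token stream (``x y z x y z ...``) and a
long four-column table (``timestamp, x, y, z``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    AlignmentError,
    FormatError,
    OrderingError,
    ParameterError,
    ParseError,
    ShapeError,
)

__all__ = [
    "SegmentDataset",
    "read_segments",
    "write_segments",
    "from_long_stream",
    "from_interleaved_stream",
    "order_by_label",
]

#: Label assigned by stream converters when no behavior labels are supplied.
UNLABELLED = "UNLABELLED"

AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class SegmentDataset:
    """Matrix of even-length accelerometer segments with behavior labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_segments, seg_len * n_axes)``; each row is
        one segment with samples interleaved per axis in ``x, y, z`` order.
    labels
        One behavior name per segment.
    n_axes
        Number of accelerometer axes (1, 2 or 3).
    samp_freq
        Sampling frequency in Hz.  Optional, but required by the
        frequency-domain features.
    """

    values: np.ndarray
    labels: np.ndarray
    n_axes: int
    samp_freq: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if self.n_axes not in (1, 2, 3):
            raise ParameterError(f"n_axes must be 1, 2 or 3, got {self.n_axes}")
        if values.ndim != 2:
            raise ShapeError(f"values must be 2-D, got shape {values.shape}")
        if labels.shape != (values.shape[0],):
            raise ShapeError(
                f"{values.shape[0]} segments but {labels.shape[0]} labels"
            )
        if values.shape[0] > 0:
            width = values.shape[1]
            if width % self.n_axes != 0:
                raise ShapeError(
                    f"row width {width} is not divisible by n_axes={self.n_axes}"
                )
            if width // self.n_axes < 2:
                raise ShapeError(
                    f"segments must hold at least 2 samples per axis, "
                    f"got {width // self.n_axes}"
                )
            if not np.all(np.isfinite(values)):
                raise ParseError("dataset contains non-finite values")
            for i, lab in enumerate(labels):
                if not isinstance(lab, str) or lab == "":
                    raise FormatError(f"label of segment {i} is not a non-empty string")
        if self.samp_freq is not None and not self.samp_freq > 0:
            raise ParameterError(f"samp_freq must be positive, got {self.samp_freq}")

    # -- geometry -------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def seg_len(self) -> int:
        """Samples per segment per axis."""
        if self.values.shape[1] == 0:
            return 0
        return self.values.shape[1] // self.n_axes

    def axis_view(self) -> np.ndarray:
        """Return the data de-interleaved as ``(n_segments, seg_len, n_axes)``."""
        return self.values.reshape(self.n_segments, self.seg_len, self.n_axes)

    def with_samp_freq(self, samp_freq: float) -> "SegmentDataset":
        return replace(self, samp_freq=samp_freq)

    def class_counts(self) -> dict[str, int]:
        """Segment count per behavior, keyed by label."""
        names, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


def _parse_rows(rows: list[list[str]], n_axes: int, path: str) -> SegmentDataset:
    if not rows:
        return SegmentDataset(np.empty((0, 0)), np.empty((0,), dtype=object), n_axes)
    width = len(rows[0])
    start = 0
    # optional header: a first row whose data cells are not all numeric
    try:
        [float(tok) for tok in rows[0][:-1]]
    except ValueError:
        start = 1
    data_rows = rows[start:]
    if not data_rows:
        return SegmentDataset(np.empty((0, 0)), np.empty((0,), dtype=object), n_axes)
    values = np.empty((len(data_rows), width - 1), dtype=float)
    labels = np.empty(len(data_rows), dtype=object)
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {start + i + 1} has {len(row)} fields, expected {width}"
            )
        for j, tok in enumerate(row[:-1]):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {start + i + 1}, "
                    f"column {j + 1}"
                ) from None
        labels[i] = row[-1].strip()
    if (width - 1) % n_axes != 0:
        raise ShapeError(
            f"{path}: {width - 1} data columns not divisible by n_axes={n_axes}"
        )
    return SegmentDataset(values, labels, n_axes)


def read_segments(
    path: str | Path, n_axes: int = 3, samp_freq: float | None = None
) -> SegmentDataset:
    """Read a wide comma-separated segment table.

    The last column holds the behavior label; all preceding columns are
    numeric acceleration samples interleaved per axis.  A header row is
    auto-detected (any non-numeric cell outside the label column).

    Raises
    ------
    FormatError
        If rows have unequal widths.
    ParseError
        If a data cell is not numeric (the message names row and column).
    ShapeError
        If the data width is not divisible by ``n_axes``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    ds = _parse_rows(rows, n_axes, str(path))
    if samp_freq is not None:
        ds = ds.with_samp_freq(samp_freq)
    return ds


def write_segments(ds: SegmentDataset, path: str | Path) -> None:
    """Write a dataset as a header-less wide CSV (12 significant digits).

    ``read_segments(write_segments(ds))`` reproduces labels exactly and
    values to text round-trip precision.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row, lab in zip(ds.values, ds.labels):
            writer.writerow([f"{v:.12g}" for v in row] + [str(lab)])


def from_long_stream(
    records: Sequence[Sequence[float]] | np.ndarray,
    seg_len: int,
    labels: Sequence[str] | None = None,
    samp_freq: float | None = None,
) -> SegmentDataset:
    """Block a long ``timestamp, x, y, z`` stream into triaxial segments.

    Consecutive non-overlapping blocks of ``seg_len`` records become one row
    each, with samples interleaved ``x, y, z`` per sample.  A trailing partial
    block is dropped rather than padded.  When ``labels`` is None every
    segment receives the sentinel label ``"UNLABELLED"``.
    """
    if seg_len < 2:
        raise ParameterError(f"seg_len must be >= 2, got {seg_len}")
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise FormatError(
            f"long stream must have 4 columns (timestamp, x, y, z), "
            f"got shape {arr.shape}"
        )
    ts = arr[:, 0]
    if np.any(np.diff(ts) < 0):
        raise OrderingError("timestamps are not monotone non-decreasing")
    n_segments = arr.shape[0] // seg_len
    if n_segments == 0:
        raise FormatError(
            f"stream of {arr.shape[0]} records shorter than seg_len={seg_len}"
        )
    xyz = arr[: n_segments * seg_len, 1:4]
    values = xyz.reshape(n_segments, seg_len * 3)
    return SegmentDataset(
        values, _stream_labels(labels, n_segments), n_axes=3, samp_freq=samp_freq
    )


def _stream_labels(labels: Sequence[str] | None, n_segments: int) -> np.ndarray:
    if labels is None:
        return np.full(n_segments, UNLABELLED, dtype=object)
    if len(labels) != n_segments:
        raise AlignmentError(
            f"expected {n_segments} labels (one per segment), got {len(labels)}"
        )
    return np.asarray(list(labels), dtype=object)


def from_interleaved_stream(
    tokens: Sequence[float] | np.ndarray,
    seg_len: int,
    n_axes: int = 3,
    labels: Sequence[str] | None = None,
    samp_freq: float | None = None,
) -> SegmentDataset:
    """Block a flat interleaved token stream (``x y z x y z ...``) into segments.

    Applies the same non-overlapping blocking rule as :func:`from_long_stream`
    to the flat stream: each segment consumes ``seg_len * n_axes`` tokens and
    a trailing partial block is dropped.
    """
    if seg_len < 2:
        raise ParameterError(f"seg_len must be >= 2, got {seg_len}")
    arr = np.asarray(tokens, dtype=float).ravel()
    width = seg_len * n_axes
    n_segments = arr.shape[0] // width
    if n_segments == 0:
        raise FormatError(
            f"stream of {arr.shape[0]} tokens shorter than one segment "
            f"({width} tokens)"
        )
    values = arr[: n_segments * width].reshape(n_segments, width)
    return SegmentDataset(
        values, _stream_labels(labels, n_segments), n_axes=n_axes, samp_freq=samp_freq
    )


def order_by_label(ds: SegmentDataset) -> SegmentDataset:
    """Return a new dataset with rows stably sorted by behavior label.

    Labels sort lexicographically ascending; segments sharing a label keep
    their original relative order, so the operation is idempotent and a pure
    permutation of rows.
    """
    order = np.argsort(ds.labels.astype(str), kind="stable")
    return SegmentDataset(
        ds.values[order], ds.labels[order], ds.n_axes, ds.samp_freq
    )
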