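"""Reading and writing signals, dissimilarity matrices and assessment tables.

Signals travel as plain one-column text files (optional single header line);
dissimilarity matrices as labelled TSV. A best-effort loader for MAT v5
bundles of preprocessed pulse waves is provided; it is optional and the rest
of the package is fully usable without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Signal",
    "DissimilarityMatrix",
    "SignalFormatError",
    "MatrixFormatError",
    "read_signal_text",
    "write_signal_text",
    "read_supplementary_bundle",
    "read_matrix",
    "write_matrix",
    "SESSION_LABELS",
]

#: Canonical labels of the four signals of a care session, in fixed order.
SESSION_LABELS = ("Care-giver", "Before care", "During care", "After care")


class SignalFormatError(ValueError):
    """Raised when a signal file or array violates the format contract."""


class MatrixFormatError(ValueError):
    """Raised when a dissimilarity-matrix file violates the format contract."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled amplitude series.

    Parameters
    ----------
    samples : ndarray
        Real amplitude values in arbitrary units; must all be finite.
    label : str
        Free-text name, e.g. one of :data:`SESSION_LABELS`.
    sampling_rate : float, optional
        Samples per second. Unknown for the study recordings, so optional;
        nothing downstream depends on it (frequencies are normalized).
    """

    samples: np.ndarray
    label: str = ""
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise SignalFormatError(
                f"signal {self.label!r}: expected a 1-D sample array, got shape {arr.shape}"
            )
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise SignalFormatError(
                f"signal {self.label!r}: non-finite sample at index {bad}"
            )
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.size)

    def with_samples(self, samples: np.ndarray) -> "Signal":
        """Return a copy carrying new samples but the same metadata."""
        return Signal(np.asarray(samples, dtype=float), self.label, self.sampling_rate)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A labelled square matrix of pairwise distortions.

    Symmetric with a zero diagonal and finite non-negative entries; exactly
    what UPGMA requires.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    check_symmetry: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        vals = np.asarray(self.values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise MatrixFormatError("duplicate labels in dissimilarity matrix")
        if vals.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {vals.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("non-finite entry in dissimilarity matrix")
        if self.check_symmetry:
            if not np.array_equal(vals, vals.T):
                raise MatrixFormatError("dissimilarity matrix is not symmetric")
            if np.any(np.diag(vals) != 0.0):
                raise MatrixFormatError("dissimilarity matrix diagonal is not zero")
            if np.any(vals < 0.0):
                raise MatrixFormatError("negative entry in dissimilarity matrix")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def permuted(self, order: "list[str] | tuple[str, ...]") -> "DissimilarityMatrix":
        """Return the same matrix with rows/columns in a new label order."""
        idx = [self.labels.index(l) for l in order]
        if len(idx) != self.n:
            raise MatrixFormatError("permutation must use every label exactly once")
        return DissimilarityMatrix(
            tuple(order), self.values[np.ix_(idx, idx)], self.check_symmetry
        )


def _parse_value(token: str, lineno: int, path: Path) -> float:
    try:
        value = float(token)
    except ValueError:
        raise SignalFormatError(
            f"{path}: line {lineno}: not a number: {token!r}"
        ) from None
    if not np.isfinite(value):
        raise SignalFormatError(f"{path}: line {lineno}: non-finite value {token!r}")
    return value


def read_signal_text(path: str | Path, label: str = "") -> Signal:
    """Read a one-column text signal file.

    One numeric value per line. If the first non-blank line is not numeric it
    is treated as a header and skipped; every later non-numeric or non-finite
    line is an error naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    values: list[float] = []
    body_seen = False
    for lineno, raw in enumerate(lines, start=1):
        token = raw.strip()
        if not token:
            continue
        if not body_seen:
            try:
                values.append(_parse_value(token, lineno, path))
            except SignalFormatError:
                pass  # header line
            body_seen = True
            continue
        values.append(_parse_value(token, lineno, path))
    if not values:
        raise SignalFormatError(f"{path}: no numeric samples found")
    return Signal(np.asarray(values), label=label or path.stem)


def write_signal_text(signal: Signal, path: str | Path) -> None:
    """Write a signal as one full-precision value per line."""
    path = Path(path)
    path.write_text("\n".join(repr(float(v)) for v in signal.samples) + "\n")


def read_supplementary_bundle(path: str | Path) -> dict[str, Signal]:
    """Load a MAT v5 bundle of preprocessed pulse waves.

    The internal variable names of the published bundles are undocumented, so
    the loader discovers the single largest numeric array in the container and
    treats its shorter axis as the participant axis, labelling signals "1",
    "2", ... in stored order. Loaded signals are taken as already detrended
    and smoothed; no rescaling or further preprocessing is applied.

    This loader is deliberately self-contained: any failure raises a
    descriptive error and leaves the rest of the package unaffected.
    """
    from scipy.io import loadmat

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"supplementary bundle not found: {path}")
    try:
        contents = loadmat(path)
    except Exception as exc:  # corrupt / non-MAT container
        raise SignalFormatError(f"{path}: unreadable MAT container: {exc}") from exc
    arrays = {
        name: np.asarray(value)
        for name, value in contents.items()
        if not name.startswith("__")
        and isinstance(value, np.ndarray)
        and np.issubdtype(np.asarray(value).dtype, np.number)
        and np.asarray(value).size > 0
    }
    if not arrays:
        raise SignalFormatError(f"{path}: no numeric array found in MAT container")
    name, data = max(arrays.items(), key=lambda kv: kv[1].size)
    data = np.squeeze(data).astype(float)
    if data.ndim == 1:
        data = data[:, None]
    if data.ndim != 2:
        raise SignalFormatError(
            f"{path}: variable {name!r} has unsupported shape {data.shape}"
        )
    if data.shape[0] < data.shape[1]:  # signals stored as rows
        data = data.T
    if not np.all(np.isfinite(data)):
        raise SignalFormatError(f"{path}: variable {name!r} contains non-finite entries")
    return {
        str(k + 1): Signal(data[:, k], label=str(k + 1))
        for k in range(data.shape[1])
    }


def write_matrix(matrix: DissimilarityMatrix, path: str | Path) -> None:
    """Write a labelled matrix as TSV (first row and column hold the labels)."""
    for label in matrix.labels:
        if "\t" in label or "\n" in label:
            raise MatrixFormatError(f"label {label!r} contains the TSV delimiter")
    path = Path(path)
    rows = ["\t".join(("",) + matrix.labels)]
    for label, row in zip(matrix.labels, matrix.values):
        rows.append("\t".join([label] + [repr(float(v)) for v in row]))
    path.write_text("\n".join(rows) + "\n")


def read_matrix(path: str | Path) -> DissimilarityMatrix:
    """Read a labelled TSV matrix written by :func:`write_matrix`.

    Round-trips exactly: ``read_matrix(write_matrix(M)) == M`` at the full
    serialized precision. A non-square or asymmetric body is a format error.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    labels = tuple(header[1:])
    n = len(labels)
    if len(lines) - 1 != n:
        raise MatrixFormatError(
            f"{path}: {n} labels but {len(lines) - 1} data rows"
        )
    values = np.empty((n, n))
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")
        if fields[0] != labels[i]:
            raise MatrixFormatError(
                f"{path}: row label {fields[0]!r} does not match column label {labels[i]!r}"
            )
        if len(fields) - 1 != n:
            raise MatrixFormatError(
                f"{path}: row {i + 1} has {len(fields) - 1} values, expected {n}"
            )
        try:
            values[i] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: row {i + 1}: {exc}") from None
    return DissimilarityMatrix(labels, values)
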