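"""Labeled distance-matrix input/output and the ``E^d`` transform.

Minimum span clustering consumes a single data structure: a labeled,
symmetric, hollow matrix of pairwise distances.  The canonical in-memory
container is :class:`skbio.stats.distance.DistanceMatrix` (re-exported here),
whose ``ids`` are the element labels and whose ``data`` holds the distances.

Three plain-text dialects are supported:

``square_delim``
    Full square matrix.  First row is a header of labels, first column the
    row labels, cells are distances.  Tab, comma, or whitespace delimited.
``lower_triangular_delim``
    Row *i* carries the row label followed by the *i* distances to the
    previously listed elements (PHYLIP-like lower triangle; first row is a
    bare label).
``phylip_dist``
    Standard PHYLIP distance matrix: a count line, then one label plus a
    full row of distances per element (rows may wrap across lines).

Distances may be evolutionary distances (substitutions/site), BLAST
E-values, or any other non-negative dissimilarity; a strict triangle
inequality is not required.  Because E-values from all-vs-all searches are
slightly asymmetric in practice, near-symmetric input is averaged
(``(a_ij + a_ji) / 2``) when the discrepancy is within a relative tolerance,
and rejected beyond it.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "DistanceMatrix",
    "MatrixParseError",
    "MatrixValidationError",
    "FORMATS",
    "make_distance_matrix",
    "as_distance_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "transform_distances",
    "read_run_config",
]

Format = Literal["square_delim", "lower_triangular_delim", "phylip_dist"]
FORMATS: tuple[str, ...] = ("square_delim", "lower_triangular_delim", "phylip_dist")

#: Relative tolerance under which an asymmetric pair a_ij != a_ji is averaged.
ASYMMETRY_RTOL = 1e-6
#: Absolute floor for the asymmetry check, so exact zeros compare cleanly.
ASYMMETRY_ATOL = 1e-12


class MatrixParseError(ValueError):
    """A distance-matrix file could not be parsed (bad shape or cell)."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates a distance-matrix invariant."""


def make_distance_matrix(
    values: Iterable[Iterable[float]] | np.ndarray,
    labels: Sequence[str],
    *,
    rtol: float = ASYMMETRY_RTOL,
) -> DistanceMatrix:
    """Validate raw values + labels and return a ``DistanceMatrix``.

    The matrix must be square with unique labels and finite, non-negative
    entries.  Asymmetry within ``rtol`` (relative, with a tiny absolute
    floor) is resolved by averaging; larger asymmetry raises
    :class:`MatrixValidationError`.  The diagonal is forced to zero.
    """
    arr = np.array(values, dtype=float)
    labels = [str(lab) for lab in labels]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise MatrixValidationError(f"matrix is not square: shape {arr.shape}")
    n = arr.shape[0]
    if len(labels) != n:
        raise MatrixValidationError(
            f"{len(labels)} labels for a {n}x{n} matrix"
        )
    if len(set(labels)) != n:
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise MatrixValidationError(f"duplicate labels: {dupes}")
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise MatrixValidationError(
            f"non-finite distance at ({labels[i]!r}, {labels[j]!r})"
        )
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise MatrixValidationError(
            f"negative distance {arr[i, j]} at ({labels[i]!r}, {labels[j]!r})"
        )
    diff = np.abs(arr - arr.T)
    scale = np.maximum(np.abs(arr), np.abs(arr.T))
    bad = diff > (rtol * scale + ASYMMETRY_ATOL)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"asymmetry beyond tolerance at ({labels[i]!r}, {labels[j]!r}): "
            f"{arr[i, j]} vs {arr[j, i]}"
        )
    sym = (arr + arr.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(sym, ids=labels)


def as_distance_matrix(obj, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Coerce an array / DataFrame / DistanceMatrix to a validated matrix."""
    if isinstance(obj, DistanceMatrix):
        return obj
    # pandas DataFrame with labels on both axes
    if hasattr(obj, "index") and hasattr(obj, "columns"):
        if labels is None:
            if list(obj.index) != list(obj.columns):
                raise MatrixValidationError(
                    "DataFrame index and columns disagree; not a distance matrix"
                )
            labels = [str(x) for x in obj.index]
        obj = np.asarray(obj, dtype=float)
    arr = np.asarray(obj, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(arr.shape[0])]
    return make_distance_matrix(arr, labels)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _split(line: str) -> list[str]:
    if "\t" in line:
        return [tok.strip() for tok in line.rstrip("\n").split("\t")]
    if "," in line:
        return [tok.strip() for tok in line.rstrip("\n").split(",")]
    return line.split()


def _to_float(tok: str, row: str, col: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise MatrixParseError(
            f"non-numeric cell {tok!r} at row {row!r}, column {col!r}"
        ) from None


def _read_square_delim(lines: list[str]) -> tuple[list[str], np.ndarray]:
    header = _split(lines[0])
    # header may or may not carry a leading corner token for the label column
    body = [_split(ln) for ln in lines[1:] if ln.strip()]
    if not body:
        raise MatrixParseError("no data rows below the header")
    n = len(body)
    if len(header) == n + 1:
        col_labels = header[1:]
    elif len(header) == n:
        col_labels = header
    else:
        raise MatrixParseError(
            f"header lists {len(header)} labels but file has {n} data rows"
        )
    labels, values = [], np.empty((n, n), dtype=float)
    for i, toks in enumerate(body):
        if len(toks) != n + 1:
            raise MatrixParseError(
                f"row {i + 1} ({toks[0]!r}) has {len(toks) - 1} values, expected {n}"
            )
        labels.append(toks[0])
        for j, tok in enumerate(toks[1:]):
            values[i, j] = _to_float(tok, toks[0], col_labels[j])
    if labels != col_labels:
        raise MatrixParseError("row labels do not match header labels")
    return labels, values


def _read_lower_triangular(lines: list[str]) -> tuple[list[str], np.ndarray]:
    rows = [_split(ln) for ln in lines if ln.strip()]
    n = len(rows)
    if n == 0:
        raise MatrixParseError("empty lower-triangular file")
    labels, values = [], np.zeros((n, n), dtype=float)
    for i, toks in enumerate(rows):
        if len(toks) != i + 1:
            raise MatrixParseError(
                f"row {i + 1} ({toks[0]!r}) has {len(toks) - 1} values, expected {i}"
            )
        labels.append(toks[0])
        for j, tok in enumerate(toks[1:]):
            v = _to_float(tok, toks[0], labels[j])
            values[i, j] = values[j, i] = v
    return labels, values


def _read_phylip_dist(text: str) -> tuple[list[str], np.ndarray]:
    tokens = text.split()
    if not tokens:
        raise MatrixParseError("empty PHYLIP distance file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise MatrixParseError(
            f"first token {tokens[0]!r} is not the taxon count"
        ) from None
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise MatrixParseError(
            f"expected {expected} tokens for {n} taxa, found {len(tokens)}"
        )
    labels, values = [], np.empty((n, n), dtype=float)
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        pos += 1
        for j in range(n):
            values[i, j] = _to_float(tokens[pos], labels[i], f"col {j + 1}")
            pos += 1
    return labels, values


def read_distance_matrix(path: str | Path, format: Format = "square_delim") -> DistanceMatrix:
    """Read a labeled distance matrix from ``path`` in the given dialect.

    Raises :class:`MatrixParseError` for structural problems (naming the
    offending row/cell) and :class:`MatrixValidationError` for invariant
    violations (duplicate labels, asymmetry beyond tolerance, negatives).
    """
    path = Path(path)
    text = path.read_text()
    if format == "square_delim":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise MatrixParseError(f"{path}: empty file")
        labels, values = _read_square_delim(lines)
    elif format == "lower_triangular_delim":
        labels, values = _read_lower_triangular(text.splitlines())
    elif format == "phylip_dist":
        labels, values = _read_phylip_dist(text)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    return make_distance_matrix(values, labels)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    # repr round-trips float64 exactly, keeping read(write(dm)) == dm
    return repr(float(v))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path,
                          format: Format = "square_delim") -> Path:
    """Write ``dm`` to ``path`` in the given dialect (full precision)."""
    path = Path(path)
    labels = list(dm.ids)
    values = dm.data
    lines: list[str] = []
    if format == "square_delim":
        lines.append("\t".join([""] + labels))
        for i, lab in enumerate(labels):
            lines.append("\t".join([lab] + [_fmt(v) for v in values[i]]))
    elif format == "lower_triangular_delim":
        for i, lab in enumerate(labels):
            lines.append("\t".join([lab] + [_fmt(v) for v in values[i, :i]]))
    elif format == "phylip_dist":
        lines.append(str(len(labels)))
        for i, lab in enumerate(labels):
            lines.append("  ".join([lab] + [_fmt(v) for v in values[i]]))
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# E^d transform
# ---------------------------------------------------------------------------

def transform_distances(dm: DistanceMatrix, d: float) -> DistanceMatrix:
    """Raise every distance to the power ``d`` (the ``E^d`` transform).

    BLAST E-values are commonly used as distances either raw (``d = 1``) or
    strongly compressed (``d = 0.02``).  Any ``d > 0`` is a strictly
    increasing map on the positive reals, so the ordering of distinct
    positive distances — and hence the minimum-span clustering — is
    unchanged.
    """
    if not (isinstance(d, (int, float)) and math.isfinite(d) and d > 0):
        raise ValueError(f"transform exponent d must be a positive finite real, got {d!r}")
    values = np.power(dm.data, float(d))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=dm.ids)


# ---------------------------------------------------------------------------
# run configuration files
# ---------------------------------------------------------------------------

def read_run_config(path: str | Path) -> dict:
    """Read run parameters (m, n_limit, d, format, ...) from a config file.

    Accepts JSON (``{"m": 3, "n_limit": 3}``) or simple ``key=value`` lines
    (``#`` comments allowed).  Numeric-looking values are converted.
    """
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith("{"):
        cfg = json.loads(text)
        if not isinstance(cfg, dict):
            raise ValueError(f"{path}: JSON config must be an object")
        return cfg
    cfg: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno} is not 'key=value': {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        try:
            val: object = int(raw)
        except ValueError:
            try:
                val = float(raw)
            except ValueError:
                val = raw
        cfg[key] = val
    return cfg
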