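"""Reading, transforming and writing cell x marker expression tables.

Mass cytometry instruments report raw ion counts per antibody channel.  The
conventional variance-stabilising transform for such counts is the hyperbolic
arcsine with a cofactor, ``asinh(x / c)`` with ``c = 5``; all similarity
computations downstream assume transformed values.  Inputs are either FCS
3.0/3.1 list-mode files or delimited text with a header row of marker names.
Inputs are assumed pre-gated (live, single cells); missing values are
rejected rather than imputed because the Euclidean kNN distance used later
has no missing-data semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "arcsinh_transform", "write_table"]


@dataclass
class ExpressionMatrix:
    """A cells x markers numeric table, the data level of an HSNE hierarchy.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_cells, n_markers)``.  Raw instrument units
        before transformation, arcsinh units afterwards.
    cell_ids
        One identifier per row.
    marker_names
        One unique name per column.
    sample_ids
        Optional per-cell sample annotation.
    transformed
        Whether :func:`arcsinh_transform` has been applied.
    """

    values: np.ndarray
    cell_ids: list[str]
    marker_names: list[str]
    sample_ids: list[str] | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_cells, n_markers = self.values.shape
        if n_cells < 1:
            raise ValueError("expression matrix needs at least one cell")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match number of rows")
        if len(self.marker_names) != n_markers:
            raise ValueError("marker_names length does not match number of columns")
        if len(set(self.marker_names)) != n_markers:
            raise ValueError("marker names must be unique")
        if self.sample_ids is not None and len(self.sample_ids) != n_cells:
            raise ValueError("sample_ids length does not match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite (no NaN/inf)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def select_markers(self, markers: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``markers``, in the given order."""
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise KeyError(f"markers not present in matrix: {missing}")
        idx = [self.marker_names.index(m) for m in markers]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            marker_names=list(markers),
            cell_ids=list(self.cell_ids),
        )


_DELIMS = {"csv": ",", "tsv": "\t"}


def read_expression(
    path: str | os.PathLike,
    format: str | None = None,
    marker_subset: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from FCS or delimited text.

    Parameters
    ----------
    path
        File to read.
    format
        ``"fcs"``, ``"csv"`` or ``"tsv"``; inferred from the file suffix when
        omitted.
    marker_subset
        If given, restrict and reorder columns to these marker names; a
        missing name raises :class:`KeyError` listing all missing names.

    Returns
    -------
    ExpressionMatrix
        Untransformed matrix.  Cell identifiers are synthesised as
        ``"<filename>:<row>"`` when the file carries none (always, for the
        supported formats).
    """
    path = os.fspath(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    format = format.lower()
    if format not in ("fcs", "csv", "tsv"):
        raise ValueError(f"unknown format {format!r}; expected fcs, csv or tsv")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    name = os.path.basename(path)
    if format == "fcs":
        from .fcs import read_fcs

        values, markers = read_fcs(path)
    else:
        df = pd.read_csv(path, sep=_DELIMS[format], header=0)
        markers = [str(c) for c in df.columns]
        try:
            values = df.to_numpy(dtype=np.float64)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell value in {path}: {exc}") from exc
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError(f"missing or non-finite values in {path}")

    cell_ids = [f"{name}:{i}" for i in range(values.shape[0])]
    m = ExpressionMatrix(values=values, cell_ids=cell_ids, marker_names=markers)
    if marker_subset is not None:
        m = m.select_markers(list(marker_subset))
    return m


def arcsinh_transform(m: ExpressionMatrix, cofactor: float = 5.0) -> ExpressionMatrix:
    """Apply the hyperbolic-arcsine count transform ``x -> asinh(x / cofactor)``.

    The default cofactor of 5 is the mass-cytometry convention.  The transform
    is strictly monotone per entry, preserves shape, and is guarded against
    double application by the ``transformed`` flag.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if m.transformed:
        raise ValueError("matrix is already arcsinh-transformed")
    return replace(
        m,
        values=np.arcsinh(m.values / cofactor),
        cell_ids=list(m.cell_ids),
        marker_names=list(m.marker_names),
        transformed=True,
    )


def write_table(rows: pd.DataFrame | np.ndarray, path: str | os.PathLike, *, columns: Sequence[str] | None = None, sep: str = ",") -> None:
    """Write tabular data as delimited text with a header row.

    Output is reproducible byte-for-byte for identical input: fixed float
    formatting, no index column, LF line endings.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = np.asarray(rows)
        if rows.ndim == 1:
            rows = rows.reshape(-1, 1)
        if columns is None:
            columns = [f"c{i}" for i in range(rows.shape[1] if rows.size else 0)]
        rows = pd.DataFrame(rows, columns=list(columns))
    rows.to_csv(path, sep=sep, index=False, float_format="%.10g", lineterminator="\n")
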