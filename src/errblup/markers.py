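"""Marker and phenotype containers, file I/O, and coding translations.

Genotypes are held as an ``n`` individuals × ``p`` loci dosage matrix
``M``.  A *translation of the coding* replaces ``M`` by ``M - 1_n Pᵗ``
for a constant vector ``P`` — e.g. subtracting column means (the usual
allele-frequency centering) or half the maximum dosage (the symmetric
±0.5 coding for presence/absence markers).  The :class:`MarkerMatrix`
records the accumulated shift ``P`` so that downstream fits can re-apply
the training coding to new data instead of silently mixing codings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import CodingError, DimensionError, LoadError

__all__ = [
    "MarkerMatrix",
    "Phenotype",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_phenotype",
    "write_phenotype",
    "translate",
    "column_means",
    "align_phenotype",
]

TranslateMode = Literal["none", "column_mean", "symmetric", "constant"]


@dataclass
class MarkerMatrix:
    """Dosage matrix with line/marker labels and the applied coding shift.

    Parameters
    ----------
    values
        ``(n, p)`` array of real allele dosages in the *current* coding.
    line_ids, marker_ids
        Row and column labels.
    shift
        Length-``p`` vector ``P`` already subtracted from the raw
        dosages (zeros for a raw matrix).  ``raw = values + shift``.
    """

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    shift: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise DimensionError("marker matrix must be at least 1x1")
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise DimensionError(
                f"labels ({len(self.line_ids)}, {len(self.marker_ids)}) do not "
                f"match matrix shape {(n, p)}"
            )
        if self.shift is None:
            self.shift = np.zeros(p)
        self.shift = np.asarray(self.shift, dtype=float).reshape(-1)
        if self.shift.shape != (p,):
            raise DimensionError(f"shift must have length p={p}")
        if np.isnan(self.values).any():
            raise LoadError("marker matrix contains missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(self.values.copy(), list(self.line_ids),
                            list(self.marker_ids), self.shift.copy())

    def subset(self, lines: Sequence[int] | None = None,
               markers: Sequence[int] | None = None) -> "MarkerMatrix":
        """Positional row/column subset keeping labels and shift."""
        li = np.arange(self.n) if lines is None else np.asarray(lines)
        mi = np.arange(self.p) if markers is None else np.asarray(markers)
        return MarkerMatrix(
            self.values[np.ix_(li, mi)],
            [self.line_ids[i] for i in li],
            [self.marker_ids[j] for j in mi],
            self.shift[mi],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids,
                            columns=self.marker_ids)


@dataclass
class Phenotype:
    """An ``n``-vector of observations with line labels."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.line_ids = [str(x) for x in self.line_ids]
        if len(self.line_ids) != self.values.shape[0]:
            raise DimensionError("phenotype labels do not match value count")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_marker_matrix(path, format: Literal["delimited", "vcf"] = "delimited",
                       impute: Literal["none", "column_mean"] = "none",
                       ) -> MarkerMatrix:
    """Load a raw (shift = 0) dosage matrix from a delimited file or VCF.

    Delimited files carry a header row of marker IDs and a first column
    of line IDs; tab or comma is auto-detected.  VCF genotypes are
    converted to counted-allele dosages (0/0 → 0, 0/1 → 1, 1/1 → 2);
    multi-allelic sites are rejected.  With ``impute='none'`` any
    missing or non-numeric cell is an error naming the offending
    row/column; ``impute='column_mean'`` fills column means.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    if format == "delimited":
        return _read_delimited(path, impute)
    if format == "vcf":
        return _read_vcf(path, impute)
    raise LoadError(f"unknown marker format {format!r}")


def _read_delimited(path: Path, impute: str) -> MarkerMatrix:
    sep = _sniff_sep(path)
    with open(path) as fh:
        widths = {len(line.rstrip("\n").split(sep))
                  for line in fh if line.strip()}
    if len(widths) > 1:
        raise LoadError(f"{path}: ragged rows (field counts {sorted(widths)})")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    missing = num.isna()
    if impute == "none" and missing.any().any():
        r, c = np.argwhere(missing.values)[0]
        kind = "non-numeric" if bad.values[r, c] else "missing"
        raise LoadError(
            f"{path}: {kind} value at line {df.index[r]!r}, "
            f"marker {df.columns[c]!r} (value {df.iloc[r, c]!r})"
        )
    values = num.values.astype(float)
    if impute == "column_mean" and missing.any().any():
        col_mean = np.nanmean(values, axis=0)
        if np.isnan(col_mean).any():
            j = int(np.argwhere(np.isnan(col_mean))[0])
            raise LoadError(f"{path}: marker {df.columns[j]!r} has no "
                            "observed values to impute from")
        ii, jj = np.nonzero(np.isnan(values))
        values[ii, jj] = col_mean[jj]
    return MarkerMatrix(values, list(df.index), list(df.columns))


def _read_vcf(path: Path, impute: str) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise LoadError(
                f"{path}: multi-allelic site {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}) is not supported"
            )
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 0:
                dos[i] = np.nan
            else:
                dos[i] = float(sum(a > 0 for a in alleles))
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        cols.append(dos)
        ids.append(str(name))
    vcf.close()
    if not cols:
        raise LoadError(f"{path}: VCF contains no usable variants")
    values = np.column_stack(cols)
    if np.isnan(values).any():
        if impute == "none":
            i, j = np.argwhere(np.isnan(values))[0]
            raise LoadError(f"{path}: missing GT for sample {samples[i]!r} "
                            f"at {ids[j]}")
        col_mean = np.nanmean(values, axis=0)
        ii, jj = np.nonzero(np.isnan(values))
        values[ii, jj] = col_mean[jj]
    return MarkerMatrix(values, samples, ids)


def write_marker_matrix(M: MarkerMatrix, path, sep: str = "\t") -> None:
    M.to_frame().to_csv(path, sep=sep, index_label="line_id")


def read_phenotype(path) -> Phenotype:
    """Read a two-column (line_id, value) delimited file, header optional."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] != 2:
        raise LoadError(f"{path}: expected 2 columns, found {df.shape[1]}")
    first_val = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if np.isnan(first_val):  # header row
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        r = int(np.argwhere(values.isna().values)[0])
        raise LoadError(f"{path}: non-numeric phenotype for line "
                        f"{df.iloc[r, 0]!r}")
    return Phenotype(values.values, list(df.iloc[:, 0]))


def write_phenotype(y: Phenotype, path, sep: str = "\t") -> None:
    pd.DataFrame({"line_id": y.line_ids, "value": y.values}).to_csv(
        path, sep=sep, index=False)


def align_phenotype(M: MarkerMatrix, y: Phenotype) -> Phenotype:
    """Reorder ``y`` to match ``M``'s line order; error on any mismatch."""
    pos = {lid: i for i, lid in enumerate(y.line_ids)}
    try:
        order = [pos[lid] for lid in M.line_ids]
    except KeyError as exc:
        raise DimensionError(f"phenotype is missing line {exc.args[0]!r}") from None
    if len(pos) != len(y.line_ids) or len(order) != y.n:
        raise DimensionError("line IDs do not align 1:1 between marker "
                             "matrix and phenotype")
    return Phenotype(y.values[order], list(M.line_ids))


def translate(M: MarkerMatrix, mode: TranslateMode = "column_mean",
              P=None, max_dosage: float | None = None) -> MarkerMatrix:
    """Return ``M - 1_n Pᵗ`` with ``P`` chosen per ``mode``.

    ``column_mean`` subtracts each column's mean (columns of the result
    sum to zero); ``symmetric`` subtracts ``max_dosage / 2`` everywhere
    (±0.5 coding for 0/1 data); ``constant`` subtracts a user-supplied
    scalar or length-``p`` vector; ``none`` is the identity.  The
    accumulated shift is recorded on the result.
    """
    p = M.p
    if mode == "none":
        return M.copy()
    if mode == "column_mean":
        vec = M.values.mean(axis=0)
    elif mode == "symmetric":
        if max_dosage is None:
            raise CodingError("mode='symmetric' requires max_dosage")
        vec = np.full(p, float(max_dosage) / 2.0)
    elif mode == "constant":
        if P is None:
            raise CodingError("mode='constant' requires P")
        vec = np.asarray(P, dtype=float).reshape(-1)
        if vec.size == 1:
            vec = np.full(p, vec[0])
        if vec.shape != (p,):
            raise DimensionError(f"P has length {vec.size}, expected {p}")
    else:
        raise CodingError(f"unknown translate mode {mode!r}")
    return MarkerMatrix(M.values - vec, list(M.line_ids),
                        list(M.marker_ids), M.shift + vec)


def column_means(M: MarkerMatrix) -> np.ndarray:
    """Arithmetic mean of each marker column (the centering vector P)."""
    return M.values.mean(axis=0)
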