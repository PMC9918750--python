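"""Tabular I/O: cell tables, core/clinical metadata and expression matrices.

All tabular data travel as delimited text (comma by default, tab
accepted) so that a full run round-trips through plain files.  Sparse
single-cell matrices may additionally arrive as MatrixMarket coordinate
files with gene/cell name sidecars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("siascore")

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "read_cell_table",
    "write_cell_table",
    "read_core_table",
    "read_clinical_table",
    "read_expression_matrix",
]


class FormatError(ValueError):
    """The file does not conform to the expected column/layout contract."""


class ValidationError(ValueError):
    """The file parsed but carries invalid values."""


REQUIRED_CELL_COLUMNS = ("cell_id", "patient_id", "core_id", "panel_id")
REQUIRED_CORE_COLUMNS = ("core_id", "patient_id", "region", "area_mm2")


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_cell_table(path, config) -> pd.DataFrame:
    """Read a per-cell table with marker mean intensities.

    Required columns: ``cell_id``, ``patient_id``, ``core_id``,
    ``panel_id`` and one intensity column per configured marker of each
    panel that occurs in the file.  Unknown columns are preserved.
    """
    df = _read_delimited(path)
    for col in REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cell table {path} is missing required column {col!r}")
    marker_cols: set[str] = set()
    for panel_id in df["panel_id"].unique():
        if panel_id not in config.panels:
            raise FormatError(f"cell table references unknown panel {panel_id!r}")
        markers = config.panels[panel_id]
        mask = df["panel_id"] == panel_id
        for m in markers:
            if m not in df.columns:
                raise FormatError(
                    f"cell table {path} is missing intensity column {m!r} "
                    f"for panel {panel_id!r}"
                )
            vals = pd.to_numeric(df.loc[mask, m], errors="coerce")
            bad = vals < 0
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"negative intensity for marker {m!r} at row "
                    f"{df.loc[mask].index[row] + 1} of {path}"
                )
            marker_cols.add(m)
    for m in marker_cols:
        df[m] = pd.to_numeric(df[m])
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_core_table(path) -> pd.DataFrame:
    """Read core metadata (core id, patient id, region, area in mm^2)."""
    df = _read_delimited(path)
    for col in REQUIRED_CORE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"core table {path} is missing required column {col!r}")
    bad_region = ~df["region"].isin(["centre", "margin", "bulk"])
    if bad_region.any():
        raise ValidationError(
            f"unknown region label(s) {sorted(df.loc[bad_region, 'region'].unique())}"
        )
    if (df["area_mm2"] <= 0).any():
        raise ValidationError("core areas must be positive")
    return df


def read_clinical_table(path) -> pd.DataFrame:
    df = _read_delimited(path)
    if "patient_id" not in df.columns:
        raise FormatError(f"clinical table {path} is missing 'patient_id'")
    return df


@dataclass
class ExpressionMatrix:
    """Genes x samples (bulk) or genes x cells (single cell) expression.

    ``values`` holds non-negative expression with gene symbols as the
    index.  Per-sample annotations (patient, lesion, response,
    timepoint ...) live in ``obs`` indexed by sample/cell id.  Scores are
    always computed on the linear scale; a log2 matrix is exponentiated
    first via :meth:`to_linear`.
    """

    values: pd.DataFrame
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.obs.empty:
            self.obs = pd.DataFrame(index=self.values.columns)
        self.values.index = self.values.index.astype(str).str.strip()
        dup = self.values.index.duplicated(keep=False)
        if dup.any():
            names = sorted(set(self.values.index[dup]))
            logger.warning(
                "collapsing %d duplicated gene symbol(s) by summation: %s",
                len(names), ", ".join(names[:5]),
            )
            self.values = self.values.groupby(level=0, sort=False).sum()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(
            np.exp2(self.values) - 1.0, self.obs.copy(), "linear"
        )

    def gene(self, symbol: str) -> pd.Series:
        """Expression row for ``symbol``, matched case-insensitively."""
        key = symbol.strip().upper()
        match = self.values.index[self.values.index.str.upper() == key]
        if len(match) == 0:
            raise KeyError(f"gene {symbol!r} not present in matrix")
        return self.values.loc[match[0]]

    def has_gene(self, symbol: str) -> bool:
        return bool((self.values.index.str.upper() == symbol.strip().upper()).any())


def read_expression_matrix(path, layout: str = "dense", obs_path=None,
                           scale: str = "linear") -> ExpressionMatrix:
    """Read an expression matrix.

    Parameters
    ----------
    path
        Dense layout: delimited file, genes in rows, first column gene
        symbols, remaining columns samples.  MTX layout: MatrixMarket
        coordinate file; ``<stem>.genes.txt`` and ``<stem>.samples.txt``
        sidecars supply row and column names (one per line).
    layout
        ``"dense"`` or ``"mtx"``.
    obs_path
        Optional delimited table of per-sample annotations; first
        column must be the sample/cell id.
    """
    path = Path(path)
    if layout == "dense":
        df = _read_delimited(path)
        df = df.set_index(df.columns[0])
        df.index.name = "gene"
    elif layout == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_names(path.with_suffix("").with_suffix(".genes.txt"))
        samples = _read_names(path.with_suffix("").with_suffix(".samples.txt"))
        arr = mat.toarray() if scipy.sparse.issparse(mat) else np.asarray(mat)
        if arr.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX shape {arr.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(arr, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    obs = pd.DataFrame(index=df.columns)
    if obs_path is not None:
        obs = _read_delimited(obs_path)
        obs = obs.set_index(obs.columns[0])
        obs = obs.reindex(df.columns)
    return ExpressionMatrix(df, obs, scale)


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path)
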