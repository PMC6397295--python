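"""Expression matrix I/O and [0,1] rescaling.

The propagation model consumes expression values in [0,1].  Input TSVs
hold already-normalized values (any scale); :func:`rescale` optionally
log-transforms them and maps each gene to [0,1] by quantile-truncated
min-max scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ExpressionMatrix", "Design", "read_expression", "read_design", "rescale"]

log = logging.getLogger(__name__)


class ExpressionMatrix:
    """Genes x samples matrix backed by a pandas DataFrame."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = sorted(data.index[data.index.duplicated()].unique())
            raise DataError(f"duplicate gene ids: {dup}")
        if data.columns.has_duplicates:
            dup = sorted(data.columns[data.columns.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dup}")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, sample: str) -> pd.Series:
        return self.data[sample]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class Design:
    """Sample -> class label mapping."""

    labels: Mapping[str, str]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.labels.values():
            seen.setdefault(v, None)
        return list(seen)

    def samples_of(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def __contains__(self, sample: str) -> bool:
        return sample in self.labels

    def __getitem__(self, sample: str) -> str:
        return self.labels[sample]


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids).

    Empty cells and ``NA`` are kept as missing (imputed later by
    :func:`rescale`).  Duplicate gene rows are collapsed by per-sample
    maximum with a warning; duplicate sample ids are an error.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({s for s in header if header.count(s) > 1})
    if dup:
        raise DataError(f"{path}: duplicate sample ids {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    df.index = df.index.astype(str)

    def _to_float(cell: str, gene: str, sample: str) -> float:
        s = cell.strip()
        if s == "" or s.upper() in ("NA", "NAN"):
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise DataError(
                f"{path}: non-numeric value {cell!r} at gene {gene!r}, sample {sample!r}"
            ) from None

    numeric = _parse_numeric(df, _to_float)

    if numeric.index.has_duplicates:
        dup = sorted(numeric.index[numeric.index.duplicated()].unique())
        log.warning("collapsing %d duplicated gene row(s) by per-sample max: %s", len(dup), dup)
        numeric = numeric.groupby(level=0, sort=False).max()
    return ExpressionMatrix(numeric)


def _parse_numeric(df: pd.DataFrame, to_float) -> pd.DataFrame:
    arr = np.empty(df.shape, dtype=float)
    cols = list(df.columns)
    genes = list(df.index)
    raw = df.to_numpy()
    for j, sample in enumerate(cols):
        for i, gene in enumerate(genes):
            arr[i, j] = to_float(raw[i, j], gene, sample)
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


def read_design(path) -> Design:
    """Read a two-column (sample, label) TSV with no header."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}")
            sample, label = parts[0].strip(), parts[1].strip()
            if sample in mapping:
                raise DataError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            mapping[sample] = label
    return Design(labels=mapping)


def rescale(
    matrix: ExpressionMatrix,
    log_transform: bool = False,
    truncate_quantiles: tuple[float, float] = (0.0, 0.99),
    per_gene: bool = True,
) -> ExpressionMatrix:
    """Map expression values into [0,1].

    Optionally applies log2(x+1) first (non-negative inputs only), then —
    per gene by default, or over the whole matrix with ``per_gene=False`` —
    clips at the given quantiles and min-max scales.  Constant rows map to
    0.5 everywhere; missing values are imputed with the gene's post-scaling
    median (0.5 when the whole row is missing).
    """
    lo_q, hi_q = truncate_quantiles
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise DataError(f"truncate_quantiles must satisfy 0 <= low < high <= 1, got {truncate_quantiles}")
    vals = matrix.values.astype(float).copy()
    if log_transform:
        if vals.size and np.nanmin(vals) < 0:
            raise DataError("log transform requested but matrix contains negative values")
        vals = np.log2(vals + 1.0)

    def _scale_rows(block: np.ndarray) -> np.ndarray:
        # block: rows scaled independently; NaN-aware
        out = np.full_like(block, np.nan)
        with np.errstate(invalid="ignore"):
            for i in range(block.shape[0]):
                row = block[i]
                finite = np.isfinite(row)
                if not finite.any():
                    out[i] = 0.5
                    continue
                lo = np.nanquantile(row, lo_q)
                hi = np.nanquantile(row, hi_q)
                clipped = np.clip(row, lo, hi)
                rmin, rmax = np.nanmin(clipped), np.nanmax(clipped)
                if rmax - rmin == 0:
                    scaled = np.where(finite, 0.5, np.nan)
                else:
                    scaled = (clipped - rmin) / (rmax - rmin)
                med = np.nanmedian(scaled)
                scaled = np.where(np.isnan(scaled), med, scaled)
                out[i] = scaled
        return out

    if per_gene:
        scaled = _scale_rows(vals)
    else:
        scaled = _scale_rows(vals.reshape(1, -1)).reshape(vals.shape)
    scaled = np.clip(scaled, 0.0, 1.0)
    return ExpressionMatrix(pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns))
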