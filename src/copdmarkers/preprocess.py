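"""Probe-level normalization and gene-level summarization.

Implements the RMA-style preprocessing chain used for single-channel
expression arrays: quantile normalization of linear-scale intensities,
log2 transformation, and median-polish summarization of the probes of
each gene into a single gene-level expression value per sample.  No
optical background correction is applied (the pipeline's inputs are
assumed to be background-free), so logs refer to the chain as
"RMA-style".
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Raised for invalid matrices (missing or non-positive values)."""


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        rows = matrix.index[matrix.isna().any(axis=1)]
        raise PreprocessError(f"matrix contains missing values (e.g. row {rows[0]!r})")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; each column's
    values are replaced by the reference value at their rank.  Tied values
    within a column receive the mean of the reference quantiles they span
    (midrank interpolation), so the operation is idempotent.

    Parameters
    ----------
    matrix:
        Probes x samples, at least two sample columns, no missing values.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise PreprocessError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=float)
        ranks[order] = positions
        # midrank for ties: average the ranks of equal values
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranks[order[i : k + 1]] = positions[i : k + 1].mean()
            i = k + 1
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; rejects non-positive entries with coordinates."""
    _check_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise PreprocessError(
            f"non-positive intensity {values[i, j]!r} at "
            f"row {matrix.index[i]!r}, column {matrix.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def median_polish(
    block: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way median polish of a probes x samples block, rows first.

    Returns ``(overall, row_effects, col_effects, residuals)`` with the
    usual decomposition ``block = overall + row + col + residual``.
    Iteration stops after ``max_iter`` sweeps or when the largest
    absolute adjustment of a sweep falls below ``tol``.
    """
    resid = np.asarray(block, dtype=float).copy()
    overall = 0.0
    row = np.zeros(resid.shape[0])
    col = np.zeros(resid.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        delta = np.median(row)
        overall += delta
        row -= delta
        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        delta2 = np.median(col)
        overall += delta2
        col -= delta2
        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return overall, row, col, resid


def summarize_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Summarize log2 probe intensities to one expression row per gene.

    Each gene's probes x samples block is decomposed by median polish into
    probe affinity, sample effect and residual; the returned gene value is
    the sample effect re-centred so the block's grand mean is preserved.
    Median polish makes the summary robust to a single aberrant probe,
    unlike a plain column mean.  Genes with one probe pass through
    unchanged.  Probes absent from the map are dropped with a logged count.

    Parameters
    ----------
    matrix:
        Normalized, log2-scale probe matrix (probes x samples).
    probe_to_gene:
        Mapping of probe id to its unique gene id.
    """
    _check_matrix(matrix)
    mapped = [p for p in matrix.index if p in probe_to_gene]
    dropped = matrix.shape[0] - len(mapped)
    if dropped:
        log.warning("dropping %d probe(s) with no gene annotation", dropped)
    genes: dict[str, list[str]] = {}
    for probe in mapped:
        genes.setdefault(str(probe_to_gene[probe]), []).append(probe)

    out = np.empty((len(genes), matrix.shape[1]))
    gene_ids = []
    for i, (gene, probes) in enumerate(sorted(genes.items())):
        block = matrix.loc[probes].to_numpy(dtype=float)
        if block.shape[0] == 1:
            out[i] = block[0]
        else:
            _, _, col, _ = median_polish(block)
            out[i] = (col - col.mean()) + block.mean()
        gene_ids.append(gene)
    return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene_id"),
                        columns=matrix.columns)
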