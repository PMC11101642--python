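"""From raw multimodal counts to analysis-ready quantities.

QC filtering on mitochondrial fraction and total UMI, log-normal
expression normalization (scale factor 100,000), centered log-ratio
(CLR) normalization of oligo-tag counts, mobility/concentration-
normalized relative permeability and permeability ratios, and
hashtag demultiplexing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .pore import DTDSpecies

__all__ = [
    "MultimodalCounts",
    "QCThresholds",
    "QC_PRESETS",
    "EmptyResultError",
    "qc_filter",
    "lognormalize_expression",
    "clr_tags",
    "relative_permeability",
    "permeability_ratio",
    "demux_hashtags",
]

LOGNORM_SCALE = 100_000


class EmptyResultError(RuntimeError):
    """An operation removed every cell."""


@dataclass
class MultimodalCounts:
    """Paired gene x cell and tag x cell counts over shared cell barcodes.

    ``gene_matrix`` is sparse CSR (genes x cells); ``tag_matrix`` a
    tags x cells integer DataFrame whose columns equal
    ``cell_barcodes``; ``gene_metadata`` must carry a boolean ``mito``
    column; ``tag_metadata`` marks each tag as ``dtd`` or ``hashtag``.
    """

    gene_matrix: sparse.csr_matrix
    tag_matrix: pd.DataFrame
    cell_barcodes: list[str]
    gene_metadata: pd.DataFrame
    tag_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.gene_matrix.shape[1] != len(self.cell_barcodes):
            raise ValueError("gene matrix columns do not match cell barcodes")
        if list(self.tag_matrix.columns) != list(self.cell_barcodes):
            raise ValueError("tag matrix columns must equal the shared cell barcodes")
        if self.gene_matrix.shape[0] != len(self.gene_metadata):
            raise ValueError("gene metadata rows do not match gene matrix")
        if (self.gene_matrix.data < 0).any() or (self.tag_matrix.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "mito" not in self.gene_metadata.columns:
            raise ValueError("gene_metadata must have a boolean 'mito' column")

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def subset_cells(self, keep: np.ndarray) -> "MultimodalCounts":
        """Subset both matrices to the boolean cell mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        barcodes = [bc for bc, k in zip(self.cell_barcodes, keep) if k]
        return MultimodalCounts(
            gene_matrix=self.gene_matrix[:, keep],
            tag_matrix=self.tag_matrix.loc[:, keep],
            cell_barcodes=barcodes,
            gene_metadata=self.gene_metadata,
            tag_metadata=self.tag_metadata,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC gates. Boundaries are inclusive on the keep side:
    'fewer than 2000 counts' discards, so exactly 2000 is kept; 'more
    than 100,000' discards, so exactly 100,000 is kept."""

    max_mito_fraction: float
    min_counts: int
    max_counts: int

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction < 1:
            raise ValueError(f"max_mito_fraction must be in (0, 1), got {self.max_mito_fraction}")
        if not self.min_counts < self.max_counts:
            raise ValueError(
                f"min_counts ({self.min_counts}) must be below max_counts ({self.max_counts})"
            )


#: presets for the three profiled systems
QC_PRESETS: dict[str, QCThresholds] = {
    "cancer": QCThresholds(0.10, 2000, 100_000),
    "mhspc": QCThresholds(0.05, 1000, 60_000),
    "tig1": QCThresholds(0.05, 2000, 60_000),
}


def qc_filter(data: MultimodalCounts, thr: QCThresholds) -> tuple[MultimodalCounts, pd.DataFrame]:
    """Remove low-quality cells and likely doublets.

    Keeps cells with mitochondrial fraction <= ``max_mito_fraction``
    and ``min_counts`` <= total UMI <= ``max_counts``; both matrices
    are subset identically. Returns the filtered data and a per-cell
    report with the removal reason (``mito``, ``low_counts``,
    ``high_counts`` or ``pass``). Raises :class:`EmptyResultError` if
    nothing survives.
    """
    totals = np.asarray(data.gene_matrix.sum(axis=0)).ravel()
    mito_mask = data.gene_metadata["mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(data.gene_matrix[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    reason = np.full(data.n_cells, "pass", dtype=object)
    reason[totals > thr.max_counts] = "high_counts"
    reason[totals < thr.min_counts] = "low_counts"
    reason[mito_fraction > thr.max_mito_fraction] = "mito"
    keep = reason == "pass"

    report = pd.DataFrame(
        {
            "barcode": data.cell_barcodes,
            "total_counts": totals.astype(int),
            "mito_fraction": mito_fraction,
            "reason": reason,
            "kept": keep,
        }
    )
    if not keep.any():
        raise EmptyResultError(
            f"QC removed all {data.n_cells} cells (thresholds {thr}); nothing to analyse"
        )
    return data.subset_cells(keep), report


def lognormalize_expression(gene_matrix, scale: float = LOGNORM_SCALE) -> np.ndarray:
    """Log-normal transformation: ``x -> ln(1 + scale * x / colsum)``.

    Depth-invariant per cell; zero entries map to 0. Zero-total cells
    (which QC should have removed) raise.
    """
    dense = np.asarray(
        gene_matrix.todense() if sparse.issparse(gene_matrix) else gene_matrix, dtype=float
    )
    colsum = dense.sum(axis=0)
    if np.any(colsum <= 0):
        bad = int(np.sum(colsum <= 0))
        raise ValueError(f"{bad} cells have zero total counts; run QC first")
    return np.log1p(scale * dense / colsum)


def clr_tags(tag_matrix, pseudocount: float = 1.0, across: str = "tags") -> pd.DataFrame:
    """Centered log-ratio normalization of tag counts.

    ``across='tags'`` (default) treats each cell's tag vector as a
    composition: ``CLR(x_i) = ln(x_i + pc) - mean_tags ln(x + pc)``, so
    every cell's CLR values sum to 0. ``across='cells'`` centers each
    tag over cells instead; this margin preserves between-cell signal
    that is shared by all tags (pore number, tension) and is the
    readout margin used for the tension screens.
    """
    if isinstance(tag_matrix, pd.DataFrame):
        values = tag_matrix.to_numpy(dtype=float)
        index, columns = tag_matrix.index, tag_matrix.columns
    else:
        values = np.asarray(tag_matrix, dtype=float)
        index = columns = None
    if np.any(values < 0):
        raise ValueError("tag counts must be non-negative")
    logx = np.log(values + pseudocount)
    if across == "tags":
        centered = logx - logx.mean(axis=0, keepdims=True)
    elif across == "cells":
        centered = logx - logx.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"across must be 'tags' or 'cells', got {across!r}")
    if index is not None:
        return pd.DataFrame(centered, index=index, columns=columns)
    return centered


def relative_permeability(counts, species: DTDSpecies):
    """Counts normalized by mobility x concentration: counts / (mu c).

    Removes the species-specific electrophoretic dose so that different
    dextran sizes are comparable; zero counts give zero permeability.
    """
    if species.mobility <= 0 or species.concentration <= 0:
        raise ValueError(
            f"species {species.name or species.barcode} needs mobility and concentration > 0 "
            f"(got {species.mobility}, {species.concentration})"
        )
    return np.asarray(counts, dtype=float) / (species.mobility * species.concentration)


def permeability_ratio(perm_a, perm_b):
    """Element-wise permeability ratio a/b; b = 0 yields NaN (undefined).

    The ratio cancels per-cell pore number (hence adhesion area /
    cell size), leaving a tension-dependent species contrast.
    """
    scalar = np.asarray(perm_a).ndim == 0 and np.asarray(perm_b).ndim == 0
    a, b = np.broadcast_arrays(
        np.atleast_1d(np.asarray(perm_a, dtype=float)),
        np.atleast_1d(np.asarray(perm_b, dtype=float)),
    )
    out = np.full(a.shape, np.nan)
    defined = b > 0
    out[defined] = a[defined] / b[defined]
    return float(out[0]) if scalar else out


def demux_hashtags(
    hashtag_counts: pd.DataFrame, margin: float = 1.0, pseudocount: float = 1.0
) -> pd.Series:
    """Assign each cell a hashtag label, ``doublet`` or ``unassigned``.

    Heuristic margin classifier on per-cell CLR across hashtags: cells
    with no hashtag counts are ``unassigned``; otherwise the argmax
    hashtag wins when its CLR exceeds the runner-up by ``margin``, and
    ties within the margin are called ``doublet``. With a single
    hashtag every cell with counts gets that label.
    """
    counts = hashtag_counts.to_numpy(dtype=float)
    if counts.shape[0] < 1:
        raise ValueError("need at least one hashtag row")
    labels = np.full(counts.shape[1], "unassigned", dtype=object)
    has_counts = counts.sum(axis=0) > 0
    if counts.shape[0] == 1:
        labels[has_counts] = hashtag_counts.index[0]
        return pd.Series(labels, index=hashtag_counts.columns, name="population")
    clr = clr_tags(counts, pseudocount=pseudocount, across="tags")
    order = np.argsort(clr, axis=0)
    top = order[-1]
    top_clr = clr[top, np.arange(counts.shape[1])]
    runner_clr = clr[order[-2], np.arange(counts.shape[1])]
    confident = (top_clr - runner_clr) >= margin
    labels[has_counts & confident] = hashtag_counts.index.to_numpy()[top[has_counts & confident]]
    labels[has_counts & ~confident] = "doublet"
    return pd.Series(labels, index=hashtag_counts.columns, name="population")
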