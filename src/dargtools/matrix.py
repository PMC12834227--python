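"""Expression-matrix container, normalization and observation filtering.

The container is deliberately minimal: a genes x observations value block
(dense ndarray or scipy CSR) plus unique gene and observation identifiers and
a ``layer`` tag that records whether the values are raw integer counts or
log-normalized expression.  Everything downstream (voting thresholds,
rank-based AUC scoring) is defined on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "normalize",
    "filter_observations",
    "RAW_COUNTS",
    "NORMALIZED",
]

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {dupes[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x observations expression values.

    Parameters
    ----------
    gene_ids
        Unique gene symbols (rows).
    obs_ids
        Unique observation barcodes (columns; cells or spots).
    values
        Non-negative matrix of shape ``(len(gene_ids), len(obs_ids))``;
        integers when ``layer == "raw_counts"``.
    layer
        ``"raw_counts"`` or ``"normalized"``.
    meta
        Free-form provenance (normalization base/scale factor, filters applied).
    """

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray | sparse.spmatrix
    layer: str = RAW_COUNTS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene_ids")
        self.obs_ids = _check_unique(self.obs_ids, "obs_ids")
        if sparse.issparse(self.values):
            self.values = sparse.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.obs_ids)} observations)"
            )
        if self.layer not in (RAW_COUNTS, NORMALIZED):
            raise ValueError(f"unknown layer {self.layer!r}")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if data.size and np.min(data) < 0:
            raise ValueError("expression values must be non-negative")
        if self.layer == RAW_COUNTS and data.size and np.any(data != np.round(data)):
            raise ValueError("raw_counts layer must contain integers only")

    # -- basic geometry -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_obs)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``; raises KeyError naming absent genes."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=np.intp)

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def to_frame(self) -> pd.DataFrame:
        """Observations x genes DataFrame (the estimator orientation)."""
        return pd.DataFrame(self.dense().T, index=self.obs_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer: str = NORMALIZED) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.columns)),
            obs_ids=list(map(str, frame.index)),
            values=frame.to_numpy().T,
            layer=layer,
        )

    def obs_totals(self) -> np.ndarray:
        """Total counts per observation."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def obs_nonzero_genes(self) -> np.ndarray:
        """Number of genes with value > 0 per observation."""
        if sparse.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=0)).ravel()
        return (self.values > 0).sum(axis=0)

    def subset_obs(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            obs_ids=[self.obs_ids[i] for i in keep],
            values=self.values[:, keep],
            meta=dict(self.meta),
        )


def normalize(
    matrix: ExpressionMatrix,
    scale_factor: float = 10_000.0,
    log_base: float = 2.0,
) -> ExpressionMatrix:
    """Library-size normalize then log-transform raw counts.

    Each value ``v`` of an observation with total count ``s`` becomes
    ``log_base(1 + v * scale_factor / s)``.  Zero counts stay exactly zero, so
    sparsity is preserved.  ``log_base=2`` with ``scale_factor=10000`` is the
    convention all default voting thresholds are calibrated against;
    natural-log (``log_base=e``) is available and recorded in ``meta``.
    """
    if matrix.layer != RAW_COUNTS:
        raise ValueError("normalize expects a raw_counts matrix")
    if scale_factor <= 0 or log_base <= 1:
        raise ValueError("scale_factor must be > 0 and log_base > 1")
    totals = matrix.obs_totals()
    if np.any(totals == 0):
        bad = [matrix.obs_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"observations with zero total counts (e.g. {bad}); "
            "run filter_observations before normalize"
        )
    if sparse.issparse(matrix.values):
        out = sparse.csr_matrix(matrix.values, dtype=np.float64, copy=True)
        # scale columns by scale_factor / total, then log1p in place on the data
        inv = scale_factor / totals
        out = out @ sparse.diags(inv)
        out = sparse.csr_matrix(out)
        np.log1p(out.data, out=out.data)
        out.data /= np.log(log_base)
    else:
        out = np.log1p(matrix.values * (scale_factor / totals)) / np.log(log_base)
    meta = dict(matrix.meta)
    meta.update(scale_factor=scale_factor, log_base=float(log_base))
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        obs_ids=list(matrix.obs_ids),
        values=out,
        layer=NORMALIZED,
        meta=meta,
    )


def filter_observations(
    matrix: ExpressionMatrix, min_unique_genes: int = 100
) -> ExpressionMatrix:
    """Keep observations with strictly more than ``min_unique_genes`` detected genes.

    The default reproduces the spot filter used for spatial sections: spots
    with >100 unique genes are kept; a spot with exactly 100 is dropped.
    """
    if matrix.layer != RAW_COUNTS:
        raise ValueError("filter_observations expects a raw_counts matrix")
    nnz = matrix.obs_nonzero_genes()
    keep = nnz > min_unique_genes
    if not keep.any():
        raise ValueError(
            f"no observation has more than {min_unique_genes} detected genes"
        )
    out = matrix.subset_obs(keep)
    out.meta.setdefault("filters", []).append(
        {"min_unique_genes": int(min_unique_genes), "kept": int(keep.sum())}
    )
    return out
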