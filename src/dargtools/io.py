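"""Readers and writers for the on-disk formats the pipeline exchanges.

Counts travel as the standard MatrixMarket triplet (``matrix.mtx`` with
1-based coordinates, plus ``features.tsv`` and ``barcodes.tsv`` companions);
spot metadata and score tables are plain CSV.  MatrixMarket parsing is
delegated to :func:`scipy.io.mmread` / :func:`scipy.io.mmwrite`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import RAW_COUNTS, ExpressionMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_spot_table",
    "write_spot_table",
    "validate_spot_table",
    "SPOT_COLUMNS",
    "TISSUES",
    "GROUPS",
]

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["obs_id", "x", "y", "tissue", "niche", "sample_id", "group"]
TISSUES = ("WM", "GM")
GROUPS = ("Ctrl", "MS")

#: default niche vocabulary: lesion core, lesion rim, perilesional WM,
#: normal-appearing WM, control WM and gray-matter zones
DEFAULT_NICHES = ("LC", "LR", "PLWM", "NAWM", "CWM", "GM1", "GM2", "GM3", "GM4")


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate gene symbols with '.1', '.2', ... in file order."""
    counts: dict[str, int] = {}
    out: list[str] = []
    for s in symbols:
        if s in counts:
            counts[s] += 1
            out.append(f"{s}.{counts[s]}")
            logger.warning("duplicate gene symbol %s renamed to %s", s, out[-1])
        else:
            counts[s] = 0
            out.append(s)
    return out


def read_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a genes x observations raw-count matrix from an MTX triplet.

    Features/barcodes are one record per line (first TSV column used).
    Duplicate symbols are suffixed ``.1``, ``.2``, ... deterministically.
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except ValueError as exc:
        raise ValueError(f"{matrix_path}: malformed MatrixMarket file: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    genes = _dedup_symbols([s.strip() for s in features.iloc[:, 0].tolist()])
    obs = [s.strip() for s in barcodes.iloc[:, 0].tolist()]
    if mat.shape != (len(genes), len(obs)):
        raise ValueError(
            f"matrix dimensions {mat.shape} do not match features ({len(genes)}) "
            f"x barcodes ({len(obs)})"
        )
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValueError(f"{matrix_path}: count matrix contains non-integer values")
    mat.data = mat.data.astype(np.int64)
    return ExpressionMatrix(gene_ids=genes, obs_ids=obs, values=mat, layer=RAW_COUNTS)


def write_counts(matrix: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the MTX triplet; returns the three paths."""
    if matrix.layer != RAW_COUNTS:
        raise ValueError("write_counts writes raw counts only")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    values = matrix.values
    if not sparse.issparse(values):
        values = sparse.coo_matrix(values)
    spio.mmwrite(str(paths["matrix"]), sparse.coo_matrix(values), field="integer")
    paths["features"].write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in matrix.obs_ids))
    return paths


def validate_spot_table(
    spots: pd.DataFrame, niche_vocabulary: tuple[str, ...] | None = DEFAULT_NICHES
) -> pd.DataFrame:
    """Validate spot metadata: columns, unique barcodes, integer grid
    coordinates, tissue/group enums, and the (sample_id, x, y) uniqueness."""
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table missing columns {missing}")
    spots = spots[SPOT_COLUMNS].copy()
    spots["obs_id"] = spots["obs_id"].astype(str)
    if spots["obs_id"].duplicated().any():
        dupes = spots.loc[spots["obs_id"].duplicated(), "obs_id"].head().tolist()
        raise ValueError(f"duplicate obs_id in spot table: {dupes}")
    for c in ("x", "y"):
        vals = spots[c].astype(float)
        if (vals < 0).any() or (vals != np.round(vals)).any():
            raise ValueError(f"column {c} must hold non-negative integers")
        spots[c] = vals.astype(int)
    if spots.duplicated(subset=["sample_id", "x", "y"]).any():
        raise ValueError("(sample_id, x, y) must be unique")
    bad_tissue = sorted(set(spots["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise ValueError(f"unknown tissue labels {bad_tissue}; expected {TISSUES}")
    bad_group = sorted(set(spots["group"]) - set(GROUPS))
    if bad_group:
        raise ValueError(f"unknown group labels {bad_group}; expected {GROUPS}")
    if niche_vocabulary is not None:
        bad_niche = sorted(set(spots["niche"]) - set(niche_vocabulary))
        if bad_niche:
            raise ValueError(
                f"unknown niche labels {bad_niche}; expected one of {niche_vocabulary}"
            )
    return spots


def read_spot_table(
    path: str | Path, niche_vocabulary: tuple[str, ...] | None = DEFAULT_NICHES
) -> pd.DataFrame:
    return validate_spot_table(pd.read_csv(path), niche_vocabulary)


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    validate_spot_table(spots, niche_vocabulary=None).to_csv(path, index=False)


def namespace_barcodes(obs_ids: list[str], sample_id: str) -> list[str]:
    """Namespace barcodes as '<sample_id>:<barcode>' to keep them unique
    when several samples are concatenated."""
    return [f"{sample_id}:{b}" for b in obs_ids]
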