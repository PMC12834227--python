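"""Gene signatures with k-of-n voting parameters, plus GMT / gene-list readers.

A signature is ``n`` ordered gene symbols with a voting rule: an observation is
called positive when at least ``k = n - t`` of the genes are expressed at or
above the threshold ``theta`` (``mode="threshold"``) or simply detected
(``mode="presence"``, where ``theta`` is ignored and positivity means a value
strictly greater than zero).  ``k`` (minimum genes) and ``t`` (tolerance, the
number of genes allowed to be missing) are interchangeable parameterizations
and must round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GeneSignature", "read_gmt", "read_gene_list", "read_signatures"]

logger = logging.getLogger(__name__)

THRESHOLD = "threshold"
PRESENCE = "presence"


def _normalize_symbols(genes, where: str) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        g = str(g).strip().upper()
        if not g:
            continue
        if g in seen:
            logger.warning("duplicate gene %s in %s dropped", g, where)
            continue
        seen.add(g)
        out.append(g)
    return out


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with its k-of-n voting rule."""

    name: str
    genes: tuple[str, ...]
    min_genes: int  # k
    expr_threshold: float = 0.0  # theta; ignored in presence mode
    mode: str = THRESHOLD
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(_normalize_symbols(self.genes, self.name)))
        n = len(self.genes)
        if n == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        if not (1 <= self.min_genes <= n):
            raise ValueError(
                f"signature {self.name!r}: min_genes k={self.min_genes} outside [1, n={n}]"
            )
        if self.mode not in (THRESHOLD, PRESENCE):
            raise ValueError(f"signature {self.name!r}: unknown mode {self.mode!r}")
        if self.expr_threshold < 0:
            raise ValueError(f"signature {self.name!r}: expr_threshold must be >= 0")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def tolerance(self) -> int:
        """Genes allowed to fall below threshold: t = n - k."""
        return self.n - self.min_genes

    @classmethod
    def from_tolerance(
        cls,
        name: str,
        genes,
        tolerance: int,
        expr_threshold: float = 0.0,
        mode: str = THRESHOLD,
        description: str = "",
    ) -> "GeneSignature":
        genes = tuple(_normalize_symbols(genes, name))
        if tolerance < 0 or tolerance >= len(genes):
            raise ValueError(
                f"signature {name!r}: tolerance t={tolerance} outside [0, n-1]"
            )
        return cls(
            name=name,
            genes=genes,
            min_genes=len(genes) - tolerance,
            expr_threshold=expr_threshold,
            mode=mode,
            description=description,
        )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (name <TAB> description <TAB> gene ...) into an ordered dict.

    Symbols are uppercased; duplicates within a set are dropped with a warning.
    Malformed lines raise with their 1-based line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = parts[0].strip()
            if not name:
                raise ValueError(f"{path}:{lineno}: empty gene-set name")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = _normalize_symbols(parts[2:], f"{path}:{lineno} ({name})")
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    path = Path(path)
    with open(path) as fh:
        raw = [ln.strip() for ln in fh]
    genes = _normalize_symbols(
        (g for g in raw if g and not g.startswith("#")), str(path)
    )
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return genes


@dataclass
class VotingParams:
    """Per-signature voting parameters supplied by configuration."""

    min_genes: int
    expr_threshold: float = 0.0
    mode: str = THRESHOLD


def read_signatures(
    path: str | Path,
    fmt: str = "gmt",
    params: dict[str, VotingParams] | None = None,
    default_params: VotingParams | None = None,
) -> list[GeneSignature]:
    """Read signatures from a GMT file (or a single gene-list file) and attach
    voting parameters from configuration.

    ``params`` maps signature name to its :class:`VotingParams`;
    ``default_params`` applies to signatures not listed.  Without either, a
    permissive default of k=1, theta=0, presence mode is used (pure gene sets).
    """
    params = params or {}
    if fmt == "gmt":
        raw = read_gmt(path)
    elif fmt == "list":
        name = Path(path).stem
        raw = {name: read_gene_list(path)}
    else:
        raise ValueError(f"unknown signature format {fmt!r}")
    out: list[GeneSignature] = []
    for name, genes in raw.items():
        p = params.get(name, default_params) or VotingParams(
            min_genes=1, expr_threshold=0.0, mode=PRESENCE
        )
        out.append(
            GeneSignature(
                name=name,
                genes=tuple(genes),
                min_genes=p.min_genes,
                expr_threshold=p.expr_threshold,
                mode=p.mode,
            )
        )
    return out
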