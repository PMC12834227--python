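"""Gene-module correspondence between datasets.

Pseudotime gene modules derived in one dataset (e.g. in vitro, the baseline
comparator) are matched to modules derived in another (ex vivo) through their
gene overlap.  Each pair gets a size-penalized overlap score — the Ochiai
coefficient |A∩B| / sqrt(|A||B|), so larger sets are penalized more than
smaller ones — and a two-sided Fisher exact test on the 2x2 membership table
over a shared gene universe.  Benjamini-Hochberg correction is applied across
all pairs jointly, and the best match per baseline module is the significant
pair with the highest scaled score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneModule",
    "scaled_overlap",
    "fisher_overlap",
    "bh_adjust",
    "match_modules",
    "ModuleMatcher",
]


@dataclass(frozen=True)
class GeneModule:
    """A named set of genes (one co-varying cluster along a trajectory)."""

    module_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(str(g).upper() for g in self.genes)
        )
        if not self.genes:
            raise ValueError(f"module {self.module_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def scaled_overlap(a: GeneModule, b: GeneModule, scaling: str = "ochiai") -> float:
    """Size-penalized overlap in [0, 1]; symmetric; 1 iff the sets are equal.

    ``"ochiai"`` (default): |A∩B| / sqrt(|A|·|B|);
    ``"containment"``: |A∩B| / max(|A|, |B|).
    """
    inter = len(a.genes & b.genes)
    if scaling == "ochiai":
        return inter / math.sqrt(len(a) * len(b))
    if scaling == "containment":
        return inter / max(len(a), len(b))
    raise ValueError(f"unknown scaling {scaling!r}")


def _fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]] with fixed margins.

    Exact integer arithmetic: sum the hypergeometric probabilities of all
    tables whose probability is <= that of the observed table, with weights
    compared as integers so ties are decided exactly.
    """
    K = a + b  # |A|
    n = a + c  # |B|
    N = a + b + c + d  # |U|
    lo = max(0, K + n - N)
    hi = min(K, n)
    w_obs = math.comb(K, a) * math.comb(N - K, n - a)
    num = 0
    for x in range(lo, hi + 1):
        w = math.comb(K, x) * math.comb(N - K, n - x)
        if w <= w_obs:
            num += w
    return num / math.comb(N, n)


def fisher_overlap(
    a: GeneModule, b: GeneModule, universe: set[str]
) -> tuple[tuple[int, int, int, int], float, float]:
    """2x2 membership table, two-sided exact p, and sample odds ratio.

    The table is (in-A&in-B, in-A-only, in-B-only, in-neither) over
    ``universe``; the odds ratio is (a*d)/(b*c), infinite on division by zero
    with a non-zero numerator and NaN for 0/0.
    """
    universe = {str(g).upper() for g in universe}
    if not a.genes <= universe:
        raise ValueError(
            f"module {a.module_id!r} has genes outside the universe: "
            f"{sorted(a.genes - universe)[:5]}"
        )
    if not b.genes <= universe:
        raise ValueError(
            f"module {b.module_id!r} has genes outside the universe: "
            f"{sorted(b.genes - universe)[:5]}"
        )
    aa = len(a.genes & b.genes)
    bb = len(a.genes) - aa
    cc = len(b.genes) - aa
    dd = len(universe) - aa - bb - cc
    p = _fisher_two_sided_exact(aa, bb, cc, dd)
    num, den = aa * dd, bb * cc
    if den == 0:
        odds = math.nan if num == 0 else math.inf
    else:
        odds = num / den
    return (aa, bb, cc, dd), p, odds


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-down adjusted q-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def match_modules(
    baseline: list[GeneModule],
    query: list[GeneModule],
    universe: set[str] | None = None,
    alpha: float = 0.05,
    scaling: str = "ochiai",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score all baseline x query pairs and assign a best match per baseline.

    ``universe`` defaults to the union of all module genes.  BH correction is
    applied across all pairs as one family.  The best match of a baseline
    module is the query module with the highest scaled score among pairs with
    q < alpha; ties go to the smaller p, then the lexicographically smaller
    query_id; a baseline with no significant pair maps to no match (None).

    Returns ``(results, best)`` DataFrames.
    """
    if not baseline or not query:
        raise ValueError("baseline and query module collections must be non-empty")
    all_genes = set().union(*(m.genes for m in baseline + query))
    if universe is None:
        universe = all_genes
    else:
        universe = {str(g).upper() for g in universe}
        if not all_genes <= universe:
            raise ValueError("universe does not cover all module genes")
    rows = []
    for bm in baseline:
        for qm in query:
            table, p, odds = fisher_overlap(bm, qm, universe)
            rows.append(
                {
                    "baseline_id": bm.module_id,
                    "query_id": qm.module_id,
                    "a": table[0],
                    "b": table[1],
                    "c": table[2],
                    "d": table[3],
                    "scaled_score": scaled_overlap(bm, qm, scaling=scaling),
                    "p": p,
                    "odds_ratio": odds,
                }
            )
    results = pd.DataFrame(rows)
    results["q_bh"] = bh_adjust(results["p"].to_numpy())
    best_rows = []
    for bm in baseline:
        sub = results[
            (results["baseline_id"] == bm.module_id) & (results["q_bh"] < alpha)
        ]
        if len(sub) == 0:
            best_rows.append(
                {"baseline_id": bm.module_id, "query_id": None, "scaled_score": np.nan,
                 "p": np.nan, "q_bh": np.nan}
            )
            continue
        sub = sub.sort_values(
            ["scaled_score", "p", "query_id"], ascending=[False, True, True]
        )
        top = sub.iloc[0]
        best_rows.append(
            {
                "baseline_id": bm.module_id,
                "query_id": top["query_id"],
                "scaled_score": top["scaled_score"],
                "p": top["p"],
                "q_bh": top["q_bh"],
            }
        )
    return results, pd.DataFrame(best_rows)


class ModuleMatcher(BaseEstimator):
    """Estimator-style wrapper: ``fit`` stores the baseline module collection
    (the comparator), ``match`` scores a query collection against it."""

    def __init__(
        self,
        universe: set[str] | None = None,
        alpha: float = 0.05,
        scaling: str = "ochiai",
    ):
        self.universe = universe
        self.alpha = alpha
        self.scaling = scaling

    def fit(self, baseline: list[GeneModule], y=None) -> "ModuleMatcher":
        if not baseline:
            raise ValueError("baseline collection must be non-empty")
        self.baseline_ = list(baseline)
        return self

    def match(self, query: list[GeneModule]) -> tuple[pd.DataFrame, pd.DataFrame]:
        check_is_fitted(self, "baseline_")
        return match_modules(
            self.baseline_,
            query,
            universe=self.universe,
            alpha=self.alpha,
            scaling=self.scaling,
        )
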