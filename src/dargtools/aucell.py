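"""Rank-based signature-recovery AUC scoring and its permutation null.

Per observation, genes with non-zero expression are ranked by decreasing
value (zero-count genes are discarded from the ranking entirely); ties are
broken by a seeded random permutation within each tie group so replays are
deterministic.  The recovery curve c(i) counts how many signature genes sit
at ranking positions <= i; the score is

    auc = sum_{i=1..T} c(i)  /  sum_{i=1..T} min(i, m)

with T = max(1, floor(top_fraction * n_genes_in_universe)) and m the number
of signature genes present in the universe.  The denominator is the maximum
achievable area, so the score lies in [0, 1] and depends only on ranks.

The background null rescores every observation with random gene sets of the
same length drawn uniformly from the gene universe; the empirical upper
quantile of the pooled scores is the data-driven confidence threshold above
which a signature score is called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix

__all__ = [
    "rank_observation",
    "recovery_auc",
    "score_signature",
    "build_null",
    "NullDistribution",
    "AUCellScorer",
]

# sub-stream tags: tie-breaking uses default_rng([seed, _TIE, obs_index]),
# null gene-set sampling uses default_rng([seed, _NULL])
_TIE = 0
_NULL = 1


def _as_obs_by_gene(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, ExpressionMatrix):
        return X.dense().T, list(X.obs_ids), list(X.gene_ids)
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            [str(i) for i in X.index],
            [str(c).upper() for c in X.columns],
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional (observations x genes)")
    return arr, [str(i) for i in range(arr.shape[0])], [str(j) for j in range(arr.shape[1])]


def _tie_rng(seed: int, obs_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _TIE, int(obs_index)])


def ranking_positions(X, seed: int = 0) -> np.ndarray:
    """1-based ranking position of every gene in every observation.

    Returns an int32 array of shape (n_obs, n_genes); zero-valued genes get
    the sentinel ``n_genes + 1`` (never inside any top fraction).  Raises on
    an all-zero observation — those must be filtered upstream.
    """
    arr, obs_ids, _ = _as_obs_by_gene(X)
    n_obs, n_genes = arr.shape
    sentinel = n_genes + 1
    out = np.empty((n_obs, n_genes), dtype=np.int32)
    for i in range(n_obs):
        v = arr[i]
        nnz = int(np.count_nonzero(v))
        if nnz == 0:
            raise ValueError(
                f"observation {obs_ids[i]!r} has no expressed genes; "
                "filter all-zero observations before scoring"
            )
        u = _tie_rng(seed, i).random(n_genes)
        order = np.lexsort((u, -v))  # decreasing value, seeded-random ties
        row = np.full(n_genes, sentinel, dtype=np.int32)
        row[order[:nnz]] = np.arange(1, nnz + 1, dtype=np.int32)
        out[i] = row
    return out


def rank_observation(expr, seed: int = 0, obs_index: int = 0) -> list:
    """Ranking of the non-zero genes of one observation, best first.

    ``expr`` is a pandas Series (index = gene symbols) or 1-d array; the
    returned list holds gene labels (or integer indices for arrays).  Ties
    are broken by the same seeded stream the matrix-level scorer uses for
    observation ``obs_index``.
    """
    if isinstance(expr, pd.Series):
        labels = list(expr.index)
        v = expr.to_numpy(dtype=float)
    else:
        v = np.asarray(expr, dtype=float)
        labels = list(range(v.size))
    if v.ndim != 1:
        raise ValueError("expr must be one observation (1-d)")
    nnz = int(np.count_nonzero(v))
    if nnz == 0:
        raise ValueError("observation has no expressed genes")
    u = _tie_rng(seed, obs_index).random(v.size)
    order = np.lexsort((u, -v))
    return [labels[j] for j in order[:nnz]]


def _auc_denominator(T: int, m: int) -> int:
    if m >= T:
        return T * (T + 1) // 2
    return m * (m + 1) // 2 + (T - m) * m


def _top_size(n_universe: int, top_fraction: float) -> int:
    T = int(np.floor(top_fraction * n_universe))
    return max(1, T)


def recovery_auc(
    ranking,
    sig_genes,
    top_fraction: float = 0.05,
    m: int | None = None,
    n_universe: int | None = None,
) -> float:
    """Recovery AUC of one observation from an explicit ranking.

    ``ranking`` lists the non-zero genes best-first; ``n_universe`` is the
    size of the gene universe the ranking was built from (defaults to the
    ranking length) and sets T; ``m`` is the number of signature genes in the
    universe (defaults to ``len(sig_genes)``).  Signature genes absent from
    the ranking are never recovered.
    """
    ranking = list(ranking)
    sig = set(sig_genes)
    if m is None:
        m = len(sig)
    if m == 0:
        raise ValueError("signature has no genes in the universe (m = 0)")
    if n_universe is None:
        n_universe = len(ranking)
    T = _top_size(n_universe, top_fraction)
    if T < 1:
        raise ValueError("top fraction selects no genes (T < 1)")
    num = 0
    for pos, gene in enumerate(ranking[:T], start=1):
        if gene in sig:
            num += T - pos + 1
    return num / _auc_denominator(T, m)


def _scores_from_positions(
    positions: np.ndarray, sig_cols: np.ndarray, top_fraction: float
) -> np.ndarray:
    n_universe = positions.shape[1]
    T = _top_size(n_universe, top_fraction)
    m = len(sig_cols)
    credit = np.clip(T + 1 - positions[:, sig_cols].astype(np.int64), 0, None)
    return credit.sum(axis=1) / _auc_denominator(T, m)


def score_signature(
    matrix,
    sig_genes,
    top_fraction: float = 0.05,
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Recovery AUC of a signature for every observation.

    Returns a DataFrame indexed by obs_id with one column ``auc``.  Passing a
    precomputed ``positions`` array (from :func:`ranking_positions` with the
    same seed) avoids re-ranking when several signatures are scored.
    """
    arr, obs_ids, genes = _as_obs_by_gene(matrix)
    lookup = {g: j for j, g in enumerate(genes)}
    sig_cols = np.array(
        [lookup[g] for g in {str(g).upper() for g in sig_genes} if g in lookup],
        dtype=np.intp,
    )
    if sig_cols.size == 0:
        raise ValueError("no signature gene is present in the matrix universe")
    if positions is None:
        positions = ranking_positions(arr, seed=seed)
    auc = _scores_from_positions(positions, sig_cols, top_fraction)
    return pd.DataFrame({"auc": auc}, index=pd.Index(obs_ids, name="obs_id"))


@dataclass
class NullDistribution:
    """Pooled background distribution of recovery-AUC scores.

    ``scores`` pools all observations x ``n_perm`` random gene sets of length
    ``sig_length``; ``threshold`` is the empirical ``quantile_q`` quantile —
    the dataset-level confidence limit on AUC background noise.
    """

    scores: np.ndarray
    n_perm: int
    sig_length: int
    quantile_q: float
    threshold: float
    seed: int
    top_fraction: float = 0.05
    n_obs: int = 0

    def summary(self) -> dict:
        return {
            "n_perm": int(self.n_perm),
            "sig_length": int(self.sig_length),
            "quantile_q": float(self.quantile_q),
            "threshold": float(self.threshold),
            "seed": int(self.seed),
            "top_fraction": float(self.top_fraction),
            "n_obs": int(self.n_obs),
            "n_scores": int(self.scores.size),
        }

    def save(self, path: str | Path, raw_scores: str | Path | None = None) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")
        if raw_scores is not None:
            pd.DataFrame({"auc": self.scores}).to_csv(raw_scores, index=False)


def build_null(
    matrix,
    sig_length: int,
    n_perm: int = 10_000,
    quantile_q: float = 0.95,
    seed: int = 0,
    top_fraction: float = 0.05,
    positions: np.ndarray | None = None,
) -> NullDistribution:
    """Permutation background of AUC scores from random gene sets.

    For each of ``n_perm`` permutations, ``sig_length`` genes are sampled
    uniformly without replacement from the matrix gene universe and every
    observation is rescored; all scores are pooled and the ``quantile_q``
    empirical quantile becomes the calling threshold.  Rankings (and their
    tie-break streams) are shared with :func:`score_signature` at the same
    seed, so the true signature is compared against an identically ranked
    background.
    """
    arr, _, genes = _as_obs_by_gene(matrix)
    n_genes = len(genes)
    m = int(sig_length)
    if not (0 < m < n_genes):
        raise ValueError(
            f"sig_length m={m} must be positive and smaller than the universe ({n_genes})"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0.0 < quantile_q < 1.0):
        raise ValueError("quantile_q must lie in (0, 1)")
    if positions is None:
        positions = ranking_positions(arr, seed=seed)
    n_obs = positions.shape[0]
    T = _top_size(n_genes, top_fraction)
    den = _auc_denominator(T, m)
    credit = np.clip(T + 1 - positions.astype(np.int32), 0, None).astype(np.int32)
    rng = np.random.default_rng([int(seed), _NULL])
    pooled = np.empty((n_perm, n_obs), dtype=np.float32)
    for p in range(n_perm):
        cols = rng.choice(n_genes, size=m, replace=False)
        pooled[p] = credit[:, cols].sum(axis=1, dtype=np.int64) / den
    scores = pooled.ravel()
    threshold = float(np.quantile(scores, quantile_q))
    return NullDistribution(
        scores=scores,
        n_perm=int(n_perm),
        sig_length=m,
        quantile_q=float(quantile_q),
        threshold=threshold,
        seed=int(seed),
        top_fraction=float(top_fraction),
        n_obs=int(n_obs),
    )


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer producing per-observation recovery AUCs.

    ``fit`` records the gene universe and locates the signature genes;
    ``transform`` returns an (n_obs, 1) array of AUC scores for new data with
    the same gene columns.
    """

    def __init__(self, genes=(), top_fraction: float = 0.05, random_state: int = 0):
        self.genes = genes
        self.top_fraction = top_fraction
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "AUCellScorer":
        _, _, universe = _as_obs_by_gene(X)
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in (0, 1]")
        sig = {str(g).upper() for g in self.genes}
        if not sig:
            raise ValueError("signature has no genes")
        self.feature_names_in_ = np.asarray(universe, dtype=object)
        self.n_features_in_ = len(universe)
        self.genes_present_ = sorted(sig & set(universe))
        self.missing_genes_ = sorted(sig - set(universe))
        if not self.genes_present_:
            raise ValueError(
                f"no signature gene in the matrix universe: {self.missing_genes_}"
            )
        self.m_ = len(self.genes_present_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "genes_present_")
        scores = score_signature(
            X,
            self.genes_present_,
            top_fraction=self.top_fraction,
            seed=self.random_state,
        )
        return scores["auc"].to_numpy()[:, None]
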