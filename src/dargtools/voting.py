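"""k-of-n gene-signature voting.

An observation is called positive for a signature when at least ``k`` of its
``n`` genes are expressed at or above the threshold ``theta`` (threshold mode,
inclusive comparison) or detected at all (presence mode, strictly > 0).
Signature genes absent from the matrix count as never expressed — ``n`` stays
fixed so the k-of-n semantics are stable across datasets — and are logged.

The same rule, parameterized by a tolerance ``t = n - k`` (how many genes may
be missing), selects pseudotime anchor regions: the trajectory start in the
in-vitro data uses TOP2A, CENPF, UBE2C, ASPM, APOLD1 at theta=2 with t=1, the
end region IFIT2 and CDKN2A at theta=1.5 with t=0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import NORMALIZED, ExpressionMatrix
from .signatures import PRESENCE, THRESHOLD, GeneSignature

__all__ = ["SignatureVoter", "vote", "select_anchor_cells", "positive_fraction"]

logger = logging.getLogger(__name__)


class SignatureVoter(BaseEstimator, TransformerMixin):
    """Classify observations by k-of-n signature voting.

    Parameters
    ----------
    genes : sequence of str
        Signature genes (the ``n`` voters).
    min_genes : int
        Minimum voters required for a positive call (``k``).
    expr_threshold : float, default 0.0
        Per-gene expression threshold ``theta`` (inclusive); ignored in
        presence mode.
    mode : {"threshold", "presence"}, default "threshold"
        Presence mode counts genes with value strictly greater than zero.
    average_mode : bool, default False
        Optional variant: additionally require the mean expression of the
        signature genes (present in the matrix) to reach ``expr_threshold``.

    Attributes
    ----------
    feature_names_in_ : ndarray of str
        Gene universe seen during :meth:`fit`.
    genes_present_ : list of str
        Signature genes found in the universe.
    missing_genes_ : list of str
        Signature genes absent from the universe (count as never expressed).
    """

    def __init__(
        self,
        genes=(),
        min_genes: int = 1,
        expr_threshold: float = 0.0,
        mode: str = THRESHOLD,
        average_mode: bool = False,
    ):
        self.genes = genes
        self.min_genes = min_genes
        self.expr_threshold = expr_threshold
        self.mode = mode
        self.average_mode = average_mode

    @classmethod
    def from_signature(cls, sig: GeneSignature) -> "SignatureVoter":
        return cls(
            genes=sig.genes,
            min_genes=sig.min_genes,
            expr_threshold=sig.expr_threshold,
            mode=sig.mode,
        )

    # -- estimator API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "SignatureVoter":
        """Record the gene universe and locate the signature genes.

        ``X`` is observations x genes with gene symbols as columns.
        """
        X = self._as_frame(X)
        genes = [str(g).upper() for g in self.genes]
        if len(genes) == 0:
            raise ValueError("signature has no genes")
        if len(set(genes)) != len(genes):
            raise ValueError("signature genes must be unique")
        if not (1 <= self.min_genes <= len(genes)):
            raise ValueError(
                f"min_genes k={self.min_genes} outside [1, n={len(genes)}]"
            )
        if self.mode not in (THRESHOLD, PRESENCE):
            raise ValueError(f"unknown mode {self.mode!r}")
        universe = {str(c).upper() for c in X.columns}
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.genes_present_ = [g for g in genes if g in universe]
        self.missing_genes_ = [g for g in genes if g not in universe]
        if not self.genes_present_:
            raise ValueError(
                f"none of the signature genes are in the matrix: {self.missing_genes_}"
            )
        if self.missing_genes_:
            logger.warning(
                "%d/%d signature genes missing from matrix (counted as never "
                "expressed): %s",
                len(self.missing_genes_),
                len(genes),
                self.missing_genes_,
            )
        return self

    def transform(self, X) -> np.ndarray:
        """Vote counts per observation, shape (n_obs, 1)."""
        return self.vote_counts(X).to_numpy()[:, None]

    def predict(self, X) -> np.ndarray:
        """Boolean positive calls per observation."""
        check_is_fitted(self, "genes_present_")
        counts = self.vote_counts(X)
        calls = counts >= self.min_genes
        if self.average_mode and self.mode == THRESHOLD:
            sub = self._as_frame(X)[self.genes_present_]
            calls &= sub.mean(axis=1) >= self.expr_threshold
        return calls.to_numpy()

    def vote_counts(self, X) -> pd.Series:
        """Number of signature genes positive per observation."""
        check_is_fitted(self, "genes_present_")
        X = self._as_frame(X)
        sub = X[self.genes_present_].to_numpy()
        if self.mode == PRESENCE:
            pos = sub > 0
        else:
            pos = sub >= self.expr_threshold
        return pd.Series(pos.sum(axis=1), index=X.index, name="vote_count")

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ExpressionMatrix):
            return X.to_frame()
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a DataFrame (observations x genes) or ExpressionMatrix"
            )
        out = X.rename(columns=lambda c: str(c).upper())
        if out.columns.duplicated().any():
            raise ValueError("gene columns not unique after uppercasing")
        return out


def _require_normalized(matrix: ExpressionMatrix, sig_mode: str) -> None:
    if sig_mode == THRESHOLD and matrix.layer != NORMALIZED:
        raise ValueError(
            "threshold-mode voting is defined on the normalized layer; "
            "call normalize() first (presence mode accepts raw counts)"
        )


def vote(matrix: ExpressionMatrix, sig: GeneSignature) -> pd.DataFrame:
    """Apply a signature's voting rule to every observation.

    Returns a DataFrame indexed by obs_id with columns ``vote_count`` and
    ``call``.
    """
    _require_normalized(matrix, sig.mode)
    voter = SignatureVoter.from_signature(sig)
    frame = matrix.to_frame()
    voter.fit(frame)
    counts = voter.vote_counts(frame)
    return pd.DataFrame(
        {"vote_count": counts, "call": counts >= sig.min_genes}, index=frame.index
    )


def select_anchor_cells(
    matrix: ExpressionMatrix,
    genes,
    expr_threshold: float,
    tolerance: int,
) -> set[str]:
    """Observations expressing at least ``n - tolerance`` of ``genes`` at
    ``>= expr_threshold`` — the pseudotime anchor-region rule.

    Missing genes count toward the tolerance (they are never expressed).
    """
    sig = GeneSignature.from_tolerance(
        name="anchor",
        genes=genes,
        tolerance=tolerance,
        expr_threshold=expr_threshold,
        mode=THRESHOLD,
    )
    calls = vote(matrix, sig)
    return set(calls.index[calls["call"]])


def positive_fraction(calls: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-label positive fractions (e.g. RG-like frequency per cluster, or
    the fraction of cells with non-zero SenMayo expression per lesion area).

    Returns a DataFrame with columns label, n_positive, n_total, fraction.
    """
    calls = pd.Series(calls).astype(bool)
    labels = pd.Series(labels)
    unlabeled = calls.index.difference(labels.index)
    if len(unlabeled):
        raise ValueError(f"observations without a label: {list(unlabeled[:5])}")
    labels = labels.reindex(calls.index)
    if labels.isna().any():
        raise ValueError("observations with missing label values")
    grouped = calls.groupby(labels, sort=True)
    out = pd.DataFrame(
        {
            "label": grouped.sum().index,
            "n_positive": grouped.sum().to_numpy(),
            "n_total": grouped.count().to_numpy(),
        }
    )
    out["fraction"] = out["n_positive"] / out["n_total"]
    return out
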