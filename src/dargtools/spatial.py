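"""DARG-high spot calling and niche/patient-level summaries.

A spot is called DARG-high when (1) its DARG signature AUC exceeds the
permutation-null confidence threshold and (2) it expresses strictly more than
a tissue-specific number of genes from BOTH the radial-glia and the
inflammatory signature subsets — more than 6 genes in white-matter samples,
more than 4 in gray-matter samples (presence counting by default).  Both
inequalities are strict.  Summaries aggregate the calls per spatial niche
(lesion core -> rim -> perilesional WM -> NAWM) and per patient, and the
quantile-binned t-test compares enrichment-score distributions between
groupings without inflating n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .aucell import NullDistribution, build_null, ranking_positions, score_signature
from .matrix import ExpressionMatrix
from .voting import SignatureVoter

__all__ = [
    "GENE_COUNT_THRESHOLDS",
    "DargCall",
    "call_darg_high",
    "niche_summary",
    "patient_summary",
    "quantile_bin_test",
    "associate_covariate",
    "DargHighClassifier",
]

#: strictly-greater-than gene-count gates per tissue class
GENE_COUNT_THRESHOLDS = {"WM": 6, "GM": 4}


@dataclass(frozen=True)
class DargCall:
    obs_id: str
    auc: float
    passed_auc: bool
    rg_vote_count: int
    infl_vote_count: int
    tissue: str
    darg_high: bool


def call_darg_high(
    scores: pd.DataFrame,
    null: NullDistribution | float,
    rg_votes: pd.Series,
    infl_votes: pd.Series,
    spot_table: pd.DataFrame,
    gene_count_thresholds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Combine the AUC gate and the dual vote-count gate into DARG-high calls.

    All inputs must cover the same observations (aligned on obs_id).  Returns
    a DataFrame with columns obs_id, auc, passed_auc, rg_vote_count,
    infl_vote_count, tissue, darg_high.
    """
    thresholds = dict(GENE_COUNT_THRESHOLDS)
    if gene_count_thresholds:
        thresholds.update(gene_count_thresholds)
    thr = null.threshold if isinstance(null, NullDistribution) else float(null)
    obs = pd.Index(scores.index.astype(str), name="obs_id")
    spot = spot_table.set_index(spot_table["obs_id"].astype(str))
    for name, series in (
        ("rg_votes", rg_votes),
        ("infl_votes", infl_votes),
        ("spot_table", pd.Series(spot["tissue"])),
    ):
        missing = obs.difference(series.index.astype(str))
        if len(missing):
            raise ValueError(
                f"{name} is missing observations present in scores: "
                f"{list(missing[:5])}"
            )
    tissue = spot.loc[obs, "tissue"]
    unknown = sorted(set(tissue) - set(thresholds))
    if unknown:
        raise ValueError(f"no gene-count threshold for tissue {unknown}")
    g = tissue.map(thresholds).to_numpy()
    auc = scores["auc"].to_numpy(dtype=float)
    rg = rg_votes.reindex(obs).to_numpy(dtype=int)
    infl = infl_votes.reindex(obs).to_numpy(dtype=int)
    passed_auc = auc > thr
    darg_high = passed_auc & (rg > g) & (infl > g)
    return pd.DataFrame(
        {
            "obs_id": obs,
            "auc": auc,
            "passed_auc": passed_auc,
            "rg_vote_count": rg,
            "infl_vote_count": infl,
            "tissue": tissue.to_numpy(),
            "darg_high": darg_high,
        }
    ).reset_index(drop=True)


def niche_summary(calls: pd.DataFrame, spot_table: pd.DataFrame) -> pd.DataFrame:
    """Per-niche spot counts, DARG-high counts and fractions, and mean AUC."""
    spot = spot_table.set_index(spot_table["obs_id"].astype(str))
    obs = calls["obs_id"].astype(str)
    missing = obs[~obs.isin(spot.index)]
    if len(missing):
        raise ValueError(f"spots without niche labels: {missing.head().tolist()}")
    niche = spot.loc[obs, "niche"].to_numpy()
    df = calls.assign(niche=niche)
    grouped = df.groupby("niche", sort=True)
    out = pd.DataFrame(
        {
            "niche": grouped.size().index,
            "n_spots": grouped.size().to_numpy(),
            "n_darg_high": grouped["darg_high"].sum().to_numpy().astype(int),
            "mean_auc": grouped["auc"].mean().to_numpy(),
        }
    )
    out["fraction"] = out["n_darg_high"] / out["n_spots"]
    return out[["niche", "n_spots", "n_darg_high", "fraction", "mean_auc"]]


def patient_summary(
    scores: pd.DataFrame,
    spot_table: pd.DataFrame,
    paired: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-sample mean AUC and a two-sided rank test between the two groups.

    Default is the unpaired Wilcoxon rank-sum (Mann-Whitney) test on the
    per-sample means, exact for small samples without ties; ``paired=True``
    switches to the signed-rank test (samples matched by order within group).
    """
    spot = spot_table.set_index(spot_table["obs_id"].astype(str))
    obs = scores.index.astype(str)
    missing = obs.difference(spot.index)
    if len(missing):
        raise ValueError(f"spots without sample metadata: {list(missing[:5])}")
    df = pd.DataFrame(
        {
            "auc": scores["auc"].to_numpy(dtype=float),
            "sample_id": spot.loc[obs, "sample_id"].to_numpy(),
            "group": spot.loc[obs, "group"].to_numpy(),
        }
    )
    per_sample = (
        df.groupby(["sample_id", "group"], sort=True)["auc"]
        .mean()
        .reset_index()
        .rename(columns={"auc": "mean_auc"})
    )
    groups = sorted(per_sample["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    a = per_sample.loc[per_sample["group"] == groups[0], "mean_auc"].to_numpy()
    b = per_sample.loc[per_sample["group"] == groups[1], "mean_auc"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        p = stats.wilcoxon(a, b, alternative="two-sided").pvalue
    else:
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    return per_sample, float(p)


def quantile_bin_test(
    values_a,
    values_b,
    n_bins: int = 20,
    equal_var: bool = False,
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Quantile-bin each group, average per bin, then two-sided t-test.

    Within each group independently the values are sorted and split into
    ``n_bins`` quantile bins whose sizes differ by at most one; the bin means
    become the test inputs for a Welch (default) two-sample t-test.  Returns
    (t, df, p, bin_means_a, bin_means_b).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    for name, v in (("A", a), ("B", b)):
        if v.size < n_bins:
            raise ValueError(f"group {name} has fewer values ({v.size}) than bins")
    means_a = np.array([seg.mean() for seg in np.array_split(a, n_bins)])
    means_b = np.array([seg.mean() for seg in np.array_split(b, n_bins)])
    res = stats.ttest_ind(means_a, means_b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue), means_a, means_b


def associate_covariate(
    scores_by_unit,
    covariate_by_unit,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate unit-level enrichment with a covariate (e.g. a niche's mean
    DARG score per patient against its oligodendrocyte proportion)."""
    x = np.asarray(scores_by_unit, dtype=float)
    y = np.asarray(covariate_by_unit, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 units")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


class DargHighClassifier(BaseEstimator):
    """End-to-end DARG-high spot caller in estimator form.

    ``fit(X)`` ranks the observations, scores the combined DARG signature,
    and builds the permutation null on the same rankings; ``predict(X,
    tissue)`` applies the dual criterion.  ``X`` is an observations x genes
    DataFrame of normalized expression (or an ExpressionMatrix); the
    vote-count gates use presence counting by default, matching "expressing
    >6 genes".
    """

    def __init__(
        self,
        rg_genes=(),
        infl_genes=(),
        top_fraction: float = 0.05,
        n_perm: int = 10_000,
        quantile_q: float = 0.95,
        wm_gene_threshold: int = 6,
        gm_gene_threshold: int = 4,
        vote_mode: str = "presence",
        vote_threshold: float = 0.0,
        random_state: int = 0,
    ):
        self.rg_genes = rg_genes
        self.infl_genes = infl_genes
        self.top_fraction = top_fraction
        self.n_perm = n_perm
        self.quantile_q = quantile_q
        self.wm_gene_threshold = wm_gene_threshold
        self.gm_gene_threshold = gm_gene_threshold
        self.vote_mode = vote_mode
        self.vote_threshold = vote_threshold
        self.random_state = random_state

    @property
    def _darg_genes(self) -> list[str]:
        rg = [str(g).upper() for g in self.rg_genes]
        infl = [str(g).upper() for g in self.infl_genes]
        return rg + [g for g in infl if g not in set(rg)]

    def fit(self, X, y=None) -> "DargHighClassifier":
        if not self.rg_genes or not self.infl_genes:
            raise ValueError("both rg_genes and infl_genes are required")
        frame = X.to_frame() if isinstance(X, ExpressionMatrix) else X
        positions = ranking_positions(frame, seed=self.random_state)
        darg = self._darg_genes
        present = [g for g in darg if g in {str(c).upper() for c in frame.columns}]
        if not present:
            raise ValueError("no DARG signature gene in the matrix universe")
        self.sig_length_ = len(present)
        self.null_ = build_null(
            frame,
            sig_length=self.sig_length_,
            n_perm=self.n_perm,
            quantile_q=self.quantile_q,
            seed=self.random_state,
            top_fraction=self.top_fraction,
            positions=positions,
        )
        self.threshold_ = self.null_.threshold
        self._fit_positions = positions
        self._fit_index = [str(i) for i in frame.index]
        return self

    def score_table(self, X) -> pd.DataFrame:
        """Per-observation AUC of the combined DARG signature."""
        check_is_fitted(self, "null_")
        frame = X.to_frame() if isinstance(X, ExpressionMatrix) else X
        positions = None
        if [str(i) for i in frame.index] == self._fit_index:
            positions = self._fit_positions
        return score_signature(
            frame,
            self._darg_genes,
            top_fraction=self.top_fraction,
            seed=self.random_state,
            positions=positions,
        )

    def _votes(self, frame: pd.DataFrame, genes) -> pd.Series:
        voter = SignatureVoter(
            genes=genes,
            min_genes=1,
            expr_threshold=self.vote_threshold,
            mode=self.vote_mode,
        )
        return voter.fit(frame).vote_counts(frame)

    def predict(self, X, tissue: pd.Series | str = "WM") -> np.ndarray:
        """Boolean DARG-high calls; ``tissue`` is a per-observation Series of
        'WM'/'GM' labels or a single label for the whole matrix."""
        return self.calls(X, tissue)["darg_high"].to_numpy()

    def calls(self, X, tissue: pd.Series | str = "WM") -> pd.DataFrame:
        check_is_fitted(self, "null_")
        frame = X.to_frame() if isinstance(X, ExpressionMatrix) else X
        obs = [str(i) for i in frame.index]
        if isinstance(tissue, str):
            tissue = pd.Series(tissue, index=obs)
        scores = self.score_table(frame)
        spot_table = pd.DataFrame(
            {
                "obs_id": obs,
                "tissue": pd.Series(tissue).reindex(obs).to_numpy(),
            }
        )
        return call_darg_high(
            scores,
            self.null_,
            rg_votes=self._votes(frame, self.rg_genes),
            infl_votes=self._votes(frame, self.infl_genes),
            spot_table=spot_table,
            gene_count_thresholds={
                "WM": self.wm_gene_threshold,
                "GM": self.gm_gene_threshold,
            },
        )
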