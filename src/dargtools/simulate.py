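"""Synthetic count matrices, spatial layouts and module collections with
planted ground truth.

The generators emulate the statistical structure the analysis assumes:
sparse overdispersed UMI counts (negative binomial, variance = mu + phi*mu^2)
with lognormal gene-level means and per-observation lognormal library-size
factors; planted signature-expressing subpopulations whose signature genes
are up-shifted by a log2 fold change; and a concentric white-matter lesion
layout (lesion core / lesion rim / perilesional WM / normal-appearing WM)
in which DARG-truth spots are drawn per niche, most densely at the rim.
Gray matter is modeled as stacked horizontal neuronal-enrichment bands
through the same geometry interface.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .matrix import RAW_COUNTS, ExpressionMatrix

__all__ = [
    "Population",
    "SimulationTruth",
    "ConcentricLayout",
    "BandedLayout",
    "simulate_counts",
    "simulate_spatial",
    "simulate_module_sets",
    "default_gene_ids",
]


def default_gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


@dataclass(frozen=True)
class Population:
    """A planted subpopulation: a fraction of observations in which the
    listed signature genes have their mean multiplied by 2**log2_fold_change."""

    name: str
    fraction: float
    signature_genes: tuple[str, ...]
    log2_fold_change: float = 2.0


@dataclass
class SimulationTruth:
    """Planted ground truth plus the full parameter record."""

    obs_labels: pd.Series | None = None
    darg_truth: pd.Series | None = None
    module_mapping: dict[str, str] | None = None
    parameters: dict = field(default_factory=dict)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance = mean + dispersion * mean**2 (Poisson at 0)."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    n_genes: int = 2_000,
    n_obs: int = 1_000,
    mean_expression: tuple[float, float] = (np.log(0.5), 1.0),
    dispersion: float = 0.5,
    library_size: tuple[float, float] = (0.0, 0.3),
    populations: list[Population] | None = None,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Sparse NB count matrix with planted signature-expressing populations.

    ``mean_expression`` are (meanlog, sdlog) of the lognormal gene-level
    means; ``library_size`` are (meanlog, sdlog) of the per-observation
    multiplicative library factor (meanlog is re-centered so the factor has
    unit mean).  Population fractions must sum to at most 1; the remainder of
    the observations form the unlabeled background.
    """
    populations = list(populations or [])
    if not (0.0 <= dropout_rate <= 1.0):
        raise ValueError("dropout_rate must lie in [0, 1]")
    total_frac = sum(p.fraction for p in populations)
    if any(p.fraction < 0 for p in populations) or total_frac > 1 + 1e-9:
        raise ValueError("population fractions must be >= 0 and sum to <= 1")
    if any(p.log2_fold_change < 0 for p in populations):
        raise ValueError("log2_fold_change must be >= 0")
    rng = np.random.default_rng(seed)
    gene_ids = default_gene_ids(n_genes)
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    mu = rng.lognormal(mean_expression[0], mean_expression[1], size=n_genes)
    lib_meanlog, lib_sdlog = library_size
    ell = rng.lognormal(lib_meanlog - lib_sdlog**2 / 2.0, lib_sdlog, size=n_obs)

    # deterministic population sizes, shuffled assignment
    labels = np.array(["background"] * n_obs, dtype=object)
    counts_per_pop = [int(round(p.fraction * n_obs)) for p in populations]
    if sum(counts_per_pop) > n_obs:
        raise ValueError("population fractions leave no room (rounding overflow)")
    order = rng.permutation(n_obs)
    start = 0
    for pop, c in zip(populations, counts_per_pop):
        labels[order[start : start + c]] = pop.name
        start += c

    mean = ell[:, None] * mu[None, :]
    for pop in populations:
        missing = [g for g in pop.signature_genes if str(g).upper() not in gene_pos]
        if missing:
            raise ValueError(f"population {pop.name!r}: unknown genes {missing[:5]}")
        cols = [gene_pos[str(g).upper()] for g in pop.signature_genes]
        rows = np.flatnonzero(labels == pop.name)
        mean[np.ix_(rows, cols)] *= 2.0**pop.log2_fold_change
    counts = _nb_sample(rng, mean, dispersion)
    if dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= dropout_rate)
    obs_ids = [f"cell{i:05d}" for i in range(n_obs)]
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        obs_ids=obs_ids,
        values=sparse.csr_matrix(counts.T.astype(np.int64)),
        layer=RAW_COUNTS,
    )
    truth = SimulationTruth(
        obs_labels=pd.Series(labels, index=obs_ids, name="population"),
        parameters={
            "n_genes": n_genes,
            "n_obs": n_obs,
            "mean_expression": tuple(mean_expression),
            "dispersion": dispersion,
            "library_size": tuple(library_size),
            "populations": [
                {
                    "name": p.name,
                    "fraction": p.fraction,
                    "n_signature_genes": len(p.signature_genes),
                    "log2_fold_change": p.log2_fold_change,
                }
                for p in populations
            ],
            "dropout_rate": dropout_rate,
            "seed": seed,
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# spatial layouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentricLayout:
    """White-matter lesion geometry: concentric rings around the grid center.

    Spots within ``lc_radius`` of the center are lesion core, the next
    ``lr_width`` ring is lesion rim, then ``plwm_width`` of perilesional WM;
    the remainder is normal-appearing WM.
    """

    lc_radius: float = 8.0
    lr_width: float = 5.0
    plwm_width: float = 7.0
    tissue: str = "WM"

    def validate(self, grid_w: int, grid_h: int) -> None:
        if min(self.lc_radius, self.lr_width, self.plwm_width) < 0:
            raise ValueError("layout radii/widths must be >= 0")
        if self.lc_radius + self.lr_width + self.plwm_width > min(grid_w, grid_h) / 2.0:
            raise ValueError("concentric layout exceeds the grid")

    def niches(self) -> list[str]:
        return ["LC", "LR", "PLWM", "NAWM"]

    def assign(self, x: np.ndarray, y: np.ndarray, grid_w: int, grid_h: int) -> np.ndarray:
        cx, cy = (grid_w - 1) / 2.0, (grid_h - 1) / 2.0
        r = np.hypot(x - cx, y - cy)
        out = np.full(x.shape, "NAWM", dtype=object)
        out[r <= self.lc_radius + self.lr_width + self.plwm_width] = "PLWM"
        out[r <= self.lc_radius + self.lr_width] = "LR"
        out[r <= self.lc_radius] = "LC"
        return out


@dataclass(frozen=True)
class BandedLayout:
    """Gray-matter geometry: stacked horizontal zones (e.g. neuronal-
    enrichment bands GM1..GM4 from the top of the grid downward)."""

    band_heights: tuple[int, ...] = ()
    band_niches: tuple[str, ...] = ("GM1", "GM2", "GM3", "GM4")
    tissue: str = "GM"

    def validate(self, grid_w: int, grid_h: int) -> None:
        heights = self._heights(grid_h)
        if len(heights) != len(self.band_niches):
            raise ValueError("one height per band niche required")
        if sum(heights) != grid_h:
            raise ValueError("band heights must cover the grid height exactly")

    def _heights(self, grid_h: int) -> tuple[int, ...]:
        if self.band_heights:
            return self.band_heights
        base = grid_h // len(self.band_niches)
        heights = [base] * len(self.band_niches)
        heights[-1] += grid_h - base * len(self.band_niches)
        return tuple(heights)

    def niches(self) -> list[str]:
        return list(self.band_niches)

    def assign(self, x: np.ndarray, y: np.ndarray, grid_w: int, grid_h: int) -> np.ndarray:
        bounds = np.cumsum(self._heights(grid_h))
        idx = np.searchsorted(bounds, y, side="right")
        return np.array([self.band_niches[i] for i in idx], dtype=object)


DEFAULT_DARG_RATES = {"LC": 0.01, "LR": 0.06, "PLWM": 0.03, "NAWM": 0.005}


def simulate_spatial(
    grid_w: int = 60,
    grid_h: int = 60,
    layout: ConcentricLayout | BandedLayout | None = None,
    darg_rate_per_niche: dict[str, float] | None = None,
    n_rg_genes: int = 20,
    n_infl_genes: int = 20,
    log2_fold_change: float = 2.0,
    n_genes: int = 10_000,
    mean_expression: tuple[float, float] = (np.log(0.2), 0.5),
    marker_baseline: float = 0.21,
    dispersion: float = 0.05,
    library_size: tuple[float, float] = (0.0, 0.08),
    dropout_rate: float = 0.0,
    sample_id: str = "sim",
    group: str = "MS",
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimulationTruth]:
    """Spatial section with a planted lesion layout and DARG-truth spots.

    Every grid position is a spot assigned a niche by the layout geometry;
    DARG-truth spots are Bernoulli draws at the per-niche rates.  The first
    ``n_rg_genes`` genes of the universe act as the radial-glia signature and
    the next ``n_infl_genes`` as the inflammatory signature; both have a flat
    baseline mean of ``marker_baseline`` counts (marker genes are lowly
    expressed outside their population) and are up-shifted by
    ``2**log2_fold_change`` in DARG-truth spots.  Background genes draw their
    means from the ``mean_expression`` lognormal.
    """
    layout = layout or ConcentricLayout()
    layout.validate(grid_w, grid_h)
    rates = dict(DEFAULT_DARG_RATES if darg_rate_per_niche is None else darg_rate_per_niche)
    missing_rates = [n for n in layout.niches() if n not in rates]
    if missing_rates:
        raise ValueError(f"darg_rate_per_niche missing niches {missing_rates}")
    if any(not (0.0 <= r <= 1.0) for r in rates.values()):
        raise ValueError("DARG rates must lie in [0, 1]")
    if log2_fold_change < 0:
        raise ValueError("log2_fold_change must be >= 0")
    if n_rg_genes + n_infl_genes > n_genes:
        raise ValueError("more signature genes than genes in the universe")

    rng = np.random.default_rng(seed)
    gene_ids = default_gene_ids(n_genes)
    rg_genes = gene_ids[:n_rg_genes]
    infl_genes = gene_ids[n_rg_genes : n_rg_genes + n_infl_genes]

    xx, yy = np.meshgrid(np.arange(grid_w), np.arange(grid_h), indexing="ij")
    x, y = xx.ravel(), yy.ravel()
    niche = layout.assign(x, y, grid_w, grid_h)
    n_obs = x.size
    obs_ids = [f"{sample_id}:{xi}_{yi}" for xi, yi in zip(x, y)]

    p_darg = np.array([rates[n] for n in niche])
    darg = rng.random(n_obs) < p_darg

    mu = rng.lognormal(mean_expression[0], mean_expression[1], size=n_genes)
    mu[: n_rg_genes + n_infl_genes] = marker_baseline
    lib_meanlog, lib_sdlog = library_size
    ell = rng.lognormal(lib_meanlog - lib_sdlog**2 / 2.0, lib_sdlog, size=n_obs)
    mean = (ell[:, None] * mu[None, :]).astype(np.float64)
    mean[np.ix_(darg, np.arange(n_rg_genes + n_infl_genes))] *= 2.0**log2_fold_change
    counts = _nb_sample(rng, mean, dispersion)
    if dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= dropout_rate)

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        obs_ids=obs_ids,
        values=sparse.csr_matrix(counts.T.astype(np.int64)),
        layer=RAW_COUNTS,
    )
    spots = pd.DataFrame(
        {
            "obs_id": obs_ids,
            "x": x,
            "y": y,
            "tissue": layout.tissue,
            "niche": niche,
            "sample_id": sample_id,
            "group": group,
        }
    )
    truth = SimulationTruth(
        darg_truth=pd.Series(darg, index=obs_ids, name="darg_truth"),
        parameters={
            "grid_w": grid_w,
            "grid_h": grid_h,
            "layout": repr(layout),
            "darg_rate_per_niche": rates,
            "rg_genes": rg_genes,
            "infl_genes": infl_genes,
            "log2_fold_change": log2_fold_change,
            "n_genes": n_genes,
            "mean_expression": tuple(mean_expression),
            "marker_baseline": marker_baseline,
            "dispersion": dispersion,
            "library_size": tuple(library_size),
            "dropout_rate": dropout_rate,
            "sample_id": sample_id,
            "group": group,
            "seed": seed,
        },
    )
    return matrix, spots, truth


def simulate_module_sets(
    universe_size: int = 2_000,
    n_modules: int = 5,
    module_size_range: tuple[int, int] = (50, 150),
    planted_jaccard: float = 0.5,
    noise_genes: int = 0,
    seed: int = 0,
):
    """Baseline and query gene-module collections with a planted 1:1 mapping.

    Query module i shares genes with baseline module i so that their Jaccard
    index is approximately ``planted_jaccard`` (exactly 1 means identical
    sets), with its remaining genes — plus ``noise_genes`` extras — drawn at
    the hypergeometric background rate from the rest of the universe.
    Returns (baseline_modules, query_modules, truth).
    """
    from .modules import GeneModule

    if not (0.0 < planted_jaccard <= 1.0):
        raise ValueError("planted_jaccard must lie in (0, 1]")
    lo, hi = module_size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid module_size_range")
    if hi + noise_genes > universe_size:
        raise ValueError("module sizes infeasible within the universe")
    rng = np.random.default_rng(seed)
    universe = np.array(default_gene_ids(universe_size, prefix="U"))
    baseline, query = [], []
    mapping: dict[str, str] = {}
    for i in range(n_modules):
        s = int(rng.integers(lo, hi + 1))
        base_genes = rng.choice(universe_size, size=s, replace=False)
        # overlap o solves jaccard = o / (2s - o) for equal sizes
        o = int(round(2 * s * planted_jaccard / (1.0 + planted_jaccard)))
        o = min(max(o, 1), s)
        kept = rng.choice(base_genes, size=o, replace=False)
        pool = np.setdiff1d(np.arange(universe_size), base_genes, assume_unique=False)
        fresh = rng.choice(pool, size=s - o + noise_genes, replace=False)
        bid, qid = f"invitro_{i}", f"exvivo_{i}"
        baseline.append(GeneModule(bid, frozenset(universe[base_genes])))
        query.append(GeneModule(qid, frozenset(universe[np.concatenate([kept, fresh])])))
        mapping[bid] = qid
    truth = SimulationTruth(
        module_mapping=mapping,
        parameters={
            "universe_size": universe_size,
            "n_modules": n_modules,
            "module_size_range": tuple(module_size_range),
            "planted_jaccard": planted_jaccard,
            "noise_genes": noise_genes,
            "seed": seed,
        },
    )
    return baseline, query, truth
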