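# dargtools

Gene-signature voting, rank-based signature-recovery AUC scoring, and
DARG-high spot calling for single-cell and spatial transcriptomics.

Disease-associated radial-glia-like cells (DARGs) are a non-neurogenic,
senescence- and interferon-signature-positive glial population found in and
around chronic demyelinating lesions. Locating them in expression data takes
a small set of bespoke statistical steps that are usually buried inside
one-off analysis scripts. This package implements those steps as a tested,
reusable library with scikit-learn-style estimators, plus a CLI and a
synthetic-data module so every stage can be exercised end to end on data
with planted ground truth — no downloads required.

## What it computes

**k-of-n signature voting** (`SignatureVoter`, `vote`). An observation is
positive for a signature of *n* genes when at least *k* of them are
expressed at a normalized level ≥ θ (threshold mode, inclusive) or simply
detected (> 0, presence mode). Equivalently parameterized by a tolerance
*t = n − k* of missing genes, which is how pseudotime anchor regions are
selected (`select_anchor_cells`). Default rules (configurable): radial glia
6/9 at θ=1; astroglial progenitors 7/10 at θ=0.5; neural progenitors 5/7 at
θ=0.5; IFN-α/β 3/6 at θ=0.5; NOTCH1 13/16 presence/absence.

**Recovery AUC** (`AUCellScorer`, `score_signature`). Per observation, genes
with non-zero expression are ranked by decreasing value (zero-count genes
are discarded from the ranking; ties broken by a seeded random permutation).
With recovery curve c(i) = number of signature genes at ranking positions
≤ i,

    AUC = Σ_{i=1..T} c(i) / Σ_{i=1..T} min(i, m),

where T = ⌊top_fraction · |universe|⌋ and m is the number of signature
genes in the universe — the maximum-achievable-area normalization bounds
the score in [0, 1].

**Permutation null** (`build_null`). The signature is rescored with 10,000
random gene sets of equal length; the pooled empirical 0.95 quantile is the
data-driven confidence limit on AUC background noise.

**DARG-high calling** (`DargHighClassifier`, `call_darg_high`). A spot is
DARG-high when its DARG AUC exceeds the null threshold **and** it expresses
strictly more than 6 genes (white matter) or 4 genes (gray matter) from
*both* the radial-glia and the inflammatory signature subsets. Niche and
patient summaries, a rank test between patient groups, a quantile-binned
Welch t-test (bin, average, then test — avoids inflating n), and covariate
correlation round out the spatial module.

**Module matching** (`ModuleMatcher`, `match_modules`). Pseudotime gene
modules from a baseline dataset are matched to modules from a query dataset
by the size-penalized Ochiai overlap |A∩B|/√(|A||B|) with a two-sided Fisher
exact test per pair (exact integer enumeration), Benjamini-Hochberg
correction across all pairs, and best-match assignment.

**Synthetic data** (`simulate_counts`, `simulate_spatial`,
`simulate_module_sets`). Negative-binomial counts with lognormal gene means
and library factors, planted signature-expressing populations, a concentric
lesion layout (core / rim / perilesional / normal-appearing WM) with
DARG-truth spots enriched at the rim, and module collections with a planted
correspondence.

## Worked example

Simulate a small 30×30 lesion section and run the full pipeline:

```sh
cat > config.yaml <<EOF
sim.grid_w: 30
sim.grid_h: 30
sim.n_genes: 2000
sim.lc_radius: 5.0
sim.lr_width: 3.0
sim.plwm_width: 4.0
null.n_perm: 1000
EOF
dargtools simulate --config config.yaml --seed 7 --out data
dargtools run --config config.yaml --seed 7 --data data --out out
```

which prints

```
{"n_darg_high": 13, "auc_threshold": 0.07732919603586197}
```

and writes `out/report.json` with, among other things, the per-niche
summary:

```
niche  n_spots  n_darg_high  fraction  mean_auc
LC          80            0    0.0000    0.0220
LR         128            7    0.0547    0.0332
PLWM       240            3    0.0125    0.0281
NAWM       452            3    0.0066    0.0233
```

The AUC threshold (0.0773) is the 0.95 quantile of 1,000 random-gene-set
scores pooled over all 900 spots; 13 spots pass both the AUC gate and the
dual >6-gene vote gate, and the DARG-high fraction peaks at the lesion rim
(5.5%), the niche the simulator enriches — the qualitative core → rim
gradient the method is designed to detect.

The same steps are available as library calls:

```python
from dargtools import DargHighClassifier, filter_observations, normalize, simulate_spatial

matrix, spots, truth = simulate_spatial(seed=7)
X = normalize(filter_observations(matrix)).to_frame()   # spots x genes
clf = DargHighClassifier(rg_genes=truth.parameters["rg_genes"],
                         infl_genes=truth.parameters["infl_genes"],
                         random_state=7).fit(X)
calls = clf.calls(X, tissue="WM")
```

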