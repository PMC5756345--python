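# Methods

## Model and procedure

`driverplex` ranks genes by how much more connected they are *within* a
pathway than a uniform-edge null predicts, independently in several
interaction layers, and calls a gene a network driver when the excess is
seen in at least two layers.

Per gene *i*, pathway *P* (k genes) and layer *N* (m nodes, taken as the
endpoint union of the edge list as read):

- `di_N` — degree of *i* in the layer;
- `di_P` — degree of *i* counting only neighbours annotated to *P*
  (*i* itself never counts; *i* need not belong to *P* for the quantity to
  be defined, though records are only emitted for pathway members);
- `di_E = di_N * k / m` — the within-pathway degree expected if the layer's
  edges attached to *i* were distributed uniformly over the m nodes
  (`di_N / m = di_E / k`).

Two criterion modes are implemented, both with strict inequality (ties are
non-drivers):

- **literal** (default): `di_P / k > di_E`. The left side is a density,
  the right a raw degree, so the comparison is scale-asymmetric: since
  `di_N ≥ di_P`, it can only ever fire when `k² < m`, and a single
  within-pathway edge should not fire it, which additionally requires a
  background degree above `m/k² − 1`. Real pathway-versus-interactome data
  (pathways of tens of genes against networks of 10⁴ nodes) satisfies
  both conditions comfortably; small simulated universes may not (see
  "Simulation regimes" below).
- **unnormalized**: `di_P > di_E`, equivalent to comparing the densities
  `di_P/k > di_N/m`. Dimensionally consistent, but when `di_E < 1` (small
  pathways, sparse layers) any single within-pathway edge passes, which
  inflates false positives in sparse regimes.

Multiplex aggregation: a gene qualifies when it passes in ≥ `min_layers`
layers (default 2), either in any pathways (`per_gene`, default — the
layer-level reading used for Venn-style layer comparisons) or within one
and the same pathway (`per_pathway`, the stricter reading; always a subset
of `per_gene`). Venn region counts assign each gene of the per-layer-set
union to the exact subset of layers containing it.

Pathway size `k` defaults to the annotated size as read (`k_mode =
"annotated"`); `k_mode = "in_layer"` restricts to members present in the
layer (floored at 1 so `di_E` stays defined).

## Differential expression

The DEA stage is intentionally simple and self-contained: raw counts →
log2 counts-per-million with pseudo-count 1
(`log2(1e6·(c+1)/(libsize + n_genes))`) → per-gene two-sided Welch t-test
(tumour minus normal log2 means as logFC) → Benjamini–Hochberg step-up →
flags `|logFC| > 1` and `FDR < 0.01` (both strict, both configurable).
Genes with all-zero counts are dropped before testing; genes with zero
variance in both classes are assigned p = 1 (a deliberate, documented
contract — degenerate for continuous data). The module boundary allows a
drop-in replacement test (e.g. a count-model GLM) without touching the
rest of the pipeline. Unpaired designs only.

## Per-gene random-forest validation

Each candidate gene is scored alone: a random forest (500 trees,
`mtry = max(1, ceil(sqrt(p)))`, so 1 for single-gene models) is trained
per fold of a stratified k-fold split (k = 10, reduced with a warning when
the smaller class has fewer members), out-of-fold tumour-class
probability fractions are pooled across folds, and a single rank-based
AUC is computed from the pooled scores (pooling is more stable than
averaging per-fold AUCs on small folds). Ranking is by descending AUC
with alphabetical tie-break; rank-band means (e.g. ranks 11–50) are
computed on the same ordering. A constant gene is defined to have
AUC 0.5. A multivariate model over all driver genes can be obtained by
passing the full gene list as features to scikit-learn directly; the
package's reported quantity is the per-gene AUC.

Note on invariance: with threshold trees, AUC is exactly invariant under
affine transforms of a gene's values but only approximately invariant
under nonlinear monotone transforms, because split thresholds are
midpoints between sorted training values and a test point near a split
can change sides. The test suite asserts exact affine invariance and
near-invariance (±0.05) under `exp`.

## Synthetic data

Bundles emulate the pipeline's three inputs. Pathways are sampled
uniformly from a universe of `n_genes` symbols. Each layer is an
Erdős–Rényi background at `background_edge_prob`; per pathway,
`planted_drivers` member genes are designated drivers and gain edges to
their co-members with probability `planted_within_pathway_prob` in exactly
`n_layers_planted` designated layers, so the ≥2-layer rule is testable at
thresholds 1 and 2. Counts are negative-binomial with
`variance = mu + dispersion·mu²` (dispersion 0.1, typical of bulk
RNA-seq), baselines log-uniform on [16, 1024]; a fraction of the drivers
plus `n_decoy_de` non-driver decoys get a `2**planted_log_fc` mean shift
(random sign) in the tumour class. Everything is a pure function of
(config, seed); seeds are expanded per stage via
`SeedSequence([seed, stage_tag])`.

What the generator does *not* emulate: GC-content and library-preparation
biases, batch effects, correlated co-expression, scale-free degree
distributions, or annotation errors. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
model, not performance on real cancer cohorts.

### Simulation regimes

The default config (600 genes, 12 pathways of 15–40 genes, 3 layers,
background 0.02, planted within-pathway probability 0.5, 3 drivers per
pathway in 2 layers) deliberately stresses the criterion in a regime
where the literal form is mostly out of its feasible region (`k² < m`
fails for k ≥ 25 when m = 600) and the unnormalized form is swamped
(`di_E ≈ 0.5`, so any co-member of a planted driver passes). The
recovery numbers the acceptance script reports at these settings —
literal: sensitivity ≈ 0.02 with FPR 0; unnormalized: sensitivity 1.0
with FPR ≈ 0.9 — quantify those two failure modes and delimit where the
statistic is meaningful.

`SimulationConfig.sparse_pathway_regime()` reproduces, at desk scale, the
balance real data has (pathways small relative to the network and
background degree above `m/k² − 1`): 8 pathways of 10–14 genes in a
600-gene universe, background 0.01, one 0.7-enriched driver per pathway
planted in 2 of 3 layers, 30 samples per class. There the literal
criterion attains sensitivity 1.0 at FPR ≈ 0.03 (10 seeds), and the
end-to-end run recovers every planted driver-DE gene in the top-10 AUC
list. These sizes were chosen once for tractability on a single CPU; the
per-stage cardinalities are logged by the pipeline.

## Numerical and design choices

- Gene symbols are upper-cased at ingest; edge weights are ignored
  (unweighted degree only); self-loops are dropped with a counted warning;
  a self-loop's endpoint still counts as a node.
- Class labels are case-insensitive; "tumor"/"tumoural" fold onto
  "tumour"; any other value is an error, never a third class.
- `di_E` is kept at full float precision; no rounding before comparison.
- Percentages support two printing conventions (`round1`,
  `truncate_int`) because published overlap tables mix them.
- BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`;
  an independently coded step-up oracle checks it in the tests.
- Fold assignment uses `StratifiedKFold(shuffle=True)` over sorted sample
  ids; forests get `random_state = seed*1000 + fold`, making the AUC table
  bitwise reproducible for a given seed.
- Empty driver sets and empty driver-DEG sets degrade to warnings with
  defined outputs (percentage 0, single-group FDR summary) rather than
  errors, so multi-condition sweeps do not abort.

## Known limitations

- The literal criterion's scale asymmetry is inherited by design; both
  modes are exposed and the feasibility bounds above tell you which is
  informative for a given (k, m, density).
- The Welch-on-logCPM test is a stand-in for count-model DEA; it is well
  calibrated on the generator's negative-binomial data (null DEG rate
  ≈ 0 per 1000 genes at FDR < 0.01) but less powerful than a GLM for
  low counts.
- Per-gene forests ignore gene–gene correlation; ranking near-tied AUCs
  is alphabetical and should not be over-interpreted.
- No paired designs, no covariates, no batch correction.
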