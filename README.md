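# genecoord

Eigen-spectrum **coordination analysis** of gene sets for two-group
transcriptomic studies, together with the supporting stages of a typical
hub-gene workflow: synthetic data generation, differential-expression
filtering with Benjamini–Hochberg correction, PPI degree-based hub ranking,
and a weighted soft-voting classifier ensemble with from-scratch ROC/AUC.

## The problem

Pairwise correlation says how two genes co-vary; it does not say whether a
whole *set* of genes (say, T-cell receptor hub genes plus a pathology
anchor such as *MAPT* or *APP*) moves as one coordinated block, nor whether
that coordination differs between cases and controls. `genecoord`
quantifies this with the eigen-spectrum of the gene set's inner-product
matrix.

## The statistic

For a group of m samples, stack the Z-scored expression rows of the n genes
into Z (n × m) and form the Gram matrix

```
R = Z Zᵀ,   R_ij = Σ_s z_is z_js
```

R is symmetric positive semi-definite, so R = Q diag(λ) Qᵀ with orthogonal
Q. Normalizing

```
λ_i ← λ_i / Σ_k λ_k
```

gives a unit-sum, scale-invariant spectrum. A dominant λ₁ means the genes
co-vary as a single block; a flat spectrum (all 1/n) means independence.
Computing the spectrum separately per group and differencing rank by rank
(`per_rank_delta`, which sums to 0) measures the *change in coordination*
between groups. For an equicorrelated set with common correlation ρ the
population spectrum is closed form — λ₁ = (1+(n−1)ρ)/n, the rest (1−ρ)/n —
which anchors the test suite.

Supporting stages: `deg` (log₂ fold change, Welch t, BH step-up, strict
|logFC| > 1.5 & p < 0.05 calls), `hubs` (edge-list score filtering,
isolated-node removal, unweighted degree ranking), `classify` (RF / SVM /
per-class-Gaussian / logistic base learners combined by a weighted soft
vote, default weights 2/2/1/1), and `simulate` (multivariate-normal
generator with group-specific block equicorrelation, mean shifts, and
planted-hub edge lists — every downstream stage has known ground truth).

## Worked example

```
genecoord run-all --seed 42 --out-dir out/
```

simulates the default study (one 4-gene coordinated module — LCK, ZAP70,
CD44 anchored by MAPT — whose equicorrelation differs between 50 AD and 50
control samples, five up-shifted genes, independent background genes, and a
planted-hub network) and runs every stage. With seed 42 the outputs are:

```
CON spectrum: [0.537, 0.2013, 0.1645, 0.0972]
AD  spectrum: [0.6754, 0.1318, 0.1169, 0.0759]
largest_delta: 0.1384
DEG calls: 8 up, 0 down          # 5 planted (+3) and 3 hub genes (+2)
hub ranking: LCK 12, ZAP70 9, CD44 7
ensemble: accuracy 0.95, AUC 0.99
```

Reading: the leading normalized eigenvalue rises from ≈0.54 to ≈0.68 in the
AD group — the MAPT-anchored hub set is substantially more coordinated in
cases, exactly the structure the generator planted (population λ₁ of 0.543
vs 0.672). The same analysis is available programmatically:

```python
from genecoord import coordination_analysis, ExpressionMatrix

X = ExpressionMatrix.from_tsv("out/expression.tsv", "out/labels.tsv")
cmp = coordination_analysis(X, ["LCK", "ZAP70", "CD44"], anchor_gene="MAPT",
                            baseline_group="CON", case_group="AD")
cmp.largest_delta   # 0.1384
```

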