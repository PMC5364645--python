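# espace — hub-aware sparse partial-correlation network estimation

Gene regulatory networks are routinely reconstructed from expression
data as Gaussian graphical models: genes are nodes, and an edge joins
genes i and j when their partial correlation
ρ<sup>ij</sup> = −ω<sub>ij</sub>/√(ω<sub>ii</sub>ω<sub>jj</sub>)
(equivalently, the off-diagonal precision entry ω<sub>ij</sub>) is
nonzero. With far fewer samples than genes, sparse estimation with an
ℓ1 penalty is the standard approach — but a flat penalty treats every
potential edge alike, while decades of biology say otherwise: hub genes
(transcription factors, cancer genes) are known in advance to regulate
many targets.

This package estimates sparse partial-correlation networks with a
penalty that is *relaxed on edges touching known hubs*. Given a hub set
ℋ and tuning parameters λ > 0, α ∈ (0, 1], it solves

```
min_ρ  ½ Σᵢ wᵢ Σₖ ( Xᵢᵏ − Σ_{j≠i} ρ^{ij} √(ω_jj/ω_ii) Xⱼᵏ )²
       + αλ Σ_{i<j : i∈ℋ or j∈ℋ} |ρ^{ij}|  +  λ Σ_{i<j : i,j∉ℋ} |ρ^{ij}|
```

by an active-shooting coordinate descent over all p(p−1)/2 gene pairs
(the ESPACE estimator; with α = 1 or ℋ = ∅ it is exactly SPACE). The
same hub-weighted penalty applied to the ℓ1-penalized Gaussian
log-likelihood `log|Ω| − tr(SΩ)` gives the EGLASSO variant, solved by a
penalty-matrix graphical lasso. The pair (λ*, α*) is chosen by a
GIC-type criterion, `Σᵢ { n·log RSSᵢ + log(log n)·log(p−1)·dfᵢ }`.

Also included: a simulator that builds hub-structured networks,
converts edge sets into positive-definite precision matrices, samples
multivariate-normal expression data and adds measurement noise; and an
evaluation suite (SEN/SPE/FDR/MISR/MCC, degree-quantile hub rule) for
scoring estimated networks against a known truth.

## Worked example

`examples/03_gic_model_selection.py` simulates a 40-gene network with 3
hubs, n = 40 samples, then selects (λ, α) by GIC with and without the
hub prior:

```
hub-aware:  lambda*=33.01  alpha*=0.60  edges=29  MCC=0.497
hub-blind:  lambda*=52.98  (alpha=1)     edges=1  MCC=0.143
```

The criterion chose α* = 0.6 — it pays to weaken the penalty on
hub-adjacent pairs — and the hub-aware network recovers the truth far
better (MCC 0.50 vs 0.14; MCC is the Matthews correlation over all 780
gene pairs, 1 = perfect, 0 = random). The other examples cover the
closed-form 3-gene noise illustration (`01`), a single fixed-penalty
fit (`02`), and the penalized-likelihood variant (`04`).

A thin CLI wraps the same functions for shell use:

```sh
espace simulate --p 40 --n 40 --n-hubs 3 --seed 7 --out sim/
espace select --expr sim/expression.tsv --hubs sim/true_hubs.txt --out fit/
espace evaluate --truth sim/true_edges.tsv --estimate fit/edges.tsv --p 40
espace example          # prints the 3-gene worked example
```

## Layout

- `src/espace/core.py` — pairwise estimator (active shooting, KKT checks)
- `src/espace/eglasso.py` — penalty-matrix graphical lasso
- `src/espace/selection.py` — GIC and grid search
- `src/espace/netgen.py` — network/precision/data simulator
- `src/espace/evaluation.py` — recovery metrics and hub identification
- `src/espace/io.py`, `src/espace/cli.py` — file formats and CLI
- `docs/methods.md` — modeling assumptions, algorithms, numerical choices
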