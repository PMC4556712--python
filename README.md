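# ggmbench

Benchmark framework for network recovery from Gaussian graphical model
(GGM) time series. It generates known network topologies, builds valid
GGMs on them, simulates AR(1)-autocorrelated multivariate Gaussian series,
recovers networks with four estimators — pairwise correlation, and partial
correlations via shrinkage, Moore–Penrose pseudoinverse, and the graphical
lasso — and quantifies recovery through network metrics and true/false
positive rates. It also provides a hierarchical ROI fixture and consistency
analyses for parcellated time-series matrices.

## Pipeline overview

| module | role |
| --- | --- |
| `ggmbench.topology` | ER (probability or exact edge count), acquaintance small-world (± hubs via `p_d`), preferential attachment generators; largest-component finalization; representative selection |
| `ggmbench.ggm` | edge weights from U([−1,−.01]∪[.01,1]), PD regularization with exact-zero support, partial-correlation → correlation → covariance (uniform variance 2) |
| `ggmbench.timeseries` | AR(1) Gaussian simulation (stationary recursion, equivalent to the Toeplitz-Cholesky construction), nested prefix subsets, effective sample size n(1−ρ)/(1+ρ) |
| `ggmbench.estimators` | the four weight estimators; glasso penalty found by bisection to hit a target edge count (ADMM fallback when coordinate descent diverges) |
| `ggmbench.selection` | top-k absolute-weight binarization; true/−20 %/+20 % density variants; fixed 3 %-density rule |
| `ggmbench.metrics` | average path length (reachable pairs), transitivity and triangles, small-worldness vs matched ER ensembles, components, betweenness, degree/strength |
| `ggmbench.recovery` | TPR/FPR (overall and per degree-bin pairing), normalized node-metric differences, exp(−100·FPR) transform, edge overlap, within/between-area connectivity |
| `ggmbench.runner` / `ggmbench.roi` | factorial study orchestration with manifests; nested-parcellation fixture and length/resolution consistency tables |

### Python example

```python
from ggmbench import *

topo = finalize_connected(generate_random(200, count=600, seed=0))
ggm = build_ggm(topo, seed=1)                      # R, C, Sigma
ts = simulate_ar1_gaussian(ggm.cov, 1000, rho=0.5, seed=2)
wm = estimate("shrinkage", ts)
net = select_top_k(wm, topo.n_edges)               # matched density
print(tpr_fpr(net, topo), small_worldness(net))
```

### CLI

Each pipeline stage is a subcommand working on plain-text artifacts
(edge-list TSV, CSV matrices, time-series TSV, JSON reports):

```bash
ggmbench topology --kind random --n-nodes 200 --count 600 --seed 0 --out topo.tsv
ggmbench ggm --topology-file topo.tsv --seed 1 --out-prefix model
ggmbench simulate --cov model.cov.csv -t 1000 --rho 0.5 --seed 2 --out ts.tsv
ggmbench estimate --series ts.tsv --method shrinkage --out weights.csv
ggmbench select --weights weights.csv --k 600 --out net.tsv
ggmbench metrics --network net.tsv --out metrics.json
ggmbench evaluate --estimated net.tsv --truth topo.tsv
ggmbench run-study --config study.yaml --out-dir results/
ggmbench roi-fixture --sizes 68,114,219,448,1000 -t 240 --out-dir roi/
ggmbench consistency --sizes 34,68,136 -t 240 --out consistency.tsv
```

## Tests

```bash
python -m pytest tests/
```

The suite includes brute-force oracles for every graph metric, analytic
oracles for the estimators' closed-form limits, property tests
(hypothesis), and `tests/test_acceptance.py`, which re-derives the
benchmark's headline quantities (ensemble statistics at 2000 nodes and the
scaled p = 200 comparative study). The full run takes ~10–15 minutes on one
CPU; everything outside `test_acceptance.py` finishes in under a minute.

## Conventions worth knowing

- Node indices are 0-based in memory, 1-based in serialized edge lists.
- Average path length averages over *reachable* ordered pairs only, and
  betweenness credits each unordered endpoint pair once — both matching the
  graph library the reference results were produced with.
- Strength sums absolute weights.
- All randomness flows from explicit integer seeds; identical seeds give
  bit-identical artifacts.
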