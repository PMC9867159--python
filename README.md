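# thermoselect

Feature ranking for plantar-thermogram classification of diabetic-foot-ulcer
(DFU) risk.

Diabetic feet exhibit abnormal plantar temperature patterns well before an
ulcer forms. Given infrared thermograms of both feet, segmented into the four
plantar angiosomes (MPA, LPA, MCA, LCA — the regions supplied by the medial/
lateral plantar and calcaneal arteries), a large battery of thermal features
can be computed per region: summary statistics, normalized-temperature-range
(NTR) occupancies, the estimated temperature (ET), inter-foot ET differences
(ETD), a hot-spot estimator (HSE), and the thermal change index (TCI). The
question this package addresses is *which of those features matter* for
classifying healthy vs. diabetic subjects.

The core method is embedded feature selection by stochastic input gates on a
small neural classifier:

* **Variational dropout** — each input x_d is multiplied by a Gaussian gate
  with posterior q(w_d) = N(θ_d, α_d θ_d²), sampled as w_d = θ_d(1 + √α_d ε),
  ε ~ N(0,1). Training maximizes the mini-batch evidence-lower-bound
  estimator, −(N/M) Σ log p(y|x, w) + λ·D_KL(q‖p) with the log-uniform prior
  KL in Molchanov's approximation. A large learned noise level α_d marks
  feature d as irrelevant; the effective drop probability is
  ρ_d = α_d/(1+α_d).
* **Concrete dropout** — each input is multiplied by a relaxed Bernoulli keep
  gate 1 − σ((logit ρ_d + logit ε)/t), ε ~ U(0,1), with learned drop
  probability ρ_d. The loss is the batch-mean cross-entropy plus
  λ·(1/D) Σ_d (1 − ρ_d), a smooth count of features left active.

In both cases λ anneals linearly (2.5×10⁻³ per epoch, capped at 1) so the
network learns before it is penalized; after 500 epochs a threshold τ = 0.9
on ρ_d yields a sparse mask, and 1 − ρ_d orders the features. Two classical
rankers (L1-logistic "LASSO" coefficients and random-forest impurity
importance) provide baselines, a coincidence rule intersects the top-30 of
all methods, and a fixed-configuration RBF-SVM (γ = 0.1, C = 1) scores any
candidate feature subset by stratified 5-fold cross-validation, so that
comparisons reflect the features rather than classifier tuning.

Real thermogram cohorts are not redistributable, so the package ships a
synthetic module that generates foot-shaped temperature maps with
class-conditional means (diabetic 30.2 ± 1.3 °C, healthy 26.8 ± 1.8 °C),
localized diabetic hot spots, and angiosome masks — plus plain tabular
benchmarks with a known informative-feature subset for quantitative
validation of the selectors.

## Worked example

Rank features on a synthetic benchmark at study scale — 140 features, 122
samples per class, 10 informative columns shifted by 2 SD:

```python
import thermoselect as ts

spec = ts.TabularSpec(n_per_class=122, n_features=140, n_informative=10,
                      effect_size=2.0, seed=7)
table, informative = ts.make_tabular(spec)

state, log = ts.train_selector(table, kind="concrete", config=ts.TrainConfig(seed=0))
ranking = ts.rank_and_sparsify(state, tau=0.9)

print("top-10:", ranking.top(10))
print(f"sparse rate: {ranking.sparse_rate:.3f}")
hits = len(set(ranking.top(20)) & {f"f{j:03d}" for j in sorted(informative)})
print(f"informative recovered in top-20: {hits}/10")
```

```
top-10: ['f009', 'f003', 'f008', 'f005', 'f000', 'f001', 'f002', 'f006', 'f004', 'f007']
sparse rate: 0.921
informative recovered in top-20: 10/10
```

The ten informative columns (`f000`–`f009`) occupy the entire top-10, and
the gate threshold discards 92% of the inputs — consistent with 130 of the
140 columns being pure noise.

The full pipeline (generate thermograms → extract features → SMOTE balance →
prune correlated features → rank with all four methods → coincidence →
fixed-SVM evaluation) runs from the command line:

```bash
thermoselect run-all --seed 17 --out run/
```

and writes `features.csv`, `pruned.csv`, `ranking_<method>.json`,
`coincidence.json`, `metrics.json` and a manifest carrying the seed and a
configuration hash. Individual stages are available as `generate`,
`extract`, `preprocess`, `select`, `coincide` and `evaluate` verbs.

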