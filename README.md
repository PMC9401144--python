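# carenet

Patient-sharing provider networks and the duration of hospital stay.

`carenet` is a research pipeline for quantifying how inter-institutional
medical cooperation — read off a provider network built from administrative
claims — explains the duration of hospital stay (D^in) for femoral neck
fracture. Real claims of this kind are confidential, so the package ships a
seeded synthetic claims generator with a planted cooperation effect; every
estimator in the pipeline can therefore be checked against ground truth.

It is written for health-services and network-science researchers who work
with claims data from Python.

## The analysis

1. **Episodes of care.** Per patient, claims are linked into per-fracture
   episodes with two thresholds: an inpatient admission within τ₁ = 10 days
   of a previous discharge is a hospital transfer within the same episode,
   and an outpatient visit within τ₂ = 35 days of an admission, discharge,
   or already-linked visit is continuing care (rules applied transitively).
   D^in runs from the first admission to the last discharge. Analyzable
   cases require surgery, hospitals inside the network's giant component,
   and D^in ≤ 400 days.
2. **Provider network.** From the 0/1 patient×provider usage matrix *B*
   (any number of contacts collapses to 1), providers *i*, *j* are joined
   with weight w_ij = cos(B_i, B_j), the cosine similarity of their patient
   vectors — normalizing away provider size. Node strength
   s_i = Σ_j w_ij is read as provider *i*'s level of cooperation.
3. **Features.** Either the scalar μ_G(s) — the geometric mean of strength
   over the hospitals H_i of case *i* — or the mean node2vec vector
   μ(v) = (1/n_i) Σ_{j∈H_i} v_j. node2vec is implemented from scratch:
   second-order walks with return parameter *p* and in-out parameter *q*
   (bias 1/p, 1, 1/q by distance from the previous node), and a skip-gram
   trained with exact softmax over all nodes. A grid search over (p, q)
   scores each cell by cross-validated regression RMSE.
4. **Models.** Model 1: OLS of D^in on μ_G(s). Model 2: adds age.
   Model 3: OLS on μ(v). Model 4: regression-tree ensemble (random forest
   or least-squares boosting, both implemented here) on μ(v). Models are
   compared by R² of pooled out-of-fold predictions on identical 5-fold
   splits.
5. **Communities.** Two-level map-equation (Infomap-style) community
   detection by seeded greedy search, per-community structural features,
   and the relation between a community's μ_G(s) and its structure.

## Worked example

```bash
python examples/02_episodes_and_network.py
```

```
5665 claims -> 639 episodes
giant component: N=118, L=1534, <k>=26.00, <s>=4.17, <d>=1.87, <C>=0.560, r=-0.004
cases after filters (surgery, giant component, D^in <= 400): 618
mean D^in = 71.1 days; mean age 85.5; female share 77.0%
hospitalized at 1 / 2 / >=3 providers: 77.2% / 19.9% / 2.9%
```

The cohort regime mirrors elderly femoral-neck-fracture claims: mostly
female patients in their mid-80s, ~77% treated by a single hospital, a
mean stay around ten weeks, and a disassortative, clustered network in
which hub hospitals share patients with small clinics.

```bash
python examples/03_embedding_and_models.py
```

```
Model 1 (OLS of D^in on the geometric mean of strength):
             coefficient  std_error       t  p_value
(Intercept)       83.009      3.781  21.955      0.0
mu_G(s)           -2.495      0.615  -4.054      0.0
R^2 = 0.0129, F = 16.43 (p = 5.3e-05)

cross-validated R^2, Models 1-4 (identical folds):
  model statistic  cv_r2  adj_cv_r2
Model 1           0.0114     0.0106
Model 2           0.0113     0.0097
Model 3      mean 0.0053    -0.0075
Model 3      best 0.0086    -0.0042
Model 4      mean 0.1602     0.1494
Model 4      best 0.2003     0.1899
```

The strength slope is significantly negative — cases treated by
better-cooperating hospitals stay shorter — but explains ~1% of variance;
the tree ensemble on embedding features explains ~16–20%, an order of
magnitude more. `examples/01_simulate_claims.py` and
`examples/04_communities.py` cover the generator and the community
analysis; the `carenet` command exposes the same stages from a shell
(`carenet run --config cfg.yaml`).

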