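# Methods

`fedfilter` simulates federated training of clinical risk models across
sites whose ML-ready data views disagree — in feature count, column order,
or measurement units — and implements the knowledge-abstraction-and-
filtering mechanism that lets such sites train one global model without
manually aligning their views.

## The filtering mechanism

Each client holds a private *filtering module* with parameters
φ = (W₁, b₁, W₂, b₂).  For a sample x ∈ ℝᴰ in the client's native view and
the global *knowledge vector* h ∈ ℝᴷ:

    e₁ = W₁ᵀ x + b₁          W₁ ∈ ℝ^{D×K}
    e₂ = W₂ᵀ h + b₂          W₂ ∈ ℝ^{K×K}
    M  = σ((e₁ + e₂) / 2)
    x′ = M ⊙ h

The two layers are purely linear; the single nonlinearity is the sigmoid on
the averaged embedding.  The mask M lies strictly inside (0,1)ᴷ, so x′ is
an element-wise attenuation of h: the sample acts as a query that decides
how much of each knowledge-vector coordinate passes through.  Because a
permutation of input features can be absorbed by permuting the rows of W₁,
the mechanism can represent shuffled views exactly; arbitrary rescaling of
features is likewise absorbed by column rescaling of W₁.

Filtering can be applied recursively (default depth R = 2): stage r gates
the previous stage's output while re-reading the original sample.  Time
series and graphs reuse one filter stack across all time steps / nodes
(weight sharing); edges pass through untouched.

Numerical note: float64 sigmoid saturates to exactly 1.0 for
pre-activations above ~37, so the mask is clamped to the largest open
float64 subinterval of (0,1).  This affects only the strict-openness
guarantee, never the values at realistic scales.

## Models

Prediction models consume the K-dimensional filtered representation:

* tabular — MLP with one hidden layer (128 ReLU units) and a logistic head;
* time series — GRU with 128 hidden units over the T×K filtered sequence,
  logistic head on the final state (the gate layout is an implementation
  choice; the federation layer is agnostic to it);
* graphs — two-layer GCN (K → 128 → labels) with symmetric degree
  normalisation and self-loops, predicting per node.

The loss is mean binary cross-entropy (independent per label for
multilabel tasks; no class re-weighting by default).  All forward and
reverse passes are explicit numpy; analytic gradients of
loss∘model∘filter are verified against central finite differences to
relative error < 1e-4 in the test suite.

## Federated protocol

Per round: the server broadcasts (θ, h); each client copies them, trains
(θ_c, h_c, φ) jointly for J = 1 epoch of mini-batches (batch 64) with Adam
at β = 1e-3, stores φ locally, and reports the pseudo-gradients
∇θ = θ − θ_c and ∇h = h − h_c; the server applies

    θ ← θ − η · mean_c ∇θ^c,      h ← h − η · mean_c ∇h^c.

Design choices made where the protocol description leaves room:

* **Server step η.** The update above with η = 1 is exactly classical
  model averaging (θ ← mean θ_c), the FedAvg/FedSGD blueprint this
  framework extends, and is the package default.  A small η (e.g. 1e-3)
  shrinks each round's global movement to ~β·η per parameter, which at
  J = 1 never trains the global model within any realistic round budget;
  it remains available through the configuration.
* **Optimiser state** resets every round, keeping the pseudo-gradient a
  pure function of (θ, h, data) for that round.
* **Participation** is full (every client, every round) by default at the
  4–50 client scale; a sampling fraction is exposed.
* **Aggregation** is the unweighted client mean; a sample-count-weighted
  mean is exposed as configuration.
* **Exactness.** Local training accumulates Adam step amounts and always
  evaluates parameters as `initial − accumulated`; the reported
  pseudo-gradient *is* the accumulated total.  The server's η = 1
  single-client update therefore re-evaluates the client's own final
  floating-point expression, making the protocol reduction
  federated(1 client, η=1) ≡ local training bit-exact.
* **Determinism.** Every random stream derives from
  (seed, round, client-id hash); deltas are sorted by client id before
  averaging.  Client execution order cannot change any number, and a
  resumed run reproduces the uninterrupted run bit-exactly.

Baselines: plain FedAvg (no h, no filter; requires — and under feature
disparity is given — common-subset harmonised views, the lossy manual
alignment the framework avoids); standalone local models; and the
standalone variant of the framework itself, where (θ, h, φ) are all
trained at one site.  Personalisation fine-tunes the final global model at
each client for up to 5 local epochs, returning the epoch with the best
validation AUROC.

## Synthetic study conditions

The generator emulates a multi-site clinical cohort:

| parameter | default | meaning |
|---|---|---|
| clients | 4 | three sites with 2000 samples, one scarce site with 200 |
| features D | 28 | 20 informative, 8 pure noise |
| latent dim | 16 | shared factors driving features and labels |
| prevalence | 0.15 | per-site event rate (imbalanced, calibrated intercept) |
| noise sd | 0.5 | feature noise around the latent mixing |
| shift sd | 0.5 | per-site covariate mean shift (case-mix drift) |
| signal | 3.0 | ℓ₂ norm of the latent→logit weights |

Labels are Bernoulli draws from a logistic model on the latent factors,
with a per-site intercept solved (Brent) so the realised prevalence matches
the target.  Feature noise is calibrated so a pooled logistic oracle on the
raw features reaches AUROC ≈ 0.85 — the performance band of the clinical
tasks this simulation stands in for.  The time-series variant adds AR(1)
temporal noise around the static profile; patient graphs connect samples
by cosine union-kNN (k = 10) on z-scored features with self-loops.

View heterogeneity operators (all seeded, all audited via a recorded
`ViewTransform`, none touching labels): feature disparity (random kept
subset; the default experiment pattern keeps the full view at half the
sites and 75% — 21 of 28 — at the rest), shuffled views (per-site column
permutation), scaled views (per-feature log-uniform factors in
[0.01, 100]).  Common-subset harmonisation intersects feature names and
orders them canonically.

What the generator does **not** emulate: missing data, mixed
categorical/continuous types, informative missingness, temporal
irregularity, coding-system drift.  Passing tests show the mechanism and
protocol behave as designed under controlled heterogeneity — not that the
framework reaches any particular performance on real EHR data.

A caveat worth knowing when reading results: the per-site mean shift makes
sites identifiable from their inputs, so a sufficiently trained joint
model can partially absorb per-site permutations by first inferring the
site.  This attenuates, but does not erase, the FedAvg degradation under
shuffled views.

## Evaluation harness

Experiments draw a fresh population per run (ten independent seeds by
default), apply the scenario's transforms, split each site 65/15/20
(label-stratified, largest-remainder rounding — 100 samples split exactly
65/15/20), train every requested method, personalise the federated ones,
and score each site's test split: AUROC (rank statistic, tie mid-ranks),
AUPRC (precision–recall step integral), and sensitivity / specificity /
PPV / NPV at a threshold chosen on the validation split by Youden's J
(a fixed-0.5 policy is available).  Macro values are unweighted means
across sites (and across labels for multilabel tasks); metrics undefined
on a single-class sample are reported as missing and excluded with a
logged count, never fabricated.

Because the simulated cohorts are orders of magnitude smaller than the
clinical registries they stand in for (thousands rather than hundreds of
thousands of samples), long training overfits.  All experiment drivers
therefore select the federated round — and the standalone epoch —
with the best validation AUROC (checked every 5 rounds), symmetrically for
every method; this follows the stated practice of selecting
hyperparameters by validation performance.  Training runs use 100
federated rounds / 100 standalone epochs, sizes at which the
validation-selected models have plateaued on the synthetic tasks.

Gradient feature importance is the mean over samples of
|∂p/∂x| back-propagated through model and filter, reported per native
feature.  The disparity probe plants a strongly predictive feature
(a noisy copy of the label, emulating a decisive vital sign) that only the
richer half of the sites record, and checks that its importance at those
sites exceeds the median importance of pure-noise features.

The knowledge-size sweep repeats the disparity experiment for each K with
everything else fixed, reporting macro AUROC/AUPRC mean ± sd over runs.

## Known limitations

* The GRU and GCN layer layouts are declared defaults, not reconstructions
  of any particular reference architecture.
* Graph-mode feature importance returns gradients of the summed node
  outputs (node convolution couples samples).
* Shuffle-equivariance of the filter holds to ~1e-15 per element, not
  bit-exactly: float addition is not associative under permutation.
* Single-process simulation; no secure aggregation, differential privacy,
  client asynchrony or communication compression.
* The knowledge-size effect is weak on the default binary task: a
  single-outcome logistic label model has a low-dimensional sufficient
  statistic, so small knowledge vectors are only mildly handicapped.
  Capacity differences show more strongly on multilabel tasks, where the
  per-sample sufficient statistic grows with the number of labels.
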