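# Methods

This note documents the models implemented in `hmlm`, the assumptions behind
them, the parameters that matter, and the places where the design was
genuinely open and a choice had to be made.

## Transducer dynamics

Every species v is an information transducer with activity state
s_v(t) ∈ [0, 1].  Incoming signal is integrated as a clipped signed weighted
sum of regulator outputs,

    Omega_v(t) = clip01( sum_u W[u, v] * s_u(t) + drive_v ),

and the state follows an explicit first-order (Euler-style) discrete update
with dt = 1,

    s_v(t+1) = clip01( s_v(t) + dt * (k_int,v * Omega_v - k_deg,v * s_v(t))
                       + eps ),    eps ~ Normal(0, noise_sd).

The additive Gaussian state noise realizes the stochastic-transducer
extension of the deterministic dynamics; there is no separate output noise.
Module-specific rates (per unit time): receptors (0.40, 0.05), kinases and
second messengers (0.35, 0.08), transcription factors (0.25, 0.06),
ECM/fibrosis markers (0.15, 0.03).  Modules without their own published
calibration are assigned by functional analogy — MAPK, Rho and
mechanotransduction behave like kinases; matrix remodeling like ECM
synthesis; feedback like transcription factors — and all rates are exposed
in `SimulationConfig`.  `noise_sd` defaults to 0.015, the midpoint of the
0.01–0.02 measurement-noise band, constant per species with an optional
per-module override.  Species in the `inputs` module are experimental
stimuli and are clamped to their condition drive (plus noise).

Steady state of an isolated driven node is s* = min(1, k_int·u/k_deg); the
test suite verifies this closed form to 1e-6.  Time constants 1/k_deg range
from 12 steps (kinases) to 33 steps (ECM), which produces the cascade
propagation delays (receptor before transcription factor before collagen)
over the 100-step window.

### Initialization

Simulations start from the *rested* state: a noise-free burn-in (300 steps)
under baseline drive (0.05 on every input) relaxes the system to the control
steady state before the stimulus switches on at t = 0, as in a real
stimulation experiment.  Uniform initialization is available via
`init_mode="uniform"`.  Without the burn-in, every condition shares a large
initial transient that dominates all cross-species correlations.

## The fixture network

The fixture emulates the scale and modular organization of curated cardiac
fibroblast signaling models: 132 species over 11 functional modules with
300+ directed signed edges.  A named backbone carries the canonical biology
(TGF-β→TGFBR→SMAD3→collagen with SMAD7/BAMBI feedback; PDGF→PDGFR→PI3K/RAS;
AngII→AT1R→second messengers; IL-6→gp130→STAT3; strain→integrins→FAK with
RhoA/ROCK/YAP/MRTF mechanotransduction; MMP/TIMP matrix remodeling; DUSP
phosphatase feedback), including documented crosstalk links: SMAD3→PDGFR
(TGF-β upregulates PDGF receptors in fibroblasts), Src→PDGFR (receptor
transactivation under mechanical stimulation), MRTF/SRF→collagen
(TGF-β-independent strain-induced fibrosis).  Procedurally generated filler
species are wired predominantly feed-forward through the module layering and
mostly into other fillers, so the background circuitry does not rewire the
curated cascades.  Outgoing edges of the feedback module and of protease
inhibitors are inhibitory; everything else activates.

Edge weights are scaled by the target's steady-state gain: the total
activating in-weight of node v is about (k_deg/k_int)_v · 2/(1 + in-degree),
i.e. one active regulator transmits with roughly unit gain while a node
whose regulators all fire at once saturates only mildly.  This is what keeps
activity levels informative across multi-stage cascades — unnormalized
weights saturate everything at the [0,1] bounds, per-in-degree normalization
attenuates signals into the noise floor.

Generation is a pure function of `(n_species, seed)`.

## Attention

Initialization is purely topological: 1.0 on the diagonal, 0.8 for a direct
edge, 0.4 / 0.2 for shortest directed paths of length 2 / 3, else 0.
Refinement blends in temporal evidence:

    A[i, j] = clip01( 0.3 * A0[i, j] + 0.7 * max_{tau in {0,1,2}} R_ij(tau) ),

where R_ij(tau) is the Pearson correlation between x_i(t) and x_j(t + tau),
computed per condition and *averaged over conditions* before the max.
Averaging (rather than concatenating conditions) prevents condition-level
offsets from manufacturing correlation; its cost is that the quiescent
control condition dilutes the average, which caps cross-pathway attention
aggregates well below what co-activated pathways show within stimulated
conditions.  Negative blends are clamped to 0; zero-variance series define
R = 0 so constant control trajectories cannot poison the max.

Pathway attention is the mean of A over all ordered cross-module species
pairs.  Pathway groupings are configurable; the defaults group
receptor-proximal axes (e.g. PDGF pathway = PDGFR/PI3K/AKT — the ligand is a
stimulus, not a pathway member).

Significance uses nulls that rewire the graph degree-preservingly,
re-initialize attention from the rewired topology, and re-refine on
timepoint-bootstrap-resampled data; p-values use the add-one convention
(b+1)/(n+1).

## Features and the ensemble

Each (condition, species, timepoint) row carries three blocks:

* molecular — x_i(t); central-difference derivative (one-sided at the
  boundaries); max lagged correlation with any network neighbor over lags
  {0,1,2,3} (0 for isolated nodes); memory M_i(t) = 0.3·x_i(t) + 0.7·M_i(t−1)
  with M(0) = x(0); attention-weighted regulator activity
  Σ_u A[u,i]·x_u / Σ_u A[u,i] over significant links (A > 0.3) — A[u,i]
  scores how informative u is for predicting i, so the column aggregate is
  the model's learned receptive field for i; spectral positional-embedding
  components (eigenvectors of the normalized Laplacian of the symmetrized
  graph, k = 4 smallest nonzero eigenvalues) scaled by current activity.
* pathway — mean activity and mean derivative of the species' module.
* cellular — global mean activity, global variance, fibrosis index (mean
  activity of the ECM/fibrosis module).

Three random-forest heads (150 trees; depths 12/10/8 for molecular /
pathway / cellular) are trained independently, each on its block, pooling
all species as samples so local dynamics rules transfer across the network
and across conditions.  (A vector-output variant — one sample per network
state, all species predicted jointly — was evaluated and rejected: with only
~300 network states per training set it memorizes condition-specific global
states and fails on held-out conditions.)  Features are z-scored per column
with statistics fitted on training rows.  Ensemble weights follow the
inverse-CV-MSE rule w_h ∝ 1/MSE_h^CV (5-fold); the CV runs on a capped
subsample of rows (default 6000) because only *relative* head errors matter,
and the final heads are refit on everything.  Forests use a bagging
subsample of 0.33 per tree, bounding training cost at 132 species without
changing tree count or depth.  Predictions are clipped to [0, 1].

### Rollout

Autoregressive forecasts re-derive the derivative (backward difference at
the rolling tip), memory, attention-weighted and aggregate features from the
growing predicted trajectory; the attention matrix and the per-species
correlation feature stay frozen at training values.  Because the one-step
map was fitted on noisy trajectories, feeding it its own smooth predictions
is out of distribution and the classic errors-in-variables shrinkage
compounds into systematic under-response.  Rollouts therefore simulate the
fitted *stochastic* system: five trajectories with injected Gaussian state
noise (sd = the training one-step residual sd) are averaged into the point
forecast.  This is deterministic given the seed.

Known limitation: a model trained with no quiescent condition (the
control-held-out rotation of leave-one-condition-out evaluation) has no
representation of sustained rest, and its forecasts creep upward; together
with residual increment attenuation this compresses predicted
cross-condition contrast, so correlations *pooled across rotations* are much
lower for slow downstream readouts than the within-condition shape
correlations (0.8–0.95 for collagen/p38/contractility under stimulation).

## Baselines

Each baseline is the canonical minimal representative of its family, sharing
the fit / one-step / rollout contract: ODE (per-module rates by least squares
under the true structural form, clipped transitions excluded; with
`use_true_structure=False` only topology is trusted), LDE (one ridge map
x(t+1) = Bx(t) + c, λ = 1e-3), GNN-style (one forest on own activity plus
mean/max in-neighbor activities at t and t−1), Bayesian network (3
equal-frequency bins, ≤ 3 highest-weight parents, add-one-smoothed CPTs,
expected-bin-value prediction), and a mean predictor as the floor.
Benchmark claims are scoped to these implementations.

## Evaluation protocols

*Temporal resolution*: datasets are subsampled to 4/8/16 evenly spaced
timepoints (endpoints included) and linearly re-interpolated onto the
100-point grid; models train on the first 70% of timepoints of all four
conditions and are scored by one-step MSE on the last 30%, on the
interpolated grid so errors are comparable across resolutions.  Five trials
differ by dataset seed; the trial-to-trial coefficient of variation
(std/mean) measures stability.  One-step-ahead errors on interpolated data
are O(1e-4) — orders of magnitude below trajectory-level forecast errors,
which is worth keeping in mind when comparing error magnitudes across
protocols.

*Leave-one-condition-out rollout*: train on three conditions, roll out the
held-out condition from the first five observed timepoints, rotate over all
four conditions, and pool predicted/observed pairs across rotations for the
per-readout Pearson correlation.  TGF-β signaling dynamics are read at the
receptor (TGFBR); the ligand itself is the clamped stimulus.

*Statistics*: two-sided Wilcoxon signed-rank on paired per-trial errors with
Bonferroni adjustment (min(1, m·p)); seeded percentile bootstrap (n = 1000)
for intervals.

*Crosstalk*: C_kl = |pearson(Ā_k, Ā_l)| between pathway mean-activity
series, per-condition mean-centered before concatenation (condition offsets
otherwise dominate); C > 0.3 is flagged as biologically significant;
constant series yield 0 with a warning.

## What the synthetic data does and does not show

The generator reproduces the *structure* of fibroblast activation
experiments: modular topology, graded condition responses, cascade delays,
combined-stimulation synergy, negative feedback, stationary measurement-like
noise.  It does not emulate cell-to-cell heterogeneity, unmodeled latent
inputs, batch effects, missing data, or non-Gaussian noise; passing tests
demonstrate internal consistency of the methods under the stated dynamics,
not performance on experimental measurements.  Problem sizes used throughout
(132 species, 4 conditions × 100 timepoints, 5 benchmark trials, 1000
bootstrap draws) are the package's defaults and are what every reported
number is computed from.
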