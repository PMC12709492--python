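# hmlm — hierarchical multi-scale modeling of signaling-network dynamics

`hmlm` models intracellular signaling as a network of information
transducers: each molecular species carries an activity state
s<sub>v</sub>(t) ∈ [0, 1] that integrates the signed, weighted outputs of its
regulators, Ω<sub>v</sub>(t) = clip(Σ<sub>u</sub> W<sub>uv</sub> s<sub>u</sub>(t) + drive<sub>v</sub>),
and evolves by first-order kinetics
s<sub>v</sub>(t+1) = clip(s<sub>v</sub>(t) + Δt·(k<sub>int</sub>·Ω<sub>v</sub> − k<sub>deg</sub>·s<sub>v</sub>) + ε).
On top of this substrate the package provides:

* **a fixture network generator** — a 132-species, 300-edge cardiac-fibroblast-
  style signaling network organized into 11 functional modules (inputs,
  receptors, second messengers, kinases, MAPK, Rho, transcription factors,
  ECM/fibrosis, matrix remodeling, mechanotransduction, feedback), carrying
  the canonical TGF-β/SMAD, PDGF/PI3K, AngII, IL-6, β-adrenergic and
  integrin/FAK mechanotransduction cascades with negative feedback;
* **a simulator** for four stimulation conditions (control, TGF-β, mechanical
  strain, combined) at 100 timepoints with module-specific rates and
  Gaussian state noise;
* **attention inference** — species-pair weights initialized from graph
  distance (1.0 self / 0.8 edge / 0.4 two-hop / 0.2 three-hop) and refined
  with the maximum lagged Pearson correlation over lags {0,1,2}:
  A = clip(0.3·A⁰ + 0.7·max<sub>τ</sub> R̄(τ)), with pathway-level aggregation and
  degree-preserving-rewiring null tests;
* **multi-scale temporal features** — activity, central-difference
  derivatives, max lagged neighbor correlation, exponential memory
  M(t) = 0.3·x(t) + 0.7·M(t−1), attention-weighted regulator activity,
  spectral positional embeddings, module means, global statistics;
* **a three-head random-forest ensemble** (molecular / pathway / cellular
  heads, 150 trees at depths 12/10/8) with inverse-CV-MSE ensemble weights,
  one-step prediction and stochastic autoregressive rollout;
* **baselines and evaluation** — mechanistic (ODE), linear (LDE),
  graph-aggregation (GNN-style) and discrete Bayesian-network baselines, a
  5-trial temporal-resolution benchmark (4/8/16 subsampled timepoints),
  Wilcoxon/Bonferroni comparisons, bootstrap intervals, and pathway
  crosstalk as absolute Pearson correlation of module mean activities.

## Worked example

```python
import numpy as np
from hmlm import (
    generate_fixture_network, SimulationConfig, generate_dataset,
    init_attention, refine_attention, pathway_attention,
)
from hmlm.network import default_pathway_groups
from hmlm.model import HMLMForecaster

net = generate_fixture_network(n_species=132, seed=1)
data = generate_dataset(net, SimulationConfig(seed=1))
print(data.activity.shape)
# (4, 100, 132)   # condition x timepoint x species

att = refine_attention(init_attention(net), data)
i, j = net.index("TGFBR"), net.index("SMAD3")
print(round(float(att.refined[i, j]), 3))
# 0.685           # strong receptor -> SMAD attention on this seed

model = HMLMForecaster(random_state=1).fit(net, data.slice_times(0, 70))
print(round(model.one_step_mse(data, times=np.arange(70, 99)), 5))
# 0.0001          # held-out one-step error, far below the 0.09 variance floor
```

The attention entry says the TGF-β receptor is a strong predictor of SMAD3
dynamics (direct regulatory edge plus high lagged correlation under
stimulation); the one-step MSE is the squared error of next-step activity
prediction on the final 30 timepoints, which the model never saw.

The same pipelines are scriptable from the shell:

```bash
hmlm generate  --seed 1 --out run/            # network + tidy dataset CSV
hmlm benchmark --seed 1 --models hmlm,ode,lde,gnn,bayes --out run/bench
hmlm attention --seed 1 --out run/attn
hmlm crosstalk --seed 1 --out run/crosstalk.csv
```

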