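# mlggm — multilevel Bayesian graphical models for nested time series

Connectivity studies routinely collect *nested* data: repeated
measurements (e.g. BOLD time series) within participants, participants
within a population.  Analyzing each participant alone ignores the
structure they share; pooling the raw data first assumes they share
everything, underestimates uncertainty, and can even reverse effect
directions between levels (Simpson's paradox).  `mlggm` estimates both
levels jointly:

- **Individual level** — a Gaussian graphical model per participant:
  signal `x_t ~ N(0, Ω_n⁻¹)`, with a spike-and-slab prior on the
  off-diagonal precision elements whose binary indicators `γ_n` are the
  participant's network structure.
- **Group level** — a Curie-Weiss model over those indicators,

  `p(γ | μ, σ) ∝ exp( Σ_e γ_e μ_e + (σ/E)·γ₊² )`,

  with per-edge main effects `μ` and an average pairwise interaction
  `σ ≥ 0` acting through the squared edge count `γ₊²`.

The joint posterior `p(G, S_1…S_N | data) ∝ ∏_n p(data_n|S_n) p(S_n|G)
p(G)` is sampled by a Gibbs scheme in which participants are
conditionally independent given the group — participant updates can run
on parallel workers with bitwise-reproducible results.  The package also
ships the two conventional baselines (per-participant fits; aggregated
precision-matrix analysis), a simulator that mirrors the generative
model (group graph → main effects → Curie-Weiss individual graphs →
G-Wishart precisions → Gaussian series), and evaluation statistics:
ROC/AUC edge recovery, inclusion Bayes factors, group-predicts-individual
ROC curves with 95% bands, and per-edge heterogeneity.

It is aimed at methodologists and applied researchers working with
multi-participant time-series networks (resting-state fMRI connectivity
being the motivating case) who want edge-level evidence at both levels
instead of a single pooled or per-person answer.

See `docs/methods.md` for the model, algorithms, and numerical choices.

## Worked example

Simulate a small homogeneous study, fit all three analyses, and score
edge recovery against the simulation truth:

```python
import numpy as np
from mlggm import (SimulationConfig, simulate_study, prepare_data,
                   FitConfig, fit_multilevel, fit_individual, fit_aggregate,
                   individual_edge_auc, group_edge_auc)

truth = simulate_study(SimulationConfig(P=10, N=10, T=150, rho=100.0, seed=3))
data = [prepare_data(x) for x in truth.timeseries]
cfg = FitConfig(iterations=300, burnin=100, chains=1, seed=11)

for name, fit in [("multilevel", fit_multilevel(data, cfg)),
                  ("individual", fit_individual(data, cfg)),
                  ("aggregate",  fit_aggregate(data, cfg))]:
    print(f"{name:>10}:  individual-edge AUC {individual_edge_auc(fit, truth):.3f}"
          f"   group-edge AUC {group_edge_auc(fit, truth):.3f}")
```

which prints

```
multilevel:  individual-edge AUC 0.957   group-edge AUC 0.992
individual:  individual-edge AUC 0.878   group-edge AUC 0.992
 aggregate:  individual-edge AUC 0.814   group-edge AUC 0.938
```

With homogeneous participants (`rho = 100`) the multilevel fit pools
evidence across the cohort and recovers individual edges best; the
per-participant analysis cannot borrow strength; the aggregate analysis
pays for assuming everyone is identical.  At `rho = 0` (no shared
structure) the multilevel and individual analyses perform alike.

The same workflow is available from the shell:

```sh
mlggm simulate --nodes 10 --participants 10 --timepoints 150 --rho 100 \
      --seed 3 --out study/
mlggm fit --manifest study/manifest.tsv --method multilevel \
      --iterations 2000 --burnin 500 --chains 2 --seed 11 --out fit/
mlggm evaluate --fit fit/ --truth study/truth --out scores/
mlggm predict-individuals --fit fit/ --out prediction/
```

Every output directory contains the resolved configuration and seed, and
reruns are byte-identical.

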