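# stochbif

Estimating the **stochastic bifurcation structure** of bistable genetic
switches from single-cell flow-cytometry histograms measured across a dose
gradient.

## The problem

A deterministic bistable switch is summarised by its bifurcation diagram:
the S-shaped curve of steady states versus a control parameter, folded at
two saddle-node points. Real cellular networks are noisy — in a population
of genetically identical cells the switch manifests not as two sharp states
but as two overlapping subpopulations whose sizes and positions change with
the input. The stochastic analogue of the bifurcation diagram therefore
reports, as a function of the control parameter *g* (here: galactose
concentration, % w/v):

1. the number of distinguishable subpopulations,
2. their locations (mean log-fluorescence, in cytometer channels),
3. the variability within each subpopulation, and
4. the fraction of the population in each.

`stochbif` extracts this structure from binned cytometry data — event
counts over 1024 fluorescence channels spanning four decades of intensity —
using mixture density estimation. The observation model for a single
condition is a *K*-component Gaussian mixture in channel (log-intensity)
space plus a uniform outlier component with fixed weight 0.02:

```
p(c) = 0.02/1024 + Σᵢ wᵢ N(c; μᵢ, σᵢ²),   Σᵢ wᵢ = 0.98
```

Three estimators are provided:

* **EM** — per-condition maximum likelihood via expectation–maximisation,
  best of 100 random restarts, with the component count chosen by a
  10-fold cross-validation rule (accept *K*+1 over *K* only when the mean
  held-out per-event log-likelihood improves by more than α standard
  deviations across folds).
* **ME+EM** — density peaks are located first (width-71 running-average
  smoothing, width-71 centred finite-difference derivatives, a curvature
  threshold to reject spurious bumps); one Gaussian is pinned at each mode
  and a single EM run fits only weights and variances.
* **CEM** — a conditional mixture fit jointly across the whole dose series:
  affine subpopulation means `μ(g) = a + b·g`, dose-independent variances,
  and a low-subpopulation weight that equals 0.98 below a threshold `g0`
  and decays as `0.98·exp(−r·(g−g0))` above it.

A synthetic-data module emulates the yeast galactose-utilisation switch
experiment (17 galactose concentrations × 4 biological replicates × 2
pregrowth histories, 60,000 events per condition, ~50% scatter gating, 2%
outliers, replicate-level jitter), so every estimator is testable end to
end against known ground truth. A small deterministic module draws the
noiseless counterpart: steady states and fold points of a Hill-type
auto-activator ODE.

## Worked example

```python
import numpy as np
from stochbif import (default_paper_spec, generate_dataset, fit_cem,
                      extract_structure)

spec = default_paper_spec(seed=3)          # the full synthetic study
data = generate_dataset(spec)
hists = [data.get("gal", "1", g) for g in data.concentrations("gal", "1")]

result = fit_cem(hists)                    # conditional mixture, one EM run
m = result.model
print(f"threshold g0 = {m.g0:.4f} %gal, decay r = {m.r:.0f} /%gal")
print(f"high branch: mu(g) = {m.a_high:.0f} + {m.b_high:.0f} g")
print(f"spreads: low {m.sigma_low:.1f}, high {m.sigma_high:.1f} channels")

structure = extract_structure(m, concentrations=data.concentrations("gal"))
snap = structure[0.0087]
print(f"at g=0.0087: {snap.n_subpops} subpopulations at "
      f"{np.round(snap.locations, 1)} with fractions "
      f"{np.round(snap.fractions, 2)}")
```

prints (ground truth: g0 = 0.003, r = 150, high branch 550 + 4000·g,
spreads 40/80; the intercepts carry this replicate's biological jitter):

```
threshold g0 = 0.0030 %gal, decay r = 150 /%gal
high branch: mu(g) = 556 + 3985 g
spreads: low 40.0, high 79.6 channels
at g=0.0087: 2 subpopulations at [159.6 590.3] with fractions [0.43 0.57]
```

The fitted threshold says the high-expressing subpopulation appears
abruptly near 0.003% galactose and the low subpopulation then decays
exponentially with dose; at g = 0.0087 the population is split roughly
43/57 between the two states.

The same analysis is available from the shell:

```
stochbif simulate --seed 17 --out data.tsv
stochbif fit-cem --data data.tsv --replicate 1 --pregrowth gal --seed 1 --out cem.json
stochbif run --config config.yaml          # simulate -> fit all -> report
stochbif ode-diagram --out diagram.tsv     # deterministic S-curve
```

## Layout

| module | contents |
| --- | --- |
| `stochbif.flow_data` | histogram containers, channel↔intensity transform, TSV I/O |
| `stochbif.synthetic_data` | the synthetic study generator |
| `stochbif.mixture_em` | Gaussian-plus-uniform EM with restarts |
| `stochbif.model_selection` | event-level CV folds, component-count rule |
| `stochbif.mode_estimation` | smoothing, wide finite differences, peak detection, ME+EM |
| `stochbif.conditional_mixture` | the conditional (dose-linked) mixture and its EM |
| `stochbif.bifurcation_summary` | structure extraction, train/test NLL, variability split |
| `stochbif.deterministic_model` | auto-activator ODE, steady states, fold points |
| `stochbif.cli` | `stochbif` command-line pipeline |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and numerical details.
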