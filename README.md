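# ppdkin

Kinetic modelling of the enantioselective hydrogenation of
1-phenyl-1,2-propanedione over a cinchonidine-modified Ir/TiO₂ catalyst —
and, more generally, of any two-layer irreversible first-order reaction
network.

## The problem

Hydrogenating the prochiral dione **A** (1-phenyl-1,2-propanedione) can
reduce either carbonyl first (regioselectivity) and on either face
(enantioselectivity), giving four hydroxyketone intermediates **B**–**E**
— among them **B**, (*R*)-1-hydroxy-1-phenylpropanone (L-PAC), an
ephedrine precursor — which hydrogenate further to four diols **F**–**I**.
Up to twelve irreversible steps connect the nine species. Treating every
step as apparent first order, with hydrogen pressure, solvent, catalyst
and modifier effects lumped into the rate constants, the concentrations
obey a linear ODE system

```
dc/dt = K·c,        c(t) = expm(K·t)·c0
```

where the 9×9 rate matrix `K` holds `K[target, source] = k_reaction` on the
off-diagonals and minus the total consumption rate on the diagonal (columns
sum to zero: mass is conserved). The package provides:

- **network_model** (`ppdkin.network`) — the species/reaction topology, the
  rate matrix, validation, YAML network files;
- **forward_kinetics** (`ppdkin.kinetics`) — exact matrix-exponential
  propagation, Bateman closed forms for the intermediates, time-of-maximum,
  and an adaptive-ODE test oracle;
- **estimation** (`ppdkin.estimation`) — bound-constrained least squares for
  the 12 constants (initial guess 0.01 min⁻¹, lower bound 0), 95% marginal
  HPD intervals via a Laplace approximation or MCMC, covariance/correlation
  diagnostics, SSR;
- **synthetic_data** (`ppdkin.synthetic`) — generators emulating the sampled
  batch experiment (10 times on 0–360 min, multiplicative noise) plus the
  dataset CSV format;
- **reporting** (`ppdkin.pathways`, `ppdkin.cli`) — classification of
  negligible / preferential / intermediate routes, selectivity metrics, and
  the `ppdkin` command-line pipeline.

Constants that the optimiser pushes negative are clipped to the zero bound
and flagged; on this catalyst the fitted k₈ (E→I) and k₉ (C→G) are nil,
identifying those routes as negligible, while A–B–F and A–C–H emerge as the
preferential pathways.

## Worked example

Generate a noisy synthetic experiment, refit the constants, and classify
the routes:

```python
import numpy as np
from ppdkin import (ExperimentDesign, FitConfig, NoiseSpec, classify_pathways,
                    default_network, fit, generate_dataset, time_of_maximum)

network = default_network()
design = ExperimentDesign()                      # 10 times on [0, 360] min, pure A
data = generate_dataset(design, NoiseSpec(sigma=0.02, seed=42))
result = fit(data, network, FitConfig(weighting="relative"), c0=design.c0)

for i, (est, hw, ab) in enumerate(zip(result.estimates, result.hpd95, result.at_bound), 1):
    print(f"k{i:<3} 0            (at lower bound)" if ab
          else f"k{i:<3} {est:.3e} ± {hw:.3e} min^-1")
print(f"SSR = {result.ssr:.3e}, converged = {result.converged}")

cls = classify_pathways(result.estimates, network)
print("negligible  :", [r.label for r in cls.negligible])
print("preferential:", [r.label for r in cls.preferential])
peak = time_of_maximum(result.estimates[4] + result.estimates[5], result.estimates[:4].sum())
print(f"predicted peak of B at {peak:.0f} min")
```

prints

```
k1   8.309e-04 ± 1.383e-05 min^-1
k2   3.185e-03 ± 2.936e-05 min^-1
k3   1.485e-03 ± 2.219e-05 min^-1
k4   2.496e-03 ± 2.187e-05 min^-1
k5   1.991e-04 ± 2.333e-06 min^-1
k6   1.772e-03 ± 4.801e-05 min^-1
k7   2.255e-03 ± 4.310e-05 min^-1
k8   0            (at lower bound)
k9   0            (at lower bound)
k10  2.985e-04 ± 1.078e-04 min^-1
k11  3.740e-04 ± 9.800e-05 min^-1
k12  6.082e-04 ± 8.097e-06 min^-1
SSR = 4.795e-04, converged = True
negligible  : ['A-C-G', 'A-E-I']
preferential: ['A-C-H', 'A-B-F']
predicted peak of B at 232 min
```

Every fitted constant lands within its 95% interval of the generating truth
(2% measurement noise); the two nil constants are recovered on the bound,
the route summary is reproduced, and the intermediate of interest **B**
peaks at ≈233 min — inside the 360-min experimental window, which is why
sampling stops there.

The same pipeline from a shell:

```sh
ppdkin generate --seed 1 --out run/
ppdkin fit --data run/dataset.csv --out run/
ppdkin report --fit run/fit.json --data run/dataset.csv --out run/
```

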