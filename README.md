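# coexsim

A spatially explicit simulator of climate- and land-use-driven vertebrate
extinctions and their amplification through food webs.

Communities of virtual vertebrate species live on a lattice of localities,
each with a monthly temperature/precipitation series and a yearly fraction
*u* of primary + secondary (natural or recovering) land. Species carry a
climatic niche, a body mass, trophic attributes and a random phenotype;
local food webs are assembled from pairwise rules and perturbed by climate
change, land conversion, dispersal and acclimation. Extinction cascades
propagate through a competition-rescaled interaction matrix, and every run
is paired with a **control arm** in which the same primary extinctions occur
but no network effects — the contrast quantifies the *coextinction effect*,
the percentage increase in diversity loss attributable to species
interactions.

The package is for computational ecologists studying coextinction dynamics,
community assembly under forcing, and the sensitivity of cascade models to
their parameterization. All inputs can be generated synthetically, so the
full pipeline runs on a laptop with no external data.

## Model core

**Climatic niche.** For each climate variable *x*, the probability of local
extinction is an asymmetric pair of logistic tails meeting at the niche
optimum x̄:

```
p(x) = 1 − 1/(1 + e^(−c(x−d)))   if x ≤ x̄
p(x) = 1/(1 + e^(−a(x−b)))       if x > x̄
```

*a, b, c, d* are calibrated by slope escalation (start 0.0001, step 0.01,
intercepts re-derived each step from the closed form) so that survival is
exactly p_thresh = 0.95 at the recorded extremes v_min, v_max and the curve
is nearly flat at the optimum. The two-variable niche takes the *minimum*
survival over temperature and precipitation. Species with p_ext ≤ 0.05 in a
given month are immune; above that, extinction is a Bernoulli draw.

**Food webs.** A directed link from resource *i* to consumer *j* requires
(i) trophic ordering (TL_j > TL_i ≥ breadth floor of *j*), (ii) a body-mass
ratio strictly inside the taxon-pair window (l_l, l_u) estimated as the
central 90% of observed resource:consumer ratios, and (iii) phenotype
compatibility c_f > 0.55; the link weight is 1 − (1 − c_f)/(1 − 0.55).
Competition is encoded by rescaling each row of the adjacency matrix **A**:

```
A′_ij = A_ij · (A_ij / Σ_j A_ij)
```

Column sums of **A′** give a consumer's resource availability, row sums a
resource's consumer pressure. The extremes of these at web creation (updated
once after burn-in, then frozen) are the coextinction thresholds: consumers
below the availability minimum die bottom-up, resources above the pressure
maximum die top-down, and species disconnected from basal resources
(herbivores/insectivores, whose plant and insect resources never deplete)
die of disconnection. Cascades iterate these rules to a fixed point.

**Land use.** The yearly diversity loss is a curve in the fraction of
natural land lost, shaped by S_LUC ∈ [−1, 1] (0 = linear); casualties are
the largest-bodied species, relaxed toward random by V_LUC ∈ [0, 1].

## Worked example

```python
import numpy as np
from coexsim import (SimConfig, make_climate, make_landuse,
                     make_trait_tables, run_experiment, coextinction_effect)

rng = np.random.default_rng(0)
T, P = make_climate((5, 5), 45, trend=0.5, noise_sd=0.5, rng=rng)  # 0.5 degC/decade
landuse = make_landuse((5, 5), 45, annual_loss_rate=0.002)
tables = make_trait_tables(75, (T, P), rng)

config = SimConfig(
    pool_counts={"mammal": 75, "bird": 75, "reptile": 75, "amphibian": 75},
    species_per_cell=120, years=40, replicates=3, norm_pairs=100_000,
)
out = run_experiment(tables, T, P, landuse, config, master_seed=1)
loss = out["summary"].pivot(index="replicate", columns="arm", values="loss")
print(loss.round(3))
effects = [coextinction_effect(c, k) for c, k in zip(loss["coext"], loss["control"])]
print("mean coextinction effect: %.1f%%" % np.mean(effects))
```

prints

```
arm        coext  control
replicate
0          0.236    0.165
1          0.296    0.233
2          0.266    0.205
mean coextinction effect: 33.1%
```

Each row is one paired replicate: the fraction of post-burn-in diversity
lost after 40 years of warming and slow land conversion, with network
effects (`coext`) and without (`control`). Here cascades amplify diversity
loss by about a third; the events table in `out["events"]` attributes every
loss to climate, land use, outcompetition, or one of the three cascade
mechanisms.

The same workflow is available from the shell:

```
coexsim fixtures --out fix/ --grid 5x5 --years 45 --trend 0.5 --seed 0
coexsim run --inputs fix/ --config cfg.yaml --seed 1 --out results/
coexsim metrics --run results/
coexsim sweep --inputs fix/ --draws 20 --seed 0 --out sweep.csv
```

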