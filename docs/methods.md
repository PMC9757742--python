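# Methods

This note documents the model implemented by `coexsim`, its assumptions, the
parameters that matter, the synthetic-data generator, and the numerical and
design decisions taken where the model description left the choice open.

## 1. The model

### 1.1 Climatic niches

Each species tolerates one temperature (°C) and one precipitation (mm/month)
axis. An axis is calibrated from monthly climate samples in the species'
range over a calibration window (default 60 months): the optimum x̄ is the
sample mean, the tolerance edges v_min/v_max the sample extremes. Local
extinction probability is two logistic tails meeting at x̄ (warm tail
`1/(1+e^(−a(x−b)))` above, cold tail `1 − 1/(1+e^(−c(x−d)))` below). The
slopes start at 0.0001 and escalate in steps of 0.01, with intercepts
re-derived at every step from the closed forms

```
b = [ln(p/(1−p)) + a·v_max] / a        d = [ln((1−p)/p) + c·v_min] / c
```

which pin extinction at exactly `1 − p_thresh` (default 0.05) at the edges.
Escalation stops when the warm tail at the optimum falls to ≤ 0.001 (cold
tail ≤ 0.0002). Points of note:

* The curve is interpreted throughout as an **extinction** probability;
  survival is its complement. The immunity/persistence cutoff (0.05) and the
  edge anchor (1 − 0.95) are stated in this convention.
* The stopping rule is evaluated **at the optimum** x̄, making the curve
  flat-bottomed over the core of the recorded range; the description of the
  curve ("close to zero when conditions are optimal") fixes this choice.
* Re-deriving the intercept after every slope increment is required — with a
  stale intercept the edge anchor drifts off 0.05.
* Degenerate samples (all values equal) produce a flagged zero-width axis:
  extinction is exactly 0.05 at the single recorded value and saturates
  steeply on either side (slope 10⁴).
* A hard cap of 10⁶ increments raises an error instead of looping forever;
  it is reachable only when v_max − x̄ ≲ 4·10⁻⁴.
* The two axes combine by the *minimum-survival* rule: combined extinction
  is the maximum of the two tail values.

### 1.2 Virtual species

A species pool is built per replicate:

1. (niche, mass) records are sampled per taxon (mammal, bird, reptile,
   amphibian) from the niche-source table; requesting more than the table
   holds falls back to sampling with replacement (logged).
2. Trophic level and breadth floor are transferred from the trophic table by
   body-size matching within the same taxon: relative difference
   `(max−min)/max < r_thresh`, with r_thresh starting at 0.01 and escalating
   by 0.01 until a candidate matches; candidates admitted at the first
   feasible threshold are chosen uniformly (equivalent to scanning in random
   order), and the final threshold is recorded per species.
3. The phenotype is a random string of 1–10 lowercase letters. Compatibility
   between two phenotypes is the sum of trait-matrix entries over all
   ordered letter pairs (resource letters index rows — the 26×26 matrix is
   not symmetric), min-max normalized with constants estimated from 10⁶
   random phenotype pairs and clipped to [0, 1] (the constants are
   Monte-Carlo records, so clipping is occasionally needed).
4. Adaptive capacity A ~ U(0, 1).

A species is **basal** iff its breadth floor reaches the plant/invertebrate
level (0): herbivores and insectivores draw on a non-depletable resource
pool, participate in every web, and are immune to bottom-up coextinction and
disconnection. The taxon tag survives only as a lookup key for the
taxon-pair body-mass-ratio windows; it never affects niches, extinction or
reporting.

### 1.3 Web assembly and coextinction

Links require trophic ordering, a mass ratio strictly inside the taxon-pair
window (central 90% of observed resource:consumer ratios; pairs with < 20
records fall back to the pooled distribution), and compatibility > c_f
(default 0.55); the weight is the linear readjustment
`1 − (1−c_f)/(1−0.55)`. Non-basal species without any resource link are
dropped, iterating to a fixed point (a drop can strand its consumers).
Connectance is reported as E/n² — no interaction, including cannibalism, is
excluded a priori from the denominator, even though the strict trophic
ordering happens to forbid exact self-links.

The competition rescaling `A′_ij = A_ij²/Σ_j A_ij` and the two frozen
thresholds (minimum availability over non-basal consumers; maximum pressure
over consumed resources) define the cascade: per sweep, all three criteria
(bottom-up, top-down, disconnection) are evaluated against the same A′
snapshot and the marked species removed simultaneously, so sweeps are
order-independent and the cascade terminates in ≤ n sweeps. A species
matching several criteria is attributed to the first of
bottom-up/top-down/disconnected. Basal nodes are excluded from the
availability minimum (their vertebrate-resource availability is
legitimately zero). Webs with no non-basal consumer (or no consumed
resource) store ±∞ sentinels — thresholds that never trigger.

Cascade dynamics are **not** monotone in the perturbation: removing a
competitor lowers the total pressure on shared resources, which raises the
rescaled availability of surviving consumers and can rescue a species that a
smaller removal kills (competition release). Empirically ~95% of random
small webs behave monotonically; the test suite asserts that measured rate,
not a universal law.

### 1.4 Colonization

A dispersal event draws a distance `1 + logN(0, 1)` (grid-cell units; the
+1 guarantees adjacent cells are reachable), picks a cell uniformly among
those whose rounded Euclidean grid distance matches, and tests the
colonizer's niche against the target's climate. In the coextinction arm the
target web is rebuilt with the candidate included **under the resident web's
frozen thresholds**: a non-basal candidate without resources is rejected;
one whose entry pushes a resource past the pressure threshold (or starves a
competitor) triggers a cascade that may remove residents and/or the
candidate itself. Basal candidates always enter, but the locality's basal
richness cap (its seeding-time basal count) is enforced by removing basal
species in increasing climatic suitability — ties broken against the most
recent arrival — and those removals can cascade. In the control arm the
same cap logic is extended to the whole community against the post-burn-in
richness, with climate as the only other filter.

### 1.5 The yearly cycle

Each forcing year: (1) twelve monthly climate-mortality sweeps (immune at
p_ext ≤ 0.05, else Bernoulli at p_ext — a deterministic cutoff would make
the progressive curve a step function); (2) the land-use casualty draw,
`loss_fraction` of the response curve applied to the relative loss of
natural land, with stochastic rounding of the fractional casualty count
(avoids systematic bias in small communities); (3) the adaptation lottery —
with probability p_adp each population shifts its niche toward the previous
year's local means by `C_adp · A · d_N`, where d_N is the Euclidean distance
in **standardized** T×P space (each axis divided by its grid-wide
calibration-window standard deviation; raw Euclidean distance would be
dominated by the mm scale), translating optimum and both edges rigidly and
re-deriving the tail parameters; (4) one cascade pass over all of the
year's primary losses (coextinction arm) — the control arm applies the same
primary removals with no network; (5) a dispersal round; (6) metrics.

Adaptation state is **per population** (cell × species): the lottery is
drawn per occurrence and a shifted niche applies only in that cell;
colonizers carry their source population's niche. Dispersal is yearly by
default (configurable to monthly, or off).

### 1.6 Experiment layout and randomness

One replicate = one independently regenerated species pool and trait matrix,
one seeding + burn-in (dispersal-only, calibration-window climate filter,
webs rebuilt every 10 steps with the basal cap enforced; thresholds
recomputed once at the end and frozen), and both arms run from the same
snapshot. All randomness flows from the master seed through named streams
keyed by (process, cell, time step); mortality and adaptation draws are
additionally indexed by pool species id. Both arms consume identical
streams, so per-replicate arm contrasts are paired: as long as the two arms'
communities coincide, the same species die of the same primary causes, and
any divergence is a consequence of network structure. The indexing by pool
id costs one pool-length uniform vector per (cell, month); it is the price
of pairing and is cheap at fixture scale.

The *coextinction effect* is `100·(loss_coext − loss_control)/loss_control`,
undefined (NaN, excluded from averages) when the control loss is zero. The
parameter-randomization harness draws burn-in steps ∈ [0, 1000], c_f ∈
[0.45, 0.65], p_adp ∈ [0, 0.005], C_adp ∈ [0, 0.05], S_LUC ∈ [−1, 1] and
V_LUC ∈ [0, 1] uniformly, one experiment per draw.

## 2. Parameters

| name | default | units | role |
|---|---|---|---|
| p_thresh | 0.95 | – | survival at the tolerance edges |
| p_ext_cutoff | 0.05 | – | immunity / persistence / colonization filter |
| c_f_thresh | 0.55 | – | phenotype-compatibility link threshold |
| species_per_cell | 4500 | – | seeded candidates per fully natural cell (× u) |
| pool_counts | 5513/10425/10038/7302 | – | mammals/birds/reptiles/amphibians in the pool |
| burn_in_steps | 100 | steps | dispersal-only burn-in length |
| rebuild_every | 10 | steps | web-rebuild cadence during burn-in |
| calibration_months | 60 | months | niche-calibration window |
| p_adp | 0.001 | 1/year | per-population acclimation probability |
| C_adp | 0.01 | – | acclimation step factor |
| S_LUC | 0 | – | land-use response-curve shape (0 = linear) |
| V_LUC | 0 | – | body-size-bias relaxation of land-use casualties |
| norm_pairs | 10⁶ | – | phenotype pairs for compatibility normalization |
| ratio_min_records | 20 | – | minimum records per taxon pair before pooled fallback |

`loss_fraction(P_LUC = 0, ·) = 0` for every shape, including the S_LUC = 1
limit where the raw power expression would give P⁰ = 1: no conversion event
means no land-use mortality, which is also what keeps a stationary world at
exact equilibrium.

## 3. The synthetic-data generator

`fixtures` produces every input from scratch: seasonal sinusoidal climate
with a latitudinal gradient, optional Gaussian noise and a linear secular
trend (°C or mm per decade); land fractions with geometric yearly decay;
log-normal body masses per taxon; trophic levels increasing with body-mass
percentile (plus noise), reproducing the qualitative mass–trophic-level
association of diet data; interaction records with taxon-pair-specific
log-normal mass-ratio distributions. Two deliberate structural features:

* **Range margin.** A species' niche samples come from its home cell's 3×3
  neighbourhood, widened by 5% of the regional spread at each end — a real
  range spans far more cells than the neighbourhood, and without the margin
  a noise-free periodic climate pins every species at exactly the 0.05 edge
  probability in its most extreme month, emptying the world at seeding.
* **Size-dependent invertebrate access.** The probability that a species
  retains plant/invertebrate feeding (breadth floor 0, basal) is one minus
  its within-taxon mass percentile. Small vertebrates that cannot take
  vertebrate prey are insectivores in real diet data; drawing floors
  independently of mass creates small obligate carnivores with no feasible
  prey-mass window — starving mesopredators that invert the size structure
  of cascade vulnerability.

The noise-free, trend-free variant is exactly periodic with period 12, so a
community that passed the calibration filter can never meet a month it has
not already survived — the basis of the equilibrium tests.

What the generator does **not** emulate: spatial autocorrelation of climate
beyond the latitudinal gradient, realistic geographic range shapes,
phylogenetic structure, covariance between niche width and body mass, and
the planetary scale of the real forcing data. Passing tests therefore show
that the *mechanisms* behave as specified under controlled conditions, not
that the simulator reproduces real-world magnitudes.

## 4. Problem sizes in the test suite

The emergent-property checks run a 5×5 world, a 300-species pool (75 per
taxon), 120 seeded candidates per cell, the default 100-step burn-in, and an
80-year forcing horizon at 0.5 °C/decade (≈ 4 °C by the final year, an
upper-middle warming trajectory); 20 paired replicates. These sizes give
communities of 50–120 species per cell and webs of a few hundred links —
large enough for cascades, colonization pressure and size-structured
vulnerability to express themselves, small enough to run the whole suite on
one CPU in minutes. Equilibrium is checked on the stationary variant over 30
years with dispersal and acclimation off, matching the model's own
equilibrium guarantee ("no extinctions if conditions do not change and no
species immigrate"): under the model's rules a colonizer can legitimately
displace residents even in a stationary world, and a rare acclimation draw
can translate a borderline niche across the immunity line, so those two
processes are outside the guarantee.

Body-size trends are asserted on mean **log** mass (geometric mean):
fixture masses are log-normal over ~6 orders of magnitude, so the
arithmetic community mean is effectively a statistic of whichever giant
survives. `web_metrics` reports both.

## 5. Numerical choices

* Cascade comparisons carry a 10⁻⁹ tie guard: the node whose
  availability/pressure *defines* a frozen threshold sits exactly on it, and
  re-summation in a different association order must not flip that equality
  into a violation.
* Diameter is computed on the undirected projection of the web, as the
  maximum finite shortest-path length (i.e., within components), alongside
  the largest weakly connected component; empty webs report zeros.
* Basal-cap and control-cap removals rank by current combined extinction
  probability, ties broken by removing the most recent arrival — stable,
  deterministic, favors incumbents.
* Degenerate ratio windows (all records identical) are widened by machine
  epsilon and flagged; a degenerate trait matrix (zero score range) is
  rejected.
* Stochastic rounding converts fractional land-use losses into counts
  without systematic bias.

## 6. Known limitations

* No explicit abundances: interaction weights proxy for population-level
  resource access, as in the underlying model.
* Empty cells (u = 0 at seeding) have zero caps and can never be colonized;
  range expansion into previously uninhabited cells is outside the model.
* Between monthly mortality sweeps the coextinction arm's web retains
  already-dead species until the yearly cascade pass; with the default
  yearly dispersal this is invisible, with monthly dispersal a colonizer may
  briefly interact with a dying web.
* The control arm's richness cap uses post-burn-in richness (the state both
  arms actually start from); the basal cap uses the seeding-time basal
  count, which burn-in itself enforces.
* Monotonicity of destruction is an empirical regularity (~95% of random
  webs), not a theorem, because of competition release.
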