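# tracerflux

Analysis of stable-isotope **13C tracer experiments** on benthic
suspension feeders (sponges, bivalves, ophiuroids): animals are fed a
13C-enriched substrate — diatom-derived dissolved organic matter (DOM),
bacteria, or diatoms — then sealed into closed, stirred chambers, and the
fate of the substrate carbon is partitioned into tissue growth,
respiration and particulate waste.  The package is for experimental
ecologists and biogeochemists who need the full chain from raw chamber
tables to per-animal carbon budgets, with every step verifiable by
parameter recovery on simulated experiments.

## The model

All isotope arithmetic runs in atom fractions.  With R = 0.0111802 the
13C/12C ratio of the VPDB standard,

    F = ((δ/1000 + 1)·R) / (1 + (δ/1000 + 1)·R)

the excess 13C in a pool of C µmol is E = (F_sample − F_background)·C,
and tracer (substrate-derived) carbon is E / F_substrate.  Per chamber
(volume V, duration T):

* total POC/DOC release = (C_end − C_start)·V/T   (negative = net uptake)
* respiration = −(OLS slope of the O2 series)·V·RQ, RQ = 1 by default
* tracer fluxes = Δ(excess-13C inventory of DIC or POC)/T/F_substrate

Rates are corrected by parallel no-organism controls and standardized to
tissue organic carbon, giving µmol C (mol OC)⁻¹ h⁻¹.  Per animal, the
budget closes as turnover = respiration + POC + DOC, and the utilized
tracer-C is partitioned over incorporation, respiration and POC release.
Derived quantities include tissue-POC turnover (% d⁻¹), areal fluxes,
and the food-chain transfer efficiency (consumer-incorporated 13C over
producer (pseudo-)fecal 13C).  Group comparisons use the nonparametric
battery (exact Wilcoxon rank-sum, Kruskal-Wallis, Dunn post-hoc with
Holm adjustment).  See `docs/methods.md` for assumptions and defaults.

## Worked example

Simulate a full experiment (3 taxa × 2 substrates, 4 animals and 2
controls per condition, realistic measurement noise) and fit the budget
model:

```python
from tracerflux import TracerBudgetModel
from tracerflux.simulate import SimulationConfig, simulate_experiment, simulate_food_chain

config = SimulationConfig(seed=42)
sim = simulate_experiment(config)
foodchain, _ = simulate_food_chain(config)
results = TracerBudgetModel.from_simulation(sim, foodchain=foodchain).fit()
print(results.summary())
print(f"Transfer efficiency: {results.transfer_efficiency():.1f}%")
```

prints

```
Tracer-flux carbon budget
============================================================
  tracerflux 0.1.0
  config_hash=21323eea6889
  r_vpdb=0.0111802 respiratory_quotient=1.0
  log_base=10 background_strategy=chamber_start dunn_adjust=holm
  animals: 24   groups: 6

Group means [umol C (mol OC)-1 h-1]:
                     respiration_total  poc_total  doc_total  total_turnover  incorporation_tracer  respiration_tracer  poc_tracer
group
bivalve_bacteria                199.89      46.03      98.16          344.07                 24.90                2.50         0.5
bivalve_dom                     202.60      45.16      97.63          345.39                 24.84                2.74         0.5
hma_sponge_bacteria             150.26      12.46    -100.53           62.19                 64.57                8.05         0.2
hma_sponge_dom                  150.85      12.62     -95.85           67.61                 62.10                8.16         0.2
lma_sponge_bacteria             243.57     800.21     153.42         1197.20                 39.73               19.96         5.0
lma_sponge_dom                  247.34     798.94     147.70         1193.97                 39.42               19.96         5.0

Mean tracer-C partition (incorporation/respiration/POC):
                     frac_incorporation  frac_respiration  frac_poc
group
bivalve_bacteria                  0.892             0.090     0.018
bivalve_dom                       0.885             0.098     0.018
hma_sponge_bacteria               0.887             0.110     0.003
hma_sponge_dom                    0.881             0.116     0.003
lma_sponge_bacteria               0.614             0.309     0.077
lma_sponge_dom                    0.612             0.310     0.078

Transfer efficiency: 38.6%
```

Reading the output: each row is a feeding condition.  The total-C columns
say, e.g., that the simulated HMA sponge respires ~150 µmol C per mol of
tissue carbon per hour and *takes up* DOC (negative release), while the
fragile LMA sponge is a prolific detritus producer.  The partition table
shows that for bivalve and HMA sponge most (~88–89%) of the utilized
substrate carbon goes into tissue growth, ~9–12% is respired and little
leaves as particulate waste.  The transfer efficiency is the share of the
bivalves' (pseudo-)fecal 13C that the ophiuroid consumers built into
their tissue over the four feeding cycles (the generating truth here is
37%; 38.6% reflects one noisy realization).

The same pipeline runs from the shell on CSV tables:

```sh
tracerflux simulate --seed 42 --out data/
tracerflux report --specimens data/specimens.csv --batches data/batches.csv \
    --incubations data/incubations.csv --o2-series data/o2_series.csv \
    --foodchain data/foodchain.csv --out results/
```

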