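# rangeshift

Tools for analysing how landscape composition and configuration control the
speed of climate-driven range expansion, built around three ingredients:

1. **Expansion-zone geometry** — which monitored trap locations are genuine
   colonisation targets for a species (≥ 20 km outside its baseline range),
   and which 10-km cells the species plausibly crossed to get there (the
   cells `c` with `d(c, nearest record) + d(c, trap) < 100 km + D_min`).
2. **Landscape covariates** — proportional landcover, protected-area cover,
   growing degree-days above 5 °C and elevation summaries over each zone and
   around each trap, plus the *effective conductance* of the woodland
   habitat network: habitat cells become nodes joined by per-generation
   colonisation rates `k_ij = C·A_i·A_j·exp(−d_ij/α)` (α = δ/2 for mean
   dispersal δ), and the two-terminal conductance from the baseline range to
   the trap — solved from the network Laplacian — summarises how fast a
   species can spread across that landscape over multiple generations.
3. **Survival modelling** — time until first arrival, right-censored when a
   trap ceases operating, fitted with a constant-hazard (exponential) model
   `E[T_st] = exp(x_st'β + b_s)` with a per-species frailty `b_s`; negative
   coefficients mean faster colonisation.  Forward stepwise AIC selection
   with an interaction whitelist, correlated-pair exclusions, Akaike-weight
   model averaging and top-vs-bottom-quintile effect sizes complete the
   inference chain.

A synthetic-data generator (landscapes with controllable habitat amount and
clumpiness, species baselines, trap networks, exponential arrival times and
a mechanistic spread simulator) provides ground truth for every stage, so
the whole pipeline is testable without licensed survey data.

Audience: spatial ecologists and biostatisticians studying range shifts,
connectivity metrics, or time-to-colonisation designs.

## Worked example

```python
import rangeshift as rs
from rangeshift.survival import fit_exponential_frailty

bundle = rs.generate_landscape(rs.LandscapeConfig(extent_km=60), seed=7)
specs, occs = rs.generate_species_and_baseline(
    rs.SpeciesConfig(n_species=15, occupancy_p=0.2, range_limit_frac=(0.15, 0.35)),
    bundle, seed=8)
traps = rs.generate_traps(bundle, 20, seed=9, y_min_frac=0.6)

table = rs.assemble_covariate_table(
    bundle, specs, occs, traps, variant=rs.ConductanceVariant(5.0, False))

truth = rs.SyntheticTruth(
    beta={"Intercept": 1.0, "distance": 1.0, "log_conductance": -0.4},
    frailty_sd=0.5, frailties={s.species_id: s.frailty for s in specs})
table = rs.simulate_arrivals(truth, table, traps, seed=10)

fit = fit_exponential_frailty(table, ["distance", "log_conductance"])
print(len(table), int(table.event.sum()))
print(fit.summary().round(3))
```

prints

```
286 229
                 value  std_error      z      p
Intercept        1.091      0.348  3.131  0.002
distance         0.693      0.851  0.814  0.415
log_conductance -0.412      0.128 -3.228  0.001
```

286 species-trap pairs were analysable, of which 229 were colonised within
the 27-year windows (the rest right-censored).  The refit recovers the
generating log-conductance effect (−0.412 ± 0.128 against a truth of −0.4):
traps behind better-connected woodland are reached significantly faster.
The distance coefficient (truth 1.0) is estimated without bias but noisily
(0.69 ± 0.85) because, at this scale, distance varies mostly *between*
species and competes with the frailty term — the full-size run in
`scripts/acceptance.py` pins it down better.

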