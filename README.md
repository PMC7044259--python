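# oleoflux

Constraint-based flux analysis and bioprocess calculations for lipid
production in oleaginous yeast.

Oleaginous yeasts such as *Rhodotorula toruloides* accumulate large amounts
of storage lipid when nitrogen limits growth, which makes the molar
carbon-to-nitrogen (C/N) ratio of the medium the main process lever for
single-cell-oil production from cheap substrates — glycerol, xylose, and
acetate.  `oleoflux` implements the computational side of such a study as a
tested pipeline:

- **`gem_core`** — a stoichiometric-model container with elemental
  bookkeeping, read/written as SBML Level 3 (fbc) or a flat JSON dialect;
- **`fba_engine`** — flux balance analysis, flux variability analysis, and
  random-objective vertex sampling of the flux solution space;
- **`synthetic_models`** — a hand-built, carbon-balanced toy genome-scale
  model of oleaginous central metabolism, plus a generator of noisy
  turbidostat-style measurement tables drawn from the toy model's own flux
  solutions, so the whole pipeline runs with no external downloads;
- **`condition_pipeline`** — turns one steady-state measurement set into a
  constrained model (biomass refit to measured protein/lipid, measured rates
  fixed, O2/CO2 fitted, ATP maintenance maximized, ±2.5% relaxation,
  sampling) and summarizes NADPH sources, pathway carbon fractions,
  respiratory quotients, byproducts, and theoretical lipid yield ceilings;
- **`physiology`** — turbidostat/fed-batch rate and yield arithmetic
  (μ, Y_sx, Y_ls, q_BM, r_LIP, RQ, medium C/N, carbon recovery);
- **`fedbatch`** — the exponential feeding design and a mass-balance
  bioreactor simulator;
- **`cli`** — an `oleoflux` command with `synth`, `validate-model`, `fba`,
  `condition-run`, `theoretical-yield`, `physiology`, and `fedbatch-plan`
  subcommands.

## The core computations

Flux balance analysis solves, for a stoichiometric matrix **S** (metabolites
× reactions), flux vector **v** (mmol gDW⁻¹ h⁻¹) and objective **c**:

    max cᵀv   s.t.   S·v = 0,   lb ≤ v ≤ ub

Condition-specific models fix the measured substrate uptake, byproduct
excretion and growth rate, fit O2/CO2 to the measured transfer rates by L1
minimization, maximize the ATP-hydrolysis flux (non-growth-associated
maintenance), relax each constrained exchange to 97.5–102.5 % of its value,
and characterize the remaining solution space by random sampling
(*n* = 5000 optimal vertices of standard-normal random objectives).

The theoretical lipid-yield ceiling fixes growth to zero, opens a lipid
export, and maximizes exported lipid carbon over consumed substrate carbon.

The exponential fed-batch feed profile is

    F(t) = Y_XS · μ₀ · x₀ · V₀ · e^(μ₀ t) / (c_f − c_s)

with Y_XS the substrate consumed per biomass formed (g/gDW), μ₀ the design
growth rate (1/h), x₀·V₀ the biomass at feed start, and c_f, c_s the feed
and vessel substrate concentrations (g/L).  Its defining property — vessel
substrate stays constant while total biomass grows exponentially — is an
invariant of the simulator's ideal mode.

## Worked example

```python
from oleoflux.synthetic_models import (
    build_toy_gem, make_condition_dataset, SyntheticConditionSpec,
    toy_baseline_composition, toy_registry,
)
from oleoflux.condition_pipeline import (
    rescale_biomass, constrain_condition, estimate_ngam,
    sample_condition, attribute_fluxes, theoretical_max_lipid_yield,
)

model = build_toy_gem()
for met in ("glyc", "xyl", "ac"):
    print(met, round(theoretical_max_lipid_yield(model, met), 4))

sc = make_condition_dataset(
    model, SyntheticConditionSpec("glycerol", cn_ratio=100, mu=0.13,
                                  noise_cv=0.0, seed=1))
work = rescale_biomass(sc.model, sc.dataset.protein_content,
                       sc.dataset.lipid_content, toy_baseline_composition())
cm = constrain_condition(work, sc.dataset)
print("NGAM", round(estimate_ngam(cm), 2), "mmol ATP/gDW/h")
sample = sample_condition(cm, n=1000, seed=1)
att = attribute_fluxes(cm, sample, toy_registry())
print("RQ", round(att.predicted_rq, 3),
      "GLYCDH NADPH share", round(att.nadph_sources["GLYCDH"], 3))
```

prints

```
glyc 0.6667
xyl 0.575
ac 0.3913
NGAM 77.21 mmol ATP/gDW/h
RQ 0.884 GLYCDH NADPH share 0.862
```

i.e. on the toy network at most 66.7 % of glycerol carbon (57.5 % of xylose,
39.1 % of acetate) can end up in exported lipid; the glycerol condition at
C/N 100 supports ~77 mmol ATP gDW⁻¹ h⁻¹ of maintenance spill, respires at
RQ ≈ 0.88, and draws most NADPH from the NADP-dependent glycerol
dehydrogenase — the signature expected for glycerol-grown oleaginous yeast.

The same pipeline from the shell:

```sh
oleoflux synth --out runs/synth --seed 7
oleoflux theoretical-yield --model runs/synth/toy_model.json --source glycerol
oleoflux condition-run --model runs/synth/toy_model.json \
    --data runs/synth/conditions.tsv --registry runs/synth/registry.yaml \
    --n 5000 --seed 7 --out runs/cond
oleoflux fedbatch-plan --y-xs 3 --mu0 0.05 --cf 220 --x0 10.9 --v0 0.5 \
    --duration 48 --out runs/fb
```

## JSON model dialect

A model file is a single JSON object with flat lists mirroring the in-memory
types:

```json
{
 "id": "toy_oleaginous_gem",
 "metabolites": [
  {"id": "glyc", "name": "glycerol", "compartment": "c",
   "formula": "C3H8O3", "charge": 0}
 ],
 "reactions": [
  {"id": "GLYCDH", "name": "...", "stoichiometry": {"glyc": -1, "g3p": 1},
   "lower_bound": 0.0, "upper_bound": 1000.0, "subsystem": "..."}
 ],
 "biomass_reaction_id": "BIOMASS",
 "objective": {"BIOMASS": 1.0},
 "biomass_components": {"protein": "prot", "lipid": "lipid",
                        "carbohydrate": "carb", "nucleotide": "nuc"}
}
```

Formulas are Hill-notation strings (`null` when unknown, `""` for
carbon-free currency pseudo-species); negative stoichiometric coefficients
mean consumption; bounds are mmol gDW⁻¹ h⁻¹.

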