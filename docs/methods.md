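# Methods

This note records the models, parameter choices, and numerical conventions
behind `oleoflux`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Constraint-based model and conventions

A metabolic network is a stoichiometric matrix **S** (metabolites ×
reactions) with flux bounds; flux balance analysis (FBA) optimizes a linear
objective over `{v : S·v = 0, lb ≤ v ≤ ub}`.  Units are fixed throughout:
fluxes in mmol gDW⁻¹ h⁻¹, growth in 1/h, mass fractions in g/gDW.  Uptake is
stored positive in measurement tables and mapped to negative exchange fluxes
internally.  An exchange reaction is any reaction touching exactly one
metabolite.  Unbounded exchanges default to ±1000 mmol gDW⁻¹ h⁻¹.

LPs are solved with HiGHS (scipy.optimize.linprog) at a solver feasibility
tolerance of 1e-9; the package-level contract on returned solutions is
‖S·v‖∞ ≤ 1e-6 and bound violations ≤ 1e-6.  Ties among alternate optima are
deliberately *not* broken: degenerate optima are characterized through flux
variability analysis (FVA) and through random sampling.

### Solution-space sampling

Each sample is the optimal vertex of a random linear objective whose weights
are independent standard normals over all reactions (sign-symmetric, so
neither flux direction is favored).  Sample *i* draws its weight vector from
a generator seeded with `(seed, i)` and assigns weights to reactions in
lexicographic id order, which makes the sampler deterministic under a given
seed and equivariant under reaction reordering.  Vertex sampling was chosen
over hit-and-run because it needs no burn-in or thinning decisions and is
exactly reproducible; its samples concentrate on the boundary of the flux
polytope, so per-reaction means describe the spread of extreme behaviors,
not a uniform interior average.  The default sample size is n = 5000.

## The toy genome-scale model

The bundled toy model is a ~30-internal-reaction caricature of oleaginous
yeast central metabolism with single-compartment metabolites and lumped
reactions: glycerol assimilation through an NADP-dependent glycerol
dehydrogenase, xylose assimilation (reductase/dehydrogenase/kinase lumped,
with a xylitol overflow branch), acetate activation by acetyl-CoA synthase
(2 ATP), oxidative and non-oxidative pentose phosphate pathway,
phosphoketolase with phosphotransacetylase and acetate kinase, lower
glycolysis, pyruvate dehydrogenase and carboxylase, a PEP-carboxykinase
gluconeogenic lump, TCA cycle with NADP-dependent isocitrate dehydrogenase,
glyoxylate shunt, malic enzyme, ATP-citrate lyase, oxidative
phosphorylation, and an external NADPH dehydrogenase that re-oxidizes
surplus NADPH through the respiratory chain at a lower ATP yield than NADH
(P/O − 0.5).  Without that valve, any fixed substrate uptake above the
biosynthetic NADPH demand would be infeasible on glycerol, because the
obligatory assimilation route co-produces NADPH.

Redox and energy carriers (ATP/ADP, NAD(H), NADP(H)) are carbon-free
pseudo-species with *empty* formulas, distinct from *unknown* formulas; all
internal reactions are therefore exactly carbon- and nitrogen-balanced
(verified by the balance checker), while H/O/P are not tracked through the
lumps.  Directionalities are set so that no ATP- or NADPH-generating futile
cycle exists (e.g. malate dehydrogenase runs only toward oxaloacetate;
acetate kinase runs only toward acetate).

Key stoichiometric choices, with rationale:

| quantity | value | why |
| --- | --- | --- |
| lipid pseudo-species | C16 (palmitate equivalent), 256.4 g/mol | one acyl unit keeps carbon counting transparent |
| lipid synthesis cost | 2 NADPH + 1 ATP per acetyl-CoA incorporated | canonical fatty-acid elongation cost (2 NADPH per C2 added) |
| P/O ratio | 1.5 (NADH), 1.0 (NADPH) | textbook effective eukaryotic values; site-1 bypass for NADPH |
| protein residue | alanyl, C3H5NO, from pyruvate + NH4 + 2 NADPH + 4 ATP | smallest N-bearing residue that keeps N balance meaningful |
| carbohydrate residue | glucan C6H10O5 from G6P + ATP | storage glucan |
| nucleotide residue | AMP-like C10H12N5O6P | fixed at 5 % of biomass |
| GAM (polymerization) | 4.3 / 2.1 / 2.4 mmol ATP per mmol residue (protein / carbohydrate / nucleotide) | literature-style polymerization costs; recomputed whenever the composition changes |

The biomass reaction drains `fraction / residue-mass` mmol of each
macromolecule per gDW so one unit of biomass flux consumes exactly 1 g of
macromolecules, plus the composition-dependent GAM as ATP hydrolysis.  The
baseline composition is 45 % protein, 10 % lipid, 40 % carbohydrate, 5 %
nucleotide.

### Closed-form yield ceilings

The toy network's maximal lipid yields were derived independently by hand
(rational route accounting over carbon, NADPH and ATP; see
`tests/_oracles.py` for the full derivations) and the LP must reproduce them
to 1e-6: glycerol 2/3, xylose 23/40, acetate 9/23 of consumed carbon.  The
ordering — glycerol > xylose > acetic acid — matches the ordering reported
for the genome-scale model of *R. toruloides*; the magnitudes are the toy
network's own and are not calibrated to the published 69/61/50 % values
(the published model is an optional external input, not bundled).

"Minimal growth" in the ceiling calculation is implemented as exactly zero
growth, with maintenance at the model default (zero for the toy model,
which also makes the yield independent of the reference uptake, asserted at
uptake 1 and 10).

## Synthetic turbidostat conditions

The generator emulates the study grid: C/N ∈ {60, 80, 100, 120} on each of
glycerol/acetate/xylose, with growth rates declining as C/N rises
(glycerol 0.24→0.06 1/h, acetate 0.11→0.03, xylose 0.08→0.03 — the observed
ranges).  Nitrogen limitation is encoded as a C/N-dependent biomass
composition, linear between 10 % lipid / 50 % protein at C/N 4.5 and
60 % lipid / 20 % protein at C/N 120 (the highest lipid content observed).
Byproduct patterns follow the qualitative findings: a third of xylose
carbon to xylitol at C/N ≥ 100 (10 % below), 5 % of glycerol carbon to
pyruvate, 17 % of acetate carbon to glyoxylate at C/N 120.  Reference
uptakes are 10 (glycerol), 6 (xylose) and 15 (acetate) mmol gDW⁻¹ h⁻¹,
chosen to give comparable C-mol supply and feasible growth across the grid.

Ground-truth fluxes maximize ATP hydrolysis under those constraints — an
N-limited culture that spills surplus energy — and the "measured" table is
the truth under independent multiplicative Gaussian noise (default
CV = 2 %, a typical off-gas/HPLC precision), truncated at zero.  The noise
model is deliberately simple: no correlated drift, no instrument bias, no
replicate structure.  Passing the recovery tests therefore shows the
pipeline is self-consistent and unbiased under well-behaved noise, not that
it is robust to systematic measurement error in real bioreactor data.

## Condition pipeline

1. **Biomass refit** — protein and lipid set to measured values, nucleotide
   and "other" kept at baseline, storage carbohydrate absorbing the
   remainder (an error is raised if the remainder is negative); GAM
   recomputed from the new composition.
2. **Rate constraints** — substrate uptake and byproduct excretions fixed;
   growth fixed to the measured rate or, when infeasible, to the maximal
   achievable rate (recorded in the fit report).  If the model is
   infeasible even with free growth, the diagnostic releases each
   constraint in turn and names the binding ones.
3. **Gas fit** — "as close as possible" to OTR/CTR is implemented as a
   single L1 LP (auxiliary deviation variables for O2 and CO2), after which
   both exchanges are fixed at the achieved values.  Two-stage fixing is
   deterministic and solver-friendly.
4. **Relaxation** — every constrained value (substrate, byproducts, growth,
   O2, CO2) is widened to its 97.5–102.5 % window before sampling; zero
   stays zero.  The window is applied to all constrained exchanges alike.
5. **NGAM** — ATP hydrolysis maximized under the relaxed constraints; during
   sampling the maintenance flux is held at ≥ 97.5 % of that maximum rather
   than exactly fixed, consistent with the global relaxation and avoiding an
   empty interior.
6. **Attribution** — per sample and then averaged: NADPH producer shares
   (production-weighted, must sum to 1 over the registry), pathway carbon
   fractions (carbon entering the signature reaction over substrate carbon
   taken up), RQ (CO2 efflux / O2 influx), and positive non-gas excretions
   as C-mol fractions of uptake.  Byproducts are reported as C-mol fractions
   so different metabolites are comparable.

## Physiology arithmetic

Steady-state identities: r_LIP = lipid_content × μ; Y_sx = μ / (uptake ×
molar mass); Y_ls = lipid_content × Y_sx; q_BM = μ × biomass concentration;
RQ = CTR/OTR.  Carbon recovery is (μ × biomass C + CTR + Σ byproduct C) /
substrate C, with biomass carbon defaulting to 40 mmol C/gDW (a typical
yeast value, configurable; for synthetic datasets the exact value implied by
the generating composition is available from the model).  Medium C/N is the
elemental mol C / mol N over all components.  The 10 g/L carbon source +
5 g/L ammonium sulfate starting medium computes to C/N ≈ 4.3 by direct
elemental arithmetic; the commonly quoted 4.5 for this recipe is not
reproducible from the stated concentrations, and the package reports the
computed value.

## Fed-batch design and simulation

The exponential feed `F(t) = Y_XS μ₀ x₀ V₀ e^(μ₀ t) / (c_f − c_s)` treats
the vessel concentration c_s as a design-time constant (open-loop feeding;
the profile is not adapted to measured accumulation).  Y_XS is substrate
consumed per biomass formed (g/gDW), so the consumption term in the mass
balance is Y_XS·μ·x·V — with these units the ideal-mode invariants (constant
c_s, exponential total biomass) hold exactly.  The simulator integrates
dV/dt = F, d(xV)/dt = μ_eff·xV, d(c_sV)/dt = F·c_f − Y_XS·μ_eff·xV with a
fixed-step classical Runge-Kutta scheme, default dt = 0.01 h (smooth
exponential dynamics; first-order convergence is verified, fourth-order
achieved).  In phased mode μ_eff follows a user schedule, reproducing
substrate accumulation when the culture underperforms the design; when the
vessel substrate is exhausted, growth is capped at the feed-supported rate
and the trajectory flagged substrate-limited.  Sampling withdrawals and
gas-phase dynamics are not modeled.

## Problem sizes and determinism

Default analysis sizes: n = 5000 solution-space samples per condition,
dt = 0.01 h over 48 h of fed-batch, 12-condition synthetic grid, 20-replicate
noise recovery.  The test suite uses smaller sample counts (20–400) per
condition, which is sufficient because the assertions are containment,
determinism and mean-recovery properties rather than tail quantiles.  All
randomness (noise, sampling objectives) is driven by explicit integer seeds;
identical seeds give bitwise-identical tables and sample matrices.

## Known limitations

- The toy model is a caricature: absolute yields, NGAM values and RQs are
  its own and should not be read as predictions for *R. toruloides*; only
  structural and qualitative behaviors (substrate ordering, NADPH source
  switching, phosphoketolase/citrate-lyase usage patterns, glyoxylate
  overflow) are expected to transfer.
- Vertex sampling characterizes the boundary of the solution space; means
  are not uniform-interior averages and carry no statistical weighting
  between alternate optima.
- No thermodynamic, loopless or enzyme-capacity constraints; gene-protein-
  reaction logic is out of scope.
- The measurement-noise model is independent multiplicative Gaussian;
  correlated or systematic errors are not emulated.
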