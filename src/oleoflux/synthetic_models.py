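"""Synthetic toy genome-scale model and turbidostat-style measurement tables.

The toy network is a hand-built, carbon-balanced caricature of oleaginous
yeast central metabolism: glycerol, xylose and acetate assimilation, the
oxidative pentose phosphate pathway, phosphoketolase, a TCA cycle with the
glyoxylate shunt, ATP-citrate lyase, malic enzyme, oxidative phosphorylation,
a lumped lipid synthesis (2 NADPH and 1 ATP per acetyl-CoA incorporated, the
canonical fatty-acid elongation cost), and a macromolecular biomass equation
over protein/lipid/carbohydrate/nucleotide pseudo-species.  Redox and energy
carriers (NAD(P)(H), ATP/ADP) are carbon-free pseudo-metabolites with empty
formulas, so every internal reaction balances carbon exactly.

Condition tables are generated from the toy model's own FBA solutions:
ground-truth fluxes come from maximizing ATP hydrolysis (energy spilling
under nitrogen limitation) at a fixed uptake, growth rate and byproduct
pattern; the "measured" values are those fluxes under multiplicative
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .condition_pipeline import (
    ConditionDataset,
    PathwayRegistry,
    apply_biomass_composition,
    find_exchange,
)
from .fba_engine import FluxDistribution, InfeasibleModelError, fba
from .gem_core import (
    BiomassComposition,
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from ._formula import parse_formula

__all__ = [
    "ToyGemSpec",
    "SyntheticConditionSpec",
    "SyntheticCondition",
    "build_toy_gem",
    "make_condition_dataset",
    "toy_baseline_composition",
    "toy_registry",
    "study_condition_specs",
]

CARBON_SOURCES = ("glycerol", "xylose", "acetate")

#: metabolite id of each named carbon source in the toy model
SOURCE_METABOLITES = {"glycerol": "glyc", "xylose": "xyl", "acetate": "ac"}


@dataclass
class ToyGemSpec:
    """Tunable structure of the toy model.

    po_ratio: ATP produced per NADH oxidized (dimensionless, default 1.5, a
    textbook eukaryotic effective P/O value).  gam: ATP polymerization cost
    per gDW (mmol/gDW); None computes it from the biomass composition and the
    per-macromolecule cost table.  The include_* switches drop the
    corresponding pathway from the network.
    """

    po_ratio: float = 1.5
    gam: float | None = None
    include_phosphoketolase: bool = True
    include_acl: bool = True
    include_malic_enzyme: bool = True
    include_glyoxylate_shunt: bool = True

    def __post_init__(self) -> None:
        if self.po_ratio <= 0:
            raise ValueError(f"po_ratio must be positive, got {self.po_ratio}")
        if self.gam is not None and self.gam < 0:
            raise ValueError(f"gam must be non-negative, got {self.gam}")


@dataclass
class SyntheticConditionSpec:
    """One emulated turbidostat steady state.

    cn_ratio spans the emulated experimental grid (60-120 mol/mol); mu is the
    steady-state
    growth rate in 1/h; noise_cv is the coefficient of variation of the
    multiplicative measurement noise.
    """

    carbon_source: str
    cn_ratio: float
    mu: float
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carbon_source not in CARBON_SOURCES:
            raise ValueError(
                f"carbon_source must be one of {CARBON_SOURCES}, got {self.carbon_source!r}"
            )
        if self.cn_ratio <= 0:
            raise ValueError(f"cn_ratio must be positive, got {self.cn_ratio}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be non-negative, got {self.noise_cv}")


@dataclass
class SyntheticCondition:
    """A generated dataset together with its generating ground truth."""

    dataset: ConditionDataset
    truth: ConditionDataset
    truth_fluxes: FluxDistribution
    model: StoichiometricModel  # biomass-rescaled model that generated the data
    composition: BiomassComposition


def toy_baseline_composition() -> BiomassComposition:
    """Reference (low lipid, N-replete) biomass composition of the toy model."""
    return BiomassComposition(
        protein=0.45, lipid=0.10, carbohydrate=0.40, nucleotide=0.05, other=0.0
    )


def toy_registry() -> PathwayRegistry:
    """Pathway registry matching the toy model's reaction ids."""
    return PathwayRegistry(
        nadph_producers=["GLYCDH", "OXPPP", "IDH", "ME"],
        phosphoketolase=["PK"],
        acl=["ACL"],
        malic_enzyme=["ME"],
    )


def _met(mid: str, name: str, formula: str | None) -> Metabolite:
    return Metabolite(
        id=mid, name=name, compartment="c",
        formula=None if formula is None else parse_formula(formula),
    )


def build_toy_gem(
    spec: ToyGemSpec | None = None,
    composition: BiomassComposition | None = None,
) -> StoichiometricModel:
    """Construct the toy genome-scale model.

    Exchanges exist for glycerol/xylose/acetate/O2/CO2/NH4/xylitol/pyruvate/
    glyoxylate/lipid; all substrate uptakes are closed by default (open one
    by lowering the exchange's lower bound).  Every internal reaction is
    carbon- and nitrogen-balanced by construction.
    """
    spec = spec or ToyGemSpec()
    composition = composition or toy_baseline_composition()
    po = spec.po_ratio

    metabolites = [
        # exchangeable species
        _met("glyc", "glycerol", "C3H8O3"),
        _met("xyl", "D-xylose", "C5H10O5"),
        _met("ac", "acetate", "C2H4O2"),
        _met("o2", "oxygen", "O2"),
        _met("co2", "carbon dioxide", "CO2"),
        _met("nh4", "ammonium", "H4N"),
        _met("xlt", "xylitol", "C5H12O5"),
        _met("pyr", "pyruvate", "C3H4O3"),
        _met("glx", "glyoxylate", "C2H2O3"),
        _met("lipid", "lipid (palmitate equivalent)", "C16H32O2"),
        # internal carbon intermediates
        _met("g3p", "glyceraldehyde 3-phosphate", "C3H7O6P"),
        _met("g6p", "glucose 6-phosphate", "C6H13O9P"),
        _met("x5p", "xylulose 5-phosphate", "C5H11O8P"),
        _met("acp", "acetyl phosphate", "C2H5O5P"),
        _met("accoa", "acetyl-CoA (acetyl unit)", "C2H3O"),
        _met("oaa", "oxaloacetate", "C4H4O5"),
        _met("cit", "citrate", "C6H8O7"),
        _met("akg", "2-oxoglutarate", "C5H6O5"),
        _met("succ", "succinate", "C4H6O4"),
        _met("mal", "malate", "C4H6O5"),
        # carbon-free currency pseudo-species (empty formulas)
        _met("atp", "ATP (energy unit)", ""),
        _met("adp", "ADP (energy unit)", ""),
        _met("nad", "NAD+", ""),
        _met("nadh", "NADH", ""),
        _met("nadp", "NADP+", ""),
        _met("nadph", "NADPH", ""),
        # biomass macromolecule pseudo-species
        _met("prot", "protein (alanyl residue)", "C3H5NO"),
        _met("carb", "storage carbohydrate (glucan residue)", "C6H10O5"),
        _met("nuc", "nucleotide (AMP residue)", "C10H12N5O6P"),
    ]

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, subsystem=""):
        return Reaction(rid, name, stoich, lb, ub, subsystem)

    reactions = [
        # --- exchanges (uptakes closed by default; o2/nh4/co2 open) ---
        rxn("EX_glyc", "glycerol exchange", {"glyc": -1.0}, 0.0, 1000.0, "exchange"),
        rxn("EX_xyl", "xylose exchange", {"xyl": -1.0}, 0.0, 1000.0, "exchange"),
        rxn("EX_ac", "acetate exchange", {"ac": -1.0}, 0.0, 1000.0, "exchange"),
        rxn("EX_o2", "oxygen exchange", {"o2": -1.0}, -1000.0, 1000.0, "exchange"),
        rxn("EX_co2", "CO2 exchange", {"co2": -1.0}, -1000.0, 1000.0, "exchange"),
        rxn("EX_nh4", "ammonium exchange", {"nh4": -1.0}, -1000.0, 0.0, "exchange"),
        rxn("EX_xlt", "xylitol exchange", {"xlt": -1.0}, 0.0, 1000.0, "exchange"),
        rxn("EX_pyr", "pyruvate exchange", {"pyr": -1.0}, 0.0, 1000.0, "exchange"),
        rxn("EX_glx", "glyoxylate exchange", {"glx": -1.0}, 0.0, 1000.0, "exchange"),
        # closed by default: the yeast does not secrete lipid; the
        # theoretical-yield calculation opens it explicitly
        rxn("EX_lipid", "lipid export", {"lipid": -1.0}, 0.0, 0.0, "exchange"),
        # --- substrate assimilation ---
        rxn("GLYCDH", "glycerol dehydrogenase (NADP) + kinase, lumped",
            {"glyc": -1, "nadp": -1, "atp": -1, "g3p": 1, "nadph": 1, "adp": 1},
            subsystem="glycerol assimilation"),
        rxn("XYLASSIM", "xylose reductase/xylitol dehydrogenase/xylulokinase, lumped",
            {"xyl": -1, "nadph": -1, "nad": -1, "atp": -1,
             "x5p": 1, "nadp": 1, "nadh": 1, "adp": 1},
            subsystem="xylose assimilation"),
        rxn("XYLRED", "xylose reductase (xylitol branch)",
            {"xyl": -1, "nadph": -1, "xlt": 1, "nadp": 1},
            subsystem="xylose assimilation"),
        rxn("ACS", "acetyl-CoA synthase",
            {"ac": -1, "atp": -2, "accoa": 1, "adp": 2},
            subsystem="acetate assimilation"),
        # --- pentose phosphate pathway & phosphoketolase ---
        rxn("GNG", "gluconeogenesis to hexose phosphate, lumped",
            {"g3p": -2, "g6p": 1}, subsystem="gluconeogenesis"),
        rxn("OXPPP", "oxidative pentose phosphate pathway, lumped",
            {"g6p": -1, "nadp": -2, "x5p": 1, "co2": 1, "nadph": 2},
            subsystem="pentose phosphate pathway"),
        rxn("NONOXPPP", "non-oxidative pentose phosphate pathway, lumped",
            {"x5p": -3, "g3p": 5}, subsystem="pentose phosphate pathway"),
        rxn("PK", "phosphoketolase",
            {"x5p": -1, "acp": 1, "g3p": 1}, subsystem="phosphoketolase"),
        rxn("PTA", "phosphotransacetylase",
            {"acp": -1, "accoa": 1}, subsystem="phosphoketolase"),
        rxn("ACK", "acetate kinase",
            {"acp": -1, "adp": -1, "ac": 1, "atp": 1}, subsystem="phosphoketolase"),
        # --- lower glycolysis / anaplerosis ---
        rxn("GLYCLOW", "lower glycolysis (G3P to pyruvate), lumped",
            {"g3p": -1, "adp": -2, "nad": -1, "pyr": 1, "atp": 2, "nadh": 1},
            subsystem="glycolysis"),
        rxn("PDH", "pyruvate dehydrogenase",
            {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
            subsystem="pyruvate metabolism"),
        rxn("PC", "pyruvate carboxylase",
            {"pyr": -1, "co2": -1, "atp": -1, "oaa": 1, "adp": 1},
            subsystem="anaplerosis"),
        rxn("PEPCK", "PEP carboxykinase + upper gluconeogenesis, lumped",
            {"oaa": -1, "atp": -2, "nadh": -1, "g3p": 1, "co2": 1, "adp": 2, "nad": 1},
            subsystem="gluconeogenesis"),
        # --- TCA cycle ---
        rxn("CS", "citrate synthase",
            {"accoa": -1, "oaa": -1, "cit": 1}, subsystem="TCA cycle"),
        rxn("IDH", "isocitrate dehydrogenase (NADP)",
            {"cit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1},
            subsystem="TCA cycle"),
        rxn("AKGOX", "2-oxoglutarate to oxaloacetate (AKGDH/SDH/MDH arm), lumped",
            {"akg": -1, "nad": -2, "adp": -1, "oaa": 1, "co2": 1, "nadh": 2, "atp": 1},
            subsystem="TCA cycle"),
        # --- glyoxylate shunt ---
        rxn("ICL", "isocitrate lyase",
            {"cit": -1, "succ": 1, "glx": 1}, subsystem="glyoxylate shunt"),
        rxn("MS", "malate synthase",
            {"glx": -1, "accoa": -1, "mal": 1}, subsystem="glyoxylate shunt"),
        rxn("SUCOX", "succinate to malate (SDH/fumarase), lumped",
            {"succ": -1, "nad": -1, "mal": 1, "nadh": 1}, subsystem="TCA cycle"),
        rxn("MDH", "malate dehydrogenase",
            {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, subsystem="TCA cycle"),
        # --- NADPH / acetyl-CoA special routes ---
        rxn("ME", "malic enzyme (NADP)",
            {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1},
            subsystem="malic enzyme"),
        rxn("ACL", "ATP-citrate lyase",
            {"cit": -1, "atp": -1, "accoa": 1, "oaa": 1, "adp": 1},
            subsystem="citrate metabolism"),
        # --- energy metabolism ---
        rxn("OXPHOS", "oxidative phosphorylation",
            {"nadh": -1, "o2": -0.5, "adp": -po, "nad": 1, "atp": po},
            subsystem="oxidative phosphorylation"),
        # external NADPH dehydrogenase: lets the cell re-oxidize surplus
        # NADPH through the respiratory chain, at a lower ATP yield than
        # NADH (no site-1 proton pumping)
        rxn("NADPHOX", "external NADPH dehydrogenase + respiration",
            {"nadph": -1, "o2": -0.5, "adp": -max(po - 0.5, 0.0),
             "nadp": 1, "atp": max(po - 0.5, 0.0)},
            subsystem="oxidative phosphorylation"),
        rxn("NGAM", "non-growth-associated ATP hydrolysis",
            {"atp": -1, "adp": 1}, 0.0, 1000.0, subsystem="maintenance"),
        # --- macromolecule synthesis ---
        rxn("LIPSYN", "lipid synthesis (2 NADPH + 1 ATP per acetyl-CoA), lumped",
            {"accoa": -8, "nadph": -16, "atp": -8,
             "lipid": 1, "nadp": 16, "adp": 8},
            subsystem="lipid metabolism"),
        rxn("PROTSYN", "protein monomer synthesis (alanyl residue), lumped",
            {"pyr": -1, "nh4": -1, "nadph": -2, "atp": -4,
             "prot": 1, "nadp": 2, "adp": 4},
            subsystem="amino acid metabolism"),
        rxn("CARBSYN", "storage carbohydrate synthesis",
            {"g6p": -1, "atp": -1, "carb": 1, "adp": 1},
            subsystem="carbohydrate metabolism"),
        rxn("NUCSYN", "nucleotide synthesis, lumped",
            {"g3p": -2, "pyr": -1, "co2": -1, "nh4": -5, "atp": -6, "nadph": -2,
             "nuc": 1, "adp": 6, "nadp": 2},
            subsystem="nucleotide metabolism"),
        # biomass placeholder; coefficients set by apply_biomass_composition
        rxn("BIOMASS", "biomass equation",
            {"prot": -1.0, "lipid": -1.0, "carb": -1.0, "nuc": -1.0,
             "atp": -1.0, "adp": 1.0},
            0.0, 1000.0, subsystem="biomass"),
    ]

    if not spec.include_phosphoketolase:
        reactions = [r for r in reactions if r.id not in ("PK", "PTA", "ACK")]
    if not spec.include_acl:
        reactions = [r for r in reactions if r.id != "ACL"]
    if not spec.include_malic_enzyme:
        reactions = [r for r in reactions if r.id != "ME"]
    if not spec.include_glyoxylate_shunt:
        reactions = [r for r in reactions if r.id not in ("ICL", "MS")]

    model = StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        objective={"BIOMASS": 1.0},
        biomass_components={
            "protein": "prot",
            "lipid": "lipid",
            "carbohydrate": "carb",
            "nucleotide": "nuc",
        },
        id="toy_oleaginous_gem",
    )
    model = apply_biomass_composition(model, composition)
    if spec.gam is not None:
        biomass = model.reaction("BIOMASS")
        biomass.stoichiometry["atp"] = -spec.gam
        biomass.stoichiometry["adp"] = spec.gam
    return model


# ---------------------------------------------------------------------------
# condition generation
# ---------------------------------------------------------------------------

#: reference substrate uptake per carbon source (mmol/gDW/h); acetate is
#: dosed higher so the C-mol supply is comparable across sources
_REFERENCE_UPTAKE = {"glycerol": 10.0, "xylose": 6.0, "acetate": 15.0}

_CN_LOW, _CN_HIGH = 4.5, 120.0


def _composition_for_cn(cn_ratio: float) -> BiomassComposition:
    """Nitrogen limitation shifts biomass from protein toward storage lipid.

    Linear interpolation over the emulated C/N range: lipid rises from 0.10
    (N-replete) to 0.60 at C/N 120 (the highest content such cultures reach,
    on xylose), protein falls from 0.50 to 0.20, nucleotides stay fixed.
    """
    z = float(np.clip((cn_ratio - _CN_LOW) / (_CN_HIGH - _CN_LOW), 0.0, 1.0))
    lipid = 0.10 + 0.50 * z
    protein = 0.50 - 0.30 * z
    nucleotide = 0.05
    carbohydrate = 1.0 - lipid - protein - nucleotide
    return BiomassComposition(
        protein=protein, lipid=lipid, carbohydrate=carbohydrate,
        nucleotide=nucleotide, other=0.0,
    )


def _byproduct_pattern(carbon_source: str, cn_ratio: float) -> dict[str, float]:
    """C-mol fraction of uptake excreted as each byproduct, following the
    qualitative overflow patterns of N-limited cultures: xylitol on xylose
    (about a third at high C/N), pyruvate on glycerol, glyoxylate on acetate
    at C/N 120."""
    if carbon_source == "xylose":
        return {"xlt": 0.33 if cn_ratio >= 100 else 0.10}
    if carbon_source == "glycerol":
        return {"pyr": 0.05}
    if carbon_source == "acetate":
        return {"glx": 0.17} if cn_ratio >= 120 else {}
    return {}


def make_condition_dataset(
    model: StoichiometricModel,
    spec: SyntheticConditionSpec,
) -> SyntheticCondition:
    """Generate one noisy measurement table from the toy model's own fluxes.

    Ground truth: the biomass equation is refit to the C/N-dependent
    composition, substrate uptake is fixed at a reference rate, byproduct
    excretions at their C-mol pattern, growth at ``spec.mu``, and ATP
    hydrolysis is maximized (an N-limited culture spills surplus energy).
    Measured values are the ground truth under independent multiplicative
    Gaussian noise with CV ``noise_cv``, truncated at zero; identical seeds
    give identical datasets.
    """
    source_met = SOURCE_METABOLITES[spec.carbon_source]
    composition = _composition_for_cn(spec.cn_ratio)
    work = apply_biomass_composition(model, composition)

    uptake = _REFERENCE_UPTAKE[spec.carbon_source]
    substrate_ex = find_exchange(work, source_met)
    substrate_ex.lower_bound = substrate_ex.upper_bound = -uptake
    source_c = work.metabolite(source_met).formula["C"]

    byproducts: dict[str, float] = {}
    for met_id, c_fraction in _byproduct_pattern(spec.carbon_source, spec.cn_ratio).items():
        met_c = work.metabolite(met_id).formula["C"]
        rate = c_fraction * uptake * source_c / met_c
        ex = find_exchange(work, met_id)
        ex.lower_bound = ex.upper_bound = rate
        byproducts[met_id] = rate

    biomass = work.reaction(work.biomass_reaction_id)
    biomass.lower_bound = biomass.upper_bound = spec.mu
    truth_sol = fba(work, objective={"NGAM": 1.0}, direction="max")
    if truth_sol.status != "optimal":
        raise InfeasibleModelError(
            f"growth rate {spec.mu}/h infeasible on {spec.carbon_source} at "
            f"uptake {uptake} mmol/gDW/h with byproducts {byproducts}"
        )

    otr = -truth_sol.fluxes["EX_o2"]
    ctr = truth_sol.fluxes["EX_co2"]
    truth = ConditionDataset(
        carbon_source=source_met,
        cn_ratio=spec.cn_ratio,
        mu=spec.mu,
        substrate_uptake=uptake,
        byproduct_rates=dict(byproducts),
        otr=otr,
        ctr=ctr,
        protein_content=composition.protein,
        lipid_content=composition.lipid,
    )

    rng = np.random.default_rng(spec.seed)

    def noisy(value: float) -> float:
        return max(value * (1.0 + spec.noise_cv * rng.standard_normal()), 0.0)

    measured = ConditionDataset(
        carbon_source=source_met,
        cn_ratio=spec.cn_ratio,
        mu=noisy(truth.mu),
        substrate_uptake=noisy(truth.substrate_uptake),
        byproduct_rates={m: noisy(r) for m, r in truth.byproduct_rates.items()},
        otr=noisy(truth.otr),
        ctr=noisy(truth.ctr),
        protein_content=min(noisy(truth.protein_content), 1.0),
        lipid_content=min(noisy(truth.lipid_content), 1.0),
    )
    return SyntheticCondition(
        dataset=measured,
        truth=truth,
        truth_fluxes=truth_sol,
        model=work,
        composition=composition,
    )


def study_condition_specs(
    noise_cv: float = 0.02, seed: int = 0
) -> list[SyntheticConditionSpec]:
    """The emulated experimental grid: C/N 60/80/100/120 on each substrate,
    with growth rates declining as C/N rises (glycerol fastest, acetate and
    xylose slower), typical of nitrogen-limited turbidostats."""
    mu_by_source = {
        "glycerol": {60: 0.24, 80: 0.18, 100: 0.13, 120: 0.06},
        "acetate": {60: 0.11, 80: 0.08, 100: 0.06, 120: 0.03},
        "xylose": {60: 0.08, 80: 0.06, 100: 0.05, 120: 0.03},
    }
    specs = []
    for i, (source, by_cn) in enumerate(mu_by_source.items()):
        for j, (cn, mu) in enumerate(by_cn.items()):
            specs.append(
                SyntheticConditionSpec(
                    carbon_source=source, cn_ratio=cn, mu=mu,
                    noise_cv=noise_cv, seed=seed + 97 * i + 13 * j,
                )
            )
    return specs
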