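"""Condition-specific model building and flux attribution.

The procedure mirrors how steady-state bioreactor measurements are turned
into a constrained genome-scale model for an N-limited oleaginous yeast:

1. refit the biomass equation to the measured protein and lipid content,
   rescaling the storage carbohydrate and keeping nucleotides fixed;
2. fix substrate uptake, byproduct excretion and growth rate to their
   measured values (growth falls back to the highest achievable rate when
   the measurement is infeasible);
3. fit the O2 and CO2 exchanges as close as possible to the measured
   transfer rates (two-stage: minimize the L1 deviation, then fix);
4. maximize ATP hydrolysis to estimate non-growth-associated maintenance;
5. relax every constrained exchange to a +/-2.5% window and randomly sample
   the remaining solution space;
6. attribute NADPH production and pathway carbon fractions over the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .fba_engine import FluxDistribution, FluxSample, InfeasibleModelError, fba, random_sample
from .gem_core import (
    BiomassComposition,
    Reaction,
    StoichiometricModel,
    carbon_count,
)

__all__ = [
    "ConditionDataset",
    "ConditionModel",
    "FluxAttribution",
    "PathwayRegistry",
    "GAM_POLYMERIZATION_COSTS",
    "compute_gam",
    "apply_biomass_composition",
    "biomass_carbon_content",
    "rescale_biomass",
    "constrain_condition",
    "estimate_ngam",
    "sample_condition",
    "attribute_fluxes",
    "theoretical_max_lipid_yield",
    "read_conditions_tsv",
    "write_conditions_tsv",
]

#: ATP cost of polymerizing one mmol of monomer into each macromolecule
#: (mmol ATP/mmol residue).  Literature-style defaults: ~4.3 ATP per peptide
#: bond, ~2.1 per glycosidic bond of storage glucan, ~2.4 per nucleotide
#: added to RNA/DNA.  Lipid esterification cost is charged in the lipid
#: synthesis reaction itself, not here.
GAM_POLYMERIZATION_COSTS: dict[str, float] = {
    "protein": 4.3,
    "carbohydrate": 2.1,
    "nucleotide": 2.4,
    "lipid": 0.0,
    "other": 0.0,
}


@dataclass
class ConditionDataset:
    """Measured quantities for one steady-state (turbidostat) condition.

    Rates are specific (per gDW): substrate uptake and byproduct excretions
    in mmol/gDW/h, OTR/CTR in mmol/gDW/h, growth in 1/h, and protein/lipid
    content in g/gDW.  Uptake is stored positive and mapped to a negative
    exchange flux internally.
    """

    carbon_source: str
    cn_ratio: float
    mu: float
    substrate_uptake: float
    byproduct_rates: dict[str, float] = field(default_factory=dict)
    otr: float = 0.0
    ctr: float = 0.0
    protein_content: float = 0.0
    lipid_content: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"growth rate must be non-negative, got {self.mu}")
        if self.substrate_uptake < 0:
            raise ValueError(f"uptake must be non-negative, got {self.substrate_uptake}")
        for name in ("protein_content", "lipid_content"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")


@dataclass
class ConditionModel:
    """A measurement-constrained model plus its fit diagnostics."""

    model: StoichiometricModel
    data: ConditionDataset
    relaxation: float
    fit_report: pd.DataFrame
    ngam: float | None = None
    ngam_reaction_id: str | None = None


@dataclass
class PathwayRegistry:
    """Reaction-id sets naming the pathways whose usage is attributed."""

    nadph_producers: list[str]
    phosphoketolase: list[str] = field(default_factory=list)
    acl: list[str] = field(default_factory=list)
    malic_enzyme: list[str] = field(default_factory=list)
    nadph_metabolite: str = "nadph"


@dataclass
class FluxAttribution:
    nadph_sources: dict[str, float]
    pathway_carbon_fractions: dict[str, float]
    predicted_rq: float
    predicted_byproducts: dict[str, float]


# ---------------------------------------------------------------------------
# biomass equation
# ---------------------------------------------------------------------------

def compute_gam(
    composition: BiomassComposition,
    residue_masses: dict[str, float],
    costs: dict[str, float] | None = None,
) -> float:
    """Growth-associated maintenance (mmol ATP/gDW) as the polymerization cost
    of the macromolecules, given residue molar masses in g/mol."""
    costs = costs or GAM_POLYMERIZATION_COSTS
    gam = 0.0
    for role, fraction in composition.as_dict().items():
        if fraction == 0.0 or costs.get(role, 0.0) == 0.0:
            continue
        gam += fraction / (residue_masses[role] / 1000.0) * costs[role]
    return gam


def _biomass_residue_masses(model: StoichiometricModel) -> dict[str, float]:
    masses = {}
    for role, met_id in model.biomass_components.items():
        mw = model.metabolite(met_id).molar_mass
        if mw is None:
            raise ValueError(f"biomass component {met_id} ({role}) lacks a formula")
        masses[role] = mw
    return masses


def apply_biomass_composition(
    model: StoichiometricModel,
    composition: BiomassComposition,
    gam_costs: dict[str, float] | None = None,
    atp_id: str = "atp",
    adp_id: str = "adp",
) -> StoichiometricModel:
    """Return a copy whose biomass reaction matches ``composition``.

    Each macromolecule coefficient becomes fraction / residue mass in
    mmol/gDW so that one unit of biomass flux drains exactly 1 g of
    macromolecules per gDW; the ATP coefficient is reset to the
    polymerization-cost GAM for that composition.
    """
    if not model.biomass_components:
        raise ValueError(f"model {model.id} declares no biomass components")
    work = model.copy()
    biomass = work.reaction(work.biomass_reaction_id)
    masses = _biomass_residue_masses(work)
    for role, fraction in composition.as_dict().items():
        met_id = work.biomass_components.get(role)
        if met_id is None:
            if fraction > 0:
                raise ValueError(
                    f"composition assigns {fraction} to {role!r} but the model "
                    "has no such biomass component"
                )
            continue
        coeff = -fraction / (masses[role] / 1000.0)
        if coeff == 0.0:
            biomass.stoichiometry.pop(met_id, None)
        else:
            biomass.stoichiometry[met_id] = coeff
    gam = compute_gam(composition, masses, gam_costs)
    biomass.stoichiometry[atp_id] = -gam
    biomass.stoichiometry[adp_id] = gam
    work.validate()
    return work


def biomass_carbon_content(model: StoichiometricModel) -> float:
    """Carbon drained by one unit of biomass flux, in mmol C/gDW."""
    biomass = model.reaction(model.biomass_reaction_id)
    total = 0.0
    for met_id, coeff in biomass.stoichiometry.items():
        met = model.metabolite(met_id)
        if coeff < 0 and met.formula:
            total += -coeff * met.formula.get("C", 0)
    return total


def rescale_biomass(
    model: StoichiometricModel,
    protein: float,
    lipid: float,
    baseline: BiomassComposition,
    gam_costs: dict[str, float] | None = None,
) -> StoichiometricModel:
    """Refit the biomass equation to measured protein and lipid content.

    Nucleotide and "other" fractions stay at their baseline values and the
    storage carbohydrate absorbs the remainder so the composition still sums
    to 1 g/gDW.  A negative implied carbohydrate fraction means the
    measurements are inconsistent with 1 g of macromolecules per gDW.
    """
    carbohydrate = 1.0 - protein - lipid - baseline.nucleotide - baseline.other
    if carbohydrate < -1e-12:
        raise ValueError(
            "measured protein + lipid leave a negative carbohydrate fraction "
            f"({carbohydrate:.4f}); measurements are inconsistent with 1 g/gDW"
        )
    composition = BiomassComposition(
        protein=protein,
        lipid=lipid,
        carbohydrate=max(carbohydrate, 0.0),
        nucleotide=baseline.nucleotide,
        other=baseline.other,
    )
    return apply_biomass_composition(model, composition, gam_costs)


# ---------------------------------------------------------------------------
# constraining
# ---------------------------------------------------------------------------

def find_exchange(model: StoichiometricModel, met_id: str) -> Reaction:
    for rxn in model.reactions:
        if model.is_exchange(rxn) and met_id in rxn.stoichiometry:
            return rxn
    raise KeyError(f"no exchange reaction for metabolite {met_id!r} in {model.id}")


def find_ngam_reaction(model: StoichiometricModel) -> Reaction:
    candidates = [
        r for r in model.reactions
        if r.subsystem.lower() == "maintenance" and r.id != model.biomass_reaction_id
    ]
    if not candidates:
        raise KeyError(f"model {model.id} has no maintenance (ATP hydrolysis) reaction")
    return candidates[0]


def _feasible(model: StoichiometricModel) -> bool:
    zero = {model.biomass_reaction_id: 0.0}
    return fba(model, objective=zero, direction="min").status == "optimal"


def _fit_gas_exchanges(
    model: StoichiometricModel, targets: dict[str, float]
) -> dict[str, float]:
    """Minimize the summed absolute deviation of the listed exchange fluxes
    from their targets; return the achieved fluxes at the L1 optimum."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    n = len(model.reactions)
    k = len(targets)
    rxn_pos = {r: j for j, r in enumerate(model.reaction_ids)}
    # variables: [v, d]; minimize sum(d) s.t. |v_j - t_j| <= d_j
    c = np.concatenate([np.zeros(n), np.ones(k)])
    A_eq = np.hstack([S, np.zeros((S.shape[0], k))])
    A_ub = np.zeros((2 * k, n + k))
    b_ub = np.zeros(2 * k)
    for i, (rxn_id, target) in enumerate(targets.items()):
        j = rxn_pos[rxn_id]
        A_ub[2 * i, j] = 1.0
        A_ub[2 * i, n + i] = -1.0
        b_ub[2 * i] = target
        A_ub[2 * i + 1, j] = -1.0
        A_ub[2 * i + 1, n + i] = -1.0
        b_ub[2 * i + 1] = -target
    bounds = list(zip(lb, ub)) + [(0.0, None)] * k
    res = linprog(
        c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        raise InfeasibleModelError(
            f"gas-exchange fit infeasible on {model.id} (status {res.status})"
        )
    return {rxn_id: float(res.x[rxn_pos[rxn_id]]) for rxn_id in targets}


def _relax_interval(value: float, relaxation: float) -> tuple[float, float]:
    lo, hi = sorted((value * (1.0 - relaxation), value * (1.0 + relaxation)))
    return lo, hi


def _diagnose_infeasibility(
    model: StoichiometricModel, constrained: dict[str, tuple[float, float]]
) -> list[str]:
    """Return constrained reactions whose individual release restores
    feasibility (the binding measurements)."""
    binding = []
    for rxn_id in constrained:
        probe = model.copy()
        rxn = probe.reaction(rxn_id)
        rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
        if _feasible(probe):
            binding.append(rxn_id)
    return binding


def constrain_condition(
    model: StoichiometricModel,
    data: ConditionDataset,
    relaxation: float = 0.025,
) -> ConditionModel:
    """Build the condition-specific model from one measurement set.

    Substrate uptake and byproduct excretions are fixed to the measured
    values; growth is fixed to the measured rate, or to the highest
    achievable rate when the measurement cannot be met; O2/CO2 exchanges are
    fitted to OTR/CTR by L1 minimization and then fixed; finally every
    constrained value is widened to its [1-relaxation, 1+relaxation] window
    so the solution space can be sampled.
    """
    if relaxation < 0:
        raise ValueError(f"relaxation must be non-negative, got {relaxation}")
    work = model.copy()
    report_rows: list[dict] = []
    fixed: dict[str, tuple[float, float]] = {}

    def fix(rxn: Reaction, value: float, label: str, requested: float) -> None:
        rxn.lower_bound = rxn.upper_bound = value
        fixed[rxn.id] = (value, value)
        report_rows.append(
            {"constraint": label, "reaction": rxn.id,
             "requested": requested, "achieved": value}
        )

    substrate_ex = find_exchange(work, data.carbon_source)
    fix(substrate_ex, -data.substrate_uptake, "substrate_uptake", -data.substrate_uptake)
    for met_id, rate in data.byproduct_rates.items():
        fix(find_exchange(work, met_id), rate, f"byproduct_{met_id}", rate)

    # growth: measured value, or the highest achievable by simulation
    biomass = work.reaction(work.biomass_reaction_id)
    biomass.lower_bound, biomass.upper_bound = data.mu, data.mu
    if not _feasible(work):
        biomass.lower_bound, biomass.upper_bound = 0.0, 1000.0
        sol = fba(work, objective={work.biomass_reaction_id: 1.0}, direction="max")
        if sol.status != "optimal":
            binding = _diagnose_infeasibility(work, fixed)
            raise InfeasibleModelError(
                f"condition infeasible even with free growth; binding "
                f"constraints: {binding or 'none identified'}"
            )
        mu_achieved = sol.objective_value
    else:
        mu_achieved = data.mu
    biomass.lower_bound = biomass.upper_bound = mu_achieved
    fixed[biomass.id] = (mu_achieved, mu_achieved)
    report_rows.append(
        {"constraint": "growth", "reaction": biomass.id,
         "requested": data.mu, "achieved": mu_achieved}
    )

    # O2/CO2 as close as possible to OTR/CTR (two-stage L1 fit, then fix)
    o2_ex = find_exchange(work, "o2")
    co2_ex = find_exchange(work, "co2")
    targets = {o2_ex.id: -data.otr, co2_ex.id: data.ctr}
    achieved = _fit_gas_exchanges(work, targets)
    fix(o2_ex, achieved[o2_ex.id], "otr", -data.otr)
    fix(co2_ex, achieved[co2_ex.id], "ctr", data.ctr)

    # widen every constrained value for sampling
    for rxn_id, (value, _) in fixed.items():
        rxn = work.reaction(rxn_id)
        rxn.lower_bound, rxn.upper_bound = _relax_interval(value, relaxation)

    report = pd.DataFrame(report_rows)
    report["deviation"] = report["achieved"] - report["requested"]
    return ConditionModel(model=work, data=data, relaxation=relaxation, fit_report=report)


def estimate_ngam(cm: ConditionModel) -> float:
    """Maximize ATP hydrolysis under the condition constraints.

    The maximized flux of the maintenance reaction is the model's estimate of
    non-growth-associated maintenance (mmol ATP/gDW/h): all energy the
    constrained network can generate beyond growth demands.
    """
    ngam_rxn = find_ngam_reaction(cm.model)
    sol = fba(cm.model, objective={ngam_rxn.id: 1.0}, direction="max")
    if sol.status != "optimal":
        raise InfeasibleModelError(f"NGAM estimation: model is {sol.status}")
    cm.ngam = sol.objective_value
    cm.ngam_reaction_id = ngam_rxn.id
    return cm.ngam


def sample_condition(cm: ConditionModel, n: int = 5000, seed: int = 0) -> FluxSample:
    """Sample the condition's solution space with NGAM held near its maximum.

    The maintenance flux is constrained to at least (1 - relaxation) times
    its maximized value, so sampling explores the alternate optima around the
    maximum-maintenance solution rather than collapsing onto a single vertex.
    """
    if cm.ngam is None:
        estimate_ngam(cm)
    work = cm.model.copy()
    ngam_rxn = work.reaction(cm.ngam_reaction_id)
    ngam_rxn.lower_bound = cm.ngam * (1.0 - cm.relaxation)
    return random_sample(work, n=n, seed=seed)


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def _consumed_carbon_per_flux(model: StoichiometricModel, rxn: Reaction) -> float:
    return sum(
        -coeff * carbon_count(model.metabolite(met_id))
        for met_id, coeff in rxn.stoichiometry.items()
        if coeff < 0 and model.metabolite(met_id).formula is not None
    )


def attribute_fluxes(
    cm: ConditionModel,
    sample: FluxSample,
    registry: PathwayRegistry,
) -> FluxAttribution:
    """Summarize NADPH sourcing and pathway carbon usage over a flux sample.

    Per sample and then averaged: each registered NADPH producer's share of
    total NADPH production; the fraction of consumed substrate carbon entering
    each pathway's signature reaction; the respiratory quotient; and positive
    non-gas excretions as C-mol fractions of uptake.
    """
    model = cm.model
    for rxn_id in (registry.nadph_producers + registry.phosphoketolase
                   + registry.acl + registry.malic_enzyme):
        model.reaction(rxn_id)  # raises for unknown ids

    frame = sample.to_frame()
    nadph = registry.nadph_metabolite
    production = pd.DataFrame(index=frame.index)
    for rxn_id in registry.nadph_producers:
        coeff = model.reaction(rxn_id).stoichiometry.get(nadph, 0.0)
        production[rxn_id] = (frame[rxn_id] * coeff).clip(lower=0.0)
    totals = production.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(
            "total NADPH production is zero in at least one sample; "
            "shares are undefined"
        )
    nadph_sources = production.div(totals, axis=0).mean(axis=0).to_dict()

    substrate_ex = find_exchange(model, cm.data.carbon_source)
    source_c = carbon_count(model.metabolite(cm.data.carbon_source))
    uptake_c = (-frame[substrate_ex.id]).clip(lower=0.0) * source_c

    def carbon_fraction(rxn_ids: list[str]) -> float:
        if not rxn_ids:
            return 0.0
        pathway_c = sum(
            frame[rid].clip(lower=0.0) * _consumed_carbon_per_flux(model, model.reaction(rid))
            for rid in rxn_ids
        )
        return float((pathway_c / uptake_c).mean())

    pathway_carbon_fractions = {
        "phosphoketolase": carbon_fraction(registry.phosphoketolase),
        "acl": carbon_fraction(registry.acl),
        "malic_enzyme": carbon_fraction(registry.malic_enzyme),
    }

    o2_ex = find_exchange(model, "o2")
    co2_ex = find_exchange(model, "co2")
    rq = float((frame[co2_ex.id] / (-frame[o2_ex.id])).mean())

    gas_ids = {o2_ex.id, co2_ex.id}
    predicted_byproducts: dict[str, float] = {}
    for rxn in model.exchange_reactions():
        if rxn.id in gas_ids or rxn.id == substrate_ex.id:
            continue
        met_id = next(iter(rxn.stoichiometry))
        met = model.metabolite(met_id)
        if met.formula is None or carbon_count(met) == 0:
            continue
        efflux = frame[rxn.id].clip(lower=0.0)
        fraction = float((efflux * carbon_count(met) / uptake_c).mean())
        if fraction > 1e-9:
            predicted_byproducts[met_id] = fraction
    return FluxAttribution(
        nadph_sources=nadph_sources,
        pathway_carbon_fractions=pathway_carbon_fractions,
        predicted_rq=rq,
        predicted_byproducts=predicted_byproducts,
    )


# ---------------------------------------------------------------------------
# theoretical maximal lipid yield
# ---------------------------------------------------------------------------

def theoretical_max_lipid_yield(
    model: StoichiometricModel,
    carbon_source: str,
    uptake: float = 10.0,
    ngam: float | None = None,
    lipid_metabolite: str | None = None,
) -> float:
    """Highest fraction of consumed carbon that can leave as exported lipid.

    Growth is fixed to zero (minimal growth), maintenance stays at the
    model's default unless overridden, the substrate uptake is fixed at a
    reference value (the result is a ratio and does not depend on it), every
    other carbon uptake is closed, and lipid export is maximized.
    """
    work = model.copy()
    lipid_id = lipid_metabolite or work.biomass_components.get("lipid") or "lipid"
    try:
        lipid_met = work.metabolite(lipid_id)
    except KeyError:
        raise ValueError(f"no lipid metabolite {lipid_id!r} in model {model.id}") from None
    if lipid_met.formula is None or carbon_count(lipid_met) == 0:
        raise ValueError(f"lipid metabolite {lipid_id!r} has no known carbon count")

    substrate_ex = find_exchange(work, carbon_source)
    for rxn in work.exchange_reactions():
        met = work.metabolite(next(iter(rxn.stoichiometry)))
        if rxn.id != substrate_ex.id and met.formula is not None and carbon_count(met) > 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)  # no other carbon uptake
    substrate_ex.lower_bound = substrate_ex.upper_bound = -uptake
    biomass = work.reaction(work.biomass_reaction_id)
    biomass.lower_bound = biomass.upper_bound = 0.0
    if ngam is not None:
        find_ngam_reaction(work).lower_bound = ngam

    try:
        lipid_ex = find_exchange(work, lipid_id)
    except KeyError:
        lipid_ex = Reaction(
            id=f"EX_{lipid_id}", name=f"{lipid_id} export",
            stoichiometry={lipid_id: -1.0}, lower_bound=0.0, upper_bound=1000.0,
        )
        work.reactions.append(lipid_ex)
        work.validate()
    lipid_ex.upper_bound = 1000.0

    sol = fba(work, objective={lipid_ex.id: 1.0}, direction="max")
    if sol.status != "optimal":
        raise InfeasibleModelError(f"lipid-yield LP is {sol.status} on {model.id}")
    substrate_c = carbon_count(work.metabolite(carbon_source))
    return sol.objective_value * carbon_count(lipid_met) / (uptake * substrate_c)


# ---------------------------------------------------------------------------
# condition table I/O (TSV, one row per condition)
# ---------------------------------------------------------------------------

_BYP_PREFIX = "byp_"


def write_conditions_tsv(conditions: list[ConditionDataset], path: str | Path) -> None:
    rows = []
    for cond in conditions:
        row = {
            "carbon_source": cond.carbon_source,
            "cn_ratio": cond.cn_ratio,
            "mu": cond.mu,
            "substrate_uptake": cond.substrate_uptake,
            "otr": cond.otr,
            "ctr": cond.ctr,
            "protein_content": cond.protein_content,
            "lipid_content": cond.lipid_content,
        }
        for met_id, rate in cond.byproduct_rates.items():
            row[_BYP_PREFIX + met_id] = rate
        rows.append(row)
    # %.17g keeps the full double precision so tables round-trip exactly
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_conditions_tsv(path: str | Path) -> list[ConditionDataset]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    conditions = []
    for _, row in frame.iterrows():
        byproducts = {
            col[len(_BYP_PREFIX):]: float(row[col])
            for col in frame.columns
            if col.startswith(_BYP_PREFIX) and not math.isnan(row[col])
        }
        conditions.append(
            ConditionDataset(
                carbon_source=str(row["carbon_source"]),
                cn_ratio=float(row["cn_ratio"]),
                mu=float(row["mu"]),
                substrate_uptake=float(row["substrate_uptake"]),
                byproduct_rates=byproducts,
                otr=float(row["otr"]),
                ctr=float(row["ctr"]),
                protein_content=float(row["protein_content"]),
                lipid_content=float(row["lipid_content"]),
            )
        )
    return conditions
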