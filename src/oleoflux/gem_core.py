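"""Data model and I/O for stoichiometric metabolic models.

A :class:`StoichiometricModel` is the in-memory container used throughout the
package: metabolites carry elemental formulas (so that carbon fractions and
carbon balances can be computed), reactions carry flux bounds in mmol/gDW/h,
and one reaction is designated as the biomass (growth) pseudo-reaction whose
flux is in 1/h.  Models round-trip through a flat JSON dialect (documented in
the README) and through SBML Level 3 with the flux-balance-constraints (fbc)
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._formula import format_formula, molar_mass, parse_formula

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "BiomassComposition",
    "MassBalanceIssue",
    "ModelValidationError",
    "ModelParseError",
    "load_model",
    "write_model",
    "carbon_count",
    "check_mass_balance",
]

#: Default magnitude for otherwise unbounded fluxes (mmol/gDW/h).
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file could not be parsed; the message names the entity."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int = 0

    def __post_init__(self) -> None:
        if self.formula is not None:
            for element, count in self.formula.items():
                if not (isinstance(count, int) and count >= 0):
                    raise ModelValidationError(
                        f"metabolite {self.id}: element count {element}={count} "
                        "must be a non-negative integer"
                    )

    @property
    def molar_mass(self) -> float | None:
        """Molar mass in g/mol, or None when the formula is absent."""
        return None if self.formula is None else molar_mass(self.formula)


@dataclass
class Reaction:
    """A (possibly pseudo-) reaction.

    ``stoichiometry`` maps metabolite id to a real coefficient, negative for
    consumption.  Bounds are fluxes in mmol/gDW/h (1/h for the biomass
    reaction).
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class BiomassComposition:
    """Macromolecular biomass composition in g/gDW; fractions sum to 1."""

    protein: float
    lipid: float
    carbohydrate: float
    nucleotide: float
    other: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not 0.0 <= value <= 1.0:
                raise ModelValidationError(f"biomass fraction {name}={value} outside [0, 1]")
        total = sum(self.as_dict().values())
        if abs(total - 1.0) > 1e-9:
            raise ModelValidationError(f"biomass fractions sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "protein": self.protein,
            "lipid": self.lipid,
            "carbohydrate": self.carbohydrate,
            "nucleotide": self.nucleotide,
            "other": self.other,
        }


@dataclass
class StoichiometricModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    objective: dict[str, float] = field(default_factory=dict)
    #: optional map of biomass component role -> pseudo-metabolite id
    #: (roles: protein, lipid, carbohydrate, nucleotide, other)
    biomass_components: dict[str, str] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup ----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id}") from None

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    # -- structure -------------------------------------------------------

    def validate(self) -> None:
        self._met_index = {}
        for met in self.metabolites:
            if met.id in self._met_index:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            self._met_index[met.id] = met
        self._rxn_index = {}
        for rxn in self.reactions:
            if rxn.id in self._rxn_index:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            self._rxn_index[rxn.id] = rxn
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
        if self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not present in model"
            )
        for rxn_id in self.objective:
            if rxn_id not in self._rxn_index:
                raise ModelValidationError(f"objective references unknown reaction {rxn_id!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix: rows = metabolites, columns = reactions."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def is_exchange(self, rxn: Reaction) -> bool:
        """An exchange reaction touches exactly one metabolite."""
        return len(rxn.stoichiometry) == 1

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolites=[replace(m, formula=None if m.formula is None else dict(m.formula))
                         for m in self.metabolites],
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            objective=dict(self.objective),
            biomass_components=dict(self.biomass_components),
            id=self.id,
        )


def carbon_count(met: Metabolite) -> int:
    """Number of carbon atoms per molecule; 0 when the formula lacks C."""
    if met.formula is None:
        raise ValueError(f"metabolite {met.id} has no formula")
    return met.formula.get("C", 0)


@dataclass
class MassBalanceIssue:
    """One reaction that is not elementally balanced (or cannot be checked)."""

    reaction_id: str
    residuals: dict[str, float]  # element -> net production per unit flux
    status: str = "unbalanced"  # or "unknown" when a formula is missing


_PSEUDO_SUBSYSTEMS = {"biomass", "maintenance", "pseudo"}


def check_mass_balance(
    model: StoichiometricModel,
    elements: tuple[str, ...] | None = None,
    tol: float = 1e-9,
) -> list[MassBalanceIssue]:
    """Report internal reactions with non-zero elemental residuals.

    Exchange reactions, the biomass reaction, and maintenance pseudo-reactions
    (tagged via ``subsystem``) are excluded: they intentionally create or
    destroy mass.  A reaction involving a metabolite without a formula is
    flagged with status ``"unknown"`` rather than silently treated as
    balanced.  An empty return value means every inspected reaction balances
    for the requested elements (all elements seen when ``elements`` is None).
    """
    issues: list[MassBalanceIssue] = []
    for rxn in model.reactions:
        if model.is_exchange(rxn):
            continue
        if rxn.id == model.biomass_reaction_id:
            continue
        if rxn.subsystem.lower() in _PSEUDO_SUBSYSTEMS:
            continue
        mets = [model.metabolite(m) for m in rxn.stoichiometry]
        if any(m.formula is None for m in mets):
            issues.append(MassBalanceIssue(rxn.id, {}, status="unknown"))
            continue
        residual: dict[str, float] = {}
        for met in mets:
            coeff = rxn.stoichiometry[met.id]
            for element, count in met.formula.items():
                residual[element] = residual.get(element, 0.0) + coeff * count
        checked = residual if elements is None else {
            e: residual.get(e, 0.0) for e in elements
        }
        bad = {e: r for e, r in checked.items() if abs(r) > tol}
        if bad:
            issues.append(MassBalanceIssue(rxn.id, bad))
    return issues


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": None if m.formula is None else format_formula(m.formula),
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
        "objective": model.objective,
        "biomass_components": model.biomass_components,
    }


def _model_from_dict(doc: dict, source: str = "<json>") -> StoichiometricModel:
    try:
        metabolites = []
        for entry in doc["metabolites"]:
            formula = entry.get("formula")
            metabolites.append(
                Metabolite(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    compartment=entry.get("compartment", "c"),
                    formula=None if formula is None else parse_formula(formula),
                    charge=int(entry.get("charge", 0)),
                )
            )
        reactions = [
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                lower_bound=float(entry["lower_bound"]),
                upper_bound=float(entry["upper_bound"]),
                subsystem=entry.get("subsystem", ""),
            )
            for entry in doc["reactions"]
        ]
        return StoichiometricModel(
            metabolites=metabolites,
            reactions=reactions,
            biomass_reaction_id=doc["biomass_reaction_id"],
            objective={k: float(v) for k, v in doc.get("objective", {}).items()},
            biomass_components=dict(doc.get("biomass_components", {})),
            id=doc.get("id", "model"),
        )
    except KeyError as exc:
        raise ModelParseError(f"{source}: missing required field {exc}") from exc


# ---------------------------------------------------------------------------
# SBML Level 3 (fbc)
# ---------------------------------------------------------------------------

def _model_to_sbml(model: StoichiometricModel) -> str:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId(f"M_{met.id}")
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(format_formula(met.formula))
        elif met.formula is not None:
            # empty formula = carbon-free currency pseudo-species; fbc cannot
            # express an empty chemicalFormula, so mark it in the notes
            s.appendNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml"><p>FORMULA: none</p></body>'
            )

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(f"R_{rxn.id}")
        r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        if rxn.subsystem:
            r.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml"><p>SUBSYSTEM: {rxn.subsystem}</p></body>'
            )
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = r.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = r.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(f"M_{met_id}")
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    obj_map = model.objective or {model.biomass_reaction_id: 1.0}
    for rxn_id, weight in obj_map.items():
        fo = objective.createFluxObjective()
        fo.setReaction(f"R_{rxn_id}")
        fo.setCoefficient(weight)

    return libsbml.writeSBMLToString(doc)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _model_from_sbml(text: str, source: str = "<sbml>") -> StoichiometricModel:
    import libsbml

    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{source}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{source}: file contains no SBML model")

    metabolites = []
    for s in sbml_model.getListOfSpecies():
        splug = s.getPlugin("fbc")
        formula = None
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        if formula is None and s.isSetNotes() and "FORMULA: none" in s.getNotesString():
            formula = {}
        metabolites.append(
            Metabolite(
                id=_strip_prefix(s.getId(), "M_"),
                name=s.getName(),
                compartment=s.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    def param_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid)
        return p.getValue() if p is not None else default

    reactions = []
    for r in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in r.getListOfReactants():
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in r.getListOfProducts():
            met = _strip_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_value(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = param_value(rplug.getUpperFluxBound(), ub)
        elif not r.getReversible():
            lb = 0.0
        subsystem = ""
        if r.isSetNotes():
            notes = r.getNotesString()
            marker = "SUBSYSTEM: "
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<")[0].strip()
        reactions.append(
            Reaction(
                id=_strip_prefix(r.getId(), "R_"),
                name=r.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=subsystem,
            )
        )

    objective: dict[str, float] = {}
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getActiveObjective() is not None:
        for fo in mplug.getActiveObjective().getListOfFluxObjectives():
            objective[_strip_prefix(fo.getReaction(), "R_")] = fo.getCoefficient()

    biomass_id = None
    for candidate in objective:
        if "biomass" in candidate.lower() or "growth" in candidate.lower():
            biomass_id = candidate
    if biomass_id is None:
        for rxn in reactions:
            if "biomass" in rxn.id.lower() or "growth" in rxn.id.lower():
                biomass_id = rxn.id
                break
    if biomass_id is None and objective:
        biomass_id = next(iter(objective))
    if biomass_id is None:
        raise ModelValidationError(f"{source}: could not identify a biomass reaction")

    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        objective=objective,
        id=sbml_model.getId() or "model",
    )


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def load_model(path: str | Path, format: str | None = None) -> StoichiometricModel:
    """Load a model from the JSON dialect or SBML Level 3 (fbc)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    text = path.read_text()
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(doc, source=str(path))
    if fmt == "sbml":
        return _model_from_sbml(text, source=str(path))
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: StoichiometricModel, path: str | Path, format: str | None = None) -> None:
    """Write a model in the JSON dialect or as SBML Level 3 (fbc)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=False) + "\n")
    elif fmt == "sbml":
        path.write_text(_model_to_sbml(model))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
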