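"""Turbidostat/batch physiology arithmetic: rates, yields, RQ, C/N, carbon balance.

All quantities follow the steady-state chemostat identities.  Specific rates
are per gDW; yields are mass-based.  The specific lipid production rate uses
the turbidostat identity r_lip = lipid_content * mu, valid when biomass
composition is at steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .condition_pipeline import ConditionDataset

__all__ = [
    "PhysiologySummary",
    "MediumComponent",
    "MediumRecipe",
    "derive_rates",
    "carbon_recovery",
    "cn_ratio",
    "fedbatch_yield_summary",
    "SUBSTRATE_MOLAR_MASS",
]

#: molar masses (g/mol) of the supported carbon sources, keyed by the toy
#: model's metabolite ids
SUBSTRATE_MOLAR_MASS = {"glyc": 92.094, "xyl": 150.13, "ac": 60.052}

#: elemental carbon content of biomass, mmol C/gDW (typical yeast value;
#: configurable in carbon_recovery)
DEFAULT_BIOMASS_CARBON = 40.0


@dataclass
class PhysiologySummary:
    """Derived steady-state quantities for one condition."""

    mu: float  # 1/h
    y_sx: float  # gDW / g substrate
    y_ls: float  # g lipid / g substrate
    q_bm: float  # gDW / (L*h)
    r_lip: float  # g lipid / (gDW*h)
    rq: float  # dimensionless
    cn_ratio: float  # mol/mol
    carbon_recovery: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "mu": self.mu,
            "y_sx": self.y_sx,
            "y_ls": self.y_ls,
            "q_bm": self.q_bm,
            "r_lip": self.r_lip,
            "rq": self.rq,
            "cn_ratio": self.cn_ratio,
            "carbon_recovery": self.carbon_recovery,
        }


def derive_rates(
    data: ConditionDataset,
    biomass_conc: float,
    substrate_molar_mass: float | None = None,
) -> PhysiologySummary:
    """Steady-state rates and yields from one measured condition.

    biomass_conc is the steady-state biomass concentration (gDW/L);
    substrate_molar_mass (g/mol) defaults to the tabulated value for the
    condition's carbon source.  RQ is CTR/OTR and is undefined when OTR is
    zero while CTR is not.
    """
    if substrate_molar_mass is None:
        try:
            substrate_molar_mass = SUBSTRATE_MOLAR_MASS[data.carbon_source]
        except KeyError:
            raise ValueError(
                f"no tabulated molar mass for {data.carbon_source!r}; "
                "pass substrate_molar_mass"
            ) from None
    uptake_mass = data.substrate_uptake * substrate_molar_mass / 1000.0  # g/gDW/h
    if data.otr == 0.0:
        if data.ctr > 0.0:
            raise ValueError("RQ undefined: CTR > 0 with OTR = 0")
        rq = 0.0
    else:
        rq = data.ctr / data.otr
    r_lip = data.lipid_content * data.mu
    y_sx = data.mu / uptake_mass if uptake_mass > 0 else 0.0
    return PhysiologySummary(
        mu=data.mu,
        y_sx=y_sx,
        y_ls=r_lip / uptake_mass if uptake_mass > 0 else 0.0,
        q_bm=data.mu * biomass_conc,
        r_lip=r_lip,
        rq=rq,
        cn_ratio=data.cn_ratio,
    )


def carbon_recovery(
    data: ConditionDataset,
    carbon_counts: dict[str, int],
    biomass_c_content: float = DEFAULT_BIOMASS_CARBON,
) -> float:
    """Fraction of consumed substrate carbon recovered in measured products.

    (biomass C + CO2 + byproduct C) / substrate C, all in mmol C/gDW/h.
    ``carbon_counts`` maps metabolite id to carbon atoms per molecule and
    must cover the substrate and every measured byproduct;
    ``biomass_c_content`` is in mmol C/gDW.
    """
    if data.substrate_uptake <= 0:
        raise ValueError("carbon recovery needs a positive substrate uptake")
    try:
        substrate_c = carbon_counts[data.carbon_source]
    except KeyError:
        raise ValueError(f"no carbon count for substrate {data.carbon_source!r}") from None
    byproduct_c = 0.0
    for met_id, rate in data.byproduct_rates.items():
        try:
            byproduct_c += rate * carbon_counts[met_id]
        except KeyError:
            raise ValueError(f"no carbon count for byproduct {met_id!r}") from None
    recovered = data.mu * biomass_c_content + data.ctr + byproduct_c
    return recovered / (data.substrate_uptake * substrate_c)


@dataclass
class MediumComponent:
    compound: str
    concentration: float  # g/L
    carbon_atoms: int  # per mol
    nitrogen_atoms: int  # per mol
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.compound}: concentration must be non-negative")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.compound}: molar mass must be positive")


@dataclass
class MediumRecipe:
    components: list[MediumComponent] = field(default_factory=list)


def cn_ratio(recipe: MediumRecipe) -> float:
    """Molar C/N ratio of a medium: sum(mol C) / sum(mol N) over components."""
    carbon = sum(
        c.concentration / c.molar_mass * c.carbon_atoms for c in recipe.components
    )
    nitrogen = sum(
        c.concentration / c.molar_mass * c.nitrogen_atoms for c in recipe.components
    )
    if nitrogen == 0:
        raise ValueError("medium contains no nitrogen-bearing component")
    return carbon / nitrogen


def fedbatch_yield_summary(
    lipid_titer: float,
    biomass: float,
    glycerol_per_biomass: float | None = None,
) -> dict[str, float]:
    """End-point fed-batch yield arithmetic.

    From the final lipid titer (g/L), biomass (gDW/L), and the substrate
    consumed per biomass formed (g/gDW): lipid content = titer/biomass, and
    when the consumption yield is given, the lipid-on-substrate yield
    y_ls = titer / (biomass * substrate per biomass).
    """
    if lipid_titer <= 0 or biomass <= 0:
        raise ValueError("lipid titer and biomass must be positive")
    out = {"lipid_content": lipid_titer / biomass}
    if glycerol_per_biomass is not None:
        if glycerol_per_biomass <= 0:
            raise ValueError("glycerol per biomass must be positive")
        out["y_ls"] = lipid_titer / (biomass * glycerol_per_biomass)
    return out


def summarize_conditions(
    conditions: list[ConditionDataset],
    biomass_conc: float = 1.0,
    carbon_counts: dict[str, int] | None = None,
    biomass_c_content: float = DEFAULT_BIOMASS_CARBON,
) -> pd.DataFrame:
    """One summary row per condition; carbon recovery included when carbon
    counts are supplied."""
    rows = []
    for cond in conditions:
        summary = derive_rates(cond, biomass_conc)
        if carbon_counts is not None:
            summary.carbon_recovery = carbon_recovery(
                cond, carbon_counts, biomass_c_content
            )
        row = {"carbon_source": cond.carbon_source}
        row.update(summary.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
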