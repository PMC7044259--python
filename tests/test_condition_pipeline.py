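"""Condition-specific constraining, NGAM, sampling, attribution, yields."""

import numpy as np
import pytest

from oleoflux.condition_pipeline import (
    ConditionDataset,
    PathwayRegistry,
    attribute_fluxes,
    biomass_carbon_content,
    constrain_condition,
    estimate_ngam,
    rescale_biomass,
    sample_condition,
    theoretical_max_lipid_yield,
    read_conditions_tsv,
    write_conditions_tsv,
)
from oleoflux.fba_engine import fva
from oleoflux.gem_core import BiomassComposition
from oleoflux.synthetic_models import (
    SOURCE_METABOLITES,
    SyntheticConditionSpec,
    ToyGemSpec,
    build_toy_gem,
    make_condition_dataset,
    toy_registry,
)

from _oracles import TOY_YIELD_CEILINGS


@pytest.fixture(scope="module")
def glycerol_condition(toy_model):
    spec = SyntheticConditionSpec("glycerol", 100, 0.13, noise_cv=0.0, seed=1)
    return make_condition_dataset(toy_model, spec)


@pytest.fixture(scope="module")
def glycerol_cm(glycerol_condition):
    cm = constrain_condition(glycerol_condition.model, glycerol_condition.dataset)
    estimate_ngam(cm)
    return cm


class TestRescaleBiomass:
    def test_carbohydrate_absorbs_remainder(self, toy_model):
        baseline = BiomassComposition(0.45, 0.10, 0.39, 0.06, 0.0)
        rescaled = rescale_biomass(toy_model, protein=0.40, lipid=0.30,
                                   baseline=baseline)
        biomass = rescaled.reaction("BIOMASS")
        carb_mw = rescaled.metabolite("carb").molar_mass
        expected = 1.0 - 0.40 - 0.30 - 0.06  # = 0.24 g/gDW
        assert biomass.stoichiometry["carb"] == pytest.approx(
            -expected / (carb_mw / 1000.0)
        )
        # nucleotides untouched
        nuc_mw = rescaled.metabolite("nuc").molar_mass
        assert biomass.stoichiometry["nuc"] == pytest.approx(-0.06 / (nuc_mw / 1000.0))

    def test_identity_when_measurements_match_baseline(self, toy_model,
                                                       baseline_composition):
        rescaled = rescale_biomass(
            toy_model,
            protein=baseline_composition.protein,
            lipid=baseline_composition.lipid,
            baseline=baseline_composition,
        )
        orig = toy_model.reaction("BIOMASS").stoichiometry
        assert rescaled.reaction("BIOMASS").stoichiometry == pytest.approx(orig)

    def test_high_lipid_composition_remains_feasible(self, toy_model):
        # 60% lipid, the highest content the cultures reached
        baseline = BiomassComposition(0.45, 0.10, 0.40, 0.05, 0.0)
        rescaled = rescale_biomass(toy_model, protein=0.20, lipid=0.60,
                                   baseline=baseline)
        biomass = rescaled.reaction("BIOMASS")
        lipid_mw = rescaled.metabolite("lipid").molar_mass
        assert biomass.stoichiometry["lipid"] == pytest.approx(
            -0.60 / (lipid_mw / 1000.0)
        )
        carb_mw = rescaled.metabolite("carb").molar_mass
        assert biomass.stoichiometry["carb"] == pytest.approx(
            -(1.0 - 0.60 - 0.20 - 0.05) / (carb_mw / 1000.0)
        )

    def test_negative_implied_carbohydrate_rejected(self, toy_model,
                                                    baseline_composition):
        with pytest.raises(ValueError, match="carbohydrate"):
            rescale_biomass(toy_model, protein=0.55, lipid=0.50,
                            baseline=baseline_composition)

    def test_gam_grows_with_protein_content(self, toy_model, baseline_composition):
        lean = rescale_biomass(toy_model, 0.30, 0.20, baseline_composition)
        rich = rescale_biomass(toy_model, 0.50, 0.20, baseline_composition)
        assert -rich.reaction("BIOMASS").stoichiometry["atp"] > \
               -lean.reaction("BIOMASS").stoichiometry["atp"]


class TestConstrainCondition:
    def test_zero_noise_fit_is_exact(self, glycerol_cm, glycerol_condition):
        report = glycerol_cm.fit_report.set_index("constraint")
        assert report["deviation"].abs().max() == pytest.approx(0.0, abs=1e-6)
        assert report.loc["growth", "achieved"] == pytest.approx(
            glycerol_condition.truth.mu
        )

    def test_relaxed_bounds_bracket_measured_values(self, glycerol_cm):
        data = glycerol_cm.data
        ex = glycerol_cm.model.reaction("EX_glyc")
        assert ex.lower_bound == pytest.approx(-data.substrate_uptake * 1.025)
        assert ex.upper_bound == pytest.approx(-data.substrate_uptake * 0.975)

    def test_unachievable_growth_fixed_at_simulated_max(self, glycerol_condition):
        data = glycerol_condition.dataset
        too_fast = ConditionDataset(
            carbon_source=data.carbon_source,
            cn_ratio=data.cn_ratio,
            mu=2.0,  # far beyond what uptake 10 supports
            substrate_uptake=data.substrate_uptake,
            byproduct_rates=data.byproduct_rates,
            otr=data.otr,
            ctr=data.ctr,
            protein_content=data.protein_content,
            lipid_content=data.lipid_content,
        )
        cm = constrain_condition(glycerol_condition.model, too_fast)
        report = cm.fit_report.set_index("constraint")
        assert report.loc["growth", "achieved"] < 2.0
        assert report.loc["growth", "requested"] == 2.0

    def test_predicted_rq_within_relaxation_of_truth(self, glycerol_cm,
                                                     glycerol_condition):
        truth_rq = glycerol_condition.truth.ctr / glycerol_condition.truth.otr
        o2 = glycerol_cm.model.reaction("EX_o2")
        co2 = glycerol_cm.model.reaction("EX_co2")
        # mid-window achieved values reproduce the generating RQ
        achieved_rq = ((co2.lower_bound + co2.upper_bound) / 2) / (
            -(o2.lower_bound + o2.upper_bound) / 2
        )
        assert achieved_rq == pytest.approx(truth_rq, rel=2 * glycerol_cm.relaxation)

    def test_negative_relaxation_rejected(self, glycerol_condition):
        with pytest.raises(ValueError, match="relaxation"):
            constrain_condition(glycerol_condition.model,
                                glycerol_condition.dataset, relaxation=-0.1)

    def test_relaxation_widening_never_shrinks_fva(self, glycerol_condition):
        """Widening the measurement window can only grow each flux range."""
        tight = constrain_condition(glycerol_condition.model,
                                    glycerol_condition.dataset, relaxation=0.0)
        wide = constrain_condition(glycerol_condition.model,
                                   glycerol_condition.dataset, relaxation=0.05)
        probe = ["GLYCDH", "OXPPP", "ACL", "PDH", "NGAM", "EX_co2"]
        r_tight = fva(tight.model, reactions=probe)
        r_wide = fva(wide.model, reactions=probe)
        for rxn_id in probe:
            assert r_wide.minimum[rxn_id] <= r_tight.minimum[rxn_id] + 1e-6
            assert r_wide.maximum[rxn_id] >= r_tight.maximum[rxn_id] - 1e-6


class TestNgam:
    def test_no_substrate_no_maintenance(self, toy_model, baseline_composition):
        data = ConditionDataset(
            carbon_source="glyc", cn_ratio=60, mu=0.0, substrate_uptake=0.0,
            otr=0.0, ctr=0.0, protein_content=baseline_composition.protein,
            lipid_content=baseline_composition.lipid,
        )
        cm = constrain_condition(toy_model, data)
        assert estimate_ngam(cm) == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_substrate_supply(self, toy_model, glycerol_condition):
        data = glycerol_condition.dataset
        doubled = ConditionDataset(
            carbon_source=data.carbon_source, cn_ratio=data.cn_ratio, mu=data.mu,
            substrate_uptake=2 * data.substrate_uptake,
            byproduct_rates=data.byproduct_rates,
            otr=2 * data.otr, ctr=2 * data.ctr,
            protein_content=data.protein_content,
            lipid_content=data.lipid_content,
        )
        base = estimate_ngam(constrain_condition(glycerol_condition.model, data))
        more = estimate_ngam(constrain_condition(glycerol_condition.model, doubled))
        assert more >= base - 1e-6

    def test_acetate_supports_less_atp_spilling_than_xylose(self, toy_model):
        """At matched C-mol uptake and growth, the C2 substrate leaves less
        surplus ATP than the pentose (energy-efficiency ordering)."""
        ngams = {}
        for source, cn, mu in (("acetate", 60, 0.03), ("xylose", 60, 0.03)):
            sc = make_condition_dataset(
                toy_model, SyntheticConditionSpec(source, cn, mu, 0.0, 0)
            )
            ngams[source] = estimate_ngam(
                constrain_condition(sc.model, sc.dataset)
            ) / (sc.dataset.substrate_uptake *
                 (2 if source == "acetate" else 5))  # per C-mol
        assert ngams["xylose"] > ngams["acetate"]


class TestSampling:
    def test_sample_rows_inside_condition_fva(self, glycerol_cm):
        sample = sample_condition(glycerol_cm, n=150, seed=3)
        work = glycerol_cm.model.copy()
        work.reaction(glycerol_cm.ngam_reaction_id).lower_bound = (
            glycerol_cm.ngam * (1 - glycerol_cm.relaxation)
        )
        ranges = fva(work)
        lo = np.array([ranges.minimum[r] for r in sample.reaction_ids])
        hi = np.array([ranges.maximum[r] for r in sample.reaction_ids])
        assert np.all(sample.matrix >= lo - 1e-6)
        assert np.all(sample.matrix <= hi + 1e-6)

    def test_sample_seed_determinism(self, glycerol_cm):
        a = sample_condition(glycerol_cm, n=30, seed=5)
        b = sample_condition(glycerol_cm, n=30, seed=5)
        assert np.array_equal(a.matrix, b.matrix)

    def test_ngam_floor_respected(self, glycerol_cm):
        sample = sample_condition(glycerol_cm, n=30, seed=5)
        floor = glycerol_cm.ngam * (1 - glycerol_cm.relaxation)
        assert np.all(sample.column("NGAM") >= floor - 1e-6)


class TestAttribution:
    def test_glycerol_nadph_dominated_by_glycerol_dehydrogenase(self, glycerol_cm):
        sample = sample_condition(glycerol_cm, n=150, seed=7)
        att = attribute_fluxes(glycerol_cm, sample, toy_registry())
        assert sum(att.nadph_sources.values()) == pytest.approx(1.0, abs=1e-6)
        assert att.nadph_sources["GLYCDH"] > 0.5
        assert all(v >= 0 for v in att.nadph_sources.values())
        assert all(0 <= v <= 1 for v in att.pathway_carbon_fractions.values())

    def test_predicted_rq_matches_generating_rq(self, glycerol_cm,
                                                glycerol_condition):
        sample = sample_condition(glycerol_cm, n=150, seed=7)
        att = attribute_fluxes(glycerol_cm, sample, toy_registry())
        truth_rq = glycerol_condition.truth.ctr / glycerol_condition.truth.otr
        assert att.predicted_rq == pytest.approx(truth_rq, rel=0.06)

    def test_single_nadph_source_gets_full_share(self, toy_model):
        """With the alternative producers removed, the oxidative PPP carries
        the entire NADPH supply on xylose."""
        slim = build_toy_gem(ToyGemSpec(include_malic_enzyme=False))
        slim.reactions = [r for r in slim.reactions if r.id != "IDH"]
        slim.validate()
        sc = make_condition_dataset(
            slim, SyntheticConditionSpec("xylose", 60, 0.05, 0.0, 0)
        )
        cm = constrain_condition(sc.model, sc.dataset)
        sample = sample_condition(cm, n=60, seed=1)
        registry = PathwayRegistry(nadph_producers=["OXPPP", "GLYCDH"])
        att = attribute_fluxes(cm, sample, registry)
        assert att.nadph_sources["OXPPP"] == pytest.approx(1.0, abs=1e-9)
        assert att.nadph_sources["GLYCDH"] == pytest.approx(0.0, abs=1e-9)

    def test_deleted_phosphoketolase_has_zero_carbon_fraction(self, toy_model):
        slim = build_toy_gem(ToyGemSpec(include_phosphoketolase=False))
        sc = make_condition_dataset(
            slim, SyntheticConditionSpec("xylose", 60, 0.05, 0.0, 0)
        )
        cm = constrain_condition(sc.model, sc.dataset)
        sample = sample_condition(cm, n=60, seed=1)
        registry = PathwayRegistry(
            nadph_producers=["GLYCDH", "OXPPP", "IDH", "ME"], phosphoketolase=[]
        )
        att = attribute_fluxes(cm, sample, registry)
        assert att.pathway_carbon_fractions["phosphoketolase"] == 0.0

    def test_acetate_prefers_synthase_over_citrate_lyase(self, toy_model):
        """Direct acetate activation makes ATP-citrate lyase nearly idle."""
        sc = make_condition_dataset(
            toy_model, SyntheticConditionSpec("acetate", 80, 0.08, 0.0, 0)
        )
        cm = constrain_condition(sc.model, sc.dataset)
        sample = sample_condition(cm, n=100, seed=2)
        att = attribute_fluxes(cm, sample, toy_registry())
        acs_flux = sample.column("ACS").mean()
        acl_flux = sample.column("ACL").mean()
        assert acs_flux > 10 * acl_flux
        assert att.pathway_carbon_fractions["acl"] < 0.05

    def test_unknown_registry_id_rejected(self, glycerol_cm):
        sample = sample_condition(glycerol_cm, n=5, seed=0)
        with pytest.raises(KeyError):
            attribute_fluxes(
                glycerol_cm, sample, PathwayRegistry(nadph_producers=["NOPE"])
            )


class TestTheoreticalYield:
    @pytest.mark.parametrize("source", sorted(TOY_YIELD_CEILINGS))
    def test_matches_closed_form_stoichiometric_ceiling(self, toy_model, source):
        value = theoretical_max_lipid_yield(toy_model, SOURCE_METABOLITES[source])
        assert value == pytest.approx(float(TOY_YIELD_CEILINGS[source]), abs=1e-6)

    def test_glycerol_beats_xylose_beats_acetate(self, toy_model):
        yields = {
            s: theoretical_max_lipid_yield(toy_model, m)
            for s, m in SOURCE_METABOLITES.items()
        }
        assert yields["glycerol"] > yields["xylose"] > yields["acetate"]

    def test_invariant_to_reference_uptake(self, toy_model):
        for met in ("glyc", "xyl", "ac"):
            y1 = theoretical_max_lipid_yield(toy_model, met, uptake=1.0)
            y10 = theoretical_max_lipid_yield(toy_model, met, uptake=10.0)
            assert y1 == pytest.approx(y10, abs=1e-9)

    def test_nonincreasing_in_ngam(self, toy_model):
        values = [
            theoretical_max_lipid_yield(toy_model, "ac", ngam=n)
            for n in (0.0, 5.0, 10.0, 20.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] < values[0]

    def test_missing_lipid_species_rejected(self, toy_model):
        stripped = toy_model.copy()
        stripped.biomass_components = {}
        with pytest.raises(ValueError, match="lipid"):
            theoretical_max_lipid_yield(stripped, "glyc", lipid_metabolite="nope")


class TestConditionTableIO:
    def test_tsv_roundtrip(self, toy_model, tmp_path):
        sc = make_condition_dataset(
            toy_model, SyntheticConditionSpec("xylose", 100, 0.05, 0.02, 3)
        )
        path = tmp_path / "conditions.tsv"
        write_conditions_tsv([sc.dataset], path)
        back = read_conditions_tsv(path)
        assert len(back) == 1
        assert back[0] == sc.dataset
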