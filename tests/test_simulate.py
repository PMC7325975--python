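"""Synthetic experiment generator: dynamics oracles, presets, determinism."""

import math

import dendropy
import numpy as np
import pytest

import custress as cs
from custress.errors import InvalidParameterError, SimulationDivergedError
from custress.simulate import _integrate, design_schedules


def logistic_closed_form(r, k, b0, t):
    return k / (1.0 + ((k - b0) / b0) * math.exp(-r * t))


def quiet_params(**kw):
    base = dict(r_max=0.8, k_cap=0.5, ec50=1.0, noise_sigma=0.0)
    base.update(kw)
    return cs.IsolateParams(**base)


class TestReplicateDynamics:
    @pytest.mark.parametrize(
        "r,k", [(0.8, 0.5), (1.2, 0.8), (0.4, 4.0), (1.0, 0.2)]
    )
    def test_control_matches_logistic_closed_form(self, r, k, design17):
        """Copper-free growth is plain logistic; the integrator must track it."""
        params = quiet_params(r_max=r, k_cap=k)
        sched = cs.build_control_schedule(9)
        biomass, _ = cs.simulate_replicate(params, sched, design17, seed=0)
        expected = logistic_closed_form(r, k, params.b0, 14.0)
        assert biomass == pytest.approx(expected, rel=1e-3)

    def test_no_inhibition_limit_equals_control(self, design17, default_schedules):
        """With a huge ec50 and no damage/shock, copper has no growth effect."""
        params = quiet_params(ec50=1e9)
        results = {
            arm: cs.simulate_replicate(params, sched, design17, seed=0)[0]
            for arm, sched in default_schedules.items()
        }
        assert results["gradual"] == pytest.approx(results["control"], rel=1e-12)
        assert results["abrupt"] == pytest.approx(results["control"], rel=1e-12)

    def test_zero_uptake_gives_zero_accumulation(self, design17, default_schedules):
        params = quiet_params(uptake_vmax=0.0)
        for sched in default_schedules.values():
            _, cu = cs.simulate_replicate(params, sched, design17, seed=0)
            assert cu == 0.0

    def test_control_without_baseline_uptake_accumulates_nothing(self, design17):
        params = quiet_params(uptake_vmax=1.0, baseline_uptake=0.0)
        _, cu = cs.simulate_replicate(
            params, cs.build_control_schedule(9), design17, seed=0
        )
        assert cu == 0.0

    def test_biomass_monotone_in_final_conc(self, design17, rng):
        """Raising the endpoint concentration never helps treated growth."""
        for _ in range(5):
            params = quiet_params(
                r_max=rng.uniform(0.4, 1.0),
                k_cap=rng.uniform(0.5, 3.0),
                ec50=rng.uniform(0.5, 3.0),
                damage_rate=rng.uniform(0.0, 0.3),
                shock_sens=rng.uniform(0.0, 2.0),
            )
            last = math.inf
            for conc in (0.25, 0.5, 1.0, 2.0):
                sched = cs.build_gradual_schedule(conc, 9)
                biomass, _ = cs.simulate_replicate(params, sched, design17, seed=0)
                assert biomass <= last + 1e-12
                last = biomass

    def test_dose_rate_sensitivity_regimes(self, design17, default_schedules, rng):
        """Chronic damage punishes the long (gradual) exposure; shock
        sensitivity punishes the concentration jump of the abrupt arm."""
        grad, abr = default_schedules["gradual"], default_schedules["abrupt"]
        for _ in range(20):
            common = dict(
                r_max=rng.uniform(0.4, 0.55),
                k_cap=rng.uniform(2.0, 4.0),
                ec50=rng.uniform(2.5, 4.0),
                noise_sigma=0.0,
            )
            chronic = cs.IsolateParams(damage_rate=rng.uniform(0.15, 0.45), **common)
            bg, _ = cs.simulate_replicate(chronic, grad, design17, seed=0)
            ba, _ = cs.simulate_replicate(chronic, abr, design17, seed=0)
            assert bg <= ba
            shocky = cs.IsolateParams(shock_sens=rng.uniform(1.0, 4.0), **common)
            bg, _ = cs.simulate_replicate(shocky, grad, design17, seed=0)
            ba, _ = cs.simulate_replicate(shocky, abr, design17, seed=0)
            assert ba <= bg

    def test_divergent_parameters_raise(self, design17):
        params = quiet_params(r_max=1e6, k_cap=1e-6)
        with pytest.raises(SimulationDivergedError):
            cs.simulate_replicate(
                params, cs.build_control_schedule(9), design17, seed=0
            )

    def test_noise_reproducible_given_seed(self, design17, default_schedules):
        params = quiet_params(noise_sigma=0.1)
        a = cs.simulate_replicate(params, default_schedules["gradual"], design17, seed=42)
        b = cs.simulate_replicate(params, default_schedules["gradual"], design17, seed=42)
        assert a == b


class TestExperiment:
    def test_default_design_has_255_units(self, design17):
        panel = cs.generate_isolate_panel(17, seed=1)
        table = cs.simulate_experiment(design17, panel, seed=2)
        assert design17.n_units == 255
        assert len(table) == 255
        assert table["isolate"].nunique() == 17

    def test_zero_replicates_gives_empty_table(self):
        design = cs.ExperimentDesign(isolate_ids=("a", "b", "c"), n_replicates=0)
        panel = cs.generate_isolate_panel(3, seed=1)
        assert len(cs.simulate_experiment(design, panel, seed=0)) == 0

    def test_same_seed_is_bitwise_identical(self, design17):
        panel = cs.generate_isolate_panel(17, seed=1)
        t1 = cs.simulate_experiment(design17, panel, seed=9)
        t2 = cs.simulate_experiment(design17, panel, seed=9)
        assert t1.equals(t2)

    def test_panel_design_mismatch_rejected(self, design17):
        with pytest.raises(InvalidParameterError):
            cs.simulate_experiment(design17, cs.generate_isolate_panel(5, seed=1), seed=0)

    def test_experiment_matches_per_replicate_calls(self, design17):
        """The batch generator is just simulate_replicate per cell."""
        panel = cs.generate_isolate_panel(17, seed=1)
        table = cs.simulate_experiment(design17, panel, seed=3)
        from custress.simulate import _replicate_seed

        schedules = design_schedules(design17)
        row = table.iloc[100]
        params = panel[design17.isolate_ids.index(row["isolate"])]
        seed = _replicate_seed(3, row["isolate"], row["treatment"], row["replicate"])
        bio, cu = cs.simulate_replicate(params, schedules[row["treatment"]], design17, seed)
        assert bio == row["biomass_g"]
        assert cu == row["cu_mg_per_g"]


class TestPanels:
    def test_equal_mix_of_four_gives_one_each(self):
        mix = {k: 0.25 for k in cs.simulate.PATTERN_PRESETS}
        panel = cs.generate_isolate_panel(4, preset_mix=mix, seed=0)
        assert sorted(p.preset for p in panel) == sorted(cs.simulate.PATTERN_PRESETS)

    def test_pure_no_effect_panel_has_high_ec50(self):
        panel = cs.generate_isolate_panel(17, preset_mix={"no_effect": 1.0}, seed=0)
        assert all(p.ec50 >= 10.0 for p in panel)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.generate_isolate_panel(5, preset_mix={"no_effect": 0.6}, seed=0)
        with pytest.raises(InvalidParameterError):
            cs.generate_isolate_panel(5, preset_mix={"mystery": 1.0}, seed=0)

    def test_uniform_preset_arms_are_kinetically_equal(self, design17, default_schedules):
        """The uniform-reduction region is defined by exact arm equality of
        the noise-free endpoint (separable growth ODE)."""
        panel = cs.generate_isolate_panel(
            6, preset_mix={"uniform_reduction": 1.0}, seed=4
        )
        for p in panel:
            bg, _ = _integrate(p, default_schedules["gradual"], 5)
            ba, _ = _integrate(p, default_schedules["abrupt"], 5)
            bc, _ = _integrate(p, default_schedules["control"], 5)
            assert bg == pytest.approx(ba, rel=1e-4)
            assert bg < 0.9 * bc  # still a real reduction vs control

    def test_damage_prone_isolates_accumulate_more_under_gradual(
        self, design17, default_schedules
    ):
        panel = cs.generate_isolate_panel(
            6, preset_mix={"gradual_worse": 1.0}, seed=4
        )
        for p in panel:
            _, qg = _integrate(p, default_schedules["gradual"], 5)
            _, qa = _integrate(p, default_schedules["abrupt"], 5)
            assert qg > qa


class TestPhylogeny:
    def test_seventeen_tip_tree_is_valid_newick(self):
        ids = [f"iso{i:02d}" for i in range(1, 18)]
        tree, traits = cs.generate_phylogeny(ids, seed=7)
        assert sorted(lf.taxon.label for lf in tree.leaf_nodes()) == sorted(ids)
        newick = tree.as_string(schema="newick")
        back = dendropy.Tree.get(data=newick, schema="newick")
        assert len(back.leaf_nodes()) == 17
        assert set(traits) == set(ids)

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.generate_phylogeny(["a", "b"], seed=0)

    def test_brownian_on_zero_length_tree_is_constant(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,C:0);", schema="newick")
        traits = cs.simulate_brownian_traits(tree, seed=3)
        assert len(set(traits.values())) == 1

    def test_phylogeny_deterministic(self):
        ids = [f"x{i}" for i in range(8)]
        t1, tr1 = cs.generate_phylogeny(ids, seed=3, trait_mode="brownian")
        t2, tr2 = cs.generate_phylogeny(ids, seed=3, trait_mode="brownian")
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert tr1 == tr2
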