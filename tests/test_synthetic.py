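"""Synthetic generator: templates, effects, determinism, filter exercise."""

import numpy as np
import pandas as pd
import pytest

from lipidkit.blank_filter import apply_blank_filter
from lipidkit.errors import DesignError
from lipidkit.nomenclature import parse_species
from lipidkit.quantify import class_totals
from lipidkit.stats import differential_test
from lipidkit.synthetic import (
    GroupSpec,
    TargetSelector,
    default_rosters,
    make_effects,
    make_templates,
    null_effect,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def templates():
    return make_templates()


@pytest.fixture(scope="module")
def effects():
    return make_effects()


class TestRosters:
    def test_total_species_count(self):
        rosters = default_rosters()
        assert sum(len(v) for v in rosters.values()) >= 1000
        assert set(rosters) == {
            "CE", "CER", "DCER", "HCER", "LCER", "DG", "FFA", "LPC", "LPE",
            "PC", "PE", "PG", "PI", "PS", "SM", "TG"}

    def test_all_names_parse_into_their_class(self):
        for code, names in default_rosters().items():
            for name in names:
                assert parse_species(name).lipid_class.code == code

    def test_no_duplicate_canonicals(self):
        for names in default_rosters().values():
            canon = [parse_species(n).canonical for n in names]
            assert len(set(canon)) == len(canon)


class TestTemplates:
    def test_three_templates(self, templates):
        assert set(templates) == {"iNeuron", "iAstrocyte", "iMicroglia"}

    def test_fractions_sum_to_one(self, templates):
        for t in templates.values():
            assert sum(t.class_fractions.values()) == pytest.approx(1.0)
            for pairs in t.species_weights.values():
                assert sum(w for _, w in pairs) == pytest.approx(1.0)

    def test_ordering_constraints(self, templates):
        f = {name: t.class_fractions for name, t in templates.items()}
        neuron, astro, microglia = f["iNeuron"], f["iAstrocyte"], f["iMicroglia"]
        # astrocytes hold the largest CE stores
        assert astro["CE"] > neuron["CE"] and astro["CE"] > microglia["CE"]
        # SM ladder: microglia > astrocyte > neuron
        assert microglia["SM"] > astro["SM"] > neuron["SM"]
        # PC + PE is the largest two-class share everywhere
        for fr in f.values():
            top2 = sorted(fr.values(), reverse=True)[:2]
            assert sorted([fr["PC"], fr["PE"]], reverse=True) == top2
        # storage/FA classes peak in microglia, CER/lyso in neurons, DG in astros
        for code in ("TG", "FFA", "PS"):
            assert microglia[code] == max(fr[code] for fr in f.values())
        for code in ("CER", "LPC", "LPE"):
            assert neuron[code] == max(fr[code] for fr in f.values())
        assert astro["DG"] == max(fr["DG"] for fr in f.values())


class TestEffects:
    def test_apoe4_raises_every_ce_species(self, templates, effects):
        apoe4 = effects["apoe4"]
        for name in default_rosters()["CE"]:
            p = parse_species(name)
            assert apoe4.multiplier(p, p.canonical) > 1.0

    def test_apoe4_tg_saturation_window(self, effects):
        apoe4 = effects["apoe4"]
        for name, expect_up in [("TG 48:0", True), ("TG 48:1", True),
                                ("TG 52:3", False), ("TG 56:7", True)]:
            p = parse_species(name)
            assert (apoe4.multiplier(p, p.canonical) > 1.0) == expect_up

    def test_apoe4_sm_down(self, effects):
        p = parse_species("SM 34:1")
        assert effects["apoe4"].multiplier(p, p.canonical) < 1.0

    def test_reactive_lowers_ce_and_tg(self, effects):
        reactive = effects["reactive"]
        for name in ("CE 18:1", "TG 52:3"):
            p = parse_species(name)
            assert reactive.multiplier(p, p.canonical) < 1.0

    def test_reactive_raises_saturated_phospholipids(self, effects):
        reactive = effects["reactive"]
        up = parse_species("PC 16:0_18:1")   # 1 double bond
        flat = parse_species("PC 16:0_20:4")  # 4 double bonds
        assert reactive.multiplier(up, up.canonical) > 1.0
        assert reactive.multiplier(flat, flat.canonical) == 1.0

    def test_null_effect_identity(self):
        p = parse_species("CE 18:1")
        assert null_effect().multiplier(p, p.canonical) == 1.0

    def test_selector_species_set(self):
        sel = TargetSelector(species=frozenset({"CE 18:1"}))
        assert sel.matches(parse_species("CE 18:1"), "CE 18:1")
        assert not sel.matches(parse_species("CE 18:2"), "CE 18:2")

    def test_invalid_multiplier(self):
        from lipidkit.synthetic import EffectSpec
        with pytest.raises(ValueError):
            EffectSpec("bad", ((TargetSelector(), -1.0),))


def _two_groups(template, n=4, effect=None, **kwargs):
    return simulate_dataset(
        [GroupSpec("control", n, template),
         GroupSpec("case", n, template, effect=effect)],
        **kwargs)


class TestSimulateDataset:
    def test_determinism(self, templates):
        ds1, m1 = _two_groups(templates["iAstrocyte"], seed=123)
        ds2, m2 = _two_groups(templates["iAstrocyte"], seed=123)
        pd.testing.assert_frame_equal(ds1.concentrations, ds2.concentrations)
        assert m1 == m2

    def test_seed_changes_data(self, templates):
        ds1, _ = _two_groups(templates["iAstrocyte"], seed=1)
        ds2, _ = _two_groups(templates["iAstrocyte"], seed=2)
        assert not ds1.concentrations.equals(ds2.concentrations)

    def test_zero_noise_recovers_template_fractions(self, templates):
        template = templates["iAstrocyte"]
        ds, _ = _two_groups(template, seed=5, noise_cv=0.0,
                            n_near_blank=0, n_group_exclusive=0)
        profile = class_totals(ds)
        for code, frac in template.class_fractions.items():
            np.testing.assert_allclose(profile.percent.loc[code],
                                       100 * frac, atol=1e-9)

    def test_sample_layout(self, templates):
        ds, manifest = _two_groups(templates["iNeuron"], n=6, seed=9,
                                   n_experiments=3)
        assert len(ds.sample_ids("blank")) == 2
        assert len(ds.sample_ids("qc")) == 1
        assert len(ds.sample_ids("biological")) == 12
        reps = {ds.replicate_of()[s] for s in ds.sample_ids("biological")}
        assert reps == {"exp1", "exp2", "exp3"}
        assert manifest["synthetic"] is True

    def test_filter_exercise(self, templates):
        """Defaults must cover every filter verdict path."""
        ds, _ = _two_groups(templates["iAstrocyte"], n=6, seed=21)
        _, report = apply_blank_filter(ds)
        counts = report.counts
        assert counts["removed"] >= 1
        assert counts["reintroduced"] >= 1
        assert counts["retained"] >= 0.8 * len(report.table)

    def test_group_exclusive_species_reintroduced(self, templates):
        ds, manifest = _two_groups(templates["iAstrocyte"], n=6, seed=33)
        _, report = apply_blank_filter(ds)
        exclusive = manifest["group_exclusive_species"]
        assert exclusive
        verdicts = report.table.loc[list(exclusive), "verdict"]
        assert (verdicts == "reintroduced").all()

    def test_effect_recovery_smoke(self, templates, effects):
        """Injected CE shift is detected; 5-seed smoke version of the
        larger Monte-Carlo acceptance check."""
        template = templates["iAstrocyte"]
        hits = 0
        for seed in range(5):
            ds, _ = _two_groups(template, n=9, effect=effects["apoe4"],
                                seed=seed, noise_cv=0.2)
            filtered, _ = apply_blank_filter(ds)
            profile = class_totals(filtered)
            res = differential_test(profile.percent, filtered.group_of(),
                                    "case", "control")
            if res.table.loc["CE", "q"] < 0.05:
                hits += 1
        assert hits == 5

    def test_missing_rate(self, templates):
        ds, _ = _two_groups(templates["iNeuron"], seed=2, missing_rate=0.1)
        bio = ds.concentrations[ds.sample_ids("biological")]
        frac = bio.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15
        blanks = ds.concentrations[ds.sample_ids("blank")]
        assert not blanks.isna().any().any()

    @pytest.mark.parametrize("kwargs", [
        dict(groups=[]),
        dict(groups=[("g", 0)]),
        dict(groups=[("g", 3), ("g", 3)]),
    ])
    def test_invalid_designs(self, templates, kwargs):
        specs = [GroupSpec(name, n, templates["iNeuron"])
                 for name, n in kwargs["groups"]]
        with pytest.raises(DesignError):
            simulate_dataset(specs, seed=1)

    def test_mixed_templates_per_group(self, templates):
        ds, _ = simulate_dataset(
            [GroupSpec("neu", 3, templates["iNeuron"]),
             GroupSpec("ast", 3, templates["iAstrocyte"])],
            seed=4, noise_cv=0.05, n_near_blank=0, n_group_exclusive=0)
        profile = class_totals(ds)
        neu = profile.percent.loc["CE", ds.groups()["neu"]].mean()
        ast = profile.percent.loc["CE", ds.groups()["ast"]].mean()
        assert ast > neu
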