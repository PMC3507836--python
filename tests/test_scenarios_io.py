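import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from growthzones import build_diagram, classify_phenotype, generate_scenarios
from growthzones.cli import main as cli_main
from growthzones.continuation import FAST_SETTINGS
from growthzones.io import ConfigError, load_config, load_scenarios, write_outputs


class TestArchetypes:
    @pytest.mark.parametrize("archetype,expected", [
        ("wt", "WT_NETO"),
        ("orb_like", "orb"),
        ("tea_like_low_eps", "no_NETO_monopolar"),
        ("high_eps_bipolar", "premature_bipolar"),
        ("low_beta", "delayed_NETO"),
        ("high_beta", "weak_monopolar_early_NETO"),
    ])
    def test_intended_phenotype_reproduced(self, archetype, expected):
        """Every bundled two-zone scenario's diagram reproduces its intended
        phenotype under independent classification."""
        sc = generate_scenarios(archetype)[0]
        d = build_diagram(sc.params, sc.suggested_l_range, FAST_SETTINGS)
        assert classify_phenotype(d, sc.cycle_window).label == expected

    def test_wt_neto_fraction_near_one_third(self):
        sc = generate_scenarios("wt")[0]
        d = build_diagram(sc.params, sc.suggested_l_range, FAST_SETTINGS)
        ph = classify_phenotype(d, sc.cycle_window)
        assert abs(ph.neto_cycle_fraction - 1 / 3) < 0.05

    def test_beta_ordering_of_neto_lengths(self):
        """Lower autocatalysis shifts NETO to larger l, higher to smaller."""
        from growthzones.phenotypes import monopolar_neto_l
        wt = generate_scenarios("wt")[0]
        lo = generate_scenarios("low_beta")[0]
        hi = generate_scenarios("high_beta")[0]
        n_wt = monopolar_neto_l(wt.params)
        assert monopolar_neto_l(lo.params) > n_wt > monopolar_neto_l(hi.params)

    def test_replicates_deterministic_for_fixed_seed(self):
        a = generate_scenarios("wt", n=5, noise=0.1, seed=42)
        b = generate_scenarios("wt", n=5, noise=0.1, seed=42)
        assert [s.to_dict() for s in a] == [s.to_dict() for s in b]
        assert len({s.params.epsilon for s in a}) == 5

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            generate_scenarios("wt", n=2, noise=0.1)

    def test_unknown_archetype(self):
        with pytest.raises(ValueError):
            generate_scenarios("hyphal")


class TestAsymmetricAndOverlapArchetypes:
    def test_moderate_asymmetry_weak_tip_switches_then_takes_off(self):
        """Born monopolar on the disfavoured tip (the island branch), the
        cell suddenly switches polarity to the strong tip when the island
        ends, and NETO follows later."""
        from growthzones import GrowthLaw, classify_growth_pattern, simulate_cycle
        sc = generate_scenarios("asym_moderate")[0]
        tr = simulate_cycle(sc.params, sc.l_birth, [0.0, 0.75],
                            GrowthLaw("linear_l", 1.0, 200))
        pat = classify_growth_pattern(tr)
        assert pat.label == "tip_switch_then_NETO"
        assert tr.events_of("tip_switch")

    def test_strong_asymmetry_has_no_tip_switch_pattern(self):
        """With the island gone, only the standard monopolar-NETO pattern
        remains, whichever tip starts."""
        from growthzones import GrowthLaw, classify_growth_pattern, simulate_cycle
        sc = generate_scenarios("asym_strong")[0]
        for init in ([0.75, 0.0], [0.0, 0.75]):
            tr = simulate_cycle(sc.params, sc.l_birth, init,
                                GrowthLaw("linear_l", 1.0, 200))
            assert classify_growth_pattern(tr).label == "monopolar_then_NETO"
            assert not tr.events_of("tip_switch")

    def test_overlap_archetype_sustains_both_patterns_across_generations(self):
        """In the deep monopolar/bipolar overlap regime, daughters born with
        an active old end grow monopolar without NETO while daughters born
        with scar residual on both tips grow bipolar from birth — both
        patterns persist in every generation."""
        from growthzones import GrowthLaw, classify_growth_pattern, simulate_cycle
        sc = generate_scenarios("for3_like_overlap")[0]
        law = GrowthLaw("linear_l", 1.0, 100)
        scar = 0.35
        mono_parent = [0.7, 0.0]
        for generation in range(3):
            tr_mono = simulate_cycle(sc.params, sc.l_birth, mono_parent, law)
            tr_scar = simulate_cycle(sc.params, sc.l_birth, [scar, scar], law)
            labels = {
                classify_growth_pattern(tr_mono).label,
                classify_growth_pattern(tr_scar).label,
            }
            assert labels == {"monopolar_no_NETO", "bipolar_from_birth"}
            # next generation's monopolar daughter inherits the active tip
            mono_parent = [float(np.clip(tr_mono.end_state[0], 0, 1)), 0.0]


class TestThreeZoneWeakLateral:
    def test_lateral_zone_joins_only_beyond_division_length(self):
        """With two strong tips and a weak lateral site, the tips follow the
        two-zone pattern over the cycle while the lateral zone activates
        only at lengths past normal division (the long-cell behaviour)."""
        from growthzones.equilibria import enumerate_equilibria
        sc = generate_scenarios("three_zone_weak_lateral")[0]
        lb, ld = sc.cycle_window
        # within the cycle window no stable state has the lateral zone active
        for l in np.linspace(lb, ld, 7):
            for e in enumerate_equilibria(sc.params, float(l), resolution=15):
                if e.is_stable:
                    assert e.x[2] < 0.3
        # far beyond division length the lateral site finally activates
        far = [e for e in enumerate_equilibria(sc.params, 3.4, resolution=15)
               if e.is_stable]
        assert any(e.x[2] > 0.3 for e in far)


class TestConfig:
    def test_round_trip_minimal(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text("epsilon: 0.07\nbeta: 20.0\na: [0.5, 0.5]\n")
        out = load_config(cfg)
        assert out["params"].epsilon == 0.07

    def test_unknown_key_is_hard_error(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text("epsilon: 0.07\nbeta: 20.0\nepsilonn: 0.1\n")
        with pytest.raises(ConfigError, match="epsilonn"):
            load_config(cfg)

    def test_weight_sum_invariant_enforced(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text("epsilon: 0.07\nbeta: 20.0\na: [0.5, 0.4]\n")
        with pytest.raises(ConfigError, match="sum"):
            load_config(cfg)

    def test_incomplete_dimensional_block(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text("k_basal: 0.1\nk_auto: 1.0\nk_off: 1.0\n")
        with pytest.raises(ConfigError, match="missing"):
            load_config(cfg)


class TestWriteOutputs:
    def test_scenario_list_round_trips_to_equality(self, tmp_path):
        scs = generate_scenarios("wt", n=3, noise=0.05, seed=3)
        write_outputs(scs, tmp_path / "scen", seed=3)
        loaded = load_scenarios(tmp_path / "scen.json")
        assert loaded == scs

    def test_diagram_csv_schema(self, tmp_path, symmetric_diagram):
        paths = write_outputs(symmetric_diagram, tmp_path / "diag")
        df = pd.read_csv(paths[0], comment="#")
        assert list(df.columns) == [
            "branch_id", "label", "point_index", "l", "x_1", "x_2", "stability"
        ]
        assert set(df["stability"]) <= {"stable", "unstable", "marginal"}

    def test_metadata_header_embedded(self, tmp_path, symmetric_diagram):
        paths = write_outputs(symmetric_diagram, tmp_path / "diag",
                              config={"epsilon": 0.1}, seed=5)
        head = paths[0].read_text().splitlines()[:4]
        assert head[0].startswith("# tool:")
        doc = json.loads(paths[1].read_text())
        assert doc["metadata"]["seed"] == 5
        assert doc["metadata"]["config"]["epsilon"] == 0.1

    def test_unsupported_object_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            write_outputs(object(), tmp_path / "x")


class TestCli:
    def test_nullclines_and_scenarios_commands(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "nullclines", "--epsilon", "0.07", "--beta", "20",
            "--l", "1.2", "--out", str(tmp_path / "nc"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "nc.csv").exists()
        r2 = runner.invoke(cli_main, [
            "scenarios", "--archetype", "wt", "--out", str(tmp_path / "sc"),
        ])
        assert r2.exit_code == 0, r2.output
        assert "eps=" in r2.output

    def test_diagram_command_bit_identical_reruns(self, tmp_path):
        runner = CliRunner()
        args = ["diagram", "--epsilon", "0.3", "--beta", "20", "--fast",
                "--l-range", "0.1:1.0"]
        r1 = runner.invoke(cli_main, args + ["--out", str(tmp_path / "d1")])
        r2 = runner.invoke(cli_main, args + ["--out", str(tmp_path / "d2")])
        assert r1.exit_code == 0 and r2.exit_code == 0, r1.output + r2.output
        assert (tmp_path / "d1.csv").read_text() == (tmp_path / "d2.csv").read_text()
        assert (tmp_path / "d1.json").read_text() == (tmp_path / "d2.json").read_text()

    def test_missing_parameters_reported(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["diagram", "--out", "x"])
        assert r.exit_code != 0
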