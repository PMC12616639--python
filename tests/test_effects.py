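"""Path enumeration, effect decomposition and the cluster bootstrap."""

import numpy as np
import pytest

from conftest import small_config, zero_noise
from sugarsem.effects import (
    EffectError,
    bootstrap_effects,
    decompose,
    effects_report,
    enumerate_paths,
)
from sugarsem.psem import CausalGraph, fit_all
from sugarsem.synthetic import default_coefficients, simulate_experiment


@pytest.fixture(scope="module")
def chain_graph():
    return CausalGraph(
        nodes=("L", "M", "Y"), edges=(("L", "M"), ("M", "Y"), ("L", "Y"))
    )


@pytest.fixture(scope="module")
def small_fits(small_dataset, graph):
    return fit_all(small_dataset, graph)


class TestEnumeratePaths:
    def test_sixteen_label_to_bid_paths(self, graph):
        paths = enumerate_paths(graph, "label", "bid")
        assert len(paths) == 16
        assert sum(len(p.path) == 2 for p in paths) == 1  # one direct path

    def test_eight_label_to_tastiness_paths(self, graph):
        assert len(enumerate_paths(graph, "label", "tastiness")) == 8

    def test_chain_with_shortcut(self, chain_graph):
        assert len(enumerate_paths(chain_graph, "L", "Y")) == 2

    def test_source_equals_target_rejected(self, graph):
        with pytest.raises(ValueError):
            enumerate_paths(graph, "label", "label")

    def test_canonical_order(self, graph):
        paths = [p.path for p in enumerate_paths(graph, "label", "tastiness")]
        assert paths == sorted(
            paths, key=lambda p: tuple(graph.nodes.index(n) for n in p)
        )
        # the fully-mediated chain sorts first, the direct path last
        assert paths[0] == ("label", "sweetness", "familiarity", "healthiness", "tastiness")
        assert paths[-1] == ("label", "tastiness")


class TestDecompose:
    def test_toy_chain(self, chain_graph):
        coefs = {"M": {"L": 2.0}, "Y": {"M": 3.0, "L": 1.0}}
        table = decompose(chain_graph, coefs, "L", "Y")
        assert table.direct == 1.0
        assert table.indirect == 6.0
        assert table.total == 7.0
        assert table.per_mediator == {"M": 6.0}

    def test_identity_total_equals_direct_plus_indirect(self, graph, small_fits):
        for target in ("bid", "tastiness"):
            t = decompose(graph, small_fits, "label", target)
            assert t.total == t.direct + t.indirect
            assert sum(p.contribution for p in t.paths) == pytest.approx(
                t.total, rel=1e-12, abs=1e-12
            )

    def test_generating_path_algebra_from_point_coefficients(self, graph):
        # with the generating coefficients, the single-path contribution
        # label -> sweetness -> tastiness is (-0.518) * 0.110 exactly
        table = decompose(graph, default_coefficients(), "label", "tastiness")
        single = [
            p for p in table.paths if p.path == ("label", "sweetness", "tastiness")
        ][0]
        assert single.contribution == pytest.approx(-0.518 * 0.110, rel=1e-12)
        assert single.contribution == pytest.approx(-0.05698, abs=1e-10)
        # the indirect sum over the seven mediated paths lands near -0.23
        assert table.indirect == pytest.approx(-0.2297, abs=5e-4)

    def test_interpolation_fits_reproduce_generating_algebra(self, graph):
        # each node fitted in its own exact-interpolation limit: the
        # assembled coefficient set reproduces the generating path algebra
        from conftest import interpolation_config
        from sugarsem.psem import fit_node

        fits = [
            fit_node(simulate_experiment(interpolation_config(node)), graph, node)
            for node in ("sweetness", "familiarity", "healthiness", "tastiness")
        ]
        fitted = decompose(graph, fits, "label", "tastiness")
        truth = decompose(graph, default_coefficients(), "label", "tastiness")
        assert fitted.direct == pytest.approx(truth.direct, abs=1e-6)
        assert fitted.indirect == pytest.approx(truth.indirect, abs=1e-6)
        for m, v in truth.per_mediator.items():
            assert fitted.per_mediator[m] == pytest.approx(v, abs=1e-6)

    def test_missing_edge_coefficient_names_edge(self, chain_graph):
        with pytest.raises(EffectError, match="M -> Y"):
            decompose(chain_graph, {"M": {"L": 2.0}, "Y": {"L": 1.0}}, "L", "Y")

    def test_standardized_mode_scales_by_observed_sds(self, graph, small_dataset, small_fits):
        raw = decompose(graph, small_fits, "label", "sweetness")
        std = decompose(
            graph, small_fits, "label", "sweetness", standardize=True, data=small_dataset
        )
        sds = small_dataset.records[["label", "sweetness"]].std(ddof=1)
        assert std.direct == pytest.approx(raw.direct * sds["label"] / sds["sweetness"])


class TestBootstrap:
    def test_same_seed_reproduces_cis_exactly(self, small_dataset, graph):
        t1, _ = bootstrap_effects(
            small_dataset, graph, "label", "sweetness", n_boot=20, seed=123
        )
        t2, _ = bootstrap_effects(
            small_dataset, graph, "label", "sweetness", n_boot=20, seed=123
        )
        assert t1.ci == t2.ci

    def test_noiseless_data_gives_degenerate_cis(self, noiseless_dataset, graph):
        table, boot = bootstrap_effects(
            noiseless_dataset, graph, "label", "sweetness", n_boot=10, seed=5
        )
        lo, hi = table.ci["total"]
        assert hi - lo == pytest.approx(0.0, abs=1e-8)
        assert boot.replicate_effects["total"].std() == pytest.approx(0.0, abs=1e-8)

    def test_replicate_count_and_unit_recorded(self, small_dataset, graph):
        table, boot = bootstrap_effects(
            small_dataset, graph, "label", "sweetness", n_boot=12, seed=9,
            resample_unit="pair",
        )
        assert boot.n_boot == 12
        assert boot.resample_unit == "pair"
        assert len(boot.replicate_effects) == 12
        assert set(table.significant) == set(table.ci)

    def test_minimum_replicates(self, small_dataset, graph):
        with pytest.raises(ValueError):
            bootstrap_effects(small_dataset, graph, "label", "sweetness", n_boot=1)


class TestReport:
    def test_row_layout(self, graph, small_dataset):
        table, _ = bootstrap_effects(
            small_dataset, graph, "label", "bid", n_boot=5, seed=2
        )
        report = effects_report([table])
        # three summary rows plus one per mediator
        assert len(report) == 7
        assert list(report["effect_type"][:3]) == ["Direct", "Indirect", "Total"]
        assert set(report.loc[report["effect_type"] == "Mediator", "variable"]) == {
            "sweetness", "familiarity", "healthiness", "tastiness",
        }

    def test_no_mediators_gives_three_rows(self, graph, small_fits):
        table = decompose(graph, small_fits, "label", "sweetness")
        assert len(effects_report([table])) == 3

    def test_round_trip_of_estimates(self, graph, small_fits):
        table = decompose(graph, small_fits, "label", "tastiness")
        report = effects_report([table])
        direct = report.loc[report["effect_type"] == "Direct", "estimate"].iloc[0]
        total = report.loc[report["effect_type"] == "Total", "estimate"].iloc[0]
        assert direct == table.direct
        assert total == table.total
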