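"""Piecewise SEM: graph structure, node fits, d-separation, Fisher's C."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import interpolation_config, small_config, zero_noise
from sugarsem.psem import (
    CausalGraph,
    IndependenceClaim,
    basis_set,
    default_graph,
    dsep_test,
    fishers_c,
    fit_all,
    fit_node,
    graph_from_dict,
)
from sugarsem.synthetic import GENERATION_ORDER, simulate_experiment


class TestDefaultGraph:
    def test_fifteen_edges(self, graph):
        assert len(graph.edges) == 15

    def test_acyclic_and_topologically_ordered(self, graph):
        topo = graph.topological_order()
        pos = {n: i for i, n in enumerate(topo)}
        assert all(pos[u] < pos[v] for u, v in graph.edges)

    def test_bid_parents(self, graph):
        assert set(graph.parents("bid")) == {
            "label", "familiarity", "sweetness", "healthiness", "tastiness",
        }

    def test_controls_and_grouping(self, graph):
        for node in GENERATION_ORDER:
            assert graph.grouping[node] == ("subject_id", "pair_id")
            assert "gender" in graph.controls[node] and "age" in graph.controls[node]
        assert "trial_index" in graph.controls["bid"]
        assert "trial_index" not in graph.controls["sweetness"]

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CausalGraph(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))


class TestFitNode:
    @pytest.mark.parametrize("node", GENERATION_ORDER)
    def test_interpolation_limit_recovers_generating_coefficients(self, node, graph):
        # zero noise in the fitted equation -> exact interpolation of its
        # parents, recovering every coefficient to numerical precision
        cfg = interpolation_config(node)
        ds = simulate_experiment(cfg)
        fit = fit_node(ds, graph, node)
        for pred, beta in cfg.coefficients[node].items():
            assert fit.coefficient(pred) == pytest.approx(beta, abs=1e-6)

    def test_fully_noiseless_sweetness_fit_is_exact(self, noiseless_dataset, graph):
        # sweetness has only exogenous parents, so the all-zero-noise limit
        # is well-posed for it
        cfg = zero_noise(small_config(seed=5))
        fit = fit_node(noiseless_dataset, graph, "sweetness")
        for pred, beta in cfg.coefficients["sweetness"].items():
            assert fit.coefficient(pred) == pytest.approx(beta, abs=1e-6)

    def test_label_coefficient_recovery_on_default_data(self, default_dataset, graph):
        fit = fit_node(default_dataset, graph, "sweetness")
        est = fit.coefficient("label")
        se = float(fit.params.at["label", "se"])
        assert abs(est - (-0.518)) < 3 * se

    def test_n_obs_on_default_design(self, default_dataset, graph):
        assert fit_node(default_dataset, graph, "sweetness").n_obs == 3000

    def test_exogenous_node_rejected(self, small_dataset, graph):
        with pytest.raises(ValueError, match="endogenous"):
            fit_node(small_dataset, graph, "label")


class TestFitAll:
    def test_five_fits_in_topological_order(self, small_dataset, graph):
        fits = fit_all(small_dataset, graph)
        assert [f.response for f in fits] == list(GENERATION_ORDER)

    def test_total_aic_is_sum_of_node_aics(self, small_dataset, graph):
        from sugarsem.pipeline import _model_stats

        fits = fit_all(small_dataset, graph)
        stats_df = _model_stats(fits)
        total = stats_df.loc[stats_df["response"] == "TOTAL", "aic"].iloc[0]
        assert total == pytest.approx(sum(f.aic for f in fits))


class TestBasisSet:
    def test_default_graph_has_four_trial_index_claims(self, graph):
        claims = basis_set(graph)
        assert len(claims) == 4
        assert all(c.x == "trial_index" for c in claims)
        assert {c.y for c in claims} == {
            "familiarity", "sweetness", "healthiness", "tastiness",
        }

    def test_chain_yields_one_claim(self):
        g = CausalGraph(nodes=("a", "b", "c"), edges=(("a", "b"), ("b", "c")))
        claims = basis_set(g)
        assert len(claims) == 1
        assert (claims[0].x, claims[0].y) == ("a", "c")
        assert claims[0].conditioning_set == ("b",)

    def test_complete_graph_yields_no_claims(self):
        g = CausalGraph(
            nodes=("a", "b", "c"), edges=(("a", "b"), ("b", "c"), ("a", "c"))
        )
        assert basis_set(g) == []

    def test_invariant_to_edge_listing_order(self, graph):
        shuffled = CausalGraph(
            nodes=graph.nodes,
            edges=tuple(reversed(graph.edges)),
            controls=graph.controls,
            grouping=graph.grouping,
        )
        assert basis_set(shuffled) == basis_set(graph)


class TestDsepTest:
    def test_detects_an_omitted_dependence(self, graph):
        # generate data where the bidding position genuinely shifts
        # sweetness: the claimed independence must be rejected
        cfg = small_config(seed=21)
        cfg.coefficients["sweetness"]["trial_index"] = 0.5
        for eq in cfg.residual_sd:
            cfg.residual_sd[eq] = 0.3
        ds = simulate_experiment(cfg)
        claim = [c for c in basis_set(graph) if c.y == "sweetness"][0]
        assert dsep_test(ds, graph, claim).p_value < 0.01

    def test_conditioning_set_recorded_verbatim(self, small_dataset, graph):
        claim = basis_set(graph)[0]
        tested = dsep_test(small_dataset, graph, claim)
        assert tested.conditioning_set == claim.conditioning_set
        assert 0 <= tested.p_value <= 1


class TestFishersC:
    @staticmethod
    def _claims(ps):
        return [
            IndependenceClaim(x="x", y=f"y{i}", conditioning_set=(), p_value=p)
            for i, p in enumerate(ps)
        ]

    def test_all_ones(self):
        gof = fishers_c(self._claims([1.0, 1.0]))
        assert gof.C == 0.0 and gof.df == 4 and gof.p_value == 1.0

    def test_closed_form_two_claims(self):
        gof = fishers_c(self._claims([0.05, 0.05]))
        assert gof.C == pytest.approx(-4 * math.log(0.05), rel=1e-12)
        assert gof.C == pytest.approx(11.983, abs=5e-4)
        assert gof.p_value == pytest.approx(0.0175, abs=5e-4)

    def test_single_half(self):
        gof = fishers_c(self._claims([0.5]))
        assert gof.C == pytest.approx(-2 * math.log(0.5), rel=1e-12)
        assert gof.df == 2

    def test_empty_convention(self):
        gof = fishers_c([])
        assert (gof.C, gof.df, gof.p_value) == (0.0, 0, 1.0)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fishers_c(self._claims([0.0, 0.5]))

    @given(
        ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
        idx=st.integers(0, 5),
        shrink=st.floats(0.1, 0.9),
    )
    def test_monotone_in_each_p(self, ps, idx, shrink):
        idx = idx % len(ps)
        before = fishers_c(self._claims(ps))
        ps2 = list(ps)
        ps2[idx] = ps2[idx] * shrink
        after = fishers_c(self._claims(ps2))
        assert after.C > before.C
        assert after.p_value <= before.p_value
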