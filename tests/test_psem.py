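import networkx as nx
import numpy as np
import pandas as pd
import pytest

from udpharm.herbfx import EffectModel
from udpharm import psem
from udpharm.psem import (
    GraphError,
    IndependenceClaim,
    PathDag,
    basis_set,
    build_initial_dag,
    fishers_c,
    fit_psem,
    prune_paths,
)

CHAIN = PathDag(
    edges=(("X", "M"), ("M", "Y")),
    roles={"X": "term", "M": "mediator", "Y": "outcome"},
)
TRIANGLE = PathDag(
    edges=(("X", "M"), ("X", "Y"), ("M", "Y")),
    roles={"X": "term", "M": "mediator", "Y": "outcome"},
)


def _chain_frame(rng, n=200, beta_xy=0.0):
    x = rng.normal(0, 1, n)
    m = 0.8 * x + rng.normal(0, 0.6, n)
    y = 0.8 * m + beta_xy * x + rng.normal(0, 0.6, n)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


class TestPathDag:
    def test_cycle_rejected(self):
        with pytest.raises(GraphError, match="cycle"):
            PathDag(edges=(("A", "B"), ("B", "A")), roles={"A": "mediator",
                                                           "B": "mediator"})

    def test_exogenous_term_with_parent_rejected(self):
        with pytest.raises(GraphError, match="parents"):
            PathDag(edges=(("M", "X"),), roles={"X": "term", "M": "mediator"})


class TestBuildInitialDag:
    def _model(self, terms, response="Y_MRS"):
        return EffectModel(
            response=response, terms=tuple(terms), intercept=0.0,
            coefficients={t: 1.0 for t in terms},
            std_coefficients={t: 1.0 for t in terms},
            pvalues={t: 0.01 for t in terms},
            r_squared=0.9, model_pvalue=0.01, n_obs=7,
        )

    def test_saturated_triangle_from_one_term_one_mediator(self):
        dag = build_initial_dag([self._model(["ZR^2"])], {"Y_MRS": ["NFkB_L"]})
        assert set(dag.edges) == {
            ("ZR^2", "Y_MRS"), ("ZR^2", "NFkB_L"), ("NFkB_L", "Y_MRS")
        }

    def test_no_mediators_gives_direct_edges_only(self):
        dag = build_initial_dag([self._model(["ZR", "ZR*PR"])], {})
        assert set(dag.edges) == {("ZR", "Y_MRS"), ("ZR*PR", "Y_MRS")}
        assert dag.roles["ZR"] == "term"

    def test_two_term_liver_mediation_topology(self):
        # herb terms -> hepatic mediator -> mucosal repair score
        dag = build_initial_dag(
            [self._model(["ZR*PR", "ZR^2"])], {"Y_MRS": ["NFkB_L"]}
        )
        assert dag.roles == {
            "ZR*PR": "term", "ZR^2": "term",
            "NFkB_L": "mediator", "Y_MRS": "outcome",
        }
        assert len(dag.edges) == 5
        assert nx.is_directed_acyclic_graph(dag.graph)

    def test_name_collision_rejected(self):
        with pytest.raises(GraphError, match="collision"):
            build_initial_dag([self._model(["ZR"])], {"Y_MRS": ["ZR"]})


class TestBasisSet:
    def test_chain_yields_single_textbook_claim(self):
        claims = basis_set(CHAIN)
        assert claims == [IndependenceClaim(x="X", y="Y", conditioning=("M",))]

    def test_saturated_triangle_has_empty_basis(self):
        assert basis_set(TRIANGLE) == []

    def test_parallel_mediators_diamond(self):
        dag = PathDag(
            edges=(("X", "M1"), ("X", "M2"), ("M1", "Y"), ("M2", "Y")),
            roles={"X": "term", "M1": "mediator", "M2": "mediator",
                   "Y": "outcome"},
        )
        claims = basis_set(dag)
        assert IndependenceClaim(x="M1", y="M2", conditioning=("X",)) in claims
        assert IndependenceClaim(x="X", y="Y", conditioning=("M1", "M2")) in claims
        assert len(claims) == 2

    def test_claims_are_valid_dseparations(self, rng):
        # every emitted claim must hold in the graph (networkx as oracle)
        for trial in range(20):
            n = int(rng.integers(3, 6))
            nodes = [f"v{i}" for i in range(n)]
            edges = tuple(
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            )
            dag = PathDag(edges=edges, roles={v: "mediator" for v in nodes})
            g = dag.graph
            for c in basis_set(dag):
                assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.conditioning))


class TestClaimTest:
    def test_perfect_dependence(self, rng):
        x = rng.normal(0, 1, 40)
        data = pd.DataFrame({"X": x, "Y": x})
        claim = IndependenceClaim(x="X", y="Y", conditioning=())
        assert psem.test_claim(claim, data) < 1e-10

    def test_duplicated_conditioning_deduplicated(self, rng):
        data = _chain_frame(rng, n=80)
        a = psem.test_claim(IndependenceClaim("X", "Y", ("M",)), data)
        b = psem.test_claim(IndependenceClaim("X", "Y", ("M", "M")), data)
        assert a == b

    def test_too_few_observations_rejected(self, rng):
        data = _chain_frame(rng, n=4)
        with pytest.raises(ValueError):
            psem.test_claim(IndependenceClaim("X", "Y", ("M",)), data)


class TestFishersC:
    def test_single_claim_closed_form(self):
        c, df, p = fishers_c([0.5])
        assert c == pytest.approx(-2 * np.log(0.5))
        assert df == 2
        assert p == pytest.approx(0.5)

    def test_empty_is_saturated_convention(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    @pytest.mark.parametrize(
        "c_stat,k,p_printed",
        [(2.569, 1, 0.277), (0.052, 1, 0.974), (0.356, 1, 0.837),
         (2.720, 2, 0.606), (1.923, 2, 0.750)],
    )
    def test_reported_caption_pairs(self, c_stat, k, p_printed):
        # invert C back to equal per-claim p-values, then forward again
        p_each = np.exp(-c_stat / (2 * k))
        c, df, p = fishers_c([p_each] * k)
        assert c == pytest.approx(c_stat, abs=1e-9)
        assert df == 2 * k
        assert p == pytest.approx(p_printed, abs=5e-4)

    def test_zero_pvalue_clamped_not_fatal(self):
        c, df, p = fishers_c([0.0, 0.5])
        assert np.isfinite(c) and 0 <= p <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([1.5])


class TestFitPsem:
    def test_saturated_model_has_zero_c(self, rng):
        data = _chain_frame(rng, n=100, beta_xy=0.4)
        fit = fit_psem(TRIANGLE, data)
        assert fit.c_statistic == 0.0
        assert fit.p_value == 1.0
        # K: M~X -> 3 params; Y~X,M -> 4 params
        assert fit.n_params == 7
        assert fit.aic == pytest.approx(2 * 7)

    def test_aic_identity_recomputed(self, rng):
        data = _chain_frame(rng, n=120)
        fit = fit_psem(CHAIN, data)
        k_manual = sum(
            len(comp.parents) + 2 for comp in fit.components
        )
        assert fit.aic == pytest.approx(fit.c_statistic + 2 * k_manual)

    def test_component_coefficients_recover_truth(self, rng):
        data = _chain_frame(rng, n=4000)
        fit = fit_psem(CHAIN, data)
        comp = {c.response: c for c in fit.components}
        assert comp["M"].coefficients["X"] == pytest.approx(0.8, abs=0.05)
        assert comp["Y"].coefficients["M"] == pytest.approx(0.8, abs=0.05)


class TestPrunePaths:
    def test_all_significant_is_fixed_point(self, rng):
        data = _chain_frame(rng, n=300)
        fit = fit_psem(CHAIN, data)
        pruned, log = prune_paths(fit, data)
        assert log == []
        assert pruned.paths.equals(fit.paths)

    def test_pure_noise_path_removed(self, rng):
        data = _chain_frame(rng, n=300)
        data["Z"] = rng.normal(0, 1, 300)  # unrelated variable
        dag = PathDag(
            edges=(("X", "M"), ("M", "Y"), ("Z", "Y")),
            roles={"X": "term", "M": "mediator", "Z": "term", "Y": "outcome"},
        )
        fit = fit_psem(dag, data)
        pruned, log = prune_paths(fit, data)
        assert [(r["from"], r["to"]) for r in log] == [("Z", "Y")]
        assert "Z" not in pruned.dag.nodes

    def test_removal_log_length_matches_edge_difference(self, rng):
        data = pd.DataFrame(rng.normal(0, 1, (60, 4)), columns=list("ABCD"))
        dag = PathDag(
            edges=(("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")),
            roles={"A": "term", "B": "mediator", "C": "mediator",
                   "D": "outcome"},
        )
        fit = fit_psem(dag, data)
        pruned, log = prune_paths(fit, data)
        assert len(log) == len(dag.edges) - len(pruned.dag.edges)

    def test_pruning_to_empty_is_flagged_not_raised(self, rng):
        data = pd.DataFrame(rng.normal(0, 1, (50, 2)), columns=["A", "B"])
        dag = PathDag(edges=(("A", "B"),), roles={"A": "term", "B": "outcome"})
        pruned, log = prune_paths(fit_psem(dag, data), data)
        assert pruned.empty
        assert len(log) == 1
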