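"""Conditional-Gaussian scoring, constraints, neighborhoods and search."""

import math

import numpy as np
import pandas as pd
import pytest

from cgbnet import CohortTable
from cgbnet.bn import (
    ConstraintError,
    ConstraintSet,
    Dag,
    Node,
    Scorer,
    SizeLimitError,
    drug_trial_constraints,
    enumerate_dags,
    exhaustive_best,
    hill_climb,
    neighbors,
    validate,
)
from cgbnet.bn import apply_op

from conftest import chain_cohort, continuous_cohort, make_nodes, random_mixed_problem


class TestLocalScore:
    def test_single_gaussian_node_closed_form(self, rng):
        x = rng.normal(2.0, 1.5, size=200)
        co = continuous_cohort({"X": x})
        sc = Scorer(co)
        n = x.size
        sigma2 = x.var()  # MLE
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        expected = loglik - (2 / 2) * math.log(n)  # mean + variance
        assert sc.local_score("X") == pytest.approx(expected, rel=1e-12)

    def test_multinomial_closed_form(self):
        vals = ["a"] * 30 + ["b"] * 70
        co = CohortTable(pd.DataFrame({"D": vals}), {"D": "discrete"})
        expected = 30 * math.log(0.3) + 70 * math.log(0.7) - 0.5 * math.log(100)
        assert Scorer(co).local_score("D") == pytest.approx(expected, rel=1e-12)

    def test_score_equivalence_two_nodes(self, rng):
        x = rng.normal(size=500)
        y = 0.8 * x + rng.normal(size=500)
        sc = Scorer(continuous_cohort({"X": x, "Y": y}))
        fwd = sc.local_score("X") + sc.local_score("Y", {"X"})
        bwd = sc.local_score("Y") + sc.local_score("X", {"Y"})
        assert fwd == pytest.approx(bwd, abs=1e-8)

    def test_cg_violation_raises(self, rng):
        co = CohortTable(
            pd.DataFrame({"X": rng.normal(size=50), "D": rng.integers(0, 2, 50)}),
            {"X": "continuous", "D": "discrete"},
        )
        with pytest.raises(ConstraintError):
            Scorer(co).local_score("D", {"X"})

    def test_discrete_parent_partitions_gaussian_fit(self, rng):
        """Score with a binary parent equals the sum of per-group Gaussian
        fits minus the doubled parameter penalty."""
        d = rng.integers(0, 2, 400)
        x = rng.normal(size=400) + 2.0 * d
        co = CohortTable(
            pd.DataFrame({"X": x, "D": d}), {"X": "continuous", "D": "discrete"}
        )
        sc = Scorer(co)
        loglik = 0.0
        for lev in (0, 1):
            xs = x[d == lev]
            loglik += -0.5 * xs.size * (math.log(2 * math.pi * xs.var()) + 1)
        expected = loglik - 0.5 * 4 * math.log(400)  # (mean+var) per configuration
        assert sc.local_score("X", {"D"}) == pytest.approx(expected, rel=1e-12)


class TestValidate:
    CONS = drug_trial_constraints(["rs1"], ["cgA"])

    def _nodes(self):
        return make_nodes(
            TG2="continuous", TG4="continuous", rs1="discrete", cgA="continuous",
            sex="discrete", center="discrete",
        )

    def test_blacklisted_edge_reported(self):
        dag = Dag(self._nodes(), [("TG2", "TG4"), ("cgA", "TG2")])
        assert any("blacklisted" in v for v in validate(dag, self.CONS))

    def test_missing_whitelist_edge_reported(self):
        dag = Dag(self._nodes(), [])
        assert any("missing whitelist" in v for v in validate(dag, self.CONS))

    def test_no_parent_violation_reported(self):
        dag = Dag(self._nodes(), [("TG2", "TG4"), ("sex", "rs1")])
        assert any("no-parent" in v for v in validate(dag, self.CONS))

    def test_empty_dag_empty_constraints_ok(self):
        dag = Dag(make_nodes(A="continuous", B="continuous"))
        assert validate(dag, ConstraintSet.empty()) == []


class TestNeighbors:
    def test_two_free_nodes_two_adds(self):
        dag = Dag(make_nodes(A="continuous", B="continuous"))
        ops = neighbors(dag, ConstraintSet.empty())
        assert ops == [("add", "A", "B"), ("add", "B", "A")]

    def test_no_additions_into_no_parent_node(self):
        dag = Dag(make_nodes(S="discrete", X="continuous", Y="continuous"))
        cons = ConstraintSet(no_parent_nodes=frozenset({"S"}))
        for kind, u, v in neighbors(dag, cons):
            assert not (kind == "add" and v == "S")

    def test_full_three_node_dag_matches_brute_force(self):
        nodes = make_nodes(X="continuous", Y="continuous", Z="continuous")
        dag = Dag(nodes, [("X", "Y"), ("X", "Z"), ("Y", "Z")])
        ops = neighbors(dag, ConstraintSet.empty())
        assert sum(1 for o in ops if o[0] == "add") == 0
        assert sum(1 for o in ops if o[0] == "delete") == 3
        # oracle: a reverse is valid iff the modified graph passes validate()
        valid_reverses = []
        for u, v in dag.edges():
            g = dag.copy()
            g.remove_edge(u, v)
            g._parents[u].add(v)
            if not validate(g, ConstraintSet.empty()):
                valid_reverses.append(("reverse", u, v))
        assert [o for o in ops if o[0] == "reverse"] == sorted(valid_reverses)

    def test_every_operation_yields_valid_dag(self):
        cons = ConstraintSet(
            whitelist=frozenset({("A", "B")}), blacklist=frozenset({("C", "A")}),
            no_parent_nodes=frozenset({"D"}),
        )
        dag = Dag(make_nodes(A="continuous", B="continuous", C="continuous", D="discrete"),
                  [("A", "B")])
        for _ in range(30):  # walk the neighborhood graph a bit
            ops = neighbors(dag, cons)
            if not ops:
                break
            op = ops[len(ops) // 2]
            g = dag.copy()
            apply_op(g, op)
            assert validate(g, cons) == [], (op, validate(g, cons))
            dag = g


class TestEnumeration:
    def test_counts_without_constraints(self):
        two = make_nodes(A="continuous", B="continuous")
        three = make_nodes(A="continuous", B="continuous", C="continuous")
        assert len(list(enumerate_dags(two))) == 3
        assert len(list(enumerate_dags(three))) == 25

    def test_count_with_no_parent_constraint(self):
        # brute force over all 64 directed-pair configurations: 2 states each
        # for A->B and A->C, 3 for B-C, all acyclic => 12
        three = make_nodes(A="continuous", B="continuous", C="continuous")
        cons = ConstraintSet(no_parent_nodes=frozenset({"A"}))
        assert len(list(enumerate_dags(three, cons))) == 12

    def test_all_enumerated_dags_valid_and_unique(self):
        nodes = make_nodes(A="continuous", B="continuous", S="discrete")
        cons = ConstraintSet(no_parent_nodes=frozenset({"S"}))
        dags = list(enumerate_dags(nodes, cons))
        assert all(validate(d, cons) == [] for d in dags)
        assert len({tuple(d.edges()) for d in dags}) == len(dags)

    def test_size_guard(self):
        nodes = make_nodes(**{f"N{i}": "continuous" for i in range(6)})
        with pytest.raises(SizeLimitError):
            list(enumerate_dags(nodes))


class TestHillClimb:
    def test_single_node_empty_graph(self, rng):
        co = continuous_cohort({"X": rng.normal(size=100)})
        sc = Scorer(co)
        net = hill_climb(sc, rng=np.random.default_rng(1))
        assert net.dag.edges() == []
        assert net.total == pytest.approx(sc.local_score("X"))

    def test_chain_recovers_exhaustive_optimum(self):
        co = chain_cohort(2000, seed=5)
        sc = Scorer(co)
        net = hill_climb(sc, restarts=5, rng=np.random.default_rng(2))
        oracle = exhaustive_best(sc)
        assert net.total == pytest.approx(oracle.total, abs=1e-9)
        # the optimum lies in the chain's equivalence class: X-Y and Y-Z adjacent
        pairs = {tuple(sorted(e)) for e in net.dag.edges()}
        assert pairs == {("X", "Y"), ("Y", "Z")}

    def test_monotone_score_trace(self):
        co = chain_cohort(500, seed=8)
        net = hill_climb(co, restarts=0, rng=np.random.default_rng(3))
        assert all(b > a for a, b in zip(net.trace, net.trace[1:]))

    def test_decomposability_incremental_equals_full(self):
        co = random_mixed_problem(99, n_rows=200)
        sc = Scorer(co)
        cons = ConstraintSet.empty()
        net = hill_climb(sc, restarts=0, rng=np.random.default_rng(4))
        dag = net.dag
        for op in neighbors(dag, cons)[:10]:
            g = dag.copy()
            apply_op(g, op)
            full = sum(sc.local_score(n.name, g.parents(n.name)) for n in g.nodes)
            kind, u, v = op
            delta = sc.local_score(v, g.parents(v)) - sc.local_score(v, dag.parents(v))
            if kind == "reverse":
                delta += sc.local_score(u, g.parents(u)) - sc.local_score(u, dag.parents(u))
            assert full == pytest.approx(net.total + delta, abs=1e-9)

    def test_constraints_always_respected(self, small_cohort):
        cohort, _, cfg = small_cohort
        snps = [s.name for s in cfg.snps]
        cpgs = [s.paired_cpg for s in cfg.snps]
        sub = cohort.select(["age", "sex", "center", "TG2", "TG4"] + snps + cpgs)
        cons = drug_trial_constraints(snps, cpgs)
        net = hill_climb(sub, cons, restarts=1, rng=np.random.default_rng(6))
        assert validate(net.dag, cons) == []
        assert net.dag.has_edge("TG2", "TG4")
        for s in snps:
            assert net.dag.parents(s) == frozenset()

    def test_oracle_equivalence_on_random_problems(self):
        hits = 0
        for seed in range(20):
            sc = Scorer(random_mixed_problem(1000 + seed))
            hc = hill_climb(sc, restarts=20, rng=np.random.default_rng(seed))
            ex = exhaustive_best(sc)
            hits += abs(hc.total - ex.total) < 1e-9
        assert hits >= 19

    def test_unmapped_constraint_column_errors(self, rng):
        co = continuous_cohort({"X": rng.normal(size=50)})
        cons = ConstraintSet(whitelist=frozenset({("X", "nope")}))
        with pytest.raises(Exception, match="unknown column"):
            hill_climb(co, cons, rng=np.random.default_rng(0))


class TestConstraintSet:
    def test_whitelist_blacklist_overlap_rejected(self):
        with pytest.raises(ConstraintError):
            ConstraintSet(whitelist=frozenset({("A", "B")}), blacklist=frozenset({("A", "B")}))

    def test_whitelist_into_no_parent_rejected(self):
        with pytest.raises(ConstraintError):
            ConstraintSet(whitelist=frozenset({("A", "B")}), no_parent_nodes=frozenset({"B"}))

    def test_cyclic_whitelist_rejected(self):
        with pytest.raises(ConstraintError):
            ConstraintSet(whitelist=frozenset({("A", "B"), ("B", "A")}))
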