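"""The 16-model atlas: module algebra, phases, classes, corners, random maps."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from majorules import (
    Configuration,
    ModuleSpec,
    Rule,
    TwoNodeModel,
    atlas_classes,
    enumerate_models,
    ergodic_sets,
    isomorphic,
    logic_corner_table,
    module_table,
    phase_of,
    random_map_sampler,
    rho_rotate,
    stationary_and_return_times,
    support_digraph,
)
from majorules.two_node_atlas import MODULES, convergence_census

from conftest import GENERIC, HALF


class TestEnumeration:
    def test_sixteen_models(self):
        models = enumerate_models(Rule.MR)
        assert len(models) == 16
        assert len({(m.module_1, m.module_2) for m in models}) == 16

    def test_node_symmetry_orbits(self):
        """Swapping modules partitions the 16 models into 6 pairs + 4 fixed."""
        models = enumerate_models(Rule.MR)
        swap = {(m.module_1, m.module_2): (m.module_2, m.module_1) for m in models}
        fixed = [k for k, v in swap.items() if k == v]
        assert len(fixed) == 4
        paired = {frozenset((k, v)) for k, v in swap.items() if k != v}
        assert len(paired) == 6

    def test_all_matrices_are_4x4_row_stochastic(self):
        for m in enumerate_models(Rule.MR):
            tm = m.transition_model(*GENERIC)
            assert tm.size == 4
            assert all(sum(r.values()) == 1 for r in tm.rows)


class TestRhoRotation:
    def test_rho_has_order_four(self):
        for m in MODULES:
            x = m
            for _ in range(4):
                x = rho_rotate(x)
            assert x == m

    def test_four_modules_form_a_single_orbit(self):
        orbit = {MODULES[0]}
        x = MODULES[0]
        for _ in range(3):
            x = rho_rotate(x)
            orbit.add(x)
        assert orbit == set(MODULES)

    def test_rho_commutes_with_the_update_table(self):
        """Table of rho(m) equals the row-rotated table of m, all 4 cases."""

        def rotated(t):
            return (t[-1],) + t[:-1]

        for m in MODULES:
            assert module_table(rho_rotate(m)) == rotated(module_table(m))


class TestPhase:
    def test_symmetric_cross_self_activation_is_in_phase(self):
        m = TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(1, 1))
        assert phase_of(m) == "IP"

    def test_asymmetric_cross_is_out_of_phase(self):
        m = TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(1, -1))
        assert phase_of(m) == "OP"

    def test_eight_ip_and_eight_op(self):
        phases = [phase_of(m) for m in enumerate_models(Rule.MR)]
        assert phases.count("IP") == 8
        assert phases.count("OP") == 8

    def test_phase_agrees_with_tie_row_alignment(self):
        """Row-pattern phase equals the structural sign-product criterion."""
        for m in enumerate_models(Rule.MR):
            structural = (
                "IP"
                if m.module_1.self_sign * m.module_1.cross_sign
                == m.module_2.self_sign * m.module_2.cross_sign
                else "OP"
            )
            assert phase_of(m) == structural

    def test_transition_counts_by_phase(self):
        for m in enumerate_models(Rule.MR):
            g = support_digraph(m.transition_model(*GENERIC), generic=True)
            assert g.number_of_edges() == (10 if phase_of(m) == "IP" else 8)


class TestIsomorphism:
    def test_every_model_isomorphic_to_itself(self):
        for m in enumerate_models(Rule.MR)[:4]:
            ok, witness = isomorphic(m, m)
            assert ok

    def test_the_two_ip1_members_are_isomorphic(self):
        a = TwoNodeModel(ModuleSpec(1, 1), ModuleSpec(1, 1))
        b = TwoNodeModel(ModuleSpec(1, -1), ModuleSpec(1, -1))
        ok, witness = isomorphic(a, b)
        assert ok and witness is not None

    def test_no_ip_model_is_isomorphic_to_an_op_model(self):
        models = enumerate_models(Rule.MR)
        ip = [m for m in models if phase_of(m) == "IP"]
        op = [m for m in models if phase_of(m) == "OP"]
        ok, _ = isomorphic(ip[0], op[0])
        assert not ok


class TestAtlasClasses:
    @pytest.mark.parametrize("rule", [Rule.MR, Rule.IMR])
    def test_three_ip_and_three_op_classes_with_sizes_2_2_4(self, rule):
        classes = atlas_classes(rule)
        sizes = {c.label: len(c.members) for c in classes}
        assert sizes == {"IP1": 2, "IP2": 2, "IP3": 4, "OP1": 2, "OP2": 2, "OP3": 4}

    def test_imr_reproduces_the_mr_class_structure(self):
        mr = {c.label: {(m.module_1, m.module_2) for m in c.members}
              for c in atlas_classes(Rule.MR)}
        imr = {c.label: {(m.module_1, m.module_2) for m in c.members}
               for c in atlas_classes(Rule.IMR)}
        assert mr == imr

    def test_ip1_members_are_the_positive_circuit_self_activation_models(self):
        (ip1_cls,) = [c for c in atlas_classes(Rule.MR) if c.label == "IP1"]
        members = {(m.module_1, m.module_2) for m in ip1_cls.members}
        assert members == {
            (ModuleSpec(1, 1), ModuleSpec(1, 1)),
            (ModuleSpec(1, -1), ModuleSpec(1, -1)),
        }


class TestRuleVariants:
    def test_nmr_balanced_module_models_equal_their_mr_counterparts(self):
        balanced = [ModuleSpec(1, -1), ModuleSpec(-1, 1)]
        for m1, m2 in itertools.product(balanced, balanced):
            mr = TwoNodeModel(m1, m2, Rule.MR).transition_model(*GENERIC)
            nmr = TwoNodeModel(m1, m2, Rule.NMR).transition_model(*GENERIC)
            assert mr.rows == nmr.rows

    def test_nmr_convergence_census(self):
        """11 of the 16 null-rule models converge to a small attractor."""
        census = convergence_census(Rule.NMR)
        assert census["small_attractor"] == 11
        assert census["absorbing_extended"] == 9
        assert census["regular"] == 5

    def test_mr_census_matches_class_dynamics(self):
        census = convergence_census(Rule.MR)
        assert census["absorbing_extended"] == 4  # IP1 + IP2
        assert census["regular"] == 12  # IP3 and all OP models

    def test_imr_supports_match_mr_supports(self):
        for m1, m2 in itertools.product(MODULES, MODULES):
            mr = TwoNodeModel(m1, m2, Rule.MR).transition_model(*GENERIC)
            imr = TwoNodeModel(m1, m2, Rule.IMR).transition_model(*GENERIC)
            assert [set(r) for r in mr.rows] == [set(r) for r in imr.rows]

    def test_op_loop_probabilities_complementary_under_mr_equal_under_imr(self):
        """At the two states where one node ties onto itself, the MR loops
        carry x and 1-x while the IMR (keep) loops are both equal."""
        p, q = GENERIC
        for m in enumerate_models(Rule.MR):
            if phase_of(m) != "OP":
                continue
            mr = m.transition_model(p, q)
            imr = TwoNodeModel(m.module_1, m.module_2, Rule.IMR).transition_model(p, q)
            mr_loops = sorted(mr.rows[i][i] for i in range(4) if i in mr.rows[i])
            imr_loops = sorted(imr.rows[i][i] for i in range(4) if i in imr.rows[i])
            assert len(mr_loops) == len(imr_loops)
            assert len(mr_loops) in (0, 2, 4)
            # MR: loops come in complementary pairs x, 1-x
            for k in range(len(mr_loops) // 2):
                assert mr_loops[k] + mr_loops[-1 - k] == 1
            # IMR (keep): the two loops of each tied node are equal
            for k in range(0, len(imr_loops), 2):
                assert imr_loops[k] == imr_loops[k + 1]

    def test_pure_cross_circuit_is_fully_deterministic(self):
        """Two-interaction circuits have odd in-degrees: no tie ever occurs."""
        from majorules import RegulatoryNetwork, SignedEdge, probabilistic_nodes

        net = RegulatoryNetwork(
            nodes=("g1", "g2"),
            edges=frozenset({SignedEdge("g1", "g2", 1), SignedEdge("g2", "g1", -1)}),
        )
        assert probabilistic_nodes(net) == ()


class TestLogicCorners:
    def test_ip1_corner_connectors(self, ip1):
        table = logic_corner_table(ip1)
        assert table[(0, 0)] == ("AND", "AND")
        assert table[(1, 1)] == ("OR", "OR")
        assert table[(1, 0)] == ("OR", "AND")
        assert table[(0, 1)] == ("AND", "OR")

    def test_connectors_identified_for_all_models(self):
        for m in enumerate_models(Rule.MR):
            for connectors in logic_corner_table(m).values():
                assert set(connectors) <= {"AND", "OR"}


class TestRandomMapRealisation:
    def test_corner_probabilities_at_half_are_uniform(self, ip1):
        sampler = random_map_sampler(ip1, *HALF, seed=0)
        assert all(sampler.corner_probability(c) == Fraction(1, 4) for c in sampler.corners)

    def test_degenerate_corner_always_draws_ties_high_map(self, ip1):
        sampler = random_map_sampler(ip1, Fraction(1), Fraction(1), seed=0)
        assert all(sampler.draw_corner() == (1, 1) for _ in range(20))

    def test_one_step_law_matches_matrix_row(self, ip1):
        """10^5 random-map draws reproduce the matrix row within 3 stderr."""
        p, q = Fraction(1, 3), Fraction(2, 3)
        tm = ip1.transition_model(p, q)
        sampler = random_map_sampler(ip1, p, q, seed=11)
        start = tm.index.to_config(2)  # a tied state
        n = 100_000
        counts = {}
        for _ in range(n):
            nxt = sampler.step(start)
            counts[nxt.values] = counts.get(nxt.values, 0) + 1
        for j, prob in tm.rows[2].items():
            expect = float(prob)
            se = (expect * (1 - expect) / n) ** 0.5
            observed = counts.get(tm.index.to_config(j).values, 0) / n
            assert abs(observed - expect) <= 3 * se

    def test_exact_one_step_law_from_corner_products(self, ip1):
        """Summing corner probabilities per successor equals the row exactly."""
        p, q = GENERIC
        tm = ip1.transition_model(p, q)
        sampler = random_map_sampler(ip1, p, q, seed=0)
        for i in range(4):
            start = tm.index.to_config(i)
            law = {}
            for corner in sampler.corners:
                nxt = sampler.maps[corner](start).values
                law[nxt] = law.get(nxt, Fraction(0)) + sampler.corner_probability(corner)
            got = {tm.index.to_config(j).values: pr for j, pr in tm.rows[i].items()}
            assert law == got


class TestOP2CycleWeights:
    def test_period3_weight_grows_toward_extremes_period4_peaks_at_half(self):
        m = TwoNodeModel(ModuleSpec(-1, 1), ModuleSpec(-1, -1))
        assert phase_of(m) == "OP"

        def weights(t):
            tm = m.transition_model(t, t)
            g = support_digraph(tm)
            w3 = w4 = 0.0
            for cyc in nx.simple_cycles(g):
                if len(cyc) in (3, 4):
                    w = 1.0
                    for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                        w *= float(tm.rows[a][b])
                    if len(cyc) == 3:
                        w3 += w
                    else:
                        w4 += w
            return w3, w4

        grid = [Fraction(k, 10) for k in (1, 3, 5, 7, 9)]
        w3s, w4s = zip(*(weights(t) for t in grid))
        # period-3 weight is minimal at 1/2 and increases toward extremes
        assert w3s[2] < w3s[1] < w3s[0]
        assert w3s[2] < w3s[3] < w3s[4]
        # period-4 weight peaks at intermediate parameters
        assert w4s[2] > w4s[0] and w4s[2] > w4s[4]
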