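import math

import pytest

from conftest import enumerate_terminals, seed_roots
from winfunnel import parse_smiles
from winfunnel.chem import Molecule
from winfunnel.fixtures import gen_smiles_library
from winfunnel.generator import (COMPATIBILITY, FragmentLibrary, SearchNode,
                                 SearchState, apply_action, brics_decompose,
                                 cleave_bond, default_reward,
                                 enumerate_actions, find_cleavable_bonds,
                                 join_fragments, mcts_generate, uct_select)


class TestBricsDecompose:
    def test_methane_is_a_single_zero_attachment_fragment(self):
        frags = brics_decompose(parse_smiles("C"))
        assert len(frags) == 1
        assert frags[0].points == []

    def test_amide_cleaves_into_two_one_point_fragments(self):
        frags = brics_decompose(parse_smiles("CNC(C)=O"))
        assert len(frags) == 2
        assert all(len(f.points) == 1 for f in frags)

    def test_tree_molecule_k_bonds_give_k_plus_one_fragments(self):
        mol = parse_smiles("CC(=O)Nc1ccc(OC)cc1")  # acyclic cleavage sites
        k = len(find_cleavable_bonds(mol))
        frags = brics_decompose(mol)
        assert k >= 2
        assert len(frags) == k + 1

    def test_heavy_atom_conservation(self):
        for m in gen_smiles_library(100, seed=9):
            frags = brics_decompose(m)
            total = sum(f.heavy_atom_count for f in frags)
            assert total == m.heavy_atom_count

    def test_deterministic_order(self):
        m = parse_smiles("CC(=O)Nc1ccc(O)cc1")
        a = [f.to_smiles() for f in brics_decompose(m)]
        b = [f.to_smiles() for f in brics_decompose(m)]
        assert a == b == sorted(a)


class TestCleaveRejoin:
    def test_single_cleavage_closure(self):
        for m in gen_smiles_library(100, seed=13):
            for bond in find_cleavable_bonds(m):
                try:
                    fa, fb = cleave_bond(m, bond)
                except ValueError:
                    continue  # ring bond: cleaving does not split
                (pa, _), = fa.points
                (pb, _), = fb.points
                rejoined = join_fragments(fa.mol, pa, fb.mol, pb)
                re_mol = Molecule(rejoined)
                assert re_mol.heavy_atom_count == m.heavy_atom_count
                assert re_mol.bond_count == m.bond_count

    def test_incompatible_environments_rejected(self):
        fa, fb = brics_decompose(parse_smiles("CNC(C)=O"))
        # label 1 (carbonyl C) cannot bond to another label-1 point
        with pytest.raises(ValueError, match="incompatible"):
            join_fragments(fa.mol, fa.points[0][0], fa.mol, fa.points[0][0])


class TestCompatibility:
    def test_symmetric(self):
        for (a, b), bond in COMPATIBILITY.items():
            assert COMPATIBILITY[(b, a)] == bond

    def test_library_from_molecules_deduplicates(self, mcts_seeds,
                                                 mcts_library):
        again = FragmentLibrary.from_molecules(mcts_seeds)
        assert ([f.to_smiles() for f in again.fragments]
                == [f.to_smiles() for f in mcts_library.fragments])


class TestActions:
    def test_action_count_is_points_times_compatible_fragments(
            self, mcts_library):
        st = SearchState.from_mol(
            brics_decompose(parse_smiles("CNC(C)=O"))[0].mol)
        (point, label), = st.open_points
        acts = enumerate_actions(st, mcts_library)
        assert len(acts) == len(mcts_library.compatible(label))
        assert acts == sorted(acts)

    def test_terminal_state_has_no_actions(self, mcts_library):
        st = SearchState.from_mol(parse_smiles("CCO").rdkit)
        assert enumerate_actions(st, mcts_library) == []

    def test_apply_is_deterministic_and_increments_depth(self, mcts_library):
        st = SearchState.from_mol(
            brics_decompose(parse_smiles("CNC(C)=O"))[0].mol)
        act = enumerate_actions(st, mcts_library)[0]
        a = apply_action(st, act, mcts_library)
        b = apply_action(st, act, mcts_library)
        assert a == b
        assert a.depth == st.depth + 1

    def test_open_point_bookkeeping_after_join(self, mcts_library):
        # joining consumes one point on each side: (a-1) + (b-1) remain
        st = SearchState.from_mol(
            brics_decompose(parse_smiles("CNC(C)=O"))[0].mol)
        n_open = len(st.open_points)
        act = enumerate_actions(st, mcts_library)[0]
        frag_points = len(mcts_library.fragments[act[1]].points)
        nxt = apply_action(st, act, mcts_library)
        assert len(nxt.open_points) == (n_open - 1) + (frag_points - 1)


class TestUct:
    def make_node(self, n_actions=2):
        st = SearchState(smiles="[1*]C(C)=O", depth=0)
        actions = [(0, i, 0) for i in range(n_actions)]
        return SearchNode(st, actions)

    def test_unvisited_action_selected_first(self):
        node = self.make_node(2)
        node.n_sa[(0, 0, 0)] = 3
        node.w_sa[(0, 0, 0)] = 2.7
        assert uct_select(node) == (0, 1, 0)

    def test_pure_exploitation_at_c_zero(self):
        node = self.make_node(2)
        node.n_sa[(0, 0, 0)] = 5
        node.w_sa[(0, 0, 0)] = 1.0   # Q = 0.2
        node.n_sa[(0, 1, 0)] = 5
        node.w_sa[(0, 1, 0)] = 4.5   # Q = 0.9
        assert uct_select(node, c=0.0) == (0, 1, 0)

    def test_equal_stats_tie_break_canonical(self):
        node = self.make_node(3)
        for a in node.actions:
            node.n_sa[a] = 4
            node.w_sa[a] = 2.0
        assert uct_select(node, c=1.0) == (0, 0, 0)

    def test_no_actions_error(self):
        node = self.make_node(0)
        with pytest.raises(ValueError):
            uct_select(node)

    def test_visit_count_invariant(self):
        node = self.make_node(2)
        assert node.visit_count == 1
        node.n_sa[(0, 0, 0)] = 4
        assert node.visit_count == 1 + 4


class TestDefaultReward:
    def test_weighted_blend_arithmetic(self):
        m = parse_smiles("CC(=O)Nc1ccc(O)cc1")  # Ro5-compliant
        # score component sigmoid(-(-s)/scale): pick scorer giving 0.6
        scale = 5.0
        s_for_06 = -scale * math.log(0.6 / 0.4)
        r = default_reward(m, scorer=lambda _: s_for_06,
                           weights=(0.5, 0.5, 0.0))
        assert r == pytest.approx(0.5 * 0.6 + 0.5 * 1.0, abs=1e-9)

    def test_ro5_violation_with_pure_ro5_weight_is_zero(self):
        fat = parse_smiles("C" * 40)
        assert default_reward(fat, weights=(0.0, 1.0, 0.0)) == 0.0

    def test_open_points_warn_and_zero(self, mcts_library):
        frag = brics_decompose(parse_smiles("CNC(C)=O"))[0]
        with pytest.warns(UserWarning):
            assert default_reward(Molecule(frag.mol)) == 0.0

    def test_bounded_unit_interval(self):
        for m in gen_smiles_library(20, seed=3):
            assert 0.0 <= default_reward(m) <= 1.0


class TestMctsGenerate:
    def test_same_seed_identical_output(self, mcts_seeds, mcts_library):
        a = mcts_generate(mcts_seeds, mcts_library, budget=300, rng_seed=5,
                          depth_cap=3)
        b = mcts_generate(mcts_seeds, mcts_library, budget=300, rng_seed=5,
                          depth_cap=3)
        assert [(m.to_smiles(), r) for m, r in a] == [
            (m.to_smiles(), r) for m, r in b]

    def test_single_fragment_depth_one_space(self):
        frag_parent = parse_smiles("CNC(C)=O")
        fa, fb = brics_decompose(frag_parent)
        lib = FragmentLibrary([fb])
        out = mcts_generate([frag_parent], lib, budget=50, rng_seed=0,
                            depth_cap=1)
        # only one way to complete each one-point fragment with the
        # single compatible library fragment
        assert len(out) >= 1
        assert all(r >= 0 for _, r in out)

    def test_finds_enumeration_optimum(self, mcts_seeds, mcts_library):
        roots = seed_roots(mcts_seeds)
        terms = enumerate_terminals(roots, mcts_library, depth_cap=3)
        assert 0 < len(terms) <= 50
        opt = max(default_reward(parse_smiles(s)) for s in terms)
        out = mcts_generate(mcts_seeds, mcts_library, budget=2000,
                            rng_seed=11, depth_cap=3)
        assert out[0][1] == pytest.approx(opt, abs=1e-12)

    def test_best_reward_nondecreasing_in_budget(self, mcts_seeds,
                                                 mcts_library):
        best = []
        for budget in (50, 400, 2000):
            out = mcts_generate(mcts_seeds, mcts_library, budget=budget,
                                rng_seed=2, depth_cap=3)
            best.append(out[0][1])
        assert best[0] <= best[1] <= best[2]

    def test_empty_library_rejected(self, mcts_seeds):
        with pytest.raises(ValueError):
            mcts_generate(mcts_seeds, FragmentLibrary([]), budget=10,
                          rng_seed=0)

    def test_whole_seed_mode_emits_seed_itself(self, mcts_seeds,
                                               mcts_library):
        out = mcts_generate(mcts_seeds[:1], mcts_library, budget=1,
                            rng_seed=0, seed_mode="whole")
        smis = {m.to_smiles() for m, _ in out}
        assert mcts_seeds[0].to_smiles() in smis
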