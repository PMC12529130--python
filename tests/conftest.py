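import numpy as np
import pytest

from winfunnel import generator as gen
from winfunnel import parse_smiles
from winfunnel.fixtures import gen_toy_complex


@pytest.fixture(scope="session")
def mcts_seeds():
    return [
        parse_smiles("CC(=O)Nc1ccc(O)cc1", name="s1"),
        parse_smiles("c1ccncc1CNC(=O)COc1ccccc1", name="s2"),
    ]


@pytest.fixture(scope="session")
def mcts_library(mcts_seeds):
    return gen.FragmentLibrary.from_molecules(mcts_seeds)


@pytest.fixture(scope="session")
def toy_complex():
    return gen_toy_complex(8, 8, 6, seed=7)


def enumerate_terminals(roots, lib, depth_cap, heavy_cap=36):
    """Exhaustive DFS over the assembly MDP; independent of the MCTS."""
    seen: set = set()
    terminals: set = set()
    stack = list(roots)
    while stack:
        st = stack.pop()
        if st in seen:
            continue
        seen.add(st)
        acts = gen.enumerate_actions(st, lib)
        heavy = sum(1 for a in st.mol.GetAtoms() if a.GetAtomicNum() > 1)
        is_terminal = (not st.open_points or st.depth >= depth_cap
                       or heavy >= heavy_cap or not acts)
        if is_terminal:
            if not st.open_points:
                terminals.add(st.smiles)
            continue
        for a in acts:
            stack.append(gen.apply_action(st, a, lib))
    return terminals


def seed_roots(seeds):
    roots = []
    for s in seeds:
        for frag in gen.brics_decompose(s):
            st = gen.SearchState.from_mol(frag.mol)
            if st.open_points:
                roots.append(st)
    return roots


def brute_force_cross_energy(s, mask_a, mask_b):
    """O(n^2) double-loop oracle for the vectorized energy code."""
    from winfunnel.energy import pair_energy

    total = 0.0
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    for i in ia:
        for j in ib:
            r = float(np.linalg.norm(s.coords[i] - s.coords[j]))
            total += pair_energy(s.charges[i], s.charges[j], r,
                                 s.elements[i], s.elements[j])
    return total
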