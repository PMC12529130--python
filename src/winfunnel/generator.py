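"""Fragment-based molecule design: BRICS decomposition and MCTS assembly.

Molecules are deconstructed with the BRICS retrosynthetic rules into
fragments whose attachment points carry typed environment labels
(integers 1-16; the two alkene environments collapse to label 7).  Only
label pairs the rule set declares compatible may be rejoined, which keeps
every assembled molecule inside synthetically plausible chemistry.

Assembly is modelled as a deterministic-transition Markov decision
process: a state is a partial molecule with open attachment points plus
its depth, an action attaches one compatible library fragment at one
open point, and the transition function is the (deterministic) fragment
join.  The search is Monte Carlo tree search with the UCT rule

    a* = argmax_a  Q(s, a) + c * sqrt(ln N(s) / N(s, a))

where Q(s, a) = W(s, a) / N(s, a) is the mean observed reward, N counts
visits and unvisited actions are always tried first.  Rollouts attach
uniformly random compatible fragments until a terminal state (no open
points, or depth/heavy-atom cap).  The reward is pluggable; the default
blends a sigmoid-rescaled interaction score, Rule-of-Five compliance and
a surrogate activity score.

States are kept in canonical-SMILES normal form so that identical
partial molecules reached along different paths share transposition and
reward caches; this makes search on small fragment spaces cheap.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .chem import Molecule
from .filters import SurrogateActivityPredictor, compute_descriptors, ro5_check

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "SearchState",
    "SearchNode",
    "brics_decompose",
    "find_cleavable_bonds",
    "cleave_bond",
    "join_fragments",
    "enumerate_actions",
    "apply_action",
    "uct_select",
    "default_reward",
    "mcts_generate",
]


def _build_compatibility() -> dict[tuple[int, int], Chem.BondType]:
    """Label-pair -> bond-order table derived from the BRICS rule set."""
    order = {"-": Chem.BondType.SINGLE, "=": Chem.BondType.DOUBLE}
    compat: dict[tuple[int, int], Chem.BondType] = {}
    for la, lb, bond in itertools.chain.from_iterable(BRICS.reactionDefs):
        a = int(la.rstrip("ab"))
        b = int(lb.rstrip("ab"))
        compat[(a, b)] = order[bond]
        compat[(b, a)] = order[bond]
    return compat


COMPATIBILITY: dict[tuple[int, int], Chem.BondType] = _build_compatibility()


def attachment_points(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(atom index, environment label) for every open attachment point."""
    return [
        (a.GetIdx(), a.GetIsotope())
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0
    ]


@dataclass(frozen=True)
class Fragment:
    """A connected molecular graph with labelled attachment points."""

    mol: Chem.Mol = field(repr=False)
    provenance: str | None = None

    @property
    def points(self) -> list[tuple[int, int]]:
        return attachment_points(self.mol)

    @property
    def heavy_atom_count(self) -> int:
        """Heavy atoms excluding the attachment markers."""
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


class FragmentLibrary:
    """BRICS fragments plus the environment-compatibility matrix."""

    def __init__(self, fragments: Sequence[Fragment],
                 compatibility: dict[tuple[int, int], Chem.BondType] | None = None):
        self.fragments = list(fragments)
        self.compatibility = dict(compatibility or COMPATIBILITY)
        for (a, b), bond in list(self.compatibility.items()):
            if self.compatibility.get((b, a)) != bond:
                raise ValueError("compatibility matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.fragments)

    @classmethod
    def from_molecules(cls, mols: Sequence[Molecule]) -> "FragmentLibrary":
        """Pool the BRICS fragments of several molecules, deduplicated."""
        frags: dict[str, Fragment] = {}
        for m in mols:
            for f in brics_decompose(m):
                frags.setdefault(f.to_smiles(), f)
        return cls([frags[s] for s in sorted(frags)])

    def compatible(self, label: int) -> list[tuple[int, int, int]]:
        """All (fragment index, point atom index, point label) attachable
        to an open point with the given environment label."""
        out = []
        for fi, frag in enumerate(self.fragments):
            for atom_idx, flabel in frag.points:
                if (label, flabel) in self.compatibility:
                    out.append((fi, atom_idx, flabel))
        return out


def brics_decompose(mol: Molecule) -> list[Fragment]:
    """Cleave all BRICS-rule bonds; fragments carry labelled points.

    A molecule with no cleavable bond is returned unchanged as a single
    zero-attachment fragment.  Output is sorted by canonical SMILES for
    determinism.
    """
    broken = BRICS.BreakBRICSBonds(mol.rdkit)
    pieces = Chem.GetMolFrags(broken, asMols=True)
    frags = sorted(pieces, key=lambda m: Chem.MolToSmiles(m))
    return [Fragment(Chem.MolFromSmiles(Chem.MolToSmiles(f)),
                     provenance=mol.name) for f in frags]


def find_cleavable_bonds(mol: Molecule) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """BRICS-cleavable bonds as ((atom_i, atom_j), (label_i, label_j))."""
    out = []
    for (i, j), (la, lb) in BRICS.FindBRICSBonds(mol.rdkit):
        out.append(((i, j), (int(la.rstrip("ab")), int(lb.rstrip("ab")))))
    return out


def cleave_bond(
    mol: Molecule,
    bond: tuple[tuple[int, int], tuple[int, int]],
) -> tuple[Fragment, Fragment]:
    """Break one BRICS bond, yielding two fragments with one labelled
    attachment point each (on this bond)."""
    (i, j), (la, lb) = bond
    b = mol.rdkit.GetBondBetweenAtoms(i, j)
    if b is None:
        raise ValueError(f"no bond between atoms {i} and {j}")
    broken = Chem.FragmentOnBonds(
        mol.rdkit, [b.GetIdx()], dummyLabels=[(la, lb)])
    parts = Chem.GetMolFrags(broken, asMols=True)
    if len(parts) != 2:
        raise ValueError("bond is in a ring; cleaving it does not split the molecule")
    return tuple(
        Fragment(Chem.MolFromSmiles(Chem.MolToSmiles(p)), provenance=mol.name)
        for p in sorted(parts, key=lambda m: Chem.MolToSmiles(m))
    )


def join_fragments(
    mol_a: Chem.Mol, point_a: int,
    mol_b: Chem.Mol, point_b: int,
    compatibility: dict[tuple[int, int], Chem.BondType] | None = None,
) -> Chem.Mol:
    """Join two fragments by a bond between the neighbors of the chosen
    attachment markers; the markers are consumed.

    The bond order comes from the compatibility matrix; incompatible
    environment labels raise ValueError.
    """
    compat = compatibility or COMPATIBILITY
    la = mol_a.GetAtomWithIdx(point_a).GetIsotope()
    lb = mol_b.GetAtomWithIdx(point_b).GetIsotope()
    if (la, lb) not in compat:
        raise ValueError(f"incompatible environments {la} and {lb}")
    bond_type = compat[(la, lb)]
    na = mol_a.GetAtomWithIdx(point_a).GetNeighbors()[0].GetIdx()
    nb = mol_b.GetAtomWithIdx(point_b).GetNeighbors()[0].GetIdx()
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    off = mol_a.GetNumAtoms()
    combined.AddBond(na, nb + off, bond_type)
    for idx in sorted((point_a, point_b + off), reverse=True):
        combined.RemoveAtom(idx)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


@dataclass(frozen=True)
class SearchState:
    """A partial molecule (canonical form) and its assembly depth."""

    smiles: str
    depth: int

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    @property
    def open_points(self) -> list[tuple[int, int]]:
        return attachment_points(self.mol)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, depth: int = 0) -> "SearchState":
        # canonical normal form: identical partial molecules share one
        # SMILES and one (canonical) atom numbering
        return cls(Chem.MolToSmiles(mol), depth)


Action = tuple[int, int, int]  # (state point atom idx, fragment idx, fragment point atom idx)


def enumerate_actions(state: SearchState, lib: FragmentLibrary) -> list[Action]:
    """All legal attachments, in canonical (sorted-tuple) order.

    One action per open attachment point x compatible library fragment x
    compatible fragment attachment point.  Terminal states yield [].
    """
    actions: list[Action] = []
    for atom_idx, label in state.open_points:
        for fi, f_atom, _ in lib.compatible(label):
            actions.append((atom_idx, fi, f_atom))
    actions.sort()
    return actions


def apply_action(state: SearchState, action: Action,
                 lib: FragmentLibrary) -> SearchState:
    """Deterministic transition: attach the chosen fragment, depth + 1."""
    atom_idx, fi, f_atom = action
    joined = join_fragments(state.mol, atom_idx, lib.fragments[fi].mol,
                            f_atom, lib.compatibility)
    return SearchState.from_mol(joined, state.depth + 1)


class SearchNode:
    """MCTS tree node with per-action visit counts and cumulative reward.

    N(s) = 1 + sum_a N(s, a) by construction; Q(s, a) = W(s, a) / N(s, a).
    """

    __slots__ = ("state", "actions", "n_sa", "w_sa", "children")

    def __init__(self, state: SearchState, actions: list[Action]):
        self.state = state
        self.actions = actions
        self.n_sa: dict[Action, int] = {a: 0 for a in actions}
        self.w_sa: dict[Action, float] = {a: 0.0 for a in actions}
        self.children: dict[Action, SearchNode] = {}

    @property
    def visit_count(self) -> int:
        return 1 + sum(self.n_sa.values())

    def q(self, action: Action) -> float:
        n = self.n_sa[action]
        return self.w_sa[action] / n if n else 0.0


def uct_select(node: SearchNode, c: float = math.sqrt(2.0)) -> Action:
    """UCT action choice; unvisited actions first, ties by canonical order."""
    if not node.actions:
        raise ValueError("node has no actions")
    for a in node.actions:  # canonical order
        if node.n_sa[a] == 0:
            return a
    log_n = math.log(node.visit_count)
    return max(
        node.actions,
        key=lambda a: (node.q(a) + c * math.sqrt(log_n / node.n_sa[a]),
                       tuple(-x for x in a)),
    )


def default_reward(
    mol: Molecule,
    scorer: Callable[[Molecule], float] | None = None,
    weights: tuple[float, float, float] = (0.4, 0.3, 0.3),
    score_scale: float = 5.0,
) -> float:
    """Heuristic reward in [0, 1] for a completed molecule.

    Weighted blend of (1) a sigmoid-rescaled interaction score, where
    more negative scores approach 1, (2) a Rule-of-Five compliance
    indicator and (3) the surrogate activity score.  Weights must sum
    to 1.  A molecule with open attachment points gets reward 0 with a
    warning — it is not a finished design.
    """
    if attachment_points(mol.rdkit):
        warnings.warn("reward requested for a molecule with open attachment "
                      "points; returning 0", stacklevel=2)
        return 0.0
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("reward weights must sum to 1")
    w_score, w_ro5, w_act = weights
    parts = 0.0
    if w_score:
        s = scorer(mol) if scorer is not None else 0.0
        parts += w_score / (1.0 + math.exp(s / score_scale))
    if w_ro5:
        parts += w_ro5 * float(ro5_check(compute_descriptors(mol)).passes)
    if w_act:
        parts += w_act * SurrogateActivityPredictor()(mol)
    return min(max(parts, 0.0), 1.0)


def _is_terminal(state: SearchState, lib: FragmentLibrary,
                 depth_cap: int, heavy_cap: int,
                 action_cache: dict[SearchState, list[Action]]) -> bool:
    mol = state.mol
    if not attachment_points(mol):
        return True
    if state.depth >= depth_cap:
        return True
    if sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1) >= heavy_cap:
        return True
    return not _actions_of(state, lib, action_cache)


def _actions_of(state, lib, cache):
    acts = cache.get(state)
    if acts is None:
        acts = enumerate_actions(state, lib)
        cache[state] = acts
    return acts


def mcts_generate(
    seeds: Sequence[Molecule],
    lib: FragmentLibrary,
    reward: Callable[[Molecule], float] | None = None,
    budget: int = 1000,
    rng_seed: int = 0,
    depth_cap: int = 6,
    heavy_atom_cap: int = 36,
    c: float = math.sqrt(2.0),
    seed_mode: str = "fragments",
) -> list[tuple[Molecule, float]]:
    """Search fragment-assembly space from each seed; rank the designs.

    seed_mode "fragments" decomposes each seed with BRICS and starts one
    search tree per fragment that has an open attachment point;
    "whole" uses each seed molecule itself as the root.  Each root gets
    ``budget`` select-expand-rollout-backpropagate iterations.  Returns
    deduplicated completed molecules sorted by best observed reward
    (descending, ties by SMILES); bit-reproducible for a fixed rng seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(lib) == 0:
        raise ValueError("fragment library is empty")
    if seed_mode not in ("fragments", "whole"):
        raise ValueError("seed_mode must be 'fragments' or 'whole'")
    reward_fn = reward if reward is not None else default_reward
    rng = np.random.default_rng(rng_seed)

    action_cache: dict[SearchState, list[Action]] = {}
    trans_cache: dict[tuple[SearchState, Action], SearchState] = {}
    reward_cache: dict[str, float] = {}
    found: dict[str, float] = {}

    def step(state: SearchState, action: Action) -> SearchState:
        key = (state, action)
        nxt = trans_cache.get(key)
        if nxt is None:
            nxt = apply_action(state, action, lib)
            trans_cache[key] = nxt
        return nxt

    def terminal_reward(state: SearchState) -> float:
        r = reward_cache.get(state.smiles)
        if r is None:
            mol = Molecule(state.mol, source_smiles=state.smiles)
            if attachment_points(mol.rdkit):
                r = 0.0  # capped out with open points: not a design
            else:
                r = reward_fn(mol)
                found_key = state.smiles
                if found_key not in found or r > found[found_key]:
                    found[found_key] = r
            reward_cache[state.smiles] = r
        return r

    def rollout(state: SearchState) -> float:
        while not _is_terminal(state, lib, depth_cap, heavy_atom_cap,
                               action_cache):
            acts = _actions_of(state, lib, action_cache)
            state = step(state, acts[rng.integers(len(acts))])
        return terminal_reward(state)

    roots: list[SearchState] = []
    for seed in seeds:
        if seed_mode == "whole":
            roots.append(SearchState.from_mol(seed.rdkit))
        else:
            for frag in brics_decompose(seed):
                st = SearchState.from_mol(frag.mol)
                if st.open_points:
                    roots.append(st)
                else:
                    terminal_reward(st)

    for root_state in roots:
        if _is_terminal(root_state, lib, depth_cap, heavy_atom_cap,
                        action_cache):
            terminal_reward(root_state)
            continue
        root = SearchNode(root_state,
                          _actions_of(root_state, lib, action_cache))
        for _ in range(budget):
            node = root
            path: list[tuple[SearchNode, Action]] = []
            # selection: descend through fully expanded nodes
            while True:
                action = uct_select(node, c)
                path.append((node, action))
                if node.n_sa[action] == 0:
                    # expansion
                    child_state = step(node.state, action)
                    if _is_terminal(child_state, lib, depth_cap,
                                    heavy_atom_cap, action_cache):
                        value = terminal_reward(child_state)
                    else:
                        child = SearchNode(
                            child_state,
                            _actions_of(child_state, lib, action_cache))
                        node.children[action] = child
                        value = rollout(child_state)
                    break
                child = node.children.get(action)
                if child is None:
                    # action leads to a terminal state seen before
                    value = terminal_reward(step(node.state, action))
                    break
                node = child
            for n, a in path:
                n.n_sa[a] += 1
                n.w_sa[a] += value

    ranked = sorted(found.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(Molecule(Chem.MolFromSmiles(smi), source_smiles=smi), r)
            for smi, r in ranked]
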