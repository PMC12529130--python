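"""Design new molecules by BRICS fragment recombination under MCTS.

Two seed molecules are BRICS-decomposed into a fragment library; an
UCT-guided Monte Carlo tree search then reassembles fragments at
compatible attachment points, rewarding small, Rule-of-Five-compliant,
surrogate-active products.
"""

from winfunnel.chem import parse_smiles
from winfunnel.generator import FragmentLibrary, brics_decompose, mcts_generate

seeds = [parse_smiles("CC(=O)Nc1ccc(O)cc1", name="acetaminophen-like"),
         parse_smiles("c1ccncc1CNC(=O)COc1ccccc1", name="ether-amide")]
library = FragmentLibrary.from_molecules(seeds)

for s in seeds:
    frags = [f.to_smiles() for f in brics_decompose(s)]
    print(f"{s.name}: {len(frags)} BRICS fragments -> {frags}")

ranked = mcts_generate(seeds, library, budget=2000, rng_seed=0, depth_cap=3)
print(f"\n{len(ranked)} unique complete designs; top 5 by reward:")
for mol, reward in ranked[:5]:
    print(f"  {reward:.4f}  {mol.to_smiles()}")
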