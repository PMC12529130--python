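"""Triage a small library with Rule-of-Five, PAINS, and activity gates.

Each molecule is parsed, its Lipinski descriptors computed, and then run
through the three orthogonal filters a funnel would chain: drug-likeness
(Ro5), promiscuous-binder alerts (PAINS substructures), and a surrogate
activity score gate.
"""

from winfunnel.chem import compute_descriptors
from winfunnel.filters import (SurrogateActivityPredictor, activity_gate,
                               pains_scan, ro5_check)
from winfunnel.fixtures import gen_smiles_library

mols = gen_smiles_library(30, seed=4, plant_pains=True)
predictor = SurrogateActivityPredictor()

n_ro5 = n_pains = n_active = 0
for mol in mols:
    d = compute_descriptors(mol)
    verdict = ro5_check(d)
    alerts = pains_scan(mol)
    active = activity_gate(mol, predictor)
    n_ro5 += verdict.passes
    n_pains += bool(alerts)
    n_active += active
    if alerts:
        print(f"{mol.name}: PAINS alert {alerts[0]} "
              f"({mol.to_smiles()})")

print(f"{n_ro5}/{len(mols)} pass the Rule of Five "
      "(mw<500, logP<=5, HBD<=5, HBA<=10)")
print(f"{n_pains}/{len(mols)} carry a PAINS alert and would be discarded")
print(f"{n_active}/{len(mols)} clear the surrogate activity gate (>0.5)")
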