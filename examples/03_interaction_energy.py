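"""Score a toy protein-protein complex and a bound ligand, then measure
how much the ligand weakens the interface.

The surrogate energy is screened Coulomb (distance-dependent dielectric
eps = 4r) plus Lennard-Jones with a 12 A cutoff.  Disruption is the holo
(ligand-bound) interface energy minus the apo one: a positive value
means the ligand destabilises the protein-protein contact.
"""

from winfunnel.energy import ligand_receptor_energy, ppi_disruption, ppi_energy
from winfunnel.fixtures import gen_toy_complex

holo = gen_toy_complex(40, 40, 12, seed=21)

lig = ligand_receptor_energy(holo)
print(f"ligand-receptor energy: {lig.total:+.3f} kcal/mol "
      f"(coulomb {lig.coulomb:+.3f}, LJ {lig.lj:+.3f})")

hot = sorted(lig.per_residue.items(), key=lambda kv: kv[1])[:3]
for (chain, resid), e in hot:
    print(f"  hotspot {chain}{resid}: {e:+.3f} kcal/mol")

e_interface = ppi_energy(holo).total
print(f"receptor-partner interface energy: {e_interface:+.3f} kcal/mol")

# the toy lattice is rigid, so binding cannot relax the interface here;
# the disruption bookkeeping itself takes any apo/holo pair, e.g. an
# interface at -119.7 kcal/mol weakened to -80.6 by a bound ligand:
d = ppi_disruption(-119.7, -80.6)
print(f"ppi disruption for apo -119.7 -> holo -80.6: {d:+.1f} kcal/mol "
      "(positive = ligand weakens the interface)")
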