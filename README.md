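# winfunnel

A self-contained toolkit for tiered virtual-screening funnels against
protein–protein interfaces, with fragment-based molecule generation and
post-simulation trajectory analysis. Everything runs offline and
deterministically: every stochastic step takes an explicit seed, and
synthetic fixture generators stand in for external docking engines,
force fields, and MD packages.

## The science

Structure-based campaigns against a protein–protein interaction (PPI)
typically funnel a large vendor library through progressively more
expensive scoring tiers, keeping only the best fraction at each stage,
then characterise finalists by interaction energies and molecular
dynamics. `winfunnel` implements that workflow end to end as a library
plus a thin CLI:

- **Tiered funnel** — each tier either keeps the top fraction *f* of
  survivors by score (`floor(f·n)`, ties broken stably by insertion
  order) or applies a score threshold (boundary inclusive by default,
  e.g. keep docking scores ≤ −7 kcal/mol). Tiers may also attach
  property gates: Lipinski Rule of Five (MW < 500, logP ≤ 5,
  H-bond donors ≤ 5, acceptors ≤ 10), PAINS substructure alerts, and a
  surrogate activity score. Three chained top-10% tiers reduce 460,160
  molecules to exactly 460.
- **Surrogate interaction energy** — a pairwise screened-Coulomb +
  Lennard-Jones model:
  E = Σ 332.0636·qᵢqⱼ/(ε(r)·r) + 4εᵢⱼ[(σᵢⱼ/r)¹² − (σᵢⱼ/r)⁶],
  with distance-dependent dielectric ε(r) = 4r, Lorentz–Berthelot
  mixing, and a 12 Å cutoff. It reports total, Coulomb, and LJ terms
  plus a per-residue decomposition, and a PPI *disruption* metric
  ΔE = E_interface(holo) − E_interface(apo): positive values mean the
  bound ligand weakens the protein–protein contact.
- **Fragment-based generation** — seed molecules are decomposed at
  BRICS bonds into attachment-labelled fragments; a Monte Carlo tree
  search with the UCT rule (Q + c·√(ln N(s)/N(s,a)), c = √2)
  reassembles fragments at compatible points, rewarding complete,
  Rule-of-Five-compliant, surrogate-active products. Decomposition and
  reassembly conserve heavy-atom and bond counts exactly.
- **Trajectory analysis** — Kabsch least-squares superposition (SVD
  with determinant correction), backbone RMSD series, per-residue RMSF
  after an iterative fit to the average structure, representative
  conformer picking, and steered-pull analysis: smoothed rupture-force
  peak and pull work W = ∫F·v dt.
- **Synthetic fixtures** — seeded generators for score lists, stratified
  SMILES libraries (with an optional planted PAINS quinone), toy
  two-chain complexes with an interface ligand, harmonic trajectories
  with known fluctuation amplitudes (RMSF = A/√2), and rise/decay
  pull-force curves with a planted rupture peak.

Chemistry primitives (SMILES parsing, descriptors, BRICS bond typing,
PAINS catalogs) are delegated to RDKit; PDB I/O to biotite. The funnel
engine, energy model, search, and trajectory analysis are implemented
here.

## Worked example

Generate a 200-molecule synthetic library, then run a two-tier funnel —
top 20% by a pseudo docking score, then a −7 kcal/mol threshold:

```sh
$ cat funnel.toml
[[tiers]]
name = "htvs"
kind = "top_fraction"
fraction = 0.2
scorer = "pseudo"

[[tiers]]
name = "xp"
kind = "threshold"
cutoff = -7.0
direction = "le"
scorer = "pseudo"

$ winfunnel fixtures --kind smiles --n 200 --seed 3 --out library.smi
wrote smiles fixture to library.smi
$ winfunnel run --library library.smi --config funnel.toml --seed 3 \
      --out report.csv --survivors survivors.smi
htvs: 200 -> 40 [top_fraction(0.2)]
xp: 40 -> 16 [threshold(<=-7.0)]
$ head -3 survivors.smi
COc1ccccc1	M000013	htvs=-11.6457	xp=-11.5621
COC(=O)C1CCCNC1	M000016	htvs=-11.5751	xp=-11.5362
OCCc1cccc2ccccc12	M000031	htvs=-11.202	xp=-8.76336
```

Grow new designs from the survivors by BRICS recombination under MCTS,
and score a toy complex:

```sh
$ winfunnel generate --seeds survivors.smi --budget 500 --seed 0 \
      --depth-cap 3 --out designs.smi
50 designs written to designs.smi
$ head -3 designs.smi
COC(=O)C1CCCO1	D0	reward=0.717594
COC1CCCO1	D1	reward=0.716468
COC1CCCNC1	D2	reward=0.712714

$ winfunnel fixtures --kind complex --n 40 --seed 21 --out toy.pdb
wrote complex fixture to toy.pdb
$ winfunnel energy --pdb toy.pdb --mode ligand
total=-2.3564 coulomb=0.0000 lj=-2.3564 kcal/mol
```

Analyse a noisy synthetic pull-force trace (peak 280 kJ/mol/nm planted
at 220 ps):

```sh
$ winfunnel fixtures --kind force --seed 6 --peak 280 --t-peak 220 \
      --noise-sd 5 --out force.txt
wrote force fixture to force.txt
$ winfunnel traj --input force.txt --op peak --window 10
peak_force=275.9553 kJ/mol/nm at t=219.00 ps
$ winfunnel traj --input force.txt --op work --velocity 0.1
pull_work=999.1035 kJ/mol
```

The `examples/` directory contains short narrated scripts covering the
same ground through the Python API: the tiered funnel, property
filters, interaction energies, fragment generation, and trajectory
analysis.

## Layout

- `src/winfunnel/` — the library: `chem`, `filters`, `cascade`,
  `energy`, `generator`, `trajectory`, `fixtures`, `io`, `cli`.
- `examples/` — narrated scripts, one per capability.
- `tests/` — unit, property-based, and acceptance tests.
- `scripts/acceptance.py` — headline-quantity reproduction.
- `docs/methods.md` — models, parameters, numerical choices, and
  limitations.
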