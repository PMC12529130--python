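# Methods

This document specifies the models implemented in `winfunnel`, their
parameters and units, the numerical choices behind them, and where the
synthetic fixtures deliberately depart from physical realism.

## Molecular descriptors

SMILES parsing, canonicalisation, and descriptor primitives are
delegated to RDKit. The Lipinski descriptor set is:

- `mw` — average molecular weight (Da).
- `logp` — Crippen logP.
- `hbd` — count of O–H and N–H **bonds** (so a primary amide
  contributes 2, ethylenediamine 4). This is the original Lipinski
  definition; it differs from "count of heteroatoms bearing ≥1 H".
- `hba` — count of N and O atoms.
- `heavy_atoms` — non-hydrogen atom count.

The Rule-of-Five verdict passes iff `mw < 500` (strict) and
`logp ≤ 5`, `hbd ≤ 5`, `hba ≤ 10` (boundary inclusive). The
ligand-efficiency-style `effective_score` is raw score divided by
heavy-atom count and errors on molecules with no heavy atoms.

PAINS screening uses RDKit's FilterCatalog (families A, B, C
selectable); a custom pattern set can also be loaded from a TSV of
name/SMARTS pairs. A molecule is reported with the list of matching
alert names; any match fails the gate.

The surrogate activity predictor is a fixed-weight logistic over
`(mw/500, logp/5, hbd/5, hba/10, heavy/35)` with weights
`(−1.1, −0.8, −0.6, −0.4, 0.9)` and bias `1.2`. It is a deterministic
stand-in for a proprietary QSAR model so the activity gate can be
exercised offline; it has no predictive validity. The gate passes iff
the score strictly exceeds the threshold (default 0.5) and raises on
scores outside `[0, 1]`.

## Funnel semantics

A funnel is an ordered list of tiers over items carrying per-tier
scores. Two selection rules exist:

- **top_fraction(f)** — keep exactly `floor(f · n_alive)` survivors.
  Lower scores are better by default (`higher_is_better` flips this).
  Sorting is stable with ties broken by input order, so reruns are
  deterministic even with duplicate scores.
- **threshold(c)** — keep items with score ≤ c (or ≥ c for direction
  `ge`). The boundary is inclusive unless `strict` is set, so a
  −7.0 kcal/mol score passes a −7.0 cutoff.

Tiers may attach a scorer (computed lazily per tier) and a boolean
gate applied before selection. A scorer exception marks that item
failed and dead; the run continues and the per-tier report records
`n_in`, `n_out`, and `n_failed`. `n_out > n_in` is rejected as a
bookkeeping violation.

With three chained top-10% tiers, `floor` arithmetic gives
460,160 → 46,016 → 4,601 → 460 and 300,528 → 30,052 → 3,005 → 300,
independent of the score distribution as long as scores are distinct.

The CLI's `pseudo` scorer maps a SHA-256 hash of
`seed:tier:item-id` into [−12, −2] kcal/mol. A cryptographic hash
matters here: a linear checksum (CRC32) makes scores for different tier
names XOR-correlated, which visibly distorts multi-tier survivor
counts.

## Surrogate interaction energy

The energy between two atom sets is a pairwise sum

E = Σᵢⱼ k·qᵢqⱼ/(ε(rᵢⱼ)·rᵢⱼ) + 4εᵢⱼ[(σᵢⱼ/rᵢⱼ)¹² − (σᵢⱼ/rᵢⱼ)⁶]

with:

- k = 332.0636 kcal·Å/(mol·e²) (electrostatic constant),
- distance-dependent dielectric ε(r) = 4r (an implicit-solvent
  screening heuristic; the Coulomb term falls off as 1/r²),
- Lennard-Jones parameters per element (packaged CSV; e.g. C:
  σ = 3.40 Å, ε = 0.086 kcal/mol) combined by Lorentz–Berthelot rules
  (arithmetic-mean σ, geometric-mean ε),
- a hard 12 Å cutoff (pairs beyond it contribute exactly zero; no
  switching function, so E is discontinuous at the cutoff — acceptable
  for single-point scoring, unusable for dynamics).

Closed-form anchor: two unit charges at 2 Å with LJ off give
332.0636/(4·2·2) = 20.754 kcal/mol.

Atoms carry a role (`receptor`, `partner`, `ligand`).
`ligand_receptor_energy` sums ligand × everything-else with a
per-residue decomposition over the protein side;
`ppi_energy` sums receptor × partner with per-residue terms on the
receptor. Per-residue terms sum to the total exactly. The disruption
metric is `ΔE = E_holo − E_apo` on the receptor–partner interface;
positive ΔE means the bound ligand weakens the contact. The model does
not relax coordinates — given identical chain coordinates, apo and holo
interface energies are identical, so meaningful disruption values
require conformations produced elsewhere (e.g. minimised or simulated
structures).

Charges are read from a sidecar CSV (`chain,resid,atom_name,charge`);
absent a sidecar all charges default to zero with a warning, leaving
only the LJ term.

## Fragment generation

Seed molecules are decomposed at BRICS bonds. The attachment-point
compatibility matrix and bond orders are derived at import time from
RDKit's published BRICS reaction definitions (labels 7a/7b collapse to
class 7 with a double bond). Decomposition uses bond breaking followed
by connected-component extraction, which preserves fragment
multiplicity — so heavy-atom counts are conserved exactly, a property
the test suite checks, along with single-bond cleave/rejoin round
trips conserving both atom and bond counts.

Generation is a Monte Carlo tree search over assembly states. A state
is a partially built molecule, normalised to its canonical isomeric
SMILES (so identical intermediates reached by different action orders
share statistics and cached rewards — a transposition table). An
action attaches a library fragment at a compatible open point and is
identified by the canonically-sorted triple (state attachment atom,
fragment index, fragment attachment atom). Selection uses UCT:

UCT(s, a) = W(s,a)/N(s,a) + c·√(ln N(s) / N(s,a)), c = √2,

with unvisited actions tried first and deterministic canonical
tie-breaking; `N(s) = 1 + Σₐ N(s,a)` holds by construction. Rollouts
pick uniformly random actions from a seeded `numpy` generator. States
terminate when all attachment points are consumed, or at the depth cap
(default 6 attachments) or heavy-atom cap (default 36). The default
reward combines a size score (logistic in heavy atoms), a
Rule-of-Five indicator, and the surrogate activity score with weights
summing to 1; incomplete molecules (open attachment points) score 0.
Results are deduplicated by canonical SMILES keeping the best reward
and ranked descending, ties broken lexicographically.

## Trajectory analysis

- **Superposition** — Kabsch's least-squares rotation via SVD of the
  cross-covariance matrix, with the determinant sign corrected to
  exclude reflections. Requires ≥3 atoms; near-collinear inputs
  (second singular value < 1e−10 of the first) are rejected as
  degenerate. Under any proper rigid transform the residual RMSD is
  numerically zero (≈1e−14 Å in the checks).
- **RMSD series** — per-frame backbone (N, CA, C, O) RMSD to the first
  frame after superposition.
- **RMSF** — atoms are first fitted to the average structure
  iteratively (two passes: fit to the frame-0-fitted mean, recompute
  the mean, refit); RMSF per residue is the root-mean-square deviation
  of the selected atom (CA, or side-chain mode) from its mean
  position. Residues lacking the selected atom are absent from the
  result, not reported as zero.
- **Representative conformers** — the frames with the largest and
  smallest RMSD to the average structure.
- **Rupture peak** — the maximum of the force trace after a centered
  moving average (window in ps converted to samples via the median
  time step); ties resolve to the earliest time.
- **Pull work** — W = v·∫F dt by the trapezoid rule, with the pulling
  velocity converted from Å/ps to nm/ps so kJ/mol/nm forces integrate
  to kJ/mol.

## Synthetic fixtures and their realism limits

The fixture generators reproduce the *shapes and invariants* of real
inputs, not their chemistry or physics. All are pure functions of
their arguments including an explicit seed.

- **Score lists** are uniform on [−12, −2] kcal/mol with per-value
  distinctness guaranteed by binning; real docking scores are neither
  uniform nor independent of chemistry.
- **SMILES libraries** are built from a small fixed set of drug-like
  cores/tails and deliberate Rule-of-Five violators, optionally with a
  planted p-quinone PAINS motif; they exercise the filters, not
  chemical diversity.
- **Toy complexes** are coarse helical CA/CB lattices ~14 Å apart with
  a bond-length-spaced ligand chain midway between them — spacings are
  chosen so no pair sits on the steep LJ wall, keeping energies O(1)
  kcal/mol. Charges are small Gaussians. These are geometric props
  for the energy code, not protein models.
- **Harmonic trajectories** oscillate each residue's CA along a random
  direction with a random phase over an integer number of periods, so
  the expected RMSF has the closed form A/√2. Amplitude recovery is
  only clean when few residues move against a rigid scaffold: if most
  of the structure oscillates, the superposition fit absorbs part of
  the collective motion and biases RMSF low. The recovery checks
  therefore plant 3 moving residues among 60 static ones and see
  relative errors of a few percent against a 5% tolerance.
- **Force curves** rise linearly to a planted peak then decay
  exponentially (τ = a third of the remaining time). The peak time is
  snapped to the nearest time-grid point so zero-noise recovery is
  exact rather than within-half-a-step.

## Numerical choices

- All numerics are float64 `numpy`; pairwise energies are evaluated
  vectorized over the full distance matrix and validated against an
  O(n²) scalar double loop to ~1e−15 kcal/mol.
- All randomness flows through `numpy.random.default_rng(seed)`;
  no global RNG state is touched. CLI outputs are byte-reproducible
  for fixed inputs and seeds.
- Survivor counts use integer `floor` arithmetic, never rounding.
- Stable sorts with explicit tie-break keys are used everywhere an
  ordering can affect output (funnel selection, action ordering,
  result ranking).

## Limitations

- The energy model is a single-point surrogate: no solvation model
  beyond the ε(r) = 4r heuristic, no polarisation, no minimisation,
  a discontinuous cutoff, and element-level (not atom-type) LJ
  parameters. Its numbers are useful for ranking within this toolkit,
  not comparable to MM-GBSA or experimental affinities.
- The activity predictor and pseudo docking scorer are deterministic
  stand-ins with no predictive validity.
- The MCTS explores fragment spaces defined by its library; it cannot
  invent atoms or bonds outside BRICS chemistry, and ring-forming
  reactions are out of scope (ring bonds are not cleavable).
- Trajectory tools assume topology-constant, pre-imaged coordinates;
  there is no periodic-boundary handling.
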