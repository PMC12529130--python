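"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments including an explicit
integer seed, so reruns are byte-identical and no downloads or external
engines are needed: pseudo docking-score lists for funnel arithmetic,
small SMILES libraries stratified into drug-like and non-drug-like
molecules (optionally with a planted promiscuous-binder motif), toy
two-chain protein complexes with an interface ligand for the energy
model, harmonic trajectories with known fluctuation amplitudes, and
rise-then-decay pull-force curves with a planted rupture peak.

These fixtures emulate the shapes and invariants of real inputs, not
their chemistry or physics: score distributions are uniform, toy
complexes are lattice constructs, and trajectories are noiseless
oscillators unless asked otherwise.
"""

from __future__ import annotations

import numpy as np

from .chem import Molecule, parse_smiles
from .energy import Structure
from .trajectory import ForceProfile, Trajectory

__all__ = [
    "gen_scores",
    "gen_smiles_library",
    "gen_toy_complex",
    "gen_harmonic_trajectory",
    "gen_force_curve",
    "PLANTED_PAINS_SMILES",
]

# 2,5-cyclohexadiene-1,4-dione (p-quinone) core with a tail: matches the
# quinone family of the packaged PAINS alerts by construction.
PLANTED_PAINS_SMILES = "O=C1C=CC(=O)C(CCN)=C1"


def gen_scores(n: int, seed: int) -> np.ndarray:
    """n distinct pseudo docking scores (kcal/mol) in about [-12, -2].

    Each value falls in its own bin of a shuffled uniform grid, so
    distinctness holds by construction for any n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bins = rng.permutation(n).astype(float)
    offsets = rng.random(n) * 0.999
    return -12.0 + 10.0 * (bins + offsets) / n


_PASS_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccc2[nH]ccc2c1", "C1CCNCC1", "c1ccsc1",
    "C1CCOC1", "c1ccc2ccccc2c1",
]
_PASS_TAILS = ["C(=O)N", "CCO", "C(=O)OC", "CN", "CC(C)O", "S(=O)(=O)N", "OC"]
# deliberately Rule-of-Five-violating: long greasy chains (high logP) or
# polyol/guanidine chains (donor counts above 5)
_FAIL_SMILES = [
    "CCCCCCCCCCCCCCCCCCCCCCCC",
    "CCCCCCCCCCCCCCCCc1ccccc1",
    "OCC(O)C(O)C(O)C(O)C(O)C(O)CO",
    "NC(N)=NCCCC(N)C(=O)NC(CCCN=C(N)N)C(=O)NC(CO)C(O)CO",
    "CCCCCCCCCCCCCCCCCCCC(=O)OCC",
]


def gen_smiles_library(
    n: int,
    seed: int,
    fail_fraction: float = 0.3,
    plant_pains: bool = False,
) -> list[Molecule]:
    """A reproducible library of n parseable molecules.

    Roughly ``1 - fail_fraction`` of the molecules are drug-like
    (aromatic/saturated cores with small polar tails) and the rest
    violate the Rule of Five by construction.  With ``plant_pains`` the
    first molecule carries a p-quinone motif that the packaged PAINS
    alerts flag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Molecule] = []
    for i in range(n):
        if plant_pains and i == 0:
            smi = PLANTED_PAINS_SMILES
        elif rng.random() < fail_fraction:
            smi = _FAIL_SMILES[rng.integers(len(_FAIL_SMILES))]
        else:
            core = _PASS_CORES[rng.integers(len(_PASS_CORES))]
            tail = _PASS_TAILS[rng.integers(len(_PASS_TAILS))]
            smi = core + tail
        out.append(parse_smiles(smi, name=f"M{i:06d}"))
    return out


def _helical_chain(n_res: int, chain: str, origin: np.ndarray,
                   role: str, rng: np.random.Generator) -> list[tuple]:
    """CA + pseudo side-chain (CB) residues on a coarse helical lattice."""
    rows = []
    for r in range(n_res):
        theta = 100.0 * np.pi / 180.0 * r
        ca = origin + np.array(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * r])
        cb = ca + np.array([1.5 * np.cos(theta), 1.5 * np.sin(theta), 0.0])
        rows.append(("C", float(rng.normal(0.0, 0.15)), ca, chain, r + 1,
                     "ALA", "CA", role))
        rows.append((str(rng.choice(["C", "N", "O"])),
                     float(rng.normal(0.0, 0.15)), cb, chain, r + 1,
                     "ALA", "CB", role))
    return rows


def gen_toy_complex(
    n_res_a: int,
    n_res_b: int,
    ligand_atoms: int,
    seed: int,
    ligand_offset: np.ndarray | None = None,
) -> Structure:
    """A two-chain toy complex with a ligand at the interface.

    Chain A (role receptor) and chain B (role partner) are coarse helical
    traces about 14 A apart (surface gap a few angstroms, inside the
    interaction cutoff); the ligand sits midway between them unless
    ``ligand_offset`` displaces it (e.g. 100 A away to zero out all
    interactions).  Charges are small seeded Gaussians.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = _helical_chain(n_res_a, "A", np.zeros(3), "receptor", rng)
    rows += _helical_chain(n_res_b, "B", np.array([14.0, 0.0, 0.0]),
                           "partner", rng)
    mid = np.array([7.0, 0.0, 0.75 * min(n_res_a, n_res_b)])
    if ligand_offset is not None:
        mid = mid + np.asarray(ligand_offset, dtype=float)
    for k in range(ligand_atoms):
        # chain of ~bond-length-spaced atoms along z with a small jitter,
        # so no atom overlaps the protein lattice
        pos = (mid + np.array([0.0, 0.0, 1.4 * (k - ligand_atoms / 2.0)])
               + rng.normal(0.0, 0.15, size=3))
        rows.append((str(rng.choice(["C", "N", "O"])),
                     float(rng.normal(0.0, 0.2)), pos, "L", 1, "LIG",
                     f"L{k + 1}", "ligand"))
    elements, charges, coords, chains, rids, rnames, anames, roles = zip(*rows)
    return Structure(
        elements=np.array(elements, dtype=str),
        charges=np.array(charges, dtype=float),
        coords=np.array([np.asarray(c, dtype=float) for c in coords]),
        chains=np.array(chains, dtype=str),
        res_ids=np.array(rids, dtype=int),
        res_names=np.array(rnames, dtype=str),
        atom_names=np.array(anames, dtype=str),
        roles=np.array(roles, dtype=str),
    )


def gen_harmonic_trajectory(
    amplitudes: np.ndarray,
    frames: int,
    seed: int,
    cycles: int = 3,
    noise_sd: float = 0.0,
    include_side_chains: bool = True,
) -> Trajectory:
    """Each residue's CA oscillates sinusoidally with its amplitude.

    Residue i moves along a seeded random unit direction with a random
    phase, over exactly ``cycles`` whole periods, so each atom's RMSF has
    the closed form A/sqrt(2) (up to fitting error and noise).  A static
    CB pseudo side-chain atom accompanies each CA when
    ``include_side_chains``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if frames < 2:
        raise ValueError("a trajectory for RMSF needs at least 2 frames")
    rng = np.random.default_rng(seed)
    n_res = amplitudes.size
    rows: list[tuple[np.ndarray, str, int]] = []
    for i in range(n_res):
        ca = np.array([4.0 * i, 3.0 * ((-1) ** i), 0.5 * i])
        rows.append((ca, "CA", i + 1))
        if include_side_chains:
            rows.append((ca + np.array([0.0, 1.5, 0.8]), "CB", i + 1))
    base = np.array([r[0] for r in rows])
    names = np.array([r[1] for r in rows])
    rids = np.array([r[2] for r in rows], dtype=int)

    dirs = rng.normal(size=(n_res, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_res)
    theta = 2.0 * np.pi * cycles * np.arange(frames) / frames

    coords = np.repeat(base[None, :, :], frames, axis=0)
    ca_rows = np.flatnonzero(names == "CA")
    for i, row in enumerate(ca_rows):
        disp = amplitudes[i] * np.sin(theta + phases[i])
        coords[:, row, :] += disp[:, None] * dirs[i]
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    return Trajectory(
        coords=coords,
        atom_names=names,
        chains=np.array(["A"] * len(names)),
        res_ids=rids,
    )


def gen_force_curve(
    peak: float,
    t_peak: float,
    noise_sd: float,
    seed: int,
    n_samples: int = 1001,
    t_end: float = 1000.0,
    velocity_a_ps: float = 0.1,
    spring_kj_nm2: float = 200.0,
) -> ForceProfile:
    """Linear rise to a rupture peak, then exponential decay, plus noise.

    The peak time is snapped to the nearest time-grid point so the
    planted (peak, time) pair is recovered exactly at zero noise.
    Default pulling metadata matches a constant-velocity spring pull at
    0.1 A/ps with a 200 kJ/mol/nm^2 spring.
    """
    if not 0.0 < t_peak < t_end:
        raise ValueError("t_peak must lie inside (0, t_end)")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_samples)
    k_peak = int(np.argmin(np.abs(t - t_peak)))
    tp = t[k_peak]
    tau = max((t_end - tp) / 3.0, 1e-9)
    force = np.where(t <= tp, peak * t / max(tp, 1e-12),
                     peak * np.exp(-(t - tp) / tau))
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return ForceProfile(
        time_ps=t,
        force_kj_nm=force,
        velocity_a_ps=velocity_a_ps,
        spring_kj_nm2=spring_kj_nm2,
    )
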