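"""Simplified pairwise nonbonded interaction energies with per-residue
decomposition and an apo-vs-holo interface-disruption metric.

This is an explicitly labelled surrogate for MM-GBSA-style rescoring: the
generalized-Born solvent screening is approximated by a distance-dependent
dielectric eps(r) = 4r, a classic implicit-screening trick, combined with
a Lennard-Jones term under Lorentz-Berthelot mixing and a hard 12 A
cutoff:

    E(i,j) = 332.0636 q_i q_j / (4 r^2)
           + 4 eps_ij [ (sigma_ij / r)^12 - (sigma_ij / r)^6 ]

with r in angstroms, charges in elementary units and energies in
kcal/mol.  Absolute values are not comparable to real MM-GBSA numbers;
the module exists so every funnel stage, the generator reward and the
per-residue decomposition can run end to end without proprietary
engines, and externally computed MM-GBSA values are equally accepted as
plain score columns.

The protein-protein disruption metric is the bookkeeping the apo/holo
comparison needs: holo interface energy minus apo interface energy, so a
positive value means the ligand weakened the interface.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

__all__ = [
    "Structure",
    "EnergyBreakdown",
    "COULOMB_CONSTANT",
    "CUTOFF_ANGSTROM",
    "lj_parameters",
    "pair_energy",
    "ligand_receptor_energy",
    "ppi_energy",
    "ppi_disruption",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)
DIELECTRIC_SLOPE = 4.0       # eps(r) = 4r
CUTOFF_ANGSTROM = 12.0

ROLES = ("receptor", "partner", "ligand")


def lj_parameters() -> dict[str, tuple[float, float]]:
    """Packaged per-element (sigma A, epsilon kcal/mol) table."""
    table: dict[str, tuple[float, float]] = {}
    ref = resources.files("winfunnel.data").joinpath("lj_params.csv")
    with ref.open() as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            table[row[0].strip()] = (float(row[1]), float(row[2]))
    return table


_LJ = lj_parameters()


class ParameterError(KeyError):
    """An element has no Lennard-Jones parameter entry."""


@dataclass
class Structure:
    """Atoms with coordinates, charges and role tags; no periodicity.

    Roles partition the system into receptor, partner (the second protein
    chain of a complex) and ligand.  Residue ids are 1-based, as in PDB
    files, and unique within a chain.
    """

    elements: np.ndarray        # (n,) str
    charges: np.ndarray         # (n,) float, elementary units
    coords: np.ndarray          # (n, 3) float, angstrom
    chains: np.ndarray          # (n,) str
    res_ids: np.ndarray         # (n,) int
    res_names: np.ndarray       # (n,) str
    atom_names: np.ndarray      # (n,) str
    roles: np.ndarray           # (n,) str in ROLES

    def __post_init__(self) -> None:
        n = len(self.elements)
        for name in ("charges", "coords", "chains", "res_ids",
                     "res_names", "atom_names", "roles"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.elements)

    def mask(self, role: str) -> np.ndarray:
        return self.roles == role

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(*(getattr(self, f)[mask] for f in (
            "elements", "charges", "coords", "chains", "res_ids",
            "res_names", "atom_names", "roles")))


@dataclass
class EnergyBreakdown:
    """Total energy split into Coulomb and LJ, plus a per-residue map.

    The per-residue entries sum to the total (conservation); each
    atom-pair contribution is assigned to the protein residue involved.
    """

    total: float
    coulomb: float
    lj: float
    per_residue: dict[tuple[str, int], float] = field(default_factory=dict)


def _sigma_eps(elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    missing = sorted({e for e in np.unique(elements) if e not in _LJ})
    if missing:
        raise ParameterError(f"no LJ parameters for elements {missing}")
    sig = np.array([_LJ[e][0] for e in elements])
    eps = np.array([_LJ[e][1] for e in elements])
    return sig, eps


def pair_energy(
    q_i: float, q_j: float, r: float,
    element_i: str = "C", element_j: str = "C",
    lj: bool = True,
) -> float:
    """Screened-Coulomb + LJ energy of one atom pair, kcal/mol.

    Zero beyond the 12 A hard cutoff.  r = 0 is a singularity error.
    """
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    if r > CUTOFF_ANGSTROM:
        return 0.0
    e = COULOMB_CONSTANT * q_i * q_j / (DIELECTRIC_SLOPE * r * r)
    if lj:
        (s_i, e_i), (s_j, e_j) = _lookup(element_i), _lookup(element_j)
        sigma = 0.5 * (s_i + s_j)
        eps = np.sqrt(e_i * e_j)
        sr6 = (sigma / r) ** 6
        e += 4.0 * eps * (sr6 * sr6 - sr6)
    return float(e)


def _lookup(element: str) -> tuple[float, float]:
    try:
        return _LJ[element]
    except KeyError:
        raise ParameterError(f"no LJ parameters for element {element!r}") from None


def _cross_energy(
    s: Structure,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    residue_side: np.ndarray,
    lj: bool = True,
) -> EnergyBreakdown:
    """Vectorized sum of pair energies over the A x B atom cross product.

    residue_side selects which side's (chain, residue) keys receive each
    pair's contribution in the per-residue map.
    """
    a = s.subset(mask_a)
    b = s.subset(mask_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both atom groups must be non-empty")
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r <= 0):
        raise ValueError("zero interatomic distance between groups")
    within = r <= CUTOFF_ANGSTROM
    inv_r2 = np.where(within, 1.0 / (r * r), 0.0)
    coul = COULOMB_CONSTANT / DIELECTRIC_SLOPE * np.outer(a.charges, b.charges) * inv_r2
    if lj:
        sig_a, eps_a = _sigma_eps(a.elements)
        sig_b, eps_b = _sigma_eps(b.elements)
        sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
        eps = np.sqrt(np.outer(eps_a, eps_b))
        with np.errstate(divide="ignore"):
            sr6 = np.where(within, (sigma / np.where(within, r, 1.0)) ** 6, 0.0)
        ljm = 4.0 * eps * (sr6 * sr6 - sr6)
    else:
        ljm = np.zeros_like(coul)
    pairwise = coul + ljm
    # per-residue assignment on the requested side
    side_struct = a if residue_side is mask_a else b
    axis = 1 if residue_side is mask_a else 0
    per_res: dict[tuple[str, int], float] = {}
    sums = pairwise.sum(axis=axis)
    for chain, rid, val in zip(side_struct.chains, side_struct.res_ids, sums):
        key = (str(chain), int(rid))
        per_res[key] = per_res.get(key, 0.0) + float(val)
    return EnergyBreakdown(
        total=float(pairwise.sum()),
        coulomb=float(coul.sum()),
        lj=float(ljm.sum()),
        per_residue=per_res,
    )


def ligand_receptor_energy(s: Structure, lj: bool = True) -> EnergyBreakdown:
    """Interaction energy of the ligand with all protein atoms.

    Sums pair energies over ligand x (receptor + partner); the
    per-residue map assigns each pair to the protein residue involved.
    """
    lig = s.mask("ligand")
    prot = ~lig
    if not lig.any():
        raise ValueError("structure has no ligand atoms")
    if not prot.any():
        raise ValueError("structure has no protein atoms")
    return _cross_energy(s, lig, prot, residue_side=prot, lj=lj)


def ppi_energy(s: Structure, lj: bool = True) -> EnergyBreakdown:
    """Receptor-partner interface energy; ligand atoms are excluded.

    The per-residue map is keyed by receptor-chain residues.
    """
    rec = s.mask("receptor")
    par = s.mask("partner")
    if not rec.any():
        raise ValueError("structure has no receptor atoms")
    if not par.any():
        raise ValueError("structure has no partner atoms")
    return _cross_energy(s, rec, par, residue_side=rec, lj=lj)


def ppi_disruption(apo_energy: float, holo_energy: float) -> float:
    """Interface-weakening metric: holo minus apo interface energy.

    Positive means the bound ligand weakened the protein-protein
    interface (the holo interface is less negative); negative means
    stabilization.  E.g. apo -119.7 and holo -80.6 kcal/mol give +39.1.
    """
    if not (np.isfinite(apo_energy) and np.isfinite(holo_energy)):
        raise ValueError("energies must be finite")
    return holo_energy - apo_energy
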