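"""Readers, writers, and configuration for the screening pipeline.

Formats: SMILES files (one molecule per line, optional whitespace-
separated name), SDF (read-only), PDB (read/write through biotite's
fixed-column parser, altLoc resolved by occupancy), charge sidecar CSV,
two-column force traces, trajectory CSV frames, funnel-report CSV, and
TOML/JSON pipeline configuration with strict schema validation.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .cascade import FunnelReport, ScoredItem, TierSpec
from .chem import Molecule, MoleculeParseError, compute_descriptors, parse_smiles
from .energy import EnergyBreakdown, Structure
from .filters import (SurrogateActivityPredictor, activity_gate,
                      default_pains_catalog, pains_scan, ro5_check)
from .trajectory import ForceProfile, Trajectory

__all__ = [
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
    "read_pdb_structure",
    "write_pdb_structure",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_force_profile",
    "write_funnel_report",
    "write_energy_breakdown",
    "load_config",
    "build_tiers",
    "pseudo_scorer",
]


# ---------------------------------------------------------------- molecules

def read_smiles_file(path: str | Path) -> tuple[list[Molecule], list[tuple[int, str, str]]]:
    """Parse a SMILES file; failures are collected, not fatal.

    Returns (molecules, failures); each failure is (line number, line,
    message).  Ids are the optional name, else ``L<line number>``.
    Blank lines and ``#`` comments are skipped.
    """
    mols: list[Molecule] = []
    failures: list[tuple[int, str, str]] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(None, 1)
        smi = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"L{lineno}"
        try:
            mols.append(parse_smiles(smi, name=name))
        except MoleculeParseError as exc:
            failures.append((lineno, stripped, str(exc)))
    if not mols and not failures:
        warnings.warn(f"{path}: no molecules found", stacklevel=2)
    return mols, failures


def write_smiles_file(
    path: str | Path,
    mols: Sequence[Molecule],
    scores: Sequence[dict[str, float]] | None = None,
) -> None:
    """SMILES + name (+ tab-separated score columns) per line."""
    lines = []
    for i, m in enumerate(mols):
        cols = [m.to_smiles(), m.name or f"M{i}"]
        if scores is not None:
            cols += [f"{k}={v:.6g}" for k, v in sorted(scores[i].items())]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sdf(path: str | Path) -> list[Molecule]:
    """Molecules from an SDF file (2D/3D blocks; coordinates ignored)."""
    out = []
    for i, m in enumerate(Chem.SDMolSupplier(str(path), removeHs=True)):
        if m is None:
            continue
        name = m.GetProp("_Name") if m.HasProp("_Name") else f"S{i + 1}"
        out.append(Molecule(m, name=name or f"S{i + 1}",
                            source_smiles=Chem.MolToSmiles(m)))
    return out


# ---------------------------------------------------------------- structures

def _read_charge_sidecar(path: str | Path) -> dict[tuple[str, int, str], float]:
    df = pd.read_csv(path)
    needed = {"chain", "resid", "atom_name", "charge"}
    if not needed.issubset(df.columns):
        raise ValueError(f"charge sidecar must have columns {sorted(needed)}")
    return {
        (str(r.chain), int(r.resid), str(r.atom_name)): float(r.charge)
        for r in df.itertuples()
    }


def read_pdb_structure(
    path: str | Path,
    charge_sidecar: str | Path | None = None,
    hetatm_role: str = "ligand",
    chain_roles: dict[str, str] | None = None,
) -> Structure:
    """Structure from a PDB file (fixed-column parse via biotite).

    altLoc duplicates keep the highest occupancy; missing element fields
    are inferred from the atom name with a warning.  HETATM records get
    ``hetatm_role`` (default ligand).  ATOM chains map to roles via
    ``chain_roles``; by default the first chain is the receptor and the
    rest are partners.  Charges come from a sidecar CSV (chain, resid,
    atom_name, charge) and default to zero with a warning if absent.
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(
        model=1, altloc="occupancy", extra_fields=["charge"])
    elements = arr.element.astype(str)
    blank = elements == ""
    if blank.any():
        warnings.warn("element column missing for some atoms; inferring "
                      "from atom names", stacklevel=2)
        inferred = np.array([n.strip()[:1] for n in arr.atom_name])
        elements = np.where(blank, inferred, elements)

    het = arr.hetero
    protein_chains = sorted(set(arr.chain_id[~het].tolist()))
    roles = np.empty(arr.array_length(), dtype=object)
    for i in range(arr.array_length()):
        if het[i]:
            roles[i] = hetatm_role
        elif chain_roles is not None:
            roles[i] = chain_roles[str(arr.chain_id[i])]
        else:
            roles[i] = ("receptor" if arr.chain_id[i] == protein_chains[0]
                        else "partner")

    charges = np.zeros(arr.array_length())
    if charge_sidecar is not None:
        table = _read_charge_sidecar(charge_sidecar)
        for i in range(arr.array_length()):
            key = (str(arr.chain_id[i]), int(arr.res_id[i]),
                   str(arr.atom_name[i]))
            if key in table:
                charges[i] = table[key]
    else:
        warnings.warn("no charge sidecar given; all charges set to zero",
                      stacklevel=2)

    return Structure(
        elements=elements.astype(str),
        charges=charges,
        coords=np.asarray(arr.coord, dtype=float),
        chains=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        roles=roles.astype(str),
    )


def write_pdb_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure to PDB; ligand atoms become HETATM records.

    Charges are not representable in PDB columns; write a sidecar with
    :func:`write_charge_sidecar` to round-trip them.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(s)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(s.coords, dtype=np.float32)
    arr.chain_id = s.chains.astype("U4")
    arr.res_id = s.res_ids
    arr.res_name = s.res_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = s.roles == "ligand"
    f = PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def write_charge_sidecar(s: Structure, path: str | Path) -> None:
    pd.DataFrame({
        "chain": s.chains, "resid": s.res_ids,
        "atom_name": s.atom_names, "charge": s.charges,
    }).to_csv(path, index=False)


# --------------------------------------------------------------- trajectories

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Long-format frames: frame, atom, name, chain, resid, x, y, z."""
    f_idx, a_idx = np.meshgrid(np.arange(traj.n_frames),
                               np.arange(traj.n_atoms), indexing="ij")
    flat = traj.coords.reshape(-1, 3)
    pd.DataFrame({
        "frame": f_idx.ravel(), "atom": a_idx.ravel(),
        "name": np.tile(traj.atom_names, traj.n_frames),
        "chain": np.tile(traj.chains, traj.n_frames),
        "resid": np.tile(traj.res_ids, traj.n_frames),
        "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2],
    }).to_csv(path, index=False, float_format="%.6f")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    frames = int(df["frame"].max()) + 1
    atoms = int(df["atom"].max()) + 1
    df = df.sort_values(["frame", "atom"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy().reshape(frames, atoms, 3)
    first = df[df["frame"] == df["frame"].min()]
    return Trajectory(
        coords=coords,
        atom_names=first["name"].to_numpy(dtype=str),
        chains=first["chain"].to_numpy(dtype=str),
        res_ids=first["resid"].to_numpy(dtype=int),
    )


def read_multimodel_pdb_trajectory(path: str | Path) -> Trajectory:
    """Trajectory from a multi-MODEL PDB file."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure(altloc="occupancy")
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=stack.atom_name.astype(str),
        chains=stack.chain_id.astype(str),
        res_ids=stack.res_id.astype(int),
    )


def read_force_profile(
    path: str | Path,
    velocity_a_ps: float | None = None,
    spring_kj_nm2: float | None = None,
) -> ForceProfile:
    """Two-column whitespace/comma text: time (ps), force (kJ/mol/nm)."""
    data = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
    if data.shape[1] < 2:
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return ForceProfile(time_ps=data[:, 0], force_kj_nm=data[:, 1],
                        velocity_a_ps=velocity_a_ps,
                        spring_kj_nm2=spring_kj_nm2)


# ------------------------------------------------------------------- reports

def write_funnel_report(report: FunnelReport, path: str | Path) -> None:
    """Deterministic CSV: tier, rule, n_in, n_out, n_failed."""
    cols = ["tier", "rule", "n_in", "n_out", "n_failed"]
    pd.DataFrame(report.rows, columns=cols).to_csv(path, index=False)


def write_energy_breakdown(b: EnergyBreakdown, path: str | Path) -> None:
    rows = [{"chain": c, "resid": r, "energy_kcal": e}
            for (c, r), e in sorted(b.per_residue.items())]
    df = pd.DataFrame(rows, columns=["chain", "resid", "energy_kcal"])
    with open(path, "w") as fh:
        fh.write(f"# total={b.total:.6f} coulomb={b.coulomb:.6f} "
                 f"lj={b.lj:.6f} kcal/mol\n")
        df.to_csv(fh, index=False, float_format="%.6f")


# --------------------------------------------------------------------- config

_TOP_KEYS = {"tiers", "seed", "pains_families", "activity_threshold"}
_TIER_KEYS = {"name", "kind", "fraction", "cutoff", "direction", "strict",
              "higher_is_better", "scorer", "gate"}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


def load_config(path: str | Path) -> dict:
    """TOML (or JSON) pipeline config, schema-validated; unknown keys
    are rejected."""
    path = Path(path)
    if path.suffix == ".json":
        cfg = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    tiers = cfg.get("tiers")
    if not tiers:
        raise ConfigError("config must define at least one tier")
    for t in tiers:
        bad = set(t) - _TIER_KEYS
        if bad:
            raise ConfigError(f"tier {t.get('name')!r}: unknown keys {sorted(bad)}")
        if "name" not in t or "kind" not in t:
            raise ConfigError("every tier needs 'name' and 'kind'")
        if t["kind"] == "top_fraction" and "fraction" not in t:
            raise ConfigError(f"tier {t['name']!r}: top_fraction needs 'fraction'")
        if t["kind"] == "threshold" and "cutoff" not in t:
            raise ConfigError(f"tier {t['name']!r}: threshold needs 'cutoff'")
        if t["kind"] not in ("top_fraction", "threshold"):
            raise ConfigError(f"tier {t['name']!r}: unknown kind {t['kind']!r}")
    return cfg


def pseudo_scorer(tier_name: str, seed: int) -> Callable[[ScoredItem], float]:
    """A deterministic stand-in scorer: a seeded hash of the item id
    mapped into the typical docking-score range [-12, -2] kcal/mol.

    Uses a cryptographic hash so scores for different tier names are
    effectively independent (a linear checksum such as CRC32 makes tier
    scores XOR-correlated, which collapses multi-tier funnels).
    """
    def score(item: ScoredItem) -> float:
        digest = hashlib.sha256(
            f"{seed}:{tier_name}:{item.id}".encode()).digest()
        h = int.from_bytes(digest[:8], "big")
        return -12.0 + 10.0 * (h / 2**64)
    return score


def _make_gate(name: str, cfg: dict) -> Callable[[ScoredItem], bool]:
    if name == "ro5":
        return lambda it: ro5_check(compute_descriptors(it.payload)).passes
    if name == "pains":
        catalog = default_pains_catalog(
            tuple(cfg.get("pains_families", ("A", "B", "C"))))
        return lambda it: not pains_scan(it.payload, catalog)
    if name == "activity":
        predictor = SurrogateActivityPredictor()
        thr = float(cfg.get("activity_threshold", 0.5))
        return lambda it: activity_gate(it.payload, predictor, thr)
    raise ConfigError(f"unknown gate {name!r}")


def build_tiers(cfg: dict, seed: int | None = None) -> list[TierSpec]:
    """Materialize TierSpecs from a validated config dict.

    Scorer 'pseudo' attaches the seeded stand-in scorer; scorer
    'column:<name>' expects preloaded scores under <name>; no scorer
    means scores must already be present under the tier name.
    """
    seed = int(cfg.get("seed", 0)) if seed is None else seed
    tiers = []
    for t in cfg["tiers"]:
        scorer = None
        tier_name = t["name"]
        spec_scorer = t.get("scorer")
        if spec_scorer == "pseudo":
            scorer = pseudo_scorer(tier_name, seed)
        elif spec_scorer and spec_scorer.startswith("column:"):
            col = spec_scorer.split(":", 1)[1]
            scorer = (lambda c: lambda it: it.score_for(c))(col)
        elif spec_scorer:
            raise ConfigError(f"unknown scorer {spec_scorer!r}")
        if t["kind"] == "top_fraction":
            selection = ("top_fraction", float(t["fraction"]))
        else:
            selection = ("threshold", float(t["cutoff"]),
                         t.get("direction", "le"))
        gate = _make_gate(t["gate"], cfg) if t.get("gate") else None
        tiers.append(TierSpec(
            name=tier_name, selection=selection, scorer=scorer, gate=gate,
            higher_is_better=bool(t.get("higher_is_better", False)),
            strict=bool(t.get("strict", False)),
        ))
    return tiers
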