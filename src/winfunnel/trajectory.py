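"""Post-MD and steered-MD analysis: superposition RMSD, per-residue RMSF,
representative conformers, and pull-force profile characterization.

All coordinate analysis is least-squares rigid-body superposition (the
Kabsch SVD construction, with the determinant correction that guarantees
a proper rotation).  RMSD compares one frame with a reference over a
selection; RMSF measures each atom's fluctuation about its mean position
after the whole trajectory has been superposed onto an iteratively
refined average structure.

Units follow the conventions of the field: coordinates and RMSD/RMSF in
angstroms, time in picoseconds, pull forces in kJ/mol/nm, pulling
velocity in angstrom/ps, spring constants in kJ/mol/nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Trajectory",
    "ForceProfile",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "representative_conformers",
    "force_peak",
    "pull_work",
    "BACKBONE_ATOMS",
    "kj_per_nm_to_kcal_per_angstrom",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

KJ_PER_KCAL = 4.184


def kj_per_nm_to_kcal_per_angstrom(force_kj_nm: float) -> float:
    """Convert a pull force from kJ/mol/nm to kcal/mol/A."""
    return force_kj_nm / KJ_PER_KCAL / 10.0


@dataclass
class Trajectory:
    """Frame-indexed coordinates with fixed atom order and metadata."""

    coords: np.ndarray      # (n_frames, n_atoms, 3) angstrom
    atom_names: np.ndarray  # (n_atoms,) str
    chains: np.ndarray      # (n_atoms,) str
    res_ids: np.ndarray     # (n_atoms,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.coords.shape[1]
        for name in ("atom_names", "chains", "res_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names, BACKBONE_ATOMS)


@dataclass
class ForceProfile:
    """A steered-MD force-time trace with pulling metadata."""

    time_ps: np.ndarray
    force_kj_nm: np.ndarray
    velocity_a_ps: float | None = None     # pulling velocity, angstrom/ps
    spring_kj_nm2: float | None = None     # spring constant, kJ/mol/nm^2
    axis: str = "z"

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.force_kj_nm = np.asarray(self.force_kj_nm, dtype=float)
        if self.time_ps.shape != self.force_kj_nm.shape:
            raise ValueError("time and force series must have equal length")
        if self.time_ps.size and np.any(np.diff(self.time_ps) <= 0):
            raise ValueError("time must be strictly increasing")


def kabsch_superpose(
    ref: np.ndarray,
    mobile: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of mobile onto ref.

    Returns (rotation R, translation t, rmsd) such that
    ``mobile @ R.T + t`` minimizes the RMSD over the selection.  R is a
    proper rotation (det = +1).  Degenerate (collinear) selections are
    rejected.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if selection is not None:
        ref_s, mob_s = ref[selection], mobile[selection]
    else:
        ref_s, mob_s = ref, mobile
    if ref_s.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    mu_r = ref_s.mean(axis=0)
    mu_m = mob_s.mean(axis=0)
    a = ref_s - mu_r
    b = mob_s - mu_m
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    fitted = mob_s @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_s) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_series(
    traj: Trajectory,
    ref_frame: int = 0,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame superposition RMSD against a reference frame.

    Default selection is the protein backbone (N, CA, C, O atoms).
    """
    if selection is None:
        selection = traj.backbone_mask()
    if not np.any(selection):
        raise ValueError("empty atom selection")
    ref = traj.coords[ref_frame]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        _, _, out[k] = kabsch_superpose(ref, traj.coords[k], selection)
    return out


def _superpose_to_average(traj: Trajectory, passes: int = 2) -> np.ndarray:
    """Fit all frames to an iteratively refined average structure.

    Pass 1 fits to the mean of raw frames; the mean is recomputed from
    the fitted frames and the fit repeated (2 passes by default).
    Returns the fitted coordinates, shape (frames, atoms, 3).
    """
    fitted = traj.coords.copy()
    for _ in range(passes):
        avg = fitted.mean(axis=0)
        for k in range(fitted.shape[0]):
            rot, trans, _ = kabsch_superpose(avg, fitted[k])
            fitted[k] = fitted[k] @ rot.T + trans
    return fitted


def rmsf_per_residue(
    traj: Trajectory,
    mode: Literal["CA", "side-chain"] = "CA",
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (angstrom) after 2-pass average-structure fitting.

    Per atom, RMSF = sqrt(mean over frames of squared displacement from
    the atom's mean position).  CA mode reports each residue's CA atom;
    side-chain mode averages over non-backbone heavy atoms and omits
    residues that have none (e.g. glycine) rather than reporting zero.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fitted = _superpose_to_average(traj)
    mean_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))

    out: dict[tuple[str, int], float] = {}
    residues = sorted(set(zip(traj.chains.tolist(), traj.res_ids.tolist())),
                      key=lambda cr: (cr[0], cr[1]))
    backbone = traj.backbone_mask()
    for chain, rid in residues:
        in_res = (traj.chains == chain) & (traj.res_ids == rid)
        if mode == "CA":
            sel = in_res & (traj.atom_names == "CA")
        elif mode == "side-chain":
            sel = in_res & ~backbone & ~np.char.startswith(
                traj.atom_names.astype(str), "H")
        else:
            raise ValueError("mode must be 'CA' or 'side-chain'")
        if np.any(sel):
            out[(str(chain), int(rid))] = float(per_atom[sel].mean())
    return out


def representative_conformers(traj: Trajectory) -> tuple[int, int, np.ndarray]:
    """Indices of the two frames closest to the average structure.

    Frames are superposed onto the 2-pass refined average; the return is
    (best index, second-best index, rmsd-to-average per frame).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to pick two conformers")
    fitted = _superpose_to_average(traj)
    avg = fitted.mean(axis=0)
    d = np.sqrt(np.mean(np.sum((fitted - avg) ** 2, axis=2), axis=1))
    order = np.argsort(d, kind="stable")
    return int(order[0]), int(order[1]), d


def _moving_average(force: np.ndarray, half_width: int) -> np.ndarray:
    """Centered moving average, window truncated at the edges."""
    if half_width <= 0:
        return force.astype(float)
    n = force.size
    csum = np.concatenate([[0.0], np.cumsum(force, dtype=float)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def force_peak(
    profile: ForceProfile,
    smoothing_window_ps: float = 0.0,
) -> tuple[float, float]:
    """(peak force kJ/mol/nm, rupture time ps) after moving-average
    smoothing; ties resolve to the earliest time."""
    if profile.time_ps.size < 3:
        raise ValueError("force profile needs at least 3 samples")
    if smoothing_window_ps < 0:
        raise ValueError("smoothing window must be >= 0")
    dt = float(np.median(np.diff(profile.time_ps)))
    half_width = int(round(smoothing_window_ps / (2.0 * dt))) if dt > 0 else 0
    smoothed = _moving_average(profile.force_kj_nm, half_width)
    k = int(np.argmax(smoothed))  # argmax returns the first maximum
    return float(smoothed[k]), float(profile.time_ps[k])


def pull_work(profile: ForceProfile) -> float:
    """Work done by the pull, W = integral F(t) v dt, in kJ/mol.

    Trapezoid rule on the (possibly non-uniform) time grid; the constant
    pulling velocity is taken from the profile metadata (angstrom/ps,
    converted to nm/ps internally).
    """
    if profile.velocity_a_ps is None:
        raise ValueError("profile has no pulling velocity set")
    v_nm_ps = profile.velocity_a_ps / 10.0
    return float(np.trapezoid(profile.force_kj_nm, profile.time_ps) * v_nm_ps)
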