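"""Small-molecule model: SMILES parsing, descriptors, score normalization.

The :class:`Molecule` type is a thin immutable wrapper around an RDKit mol
that exposes exactly the graph-level facts the screening funnel needs
(heavy atoms, bonds, per-atom element/charge/H-count) plus Lipinski-style
descriptors.  Scores are normalized per non-hydrogen atom, a simple
ligand-efficiency measure: dividing a docking or binding energy by the
heavy-atom count removes the trivial advantage larger molecules have in
additive scoring functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Molecule",
    "DescriptorSet",
    "MoleculeParseError",
    "DescriptorError",
    "parse_smiles",
    "compute_descriptors",
    "effective_score",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed for a molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed small molecule.

    Attributes
    ----------
    rdkit : Chem.Mol
        The underlying sanitized RDKit molecule (implicit hydrogens
        assigned by standard valence rules).
    name : str or None
        Optional identifier, e.g. from a SMILES file.
    source_smiles : str or None
        The input string the molecule was parsed from, verbatim.
    """

    rdkit: Chem.Mol = field(repr=False)
    name: str | None = None
    source_smiles: str | None = None

    @property
    def heavy_atom_count(self) -> int:
        return self.rdkit.GetNumHeavyAtoms()

    @property
    def bond_count(self) -> int:
        return self.rdkit.GetNumBonds()

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        """Per-atom (element symbol, formal charge, attached-H count)."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.rdkit.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """Per-bond (begin index, end index, bond order)."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.rdkit.GetBonds()
        ]

    def to_smiles(self) -> str:
        """Canonical SMILES; round-trip stable."""
        return Chem.MolToSmiles(self.rdkit)

    def with_name(self, name: str) -> "Molecule":
        return Molecule(self.rdkit, name=name, source_smiles=self.source_smiles)


@dataclass(frozen=True)
class DescriptorSet:
    """Lipinski-relevant descriptors.

    mw is in daltons; hbd counts O-H and N-H bonds; hba counts N and O
    atoms (Lipinski's original definitions, not pharmacophoric ones);
    logp is the Wildman-Crippen atom-contribution estimate.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    heavy_atoms: int


def _locate_parse_failure(text: str) -> int:
    """Best-effort index of the first offending token via prefix parsing."""
    for i in range(1, len(text) + 1):
        if Chem.MolFromSmiles(text[:i], sanitize=False) is None:
            return i - 1
    return len(text) - 1


def parse_smiles(text: str, name: str | None = None) -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Accepts both aromatic and kekulé input.  Raises
    :class:`MoleculeParseError` naming the approximate offending position
    for malformed input.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES string")
    smi = text.strip()
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        pos = _locate_parse_failure(smi)
        raise MoleculeParseError(
            f"could not parse SMILES {smi!r}: problem at or after "
            f"position {pos} ({smi[pos:pos + 1]!r})"
        )
    return Molecule(mol, name=name, source_smiles=smi)


def compute_descriptors(mol: Molecule) -> DescriptorSet:
    """Compute the Lipinski descriptor set for a molecule.

    mw sums standard atomic masses including implicit hydrogens; hbd/hba
    use the N/O-counting rules; logp comes from the packaged
    atom-contribution parameter table.
    """
    m = mol.rdkit
    if m.GetNumAtoms() == 0:
        raise DescriptorError("molecule has no atoms")
    try:
        logp = Crippen.MolLogP(m)
        mw = Descriptors.MolWt(m)
    except Exception as exc:  # pragma: no cover - exotic elements
        elements = sorted({a.GetSymbol() for a in m.GetAtoms()})
        raise DescriptorError(
            f"descriptor parameters unavailable for elements {elements}: {exc}"
        ) from exc
    return DescriptorSet(
        mw=mw,
        logp=logp,
        hbd=Lipinski.NHOHCount(m),
        hba=Lipinski.NOCount(m),
        heavy_atoms=m.GetNumHeavyAtoms(),
    )


def effective_score(raw_score: float, mol: Molecule) -> float:
    """Score per non-hydrogen atom (ligand-efficiency normalization).

    Sign is preserved: more negative remains better.  A raw score of
    -85.8 kcal/mol over 23 heavy atoms gives -3.73 kcal/mol per atom.
    """
    n = mol.heavy_atom_count
    if n < 1:
        raise ValueError("effective_score requires at least one heavy atom")
    return raw_score / n
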