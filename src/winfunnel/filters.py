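"""Drug-likeness, PAINS, and activity gates applied between funnel tiers.

Ro5 boundary semantics follow the usual wording: molecular weight strictly
below 500 Da, logP not exceeding 5, at most 5 hydrogen-bond donors, at
most 10 acceptors.  PAINS screening removes promiscuous-binder motifs by
SMARTS substructure match; the default pattern set is the published
A/B/C family as shipped with RDKit's filter catalog, and custom
(name, SMARTS) sets can be loaded from TSV/CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

from rdkit import Chem
from rdkit.Chem import FilterCatalog

from .chem import DescriptorSet, Molecule, compute_descriptors

__all__ = [
    "Ro5Verdict",
    "PainsPatternSet",
    "default_pains_catalog",
    "ro5_check",
    "pains_scan",
    "activity_gate",
    "SurrogateActivityPredictor",
]

RO5_RULES = ("mw", "logp", "hbd", "hba")


@dataclass(frozen=True)
class Ro5Verdict:
    passes: bool
    violated_rules: tuple[str, ...]


def ro5_check(desc: DescriptorSet) -> Ro5Verdict:
    """Lipinski Rule-of-Five gate.

    Passes iff mw < 500 (strict) and logp <= 5 and hbd <= 5 and hba <= 10.
    """
    violated = []
    if not desc.mw < 500.0:
        violated.append("mw")
    if not desc.logp <= 5.0:
        violated.append("logp")
    if not desc.hbd <= 5:
        violated.append("hbd")
    if not desc.hba <= 10:
        violated.append("hba")
    return Ro5Verdict(passes=not violated, violated_rules=tuple(violated))


class _PatternMatcher(Protocol):
    def matches(self, mol: Molecule) -> list[str]: ...


class PainsConfigError(ValueError):
    """Raised when a PAINS pattern set fails to compile or validate."""


class PainsPatternSet:
    """A named, versioned set of SMARTS substructure alerts.

    Every SMARTS must compile at load time and names must be unique;
    violations raise :class:`PainsConfigError` immediately rather than at
    scan time.
    """

    def __init__(self, patterns: Iterable[tuple[str, str]], version: str = "custom"):
        self.version = version
        self._compiled: list[tuple[str, Chem.Mol]] = []
        seen: set[str] = set()
        for pat_name, smarts in patterns:
            if pat_name in seen:
                raise PainsConfigError(f"duplicate pattern name {pat_name!r}")
            seen.add(pat_name)
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise PainsConfigError(
                    f"pattern {pat_name!r}: SMARTS {smarts!r} does not compile"
                )
            self._compiled.append((pat_name, query))

    def __len__(self) -> int:
        return len(self._compiled)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._compiled]

    @classmethod
    def from_file(cls, path: str | Path, version: str | None = None) -> "PainsPatternSet":
        """Load (name, SMARTS) rows from a TSV or CSV file."""
        path = Path(path)
        delim = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        rows: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            for rec in csv.reader(fh, delimiter=delim):
                if not rec or rec[0].startswith("#"):
                    continue
                if len(rec) < 2:
                    raise PainsConfigError(f"malformed pattern row: {rec!r}")
                rows.append((rec[0].strip(), rec[1].strip()))
        return cls(rows, version=version or path.name)

    def matches(self, mol: Molecule) -> list[str]:
        return [
            name for name, query in self._compiled
            if mol.rdkit.HasSubstructMatch(query)
        ]


class _CatalogPatternSet:
    """Published PAINS A/B/C alerts via RDKit's filter catalog."""

    def __init__(self, families: Sequence[str]):
        params = FilterCatalog.FilterCatalogParams()
        cats = FilterCatalog.FilterCatalogParams.FilterCatalogs
        chosen = {"A": cats.PAINS_A, "B": cats.PAINS_B, "C": cats.PAINS_C}
        for fam in families:
            if fam.upper() not in chosen:
                raise PainsConfigError(f"unknown PAINS family {fam!r}; use A/B/C")
            params.AddCatalog(chosen[fam.upper()])
        self._catalog = FilterCatalog.FilterCatalog(params)
        self.version = "rdkit-pains-" + "".join(sorted(f.upper() for f in families))

    def __len__(self) -> int:
        return self._catalog.GetNumEntries()

    def matches(self, mol: Molecule) -> list[str]:
        return [e.GetDescription() for e in self._catalog.GetMatches(mol.rdkit)]


def default_pains_catalog(families: Sequence[str] = ("A", "B", "C")) -> _PatternMatcher:
    """The packaged PAINS alert set; families A/B/C selectable."""
    return _CatalogPatternSet(families)


def pains_scan(mol: Molecule, pattern_set: _PatternMatcher | None = None) -> list[str]:
    """Names of PAINS alerts matching the molecule; empty list = clean."""
    if pattern_set is None:
        pattern_set = default_pains_catalog()
    return pattern_set.matches(mol)


class SurrogateActivityPredictor:
    """Fixed-weight logistic scorer over basic descriptors.

    A deterministic, non-scientific stand-in for a proprietary binary QSAR
    activity model, shipped so the activity gate and end-to-end funnel can
    be exercised without external software.  Scores are in [0, 1]; higher
    nominally means more drug-like by a crude property heuristic.  It has
    no predictive validity and must not be used for real triage.
    """

    # weights on (mw/500, logp/5, hbd/5, hba/10, heavy/35), plus bias
    WEIGHTS = (-1.1, -0.8, -0.6, -0.4, 0.9)
    BIAS = 1.2

    def __call__(self, mol: Molecule) -> float:
        d = compute_descriptors(mol)
        feats = (d.mw / 500.0, d.logp / 5.0, d.hbd / 5.0, d.hba / 10.0,
                 d.heavy_atoms / 35.0)
        z = self.BIAS + sum(w * f for w, f in zip(self.WEIGHTS, feats))
        return 1.0 / (1.0 + math.exp(-z))


def activity_gate(
    mol: Molecule,
    predictor: Callable[[Molecule], float],
    threshold: float = 0.5,
) -> bool:
    """True iff the predicted activity score strictly exceeds the threshold.

    The predictor must return a score in [0, 1]; anything else is a
    contract violation and raises ValueError.
    """
    score = predictor(mol)
    if not (0.0 <= score <= 1.0):
        raise ValueError(
            f"activity predictor returned {score!r}, outside the [0, 1] contract"
        )
    return score > threshold
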