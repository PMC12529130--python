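"""Multi-tier screening funnel: ordered tiers of scoring and selection.

A funnel is a sequence of tiers.  Each tier scores every surviving item
(or reuses a precomputed score column), then applies a selection rule:
either keep the top fraction by rank (``top_fraction``, floor rounding,
stable tie-break by input order) or keep everything past a cutoff
(``threshold``, boundary inclusive).  A tier may additionally carry a
boolean gate (drug-likeness, PAINS, activity).  Full survivor bookkeeping
is kept so the funnel narrative — how many entered and left each stage —
is reproducible exactly.

Scores follow the docking convention: lower (more negative) is better.
Tiers whose score is a probability-like quantity declare
``higher_is_better=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

__all__ = [
    "ScoredItem",
    "TierSpec",
    "FunnelReport",
    "MissingScoreError",
    "select_top_fraction",
    "apply_threshold",
    "run_funnel",
]


class MissingScoreError(KeyError):
    """An alive item lacks a score for the tier being applied."""


@dataclass
class ScoredItem:
    """A molecule id with its accumulated per-tier scores."""

    id: str
    scores: dict[str, float] = field(default_factory=dict)
    alive: bool = True
    failed: bool = False
    payload: object | None = None  # typically a Molecule

    def score_for(self, tier: str) -> float:
        try:
            return self.scores[tier]
        except KeyError:
            raise MissingScoreError(
                f"item {self.id!r} has no score for tier {tier!r}"
            ) from None


Selection = tuple  # ("top_fraction", f) | ("threshold", cutoff, direction)


@dataclass
class TierSpec:
    """One stage of the funnel.

    scorer: callable(item) -> float, or None if scores are preloaded into
    ``ScoredItem.scores[name]``.  selection: ("top_fraction", f) with
    0 < f <= 1, or ("threshold", cutoff, "le"/"ge").  gate: optional
    callable(item) -> bool applied after selection (False kills the item).
    """

    name: str
    selection: Selection
    scorer: Callable[[ScoredItem], float] | None = None
    gate: Callable[[ScoredItem], bool] | None = None
    higher_is_better: bool = False
    strict: bool = False  # threshold boundary: False = inclusive

    def __post_init__(self) -> None:
        kind = self.selection[0]
        if kind == "top_fraction":
            f = self.selection[1]
            if not 0.0 < f <= 1.0:
                raise ValueError(f"fraction must be in (0, 1], got {f}")
        elif kind == "threshold":
            if self.selection[2] not in ("le", "ge"):
                raise ValueError("threshold direction must be 'le' or 'ge'")
        else:
            raise ValueError(f"unknown selection kind {kind!r}")


@dataclass
class FunnelReport:
    """Exact per-tier bookkeeping: inputs, survivors, rule, failures."""

    rows: list[dict] = field(default_factory=list)

    def add(self, tier: str, rule: str, n_in: int, n_out: int,
            n_failed: int = 0) -> None:
        if n_out > n_in:
            raise ValueError("survivor count cannot exceed input count")
        self.rows.append(
            {"tier": tier, "rule": rule, "n_in": n_in, "n_out": n_out,
             "n_failed": n_failed}
        )

    @property
    def final_count(self) -> int:
        return self.rows[-1]["n_out"] if self.rows else 0


def _alive(items: Iterable[ScoredItem]) -> list[ScoredItem]:
    return [it for it in items if it.alive]


def select_top_fraction(
    items: Sequence[ScoredItem],
    tier: str,
    fraction: float,
    higher_is_better: bool = False,
) -> list[ScoredItem]:
    """Keep the best floor(fraction * n_alive) items by tier score.

    Sorting is ascending (more negative = better) unless
    ``higher_is_better``; ties break by stable input order.  Items not
    selected are marked dead in place.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    alive = _alive(items)
    keyed = [(it.score_for(tier), i) for i, it in enumerate(alive)]
    n_keep = math.floor(fraction * len(alive))
    order = sorted(range(len(alive)),
                   key=lambda i: (-keyed[i][0] if higher_is_better
                                  else keyed[i][0], i))
    keep = set(order[:n_keep])
    survivors = []
    for i, it in enumerate(alive):
        if i in keep:
            survivors.append(it)
        else:
            it.alive = False
    return survivors


def apply_threshold(
    items: Sequence[ScoredItem],
    tier: str,
    cutoff: float,
    direction: Literal["le", "ge"] = "le",
    strict: bool = False,
) -> list[ScoredItem]:
    """Keep items whose tier score clears the cutoff.

    direction 'le' keeps score <= cutoff (the docking-energy convention,
    e.g. a -7 kcal/mol gate); 'ge' keeps score >= cutoff.  The boundary
    survives unless ``strict``.
    """
    survivors = []
    for it in _alive(items):
        s = it.score_for(tier)
        if direction == "le":
            ok = s < cutoff if strict else s <= cutoff
        else:
            ok = s > cutoff if strict else s >= cutoff
        if ok:
            survivors.append(it)
        else:
            it.alive = False
    return survivors


def _rule_label(tier: TierSpec) -> str:
    sel = tier.selection
    if sel[0] == "top_fraction":
        return f"top_fraction({sel[1]})"
    op = {"le": "<=" if not tier.strict else "<",
          "ge": ">=" if not tier.strict else ">"}[sel[2]]
    return f"threshold({op}{sel[1]})"


def run_funnel(
    items: Sequence[ScoredItem],
    tiers: Sequence[TierSpec],
) -> tuple[FunnelReport, list[ScoredItem]]:
    """Apply tiers in order with full bookkeeping.

    Scorer failures mark the item failed and dead but do not abort the
    run; the report records how many failed in each tier.  Deterministic
    given deterministic scorers and gates.
    """
    if not tiers:
        raise ValueError("funnel needs at least one tier")
    report = FunnelReport()
    current = _alive(items)
    for tier in tiers:
        n_in = len(current)
        n_failed = 0
        if tier.scorer is not None:
            for it in current:
                try:
                    it.scores[tier.name] = tier.scorer(it)
                except Exception:
                    it.alive = False
                    it.failed = True
                    n_failed += 1
            current = _alive(current)
        sel = tier.selection
        if sel[0] == "top_fraction":
            current = select_top_fraction(
                current, tier.name, sel[1], tier.higher_is_better)
        else:
            current = apply_threshold(
                current, tier.name, sel[1], sel[2], tier.strict)
        if tier.gate is not None:
            gated = []
            for it in current:
                try:
                    ok = tier.gate(it)
                except Exception:
                    it.alive = False
                    it.failed = True
                    n_failed += 1
                    continue
                if ok:
                    gated.append(it)
                else:
                    it.alive = False
            current = gated
        report.add(tier.name, _rule_label(tier), n_in, len(current), n_failed)
    return report, current
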