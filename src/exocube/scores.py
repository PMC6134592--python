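"""Compatibility scores for organisms sharing one environment.

Three scores, all simple set fractions over the assertion table of a
single environment:

* **EUS** (Environmental Uptake Score) — the fraction of the control
  pool's metabolites that the scored organism decreases:
  ``|D_scored ∩ P| / |P|`` with ``P`` the metabolites detected in the
  control.
* **OCS-FMC** (Fraction of Metabolites under Competition) — of the
  metabolites the scored organism decreases, the fraction also decreased
  by the reference organism: ``|D_scored ∩ D_reference| / |D_scored|``.
* **OCS-FME** (Fraction of Metabolites for potential Exchange) — of the
  metabolites the scored organism decreases, the fraction increased by the
  reference organism: ``|D_scored ∩ I_reference| / |D_scored|``.

A low FMC and high FME suggest a compatible pairing; the scores are a
gross simplification (no growth, toxicity or regulation effects) and are
meant only for ranking candidate partners.

The denominator of the two OCS scores is the scored organism's *total*
decrease count, not the decreases exclusive to it: with 25 shared
decreases out of 50 total the competition fraction is 0.5.  Metabolites
asserted ``NOT_INVESTIGATED`` for an organism never enter its sets.
A zero denominator yields an UNDEFINED score (``value is None``),
serialized as an empty cell — never as 0, which is a meaningful score.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import CONTROL_NAME, ActionCode, Datacube
from .errors import UnknownEntityError


@dataclass(frozen=True)
class ActionSets:
    """Per-organism decrease/increase sets and the control pool of one environment."""

    environment: str
    decreased: dict[str, frozenset[str]]
    increased: dict[str, frozenset[str]]
    control_present: frozenset[str]
    metabolites: frozenset[str]

    def organisms(self) -> list[str]:
        """Non-control organisms with any assertion here, sorted."""
        return sorted(set(self.decreased) | set(self.increased))


def action_sets(cube: Datacube, environment: str) -> ActionSets:
    """Collect D/I sets per organism and the control-present set P."""
    if environment not in cube.environments:
        raise UnknownEntityError(f"unknown environment: {environment!r}")
    decreased: dict[str, set[str]] = {}
    increased: dict[str, set[str]] = {}
    present: set[str] = set()
    universe: set[str] = set()
    for obs in cube.iter_environment(environment):
        universe.add(obs.metabolite)
        if obs.organism == CONTROL_NAME:
            if obs.action is ActionCode.DETECTED:
                present.add(obs.metabolite)
            continue
        decreased.setdefault(obs.organism, set())
        increased.setdefault(obs.organism, set())
        if obs.action is ActionCode.DECREASED:
            decreased[obs.organism].add(obs.metabolite)
        elif obs.action is ActionCode.INCREASED:
            increased[obs.organism].add(obs.metabolite)
    return ActionSets(
        environment=environment,
        decreased={o: frozenset(s) for o, s in decreased.items()},
        increased={o: frozenset(s) for o, s in increased.items()},
        control_present=frozenset(present),
        metabolites=frozenset(universe),
    )


class ScoreKind(str, Enum):
    EUS = "EUS"
    FMC = "FMC"
    FME = "FME"


@dataclass(frozen=True)
class ScoreResult:
    """One score with its provenance.

    ``value`` is ``numerator / denominator``, or ``None`` (UNDEFINED) when
    the denominator is zero.
    """

    kind: ScoreKind
    scored: str
    reference: str
    numerator: int
    denominator: int

    @property
    def value(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def _require_organism(sets: ActionSets, name: str) -> None:
    if name == CONTROL_NAME:
        raise UnknownEntityError(f"{CONTROL_NAME!r} cannot be a scored organism")
    if name not in sets.decreased and name not in sets.increased:
        raise UnknownEntityError(
            f"organism {name!r} has no assertions in {sets.environment!r}"
        )


def eus(sets: ActionSets, scored: str) -> ScoreResult:
    """Environmental Uptake Score of one organism against the control pool.

    Only decreases of metabolites actually present in the control count:
    a product absent from the starting pool cannot be consumed from it.
    """
    _require_organism(sets, scored)
    d = sets.decreased.get(scored, frozenset())
    return ScoreResult(
        kind=ScoreKind.EUS,
        scored=scored,
        reference=CONTROL_NAME,
        numerator=len(d & sets.control_present),
        denominator=len(sets.control_present),
    )


def fmc(sets: ActionSets, scored: str, reference: str) -> ScoreResult:
    """Fraction of the scored organism's decreases shared with the reference."""
    _require_organism(sets, scored)
    _require_organism(sets, reference)
    if scored == reference:
        raise UnknownEntityError("scored and reference organisms must differ")
    d_scored = sets.decreased.get(scored, frozenset())
    d_ref = sets.decreased.get(reference, frozenset())
    return ScoreResult(
        kind=ScoreKind.FMC,
        scored=scored,
        reference=reference,
        numerator=len(d_scored & d_ref),
        denominator=len(d_scored),
    )


def fme(sets: ActionSets, scored: str, reference: str) -> ScoreResult:
    """Fraction of the scored organism's decreases that the reference increases."""
    _require_organism(sets, scored)
    _require_organism(sets, reference)
    if scored == reference:
        raise UnknownEntityError("scored and reference organisms must differ")
    d_scored = sets.decreased.get(scored, frozenset())
    i_ref = sets.increased.get(reference, frozenset())
    return ScoreResult(
        kind=ScoreKind.FME,
        scored=scored,
        reference=reference,
        numerator=len(d_scored & i_ref),
        denominator=len(d_scored),
    )


def compatibility_table(
    cube: Datacube, environment: str, reference: str
) -> list[ScoreResult]:
    """Score every organism of an environment against a reference column.

    With the control as reference, one EUS per organism; with an organism
    as reference, an (FMC, FME) pair per non-reference organism.  Organism
    order is deterministic (lexicographic).
    """
    sets = action_sets(cube, environment)
    organisms = sets.organisms()
    if reference == CONTROL_NAME:
        return [eus(sets, o) for o in organisms]
    if reference not in organisms:
        raise UnknownEntityError(
            f"organism {reference!r} has no assertions in {environment!r}"
        )
    out: list[ScoreResult] = []
    for o in organisms:
        if o == reference:
            continue
        out.append(fmc(sets, o, reference))
        out.append(fme(sets, o, reference))
    return out


class InteractionMark(str, Enum):
    """Cell mark between a scored and a reference organism."""

    COMPETITION = "competition"  # both decrease the metabolite
    EXCHANGE = "exchange"  # scored decreases what the reference increases
    NONE = "none"


def interaction_marks(
    sets: ActionSets, scored: str, reference: str
) -> dict[str, InteractionMark]:
    """Per-metabolite competition/exchange marks for a reference selection.

    Counts are consistent with the scores by construction: COMPETITION
    marks equal the FMC numerator, EXCHANGE marks the FME numerator.
    """
    _require_organism(sets, scored)
    _require_organism(sets, reference)
    d_scored = sets.decreased.get(scored, frozenset())
    d_ref = sets.decreased.get(reference, frozenset())
    i_ref = sets.increased.get(reference, frozenset())
    marks: dict[str, InteractionMark] = {}
    for met in sorted(sets.metabolites):
        if met in d_scored and met in d_ref:
            marks[met] = InteractionMark.COMPETITION
        elif met in d_scored and met in i_ref:
            marks[met] = InteractionMark.EXCHANGE
        else:
            marks[met] = InteractionMark.NONE
    return marks
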