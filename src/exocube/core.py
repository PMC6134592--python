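"""Domain model for the exometabolomics assertion datacube.

The datacube relates three dimensions — metabolites, organisms and
environments — through qualitative *assertions*: one observation per
(metabolite, organism, environment) triple stating whether the metabolite
increased, decreased or did not change after microbial transformation of the
medium.  The untransformed control pool is modelled as a reserved
pseudo-organism, ``"The Environment"``, whose observations only record
whether a metabolite was detected in the starting medium.

Confidence is the magnitude of the log2 fold change between spent and
control abundances, capped at 5; it drives the shading of table cells and
web connectors, and is 0 for all non-directional actions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from .errors import DuplicateObservationError, UnknownEntityError

#: Reserved name of the control pseudo-organism (the untransformed medium).
CONTROL_NAME = "The Environment"

#: Maximum confidence score; assigned outright when a metabolite is detected
#: on only one side of the comparison (a fold change against zero is undefined).
CONFIDENCE_CAP = 5.0


class ActionCode(str, Enum):
    """Qualitative assertion for one observation.

    The string values are the words used in upload files.  ``DETECTED`` and
    ``NOT_DETECTED`` are legal only for the control pseudo-organism; the
    remaining four only for transformed (organism) observations.
    """

    DETECTED = "detected"
    NOT_DETECTED = "not detected"
    INCREASED = "increase"
    DECREASED = "decrease"
    NO_CHANGE = "no change"
    NOT_INVESTIGATED = "not investigated"


#: Actions legal for control observations.
CONTROL_ACTIONS = frozenset({ActionCode.DETECTED, ActionCode.NOT_DETECTED})
#: Actions legal for transformed (organism) observations.
ORGANISM_ACTIONS = frozenset(
    {
        ActionCode.INCREASED,
        ActionCode.DECREASED,
        ActionCode.NO_CHANGE,
        ActionCode.NOT_INVESTIGATED,
    }
)
#: Actions that carry no directional evidence and therefore zero confidence.
ZERO_CONFIDENCE_ACTIONS = frozenset(
    {
        ActionCode.DETECTED,
        ActionCode.NOT_DETECTED,
        ActionCode.NO_CHANGE,
        ActionCode.NOT_INVESTIGATED,
    }
)


@dataclass
class MetaboliteRecord:
    """One compound.

    ``putative`` marks identifications not confirmed against a pure
    reference standard; such names are rendered in parentheses.
    ``annotation`` holds free text (isomer lists, formula, retention
    time and m/z); ``msi_level`` the Metabolomics Standards Initiative
    identification level when known.
    """

    name: str
    putative: bool = False
    annotation: Optional[str] = None
    msi_level: Optional[int] = None


@dataclass
class OrganismRecord:
    """One organism (or the reserved control pseudo-organism).

    Time points or consortia profiled as separate columns are simply
    distinct organism records; ``description`` can record that context.
    """

    name: str
    is_control: bool = False
    description: Optional[str] = None


@dataclass
class EnvironmentRecord:
    """One starting metabolite pool (medium, extract, field sample...)."""

    name: str
    description: Optional[str] = None


@dataclass
class Observation:
    """One assertion for a (metabolite, organism, environment) triple.

    ``log2fc`` is log2(mean spent / mean control); it is absent when the
    metabolite was detected on only one side, in which case a directional
    action carries confidence exactly :data:`CONFIDENCE_CAP`.
    """

    metabolite: str
    organism: str
    environment: str
    action: ActionCode
    log2fc: Optional[float] = None
    confidence: float = 0.0
    p_value: Optional[float] = None
    project: Optional[str] = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.metabolite, self.organism, self.environment)


@dataclass
class Violation:
    """One invariant violation reported by :func:`validate`."""

    kind: str
    message: str
    key: Optional[tuple] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


class Datacube:
    """Keyed collection of observations over the three dimensions.

    Every cube owns exactly one control organism record named
    ``"The Environment"``; it is registered at construction.  Observations
    are keyed by (metabolite, organism, environment) and the key is unique.
    """

    def __init__(self) -> None:
        self.metabolites: dict[str, MetaboliteRecord] = {}
        self.organisms: dict[str, OrganismRecord] = {
            CONTROL_NAME: OrganismRecord(CONTROL_NAME, is_control=True)
        }
        self.environments: dict[str, EnvironmentRecord] = {}
        self.observations: dict[tuple[str, str, str], Observation] = {}

    # -- registration -------------------------------------------------

    def add_metabolite(self, record: MetaboliteRecord) -> MetaboliteRecord:
        """Register a metabolite; an existing record with the same name wins."""
        return self.metabolites.setdefault(record.name, record)

    def add_organism(self, record: OrganismRecord) -> OrganismRecord:
        return self.organisms.setdefault(record.name, record)

    def add_environment(self, record: EnvironmentRecord) -> EnvironmentRecord:
        return self.environments.setdefault(record.name, record)

    def add_observation(
        self, obs: Observation, register: bool = False, replace: bool = False
    ) -> Observation:
        """Add one observation.

        With ``register=True`` unknown metabolites/organisms/environments are
        auto-registered with default records; otherwise referencing an
        unregistered entity raises :class:`UnknownEntityError`.  A duplicate
        key raises :class:`DuplicateObservationError` unless ``replace``.
        """
        if register:
            self.add_metabolite(MetaboliteRecord(obs.metabolite))
            self.add_organism(
                OrganismRecord(obs.organism, is_control=obs.organism == CONTROL_NAME)
            )
            self.add_environment(EnvironmentRecord(obs.environment))
        else:
            for dim, name in (
                ("metabolite", obs.metabolite),
                ("organism", obs.organism),
                ("environment", obs.environment),
            ):
                if name not in getattr(self, dim + "s"):
                    raise UnknownEntityError(f"unknown {dim}: {name!r}")
        if obs.key in self.observations and not replace:
            raise DuplicateObservationError(obs.key)
        self.observations[obs.key] = obs
        return obs

    @classmethod
    def from_observations(cls, observations: Iterable[Observation]) -> "Datacube":
        """Build a cube from observations, auto-registering all entities."""
        cube = cls()
        for obs in observations:
            cube.add_observation(obs, register=True)
        return cube

    # -- access --------------------------------------------------------

    def get(self, metabolite: str, organism: str, environment: str) -> Optional[Observation]:
        return self.observations.get((metabolite, organism, environment))

    def iter_environment(self, environment: str) -> Iterator[Observation]:
        if environment not in self.environments:
            raise UnknownEntityError(f"unknown environment: {environment!r}")
        for obs in self.observations.values():
            if obs.environment == environment:
                yield obs

    @property
    def control(self) -> OrganismRecord:
        return self.organisms[CONTROL_NAME]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Datacube):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.organisms == other.organisms
            and self.environments == other.environments
            and self.observations == other.observations
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Datacube({len(self.metabolites)} metabolites, "
            f"{len(self.organisms)} organisms, "
            f"{len(self.environments)} environments, "
            f"{len(self.observations)} observations)"
        )


def search_metabolites(cube: Datacube, query: str) -> list[MetaboliteRecord]:
    """Case-insensitive substring search over metabolite names.

    An empty query matches everything.  Results are returned in
    deterministic lexicographic order (case-insensitive key, then name).
    """
    q = query.lower()
    hits = [m for name, m in cube.metabolites.items() if q in name.lower()]
    return sorted(hits, key=lambda m: (m.name.lower(), m.name))


def validate(cube: Datacube) -> list[Violation]:
    """Check every datacube invariant; return all violations found.

    An empty list means the cube is valid.  Checks: the single reserved
    control record; non-empty names; observation references; action/organism
    legality; confidence range and its zero/non-zero pairing with the action;
    log2 fold-change sign consistency; p-value range.
    """
    out: list[Violation] = []
    controls = [o for o in cube.organisms.values() if o.is_control]
    if len(controls) != 1 or controls[0].name != CONTROL_NAME:
        out.append(
            Violation(
                "control",
                f"expected exactly one control organism named {CONTROL_NAME!r}, "
                f"found {[o.name for o in controls]}",
            )
        )
    for name in cube.metabolites:
        if not name:
            out.append(Violation("name", "empty metabolite name"))
    for name in cube.environments:
        if not name:
            out.append(Violation("name", "empty environment name"))

    for key, obs in cube.observations.items():
        if key != obs.key:
            out.append(Violation("key", f"observation stored under wrong key {key}", key))
        if obs.metabolite not in cube.metabolites:
            out.append(Violation("reference", f"unknown metabolite {obs.metabolite!r}", key))
        if obs.environment not in cube.environments:
            out.append(Violation("reference", f"unknown environment {obs.environment!r}", key))
        org = cube.organisms.get(obs.organism)
        if org is None:
            out.append(Violation("reference", f"unknown organism {obs.organism!r}", key))
        else:
            legal = CONTROL_ACTIONS if org.is_control else ORGANISM_ACTIONS
            if obs.action not in legal:
                out.append(
                    Violation(
                        "action",
                        f"action {obs.action.value!r} illegal for "
                        f"{'control' if org.is_control else 'organism'} {org.name!r}",
                        key,
                    )
                )
        if not (0.0 <= obs.confidence <= CONFIDENCE_CAP):
            out.append(
                Violation(
                    "confidence",
                    f"confidence {obs.confidence} outside [0, {CONFIDENCE_CAP}]",
                    key,
                )
            )
        if obs.action in ZERO_CONFIDENCE_ACTIONS:
            if obs.confidence != 0.0:
                out.append(
                    Violation(
                        "confidence",
                        f"non-directional action {obs.action.value!r} must have "
                        f"confidence 0, got {obs.confidence}",
                        key,
                    )
                )
        elif obs.confidence <= 0.0:
            out.append(
                Violation(
                    "confidence",
                    f"directional action {obs.action.value!r} must have "
                    f"confidence > 0",
                    key,
                )
            )
        if obs.action in (ActionCode.INCREASED, ActionCode.DECREASED):
            sign = 1.0 if obs.action is ActionCode.INCREASED else -1.0
            if obs.log2fc is None:
                if obs.confidence != CONFIDENCE_CAP:
                    out.append(
                        Violation(
                            "log2fc",
                            "directional action without log2fc must carry the "
                            f"confidence cap {CONFIDENCE_CAP}",
                            key,
                        )
                    )
            elif sign * obs.log2fc <= 0:
                out.append(
                    Violation(
                        "log2fc",
                        f"log2fc {obs.log2fc} inconsistent with action "
                        f"{obs.action.value!r}",
                        key,
                    )
                )
        if obs.p_value is not None and not (0.0 <= obs.p_value <= 1.0):
            out.append(Violation("p_value", f"p-value {obs.p_value} outside [0,1]", key))
    return out
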