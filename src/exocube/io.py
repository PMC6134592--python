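"""Reading and writing datacubes.

Two formats:

* the *upload dialect* — tab-delimited UTF-8 text with a header row and the
  canonical columns ``metabolites | organisms | environments |
  action assertions | log2fc | confidence | p_value | project`` (first four
  required, header matching case-insensitive with configurable synonyms,
  CSV accepted behind a flag);
* a single-file embedded relational database (SQLite3) with separate
  tables for environments, organisms, metabolites, observations and
  projects.

Putative metabolite identifications are serialized with the name wrapped in
parentheses and recovered as ``putative=True`` on parse.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .core import (
    CONFIDENCE_CAP,
    CONTROL_ACTIONS,
    CONTROL_NAME,
    ActionCode,
    Datacube,
    EnvironmentRecord,
    MetaboliteRecord,
    Observation,
    OrganismRecord,
)
from .errors import (
    DuplicateObservationError,
    FormatError,
    RowError,
    StorageError,
)

logger = logging.getLogger(__name__)

#: Canonical upload columns, in file order.  The first four are required.
CANONICAL_COLUMNS = (
    "metabolites",
    "organisms",
    "environments",
    "action assertions",
    "log2fc",
    "confidence",
    "p_value",
    "project",
)
REQUIRED_COLUMNS = CANONICAL_COLUMNS[:4]

_DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "metabolites": ("metabolite", "compound", "compounds"),
    "organisms": ("organism",),
    "environments": ("environment",),
    "action assertions": ("action assertion", "action", "actions", "assertion"),
    "log2fc": ("log2 fold change", "log2_fc", "log2fold"),
    "confidence": ("score", "confidence score"),
    "p_value": ("pvalue", "p value", "p"),
    "project": ("projects",),
}

_ACTION_WORDS = {a.value: a for a in ActionCode}


@dataclass
class UploadDialect:
    """Configuration of the upload file dialect.

    ``strict=True`` rejects the whole file on the first bad row or duplicate
    key; ``strict=False`` keeps the first occurrence, skips bad rows and
    logs them.  ``sep=","`` accepts comma-separated uploads.
    """

    sep: str = "\t"
    strict: bool = True
    synonyms: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SYNONYMS)
    )

    def resolve_header(self, raw: str) -> Optional[str]:
        """Map a raw header cell to a canonical column name, or None."""
        h = raw.strip().lower()
        for canonical in CANONICAL_COLUMNS:
            if h == canonical or h in self.synonyms.get(canonical, ()):
                return canonical
        return None


def _parse_metabolite_name(raw: str) -> tuple[str, bool]:
    name = raw.strip()
    if len(name) >= 2 and name.startswith("(") and name.endswith(")"):
        return name[1:-1].strip(), True
    return name, False


def _serialize_metabolite(record: MetaboliteRecord) -> str:
    return f"({record.name})" if record.putative else record.name


def _opt_float(cell: str, line: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise RowError(line, f"bad number in column {column!r}: {cell!r}") from exc


def parse_upload(
    path: Union[str, Path], dialect: Optional[UploadDialect] = None
) -> Datacube:
    """Parse an upload file into a :class:`Datacube`.

    Unknown metabolites/organisms/environments are auto-registered.  Control
    rows (organism ``"The Environment"``) may only assert detected /
    not detected.  See :class:`UploadDialect` for strict vs lenient error
    handling.
    """
    dialect = dialect or UploadDialect()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(
            path, sep=dialect.sep, dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, no header row") from exc

    colmap: dict[str, str] = {}
    for raw in frame.columns:
        canonical = dialect.resolve_header(str(raw))
        if canonical is not None and canonical not in colmap:
            colmap[canonical] = raw
    missing = [c for c in REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    cube = Datacube()
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            obs = _row_to_observation(row, colmap, line, cube)
            cube.add_observation(obs, register=False)
        except DuplicateObservationError:
            if dialect.strict:
                raise
            logger.warning("%s: line %d: duplicate key, keeping first", path, line)
        except RowError:
            if dialect.strict:
                raise
            logger.warning("%s: line %d: bad row skipped", path, line)
    return cube


def _row_to_observation(
    row: "pd.Series", colmap: dict[str, str], line: int, cube: Datacube
) -> Observation:
    def cell(canonical: str) -> str:
        raw = colmap.get(canonical)
        return str(row[raw]) if raw is not None else ""

    met_name, putative = _parse_metabolite_name(cell("metabolites"))
    org_name = cell("organisms").strip()
    env_name = cell("environments").strip()
    if not met_name or not org_name or not env_name:
        raise RowError(line, "empty metabolite, organism or environment name")

    action_word = cell("action assertions").strip().lower()
    action = _ACTION_WORDS.get(action_word)
    if action is None:
        raise RowError(
            line,
            f"unknown action assertion {action_word!r}; expected one of: "
            + ", ".join(sorted(_ACTION_WORDS)),
        )
    is_control = org_name == CONTROL_NAME
    if is_control and action not in CONTROL_ACTIONS:
        raise RowError(
            line,
            f"action {action.value!r} illegal for the control pseudo-organism",
        )
    if not is_control and action in CONTROL_ACTIONS:
        raise RowError(
            line, f"action {action.value!r} legal only for {CONTROL_NAME!r}"
        )

    log2fc = _opt_float(cell("log2fc"), line, "log2fc")
    conf_cell = cell("confidence").strip()
    if conf_cell:
        confidence = float(_opt_float(conf_cell, line, "confidence"))
    elif action in (ActionCode.INCREASED, ActionCode.DECREASED):
        # derive: shade from |log2fc| capped, or the cap for one-sided calls
        confidence = (
            min(abs(log2fc), CONFIDENCE_CAP) if log2fc is not None else CONFIDENCE_CAP
        )
    else:
        confidence = 0.0
    p_value = _opt_float(cell("p_value"), line, "p_value")
    project = cell("project").strip() or None

    # register entities, preserving a putative flag seen on any row
    met = cube.add_metabolite(MetaboliteRecord(met_name, putative=putative))
    if putative:
        met.putative = True
    cube.add_organism(OrganismRecord(org_name, is_control=is_control))
    cube.add_environment(EnvironmentRecord(env_name))
    return Observation(
        metabolite=met_name,
        organism=org_name,
        environment=env_name,
        action=action,
        log2fc=log2fc,
        confidence=confidence,
        p_value=p_value,
        project=project,
    )


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_upload(
    cube: Datacube, path: Union[str, Path], dialect: Optional[UploadDialect] = None
) -> None:
    """Write a datacube in the upload dialect.

    Rows are ordered lexicographically by (environment, organism,
    metabolite); the header is exactly the canonical column names.  An empty
    cube yields a header-only file.
    """
    dialect = dialect or UploadDialect()
    rows = []
    for obs in sorted(
        cube.observations.values(),
        key=lambda o: (o.environment, o.organism, o.metabolite),
    ):
        rows.append(
            {
                "metabolites": _serialize_metabolite(cube.metabolites[obs.metabolite]),
                "organisms": obs.organism,
                "environments": obs.environment,
                "action assertions": obs.action.value,
                "log2fc": _fmt(obs.log2fc),
                "confidence": _fmt(obs.confidence),
                "p_value": _fmt(obs.p_value),
                "project": obs.project or "",
            }
        )
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(path, sep=dialect.sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# embedded relational store (SQLite)
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE environments (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    description TEXT
);
CREATE TABLE organisms (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    is_control INTEGER NOT NULL DEFAULT 0,
    description TEXT
);
CREATE TABLE metabolites (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    putative INTEGER NOT NULL DEFAULT 0,
    annotation TEXT,
    msi_level INTEGER
);
CREATE TABLE projects (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE observations (
    id INTEGER PRIMARY KEY,
    metabolite_id INTEGER NOT NULL REFERENCES metabolites(id),
    organism_id INTEGER NOT NULL REFERENCES organisms(id),
    environment_id INTEGER NOT NULL REFERENCES environments(id),
    action TEXT NOT NULL,
    log2fc REAL,
    confidence REAL NOT NULL,
    p_value REAL,
    project_id INTEGER REFERENCES projects(id),
    UNIQUE (metabolite_id, organism_id, environment_id)
);
"""


def save_db(cube: Datacube, path: Union[str, Path]) -> None:
    """Persist a datacube to a single-file SQLite database.

    The layout is relational: separate tables for environments, organisms,
    metabolites, observations and projects, with observations carrying
    foreign keys into the other four.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        env_ids = _insert_named(
            con,
            "INSERT INTO environments(name, description) VALUES (?, ?)",
            [(e.name, e.description) for e in cube.environments.values()],
        )
        org_ids = _insert_named(
            con,
            "INSERT INTO organisms(name, is_control, description) VALUES (?, ?, ?)",
            [(o.name, int(o.is_control), o.description) for o in cube.organisms.values()],
        )
        met_ids = _insert_named(
            con,
            "INSERT INTO metabolites(name, putative, annotation, msi_level)"
            " VALUES (?, ?, ?, ?)",
            [
                (m.name, int(m.putative), m.annotation, m.msi_level)
                for m in cube.metabolites.values()
            ],
        )
        projects = sorted(
            {o.project for o in cube.observations.values() if o.project is not None}
        )
        proj_ids = _insert_named(
            con, "INSERT INTO projects(name) VALUES (?)", [(p,) for p in projects]
        )
        con.executemany(
            "INSERT INTO observations(metabolite_id, organism_id, environment_id,"
            " action, log2fc, confidence, p_value, project_id)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    met_ids[o.metabolite],
                    org_ids[o.organism],
                    env_ids[o.environment],
                    o.action.value,
                    o.log2fc,
                    o.confidence,
                    o.p_value,
                    proj_ids[o.project] if o.project is not None else None,
                )
                for o in sorted(cube.observations.values(), key=lambda o: o.key)
            ],
        )
        con.commit()
    finally:
        con.close()


def _insert_named(con: sqlite3.Connection, sql: str, rows) -> dict[str, int]:
    ids: dict[str, int] = {}
    cur = con.cursor()
    for row in rows:
        cur.execute(sql, row)
        ids[row[0]] = cur.lastrowid
    return ids


def load_db(path: Union[str, Path]) -> Datacube:
    """Load a datacube from a SQLite database written by :func:`save_db`.

    A missing or corrupt file, or an observation with a dangling foreign
    key, raises :class:`StorageError`.
    """
    path = Path(path)
    if not path.exists():
        raise StorageError(f"no such database: {path}")
    con = sqlite3.connect(path)
    try:
        try:
            broken = con.execute("PRAGMA foreign_key_check").fetchall()
        except sqlite3.DatabaseError as exc:
            raise StorageError(f"{path}: not a readable database: {exc}") from exc
        if broken:
            raise StorageError(
                f"{path}: {len(broken)} dangling foreign key reference(s)"
            )
        cube = Datacube()
        try:
            for name, desc in con.execute("SELECT name, description FROM environments"):
                cube.add_environment(EnvironmentRecord(name, description=desc))
            for name, is_control, desc in con.execute(
                "SELECT name, is_control, description FROM organisms"
            ):
                cube.add_organism(
                    OrganismRecord(name, is_control=bool(is_control), description=desc)
                )
            for name, putative, annotation, msi in con.execute(
                "SELECT name, putative, annotation, msi_level FROM metabolites"
            ):
                cube.add_metabolite(
                    MetaboliteRecord(
                        name,
                        putative=bool(putative),
                        annotation=annotation,
                        msi_level=msi,
                    )
                )
            rows = con.execute(
                "SELECT m.name, o.name, e.name, v.action, v.log2fc, v.confidence,"
                " v.p_value, p.name"
                " FROM observations v"
                " JOIN metabolites m ON m.id = v.metabolite_id"
                " JOIN organisms o ON o.id = v.organism_id"
                " JOIN environments e ON e.id = v.environment_id"
                " LEFT JOIN projects p ON p.id = v.project_id"
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise StorageError(f"{path}: schema mismatch: {exc}") from exc
        for met, org, env, action, log2fc, conf, p, proj in rows:
            cube.add_observation(
                Observation(
                    metabolite=met,
                    organism=org,
                    environment=env,
                    action=ActionCode(action),
                    log2fc=log2fc,
                    confidence=conf,
                    p_value=p,
                    project=proj,
                )
            )
        return cube
    finally:
        con.close()
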