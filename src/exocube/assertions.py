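"""From replicate abundances to action assertions.

The pipeline mirrors standard metabolite-footprinting practice: relative
abundances of each metabolite are measured in replicate for the
uninoculated control medium and for the spent medium after microbial
growth.  Per metabolite:

1.  Both pools are held to the same detection threshold.  If the
    metabolite is below the limit of detection on both sides, nothing can
    be asserted (``NOT_INVESTIGATED``).
2.  Otherwise control and spent replicates are compared with a two-sided
    test (Welch's t by default; Mann-Whitney U selectable — the right test
    depends on the experimental design).  A non-significant difference is
    asserted as ``NO_CHANGE``.
3.  A significant difference is asserted as ``INCREASED`` or ``DECREASED``
    with log2 fold change log2(mean spent / mean control) and confidence
    min(|log2fc|, 5).  When the metabolite is detected on exactly one side
    the fold change against zero is undefined, so the confidence is set to
    the cap (5) exactly and no log2fc is reported.

Benjamini-Hochberg correction, when enabled, is applied across all
metabolites of one experiment before the alpha comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CONFIDENCE_CAP, CONTROL_NAME, ActionCode, Datacube, Observation
from .errors import FormatError, InputError


@dataclass
class AssertionConfig:
    """Tunable parameters of the assertion pipeline.

    detection_threshold
        Abundance (arbitrary instrument units) that a replicate must
        strictly exceed to count as detected.  Default 0: any positive
        signal counts, i.e. the instrument's own limit of detection is
        trusted.
    min_detected_replicates
        How many replicates must exceed the threshold for the pool to be
        called present (default 1).
    test
        ``"welch_t"`` (Welch's unequal-variance t) or ``"mann_whitney"``.
    alpha
        Two-sided significance level (default 0.05).
    mtc
        ``"none"`` or ``"benjamini_hochberg"``; applied per experiment
        batch, not per metabolite.
    confidence_cap
        Ceiling of the confidence shade; fixed at 5 by convention.
    """

    detection_threshold: float = 0.0
    min_detected_replicates: int = 1
    test: str = "welch_t"
    alpha: float = 0.05
    mtc: str = "none"
    confidence_cap: float = CONFIDENCE_CAP

    def __post_init__(self) -> None:
        if self.detection_threshold < 0:
            raise InputError("detection_threshold must be >= 0")
        if self.min_detected_replicates < 1:
            raise InputError("min_detected_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie in (0, 1)")
        if self.test not in ("welch_t", "mann_whitney"):
            raise InputError(f"unknown test {self.test!r}")
        if self.mtc not in ("none", "benjamini_hochberg"):
            raise InputError(f"unknown mtc {self.mtc!r}")
        if self.confidence_cap <= 0:
            raise InputError("confidence_cap must be > 0")


@dataclass
class ReplicateExperiment:
    """Replicate abundances for one organism in one environment.

    ``abundances`` maps each metabolite to a pair of replicate value lists
    (control pool, spent pool), in arbitrary but shared units.
    """

    environment: str
    organism: str
    abundances: dict[str, tuple[Sequence[float], Sequence[float]]]


@dataclass
class AssertionResult:
    """Outcome of the assertion pipeline for one metabolite."""

    action: ActionCode
    log2fc: Optional[float] = None
    confidence: float = 0.0
    p_value: Optional[float] = None


def _check_values(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("replicate list is empty")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InputError("replicate abundances must be finite and >= 0")
    return arr


def detect_presence(values: Sequence[float], config: AssertionConfig) -> bool:
    """True iff enough replicates strictly exceed the detection threshold."""
    arr = _check_values(values)
    return int(np.sum(arr > config.detection_threshold)) >= config.min_detected_replicates


def _raw_p_value(control: np.ndarray, spent: np.ndarray, config: AssertionConfig) -> float:
    """Two-sided p-value, with the degenerate zero-variance fallback.

    When the test statistic is undefined (all replicates identical on both
    sides, or single replicates): identical pools compare as p=1, constant
    but different pools as p=0.
    """
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant replicates are resolved by the fallback below
        warnings.simplefilter("ignore", RuntimeWarning)
        if config.test == "welch_t":
            p = stats.ttest_ind(spent, control, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(spent, control, alternative="two-sided").pvalue
    if math.isnan(p):
        both = np.concatenate([control, spent])
        p = 1.0 if np.all(both == both[0]) else 0.0
    return float(p)


@dataclass
class _Prepared:
    """Intermediate per-metabolite state, before the batch alpha decision."""

    detected_control: bool
    detected_spent: bool
    p_value: Optional[float]  # None when neither side was detected
    mean_control: float
    mean_spent: float


def _prepare(
    control: Sequence[float], spent: Sequence[float], config: AssertionConfig
) -> _Prepared:
    c = _check_values(control)
    s = _check_values(spent)
    det_c = detect_presence(c, config)
    det_s = detect_presence(s, config)
    if not det_c and not det_s:
        return _Prepared(det_c, det_s, None, float(c.mean()), float(s.mean()))
    return _Prepared(det_c, det_s, _raw_p_value(c, s, config), float(c.mean()), float(s.mean()))


def _finalize(prep: _Prepared, p_adjusted: Optional[float], config: AssertionConfig) -> AssertionResult:
    if prep.p_value is None:
        return AssertionResult(ActionCode.NOT_INVESTIGATED, None, 0.0, None)
    if p_adjusted is None or p_adjusted >= config.alpha:
        return AssertionResult(ActionCode.NO_CHANGE, None, 0.0, prep.p_value)
    if prep.detected_control and prep.detected_spent:
        if prep.mean_spent == prep.mean_control:
            # significant p with identical means cannot direct a call
            return AssertionResult(ActionCode.NO_CHANGE, None, 0.0, prep.p_value)
        log2fc = math.log2(prep.mean_spent / prep.mean_control)
        action = ActionCode.INCREASED if log2fc > 0 else ActionCode.DECREASED
        return AssertionResult(
            action, log2fc, min(abs(log2fc), config.confidence_cap), prep.p_value
        )
    # detected on exactly one side: direction from the detected side, no
    # fold change (it would be taken with respect to zero), confidence = cap
    action = ActionCode.INCREASED if prep.detected_spent else ActionCode.DECREASED
    return AssertionResult(action, None, config.confidence_cap, prep.p_value)


def assert_action(
    control: Sequence[float],
    spent: Sequence[float],
    config: Optional[AssertionConfig] = None,
) -> AssertionResult:
    """Assert the action for one metabolite from its replicate abundances.

    Applies the per-metabolite pipeline with the raw p-value compared to
    alpha.  Use :func:`process_experiment` for batch-level multiple-testing
    correction.
    """
    config = config or AssertionConfig()
    prep = _prepare(control, spent, config)
    return _finalize(prep, prep.p_value, config)


@dataclass
class AssertionBatch:
    """Result of :func:`process_experiment`.

    Carries one transformed observation per metabolite, one control
    observation per metabolite (detected / not detected in the control
    pool), per-metabolite errors (metabolite name → message), and the
    configuration snapshot for provenance.
    """

    environment: str
    organism: str
    observations: list[Observation]
    errors: dict[str, str]
    config: dict = field(default_factory=dict)

    def to_datacube(self, cube: Optional[Datacube] = None) -> Datacube:
        """Merge the batch into a (possibly fresh) datacube.

        Identical duplicate control observations (shared control pool
        between experiments in the same environment) are tolerated.
        """
        cube = cube or Datacube()
        for obs in self.observations:
            existing = cube.observations.get(obs.key)
            if existing is not None and existing == obs:
                continue
            cube.add_observation(obs, register=True)
        return cube


def process_experiment(
    exp: ReplicateExperiment, config: Optional[AssertionConfig] = None
) -> AssertionBatch:
    """Run the assertion pipeline over every metabolite of one experiment.

    With ``mtc="benjamini_hochberg"`` the FDR correction is applied across
    all tested metabolites of the experiment before the alpha comparison.
    Per-metabolite input errors are collected, not fatal.
    """
    config = config or AssertionConfig()
    prepared: dict[str, _Prepared] = {}
    errors: dict[str, str] = {}
    for met in sorted(exp.abundances):
        control, spent = exp.abundances[met]
        try:
            prepared[met] = _prepare(control, spent, config)
        except InputError as exc:
            errors[met] = str(exc)

    tested = [m for m, prep in prepared.items() if prep.p_value is not None]
    adjusted: dict[str, float] = {m: prepared[m].p_value for m in tested}
    if config.mtc == "benjamini_hochberg" and tested:
        _, p_adj, _, _ = multipletests(
            [prepared[m].p_value for m in tested], method="fdr_bh"
        )
        adjusted = dict(zip(tested, (float(p) for p in p_adj)))

    observations: list[Observation] = []
    for met, prep in prepared.items():
        result = _finalize(prep, adjusted.get(met), config)
        observations.append(
            Observation(
                metabolite=met,
                organism=exp.organism,
                environment=exp.environment,
                action=result.action,
                log2fc=result.log2fc,
                confidence=result.confidence,
                p_value=result.p_value,
            )
        )
        observations.append(
            Observation(
                metabolite=met,
                organism=CONTROL_NAME,
                environment=exp.environment,
                action=ActionCode.DETECTED
                if prep.detected_control
                else ActionCode.NOT_DETECTED,
            )
        )
    return AssertionBatch(
        environment=exp.environment,
        organism=exp.organism,
        observations=observations,
        errors=errors,
        config=asdict(config),
    )


# ---------------------------------------------------------------------------
# abundance-table input
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("metabolite", "group", "replicate", "abundance")


def read_abundance_table(
    path: Union[str, Path],
    environment: str,
    organism: str,
    sep: str = "\t",
    wide: bool = False,
) -> ReplicateExperiment:
    """Read a replicate abundance table.

    Long format (default): columns ``metabolite | group | replicate |
    abundance`` with group ``control`` or ``spent``.  Wide format
    (``wide=True``): one row per metabolite, replicate columns named
    ``control_*`` and ``spent_*``.
    """
    frame = pd.read_csv(path, sep=sep)
    if wide:
        return _from_wide(frame, environment, organism, path)
    cols = {c.strip().lower(): c for c in frame.columns}
    missing = [c for c in LONG_COLUMNS[:2] + LONG_COLUMNS[3:] if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    abundances: dict[str, tuple[list[float], list[float]]] = {}
    for _, row in frame.iterrows():
        met = str(row[cols["metabolite"]]).strip()
        group = str(row[cols["group"]]).strip().lower()
        if group not in ("control", "spent"):
            raise FormatError(f"{path}: unknown group {group!r} (need control|spent)")
        value = float(row[cols["abundance"]])
        pair = abundances.setdefault(met, ([], []))
        pair[0 if group == "control" else 1].append(value)
    return ReplicateExperiment(environment, organism, abundances)


def _from_wide(frame: pd.DataFrame, environment: str, organism: str, path) -> ReplicateExperiment:
    cols = [str(c) for c in frame.columns]
    met_col = cols[0]
    control_cols = [c for c in cols if c.lower().startswith("control")]
    spent_cols = [c for c in cols if c.lower().startswith("spent")]
    if not control_cols or not spent_cols:
        raise FormatError(f"{path}: wide format needs control_* and spent_* columns")
    abundances = {}
    for _, row in frame.iterrows():
        met = str(row[met_col]).strip()
        abundances[met] = (
            [float(row[c]) for c in control_cols],
            [float(row[c]) for c in spent_cols],
        )
    return ReplicateExperiment(environment, organism, abundances)


def read_config(path: Union[str, Path]) -> AssertionConfig:
    """Read a flat ``key = value`` configuration file (# comments allowed)."""
    kwargs: dict = {}
    casts = {
        "detection_threshold": float,
        "min_detected_replicates": int,
        "test": str,
        "alpha": float,
        "mtc": str,
        "confidence_cap": float,
    }
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: line {lineno}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in casts:
            raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
        kwargs[key] = casts[key](value)
    return AssertionConfig(**kwargs)
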