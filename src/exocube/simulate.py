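"""Seeded generators for datacubes and replicate-abundance experiments.

Everything here is synthetic and deterministic given a seed: random valid
datacubes for round-trip/oracle testing, ground-truth spike-in experiments
for calibrating the assertion engine, and the fixed two-isolate fixture
whose decrease/increase set sizes are back-solved from published R2A
compatibility scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    CONFIDENCE_CAP,
    CONTROL_NAME,
    ActionCode,
    Datacube,
    EnvironmentRecord,
    MetaboliteRecord,
    Observation,
    OrganismRecord,
)
from .assertions import ReplicateExperiment
from .errors import SpecError

_TRANSFORMED = (
    ActionCode.INCREASED,
    ActionCode.DECREASED,
    ActionCode.NO_CHANGE,
    ActionCode.NOT_INVESTIGATED,
)


@dataclass
class CubeSpec:
    """Shape and action mix of a random datacube.

    ``p_detected`` is the chance a metabolite is present in a control
    pool; the four transformed-action probabilities must sum to 1.
    ``p_capped`` is the chance a directional call is a one-sided detection
    (confidence pinned at the cap, no log2 fold change).
    """

    n_metabolites: int = 20
    n_organisms: int = 3
    n_environments: int = 2
    p_detected: float = 0.8
    p_increase: float = 0.2
    p_decrease: float = 0.3
    p_nochange: float = 0.4
    p_notinvestigated: float = 0.1
    p_capped: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_metabolites, self.n_organisms, self.n_environments) < 1:
            raise SpecError("dimension sizes must be >= 1")
        probs = (
            self.p_detected,
            self.p_increase,
            self.p_decrease,
            self.p_nochange,
            self.p_notinvestigated,
            self.p_capped,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SpecError("probabilities must lie in [0, 1]")
        total = self.p_increase + self.p_decrease + self.p_nochange + self.p_notinvestigated
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"transformed-action probabilities sum to {total}, not 1")


def generate_cube(spec: CubeSpec) -> Datacube:
    """Generate a dense random datacube.

    Every (metabolite, organism, environment) combination gets an
    observation, including the control column, so the observation count is
    n_metabolites x (n_organisms + 1) x n_environments.  Output is
    identical for identical specs and always passes validation.
    """
    rng = np.random.default_rng(spec.seed)
    cube = Datacube()
    width = max(3, len(str(spec.n_metabolites)))
    met_names = [f"met_{i + 1:0{width}d}" for i in range(spec.n_metabolites)]
    org_names = [f"org_{i + 1:02d}" for i in range(spec.n_organisms)]
    env_names = [f"env_{i + 1:02d}" for i in range(spec.n_environments)]
    for name in met_names:
        putative = rng.random() < 0.1
        annotation = f"isomer group {rng.integers(1, 9)}" if rng.random() < 0.1 else None
        msi = int(rng.integers(1, 5)) if rng.random() < 0.3 else None
        cube.add_metabolite(
            MetaboliteRecord(name, putative=putative, annotation=annotation, msi_level=msi)
        )
    for name in org_names:
        cube.add_organism(OrganismRecord(name))
    for name in env_names:
        cube.add_environment(EnvironmentRecord(name))

    action_p = (spec.p_increase, spec.p_decrease, spec.p_nochange, spec.p_notinvestigated)
    for env in env_names:
        for met in met_names:
            detected = rng.random() < spec.p_detected
            cube.add_observation(
                Observation(
                    metabolite=met,
                    organism=CONTROL_NAME,
                    environment=env,
                    action=ActionCode.DETECTED if detected else ActionCode.NOT_DETECTED,
                )
            )
            for org in org_names:
                action = _TRANSFORMED[rng.choice(4, p=action_p)]
                log2fc: Optional[float] = None
                confidence = 0.0
                p_value: Optional[float] = None
                project = "synthetic" if rng.random() < 0.2 else None
                if action in (ActionCode.INCREASED, ActionCode.DECREASED):
                    p_value = float(rng.uniform(1e-8, 0.05))
                    if rng.random() < spec.p_capped:
                        confidence = CONFIDENCE_CAP  # one-sided detection
                    else:
                        magnitude = float(rng.exponential(1.2)) + 0.05
                        sign = 1.0 if action is ActionCode.INCREASED else -1.0
                        log2fc = sign * magnitude
                        confidence = min(magnitude, CONFIDENCE_CAP)
                elif action is ActionCode.NO_CHANGE and rng.random() < 0.7:
                    p_value = float(rng.uniform(0.05, 1.0))
                cube.add_observation(
                    Observation(
                        metabolite=met,
                        organism=org,
                        environment=env,
                        action=action,
                        log2fc=log2fc,
                        confidence=confidence,
                        p_value=p_value,
                        project=project,
                    )
                )
    return cube


@dataclass
class ExperimentSpec:
    """Ground-truth spike-in experiment for the assertion engine.

    Baseline per-metabolite abundances are log-normal with natural-log
    mean ``baseline_log_mean`` and sd ``baseline_log_sigma`` (arbitrary
    instrument units, median ~1100 by default, essentially always above
    the detection threshold).  Replicates carry multiplicative log-normal
    noise with natural-log sd ``noise_sigma`` (0.1 ~ 10% CV, typical for
    well-behaved LCMS peak areas).  A fraction of metabolites is spiked up
    or down by ``effect_log2`` doublings: spent means are control means x
    2^(+/-effect_log2), the rest are null.
    """

    n_metabolites: int = 1000
    n_replicates: int = 5
    baseline_log_mean: float = 7.0
    baseline_log_sigma: float = 1.0
    noise_sigma: float = 0.1
    frac_increased: float = 0.1
    frac_decreased: float = 0.1
    effect_log2: float = 2.0
    detection_threshold: float = 10.0
    environment: str = "synthetic medium"
    organism: str = "synthetic isolate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise SpecError("n_metabolites must be >= 1")
        if self.n_replicates < 2:
            raise SpecError("n_replicates must be >= 2 for test-based assertions")
        if self.baseline_log_sigma <= 0 or self.noise_sigma <= 0:
            raise SpecError("sigmas must be > 0")
        if not (0.0 <= self.frac_increased + self.frac_decreased <= 1.0):
            raise SpecError("spiked fractions must sum to at most 1")
        if self.detection_threshold < 0:
            raise SpecError("detection_threshold must be >= 0")


def generate_experiment(
    spec: ExperimentSpec,
) -> tuple[ReplicateExperiment, dict[str, ActionCode]]:
    """Generate replicate abundances plus the intended action per metabolite.

    Ground truth is ``INCREASED``/``DECREASED`` for spiked metabolites and
    ``NO_CHANGE`` for nulls; metabolite order of the spike assignment is
    randomized but seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_metabolites
    width = max(4, len(str(n)))
    names = [f"met_{i + 1:0{width}d}" for i in range(n)]
    n_up = int(round(spec.frac_increased * n))
    n_down = int(round(spec.frac_decreased * n))
    signs = np.concatenate(
        [np.ones(n_up), -np.ones(n_down), np.zeros(n - n_up - n_down)]
    )
    rng.shuffle(signs)
    by_sign = {1.0: ActionCode.INCREASED, -1.0: ActionCode.DECREASED, 0.0: ActionCode.NO_CHANGE}
    truth_codes = [by_sign[s] for s in signs]

    baselines = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sigma, size=n)
    noise_c = rng.lognormal(0.0, spec.noise_sigma, size=(n, spec.n_replicates))
    noise_s = rng.lognormal(0.0, spec.noise_sigma, size=(n, spec.n_replicates))
    delta = signs * spec.effect_log2
    control = baselines[:, None] * noise_c
    spent = (baselines * np.exp2(delta))[:, None] * noise_s

    abundances = {
        name: (control[i].tolist(), spent[i].tolist()) for i, name in enumerate(names)
    }
    truth = {name: truth_codes[i] for i, name in enumerate(names)}
    return (
        ReplicateExperiment(spec.environment, spec.organism, abundances),
        truth,
    )


# ---------------------------------------------------------------------------
# the two-isolate R2A fixture
# ---------------------------------------------------------------------------

GW = "GW123-8A04"
FW = "FW300-N2A2"
R2A = "R2A"


def worked_example_fixture() -> Datacube:
    """Two soil isolates in R2A medium, back-solved from published scores.

    The published compatibility-score walkthrough for *Phenylobacterium*
    sp. GW123-8A04 and *Pseudomonas* sp. FW300-N2A2 fixes the set sizes:
    25 metabolites decreased by both; 50 decreased by GW123-8A04 in total
    (the shared 25 are half of what it decreases); 26 by FW300-N2A2
    (25/26 rounds to the published 0.96); FW300-N2A2 increases 8 of
    GW123-8A04's decreases; GW123-8A04 increases none of FW300-N2A2's.
    Metabolite names are synthetic.  The control pool holds 100 detected
    metabolites (every decreased metabolite among them) so the uptake
    score of GW123-8A04 is 50/100 = 0.5; the published uptake score of
    FW300-N2A2 (0.3) is not exactly reproducible from these counts
    (26/100 = 0.26) because the true control pool size was not published.
    """
    cube = Datacube()
    cube.add_organism(OrganismRecord(GW, description="Phenylobacterium sp. (soil isolate)"))
    cube.add_organism(OrganismRecord(FW, description="Pseudomonas sp. (soil isolate)"))
    cube.add_environment(EnvironmentRecord(R2A, description="Reasoner's 2A broth"))
    names = [f"met_{i:03d}" for i in range(1, 101)]
    for name in names:
        cube.add_metabolite(MetaboliteRecord(name))

    def obs(met: str, org: str, action: ActionCode) -> None:
        log2fc = None
        confidence = 0.0
        if action is ActionCode.DECREASED:
            log2fc, confidence = -1.0, 1.0
        elif action is ActionCode.INCREASED:
            log2fc, confidence = 1.0, 1.0
        cube.add_observation(
            Observation(
                metabolite=met,
                organism=org,
                environment=R2A,
                action=action,
                log2fc=log2fc,
                confidence=confidence,
                project="R2A two-isolate example",
            )
        )

    for i, name in enumerate(names, start=1):
        cube.add_observation(
            Observation(
                metabolite=name,
                organism=CONTROL_NAME,
                environment=R2A,
                action=ActionCode.DETECTED,
            )
        )
        if i <= 25:  # decreased by both: the competition set
            obs(name, GW, ActionCode.DECREASED)
            obs(name, FW, ActionCode.DECREASED)
        elif i <= 42:  # decreased by GW only (17)
            obs(name, GW, ActionCode.DECREASED)
            obs(name, FW, ActionCode.NO_CHANGE)
        elif i <= 50:  # decreased by GW, increased by FW: the exchange set (8)
            obs(name, GW, ActionCode.DECREASED)
            obs(name, FW, ActionCode.INCREASED)
        elif i <= 51:  # the one metabolite decreased by FW alone
            obs(name, GW, ActionCode.NO_CHANGE)
            obs(name, FW, ActionCode.DECREASED)
        else:  # untouched remainder of the control pool
            obs(name, GW, ActionCode.NO_CHANGE)
            obs(name, FW, ActionCode.NO_CHANGE)
    return cube
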