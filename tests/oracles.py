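"""Independent brute-force oracles used by the test suite.

These recompute scores and graph degrees by naive iteration over the raw
observation list, deliberately bypassing the package's ActionSets /
WebGraph machinery.
"""

from fractions import Fraction
from typing import Optional

import exocube as xc


def naive_sets(cube: xc.Datacube, environment: str):
    obs = [o for o in cube.observations.values() if o.environment == environment]
    organisms = sorted({o.organism for o in obs if o.organism != xc.CONTROL_NAME})
    present = {
        o.metabolite
        for o in obs
        if o.organism == xc.CONTROL_NAME and o.action is xc.ActionCode.DETECTED
    }

    def of(org, action):
        return {o.metabolite for o in obs if o.organism == org and o.action is action}

    decreased = {org: of(org, xc.ActionCode.DECREASED) for org in organisms}
    increased = {org: of(org, xc.ActionCode.INCREASED) for org in organisms}
    return organisms, present, decreased, increased


def naive_score(kind: str, cube: xc.Datacube, environment: str,
                scored: str, reference: str = xc.CONTROL_NAME) -> tuple[int, int, Optional[Fraction]]:
    """(numerator, denominator, exact value or None) by brute-force counting."""
    _, present, decreased, increased = naive_sets(cube, environment)
    d = decreased.get(scored, set())
    if kind == "EUS":
        num, den = len(d & present), len(present)
    elif kind == "FMC":
        num, den = len(d & decreased.get(reference, set())), len(d)
    elif kind == "FME":
        num, den = len(d & increased.get(reference, set())), len(d)
    else:  # pragma: no cover
        raise ValueError(kind)
    return num, den, (Fraction(num, den) if den else None)


def naive_degree(cube: xc.Datacube, environment: str, metabolite: str) -> int:
    """Number of distinct organisms increasing or decreasing the metabolite."""
    return len(
        {
            o.organism
            for o in cube.observations.values()
            if o.environment == environment
            and o.metabolite == metabolite
            and o.organism != xc.CONTROL_NAME
            and o.action in (xc.ActionCode.INCREASED, xc.ActionCode.DECREASED)
        }
    )


def welch_p(a, b) -> float:
    """Hand-computed two-sided Welch t-test p-value (independent of scipy)."""
    import math
    from scipy.stats import t as tdist  # distribution function only

    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    tstat = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * tdist.sf(abs(tstat), df)
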