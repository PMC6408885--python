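"""A quantitative cost-benefit model of recruitment calling at food patches.

A forager in a group of size ``N`` (out of a local population ``N_pop``) that
calls at a food source trades off:

* **dilution benefit** — per-capita predation risk falls from 1/N to 1/(N+1)
  when one recruit arrives, a gain of 1/(N(N+1)): recruiting one bird halves a
  solitary forager's risk, but adds almost nothing to a large group;
* **attraction probability** — a call is only useful if someone hears it;
  with ``N_pop - N`` potential listeners each detecting the call with
  probability ``q``, the chance of recruiting at all is 1 - (1-q)^(N_pop-N),
  which shrinks as the group absorbs more of the local population;
* **competition cost** — each extra group member competes for the patch,
  scaled by how shareable the food is: (1-s) * N/(N+1), zero for a fully
  shareable resource;
* **predation cost of calling** — calling is conspicuous; the added hazard is
  the baseline attack hazard times (conspicuousness - 1), weighted by the
  fraction of the population concentrated at the caller's patch, N/N_pop.

The verbal framework behind this module states only monotonic orderings
(call when alone or in a small group; stay silent in a large one), so every
functional form here is a documented modelling choice constrained by those
orderings, and each can be swapped via the strategy hooks on
:func:`net_benefit`. Default weights are calibrated once so that the three
qualitative regimes appear at N=1 (clear call), N around 5 (cost near
benefit) and N of 20 or more (clear no-call) for a local population of 50.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import pandas as pd

__all__ = [
    "EconomicScenario",
    "CostBenefitResult",
    "dilution_benefit",
    "attraction_probability",
    "competition_cost",
    "predation_cost_of_calling",
    "net_benefit",
    "regime_scan",
    "pool_contrast",
]


class ScenarioError(ValueError):
    """An economic scenario violates its domain constraints."""


@dataclass(frozen=True)
class EconomicScenario:
    """Social context and per-component weights for one calling decision.

    ``group_size`` is the caller's current foraging group (N >= 1);
    ``local_population`` is the number of birds in the neighbourhood
    (N_pop >= N). ``shareability`` is the degree to which the patch supports
    extra foragers without per-capita loss. Weights convert the four
    components to one utility scale.
    """

    group_size: int = 1
    local_population: int = 50
    shareability: float = 0.5
    detection_probability: float = 0.1
    baseline_hazard: float = 0.1
    conspicuousness: float = 2.0
    w_benefit: float = 1.0
    w_competition: float = 0.05
    w_predation: float = 0.2
    regime_band: float = 0.02

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ScenarioError("group_size must be >= 1")
        if self.local_population < self.group_size:
            raise ScenarioError("local_population must be >= group_size")
        if not 0.0 <= self.shareability <= 1.0:
            raise ScenarioError("shareability must be in [0, 1]")
        if not 0.0 < self.detection_probability <= 1.0:
            raise ScenarioError("detection_probability must be in (0, 1]")
        if self.baseline_hazard < 0 or self.conspicuousness < 0:
            raise ScenarioError("hazard terms must be non-negative")


@dataclass(frozen=True)
class CostBenefitResult:
    """Component values and the call/no-call decision for one group size."""

    group_size: int
    dilution_benefit: float
    attraction_probability: float
    competition_cost: float
    predation_cost_of_calling: float
    net_benefit: float
    decision: str  # CALL | NO_CALL
    regime: str    # ALONE | SMALL_GROUP | LARGE_GROUP


def dilution_benefit(group_size: int) -> float:
    """Per-capita predation-risk drop from one recruit: 1/N - 1/(N+1).

    Equals 1/(N(N+1)); strictly decreasing in N. A solitary forager (N=1)
    halves its risk (0.5); for large groups the gain is negligible.
    """
    n = int(group_size)
    if n < 1:
        raise ScenarioError(f"group_size must be >= 1, got {group_size}")
    return 1.0 / (n * (n + 1))


def attraction_probability(group_size: int, local_population: int,
                           detection_probability: float) -> float:
    """Probability at least one of the N_pop - N listeners detects the call.

    Geometric detection: 1 - (1-q)^(N_pop - N); non-increasing in N and zero
    when the whole local population already forages in the group.
    """
    n, n_pop = int(group_size), int(local_population)
    if n < 1:
        raise ScenarioError("group_size must be >= 1")
    if n > n_pop:
        raise ScenarioError(f"group_size {n} exceeds local_population {n_pop}")
    q = detection_probability
    if not 0.0 < q <= 1.0:
        raise ScenarioError("detection_probability must be in (0, 1]")
    return 1.0 - (1.0 - q) ** (n_pop - n)


def competition_cost(group_size: int, shareability: float) -> float:
    """Within-group competition from one recruit: (1-s) * N/(N+1).

    Zero for fully shareable food, strictly increasing in N otherwise, and
    bounded above by 1-s.
    """
    n = int(group_size)
    if n < 1:
        raise ScenarioError("group_size must be >= 1")
    if not 0.0 <= shareability <= 1.0:
        raise ScenarioError("shareability must be in [0, 1]")
    return (1.0 - shareability) * n / (n + 1)


def predation_cost_of_calling(scenario: EconomicScenario) -> float:
    """Added attack hazard from the conspicuousness of calling.

    Baseline hazard times (conspicuousness - 1), scaled by N/N_pop: the more
    of the local population is concentrated at the caller's patch, the more
    detectable (and valuable to a predator) the calling group is.
    """
    return (scenario.baseline_hazard * (scenario.conspicuousness - 1.0)
            * scenario.group_size / scenario.local_population)


def net_benefit(
    scenario: EconomicScenario,
    benefit_fn: Callable[[int], float] = dilution_benefit,
    competition_fn: Callable[[int, float], float] = competition_cost,
) -> CostBenefitResult:
    """Net utility of calling and the resulting decision for one scenario.

    net = w_b * attraction * dilution - w_c * competition - w_p * predation.
    The caller should CALL exactly when the net benefit is positive. Regimes:
    ALONE is N=1; groups whose net benefit sits above -regime_band are
    SMALL_GROUP (at or near the cost=benefit boundary); below it,
    LARGE_GROUP. Alternative functional forms can be swapped in via
    ``benefit_fn`` / ``competition_fn``.
    """
    n = scenario.group_size
    dil = benefit_fn(n)
    attract = attraction_probability(n, scenario.local_population,
                                     scenario.detection_probability)
    comp = competition_fn(n, scenario.shareability)
    pred = predation_cost_of_calling(scenario)
    net = (scenario.w_benefit * attract * dil
           - scenario.w_competition * comp
           - scenario.w_predation * pred)
    decision = "CALL" if net > 0 else "NO_CALL"
    if n == 1:
        regime = "ALONE"
    elif net >= -scenario.regime_band:
        regime = "SMALL_GROUP"
    else:
        regime = "LARGE_GROUP"
    return CostBenefitResult(n, dil, attract, comp, pred, net, decision, regime)


def regime_scan(
    local_population: int,
    scenario: EconomicScenario | None = None,
    **overrides,
) -> pd.DataFrame:
    """Components, net benefit and decision for every group size 1..N_pop."""
    if local_population < 2:
        raise ScenarioError("local_population must be >= 2")
    base = scenario or EconomicScenario()
    base = replace(base, local_population=local_population, group_size=1, **overrides)
    rows = []
    for n in range(1, local_population + 1):
        r = net_benefit(replace(base, group_size=n))
        rows.append({
            "group_size": r.group_size,
            "dilution_benefit": r.dilution_benefit,
            "attraction_probability": r.attraction_probability,
            "competition_cost": r.competition_cost,
            "predation_cost_of_calling": r.predation_cost_of_calling,
            "net_benefit": r.net_benefit,
            "decision": r.decision,
            "regime": r.regime,
        })
    return pd.DataFrame(rows)


def pool_contrast(
    pool_sizes: Sequence[int],
    scenario: EconomicScenario | None = None,
) -> pd.DataFrame:
    """Compare scans across listener-pool sizes (morning vs afternoon analogue).

    A shrinking local population — fewer birds left to recruit later in the
    day — lowers the attraction probability, hence the net benefit of calling,
    at every group size below the pool size.
    """
    frames = []
    for n_pop in pool_sizes:
        scan = regime_scan(n_pop, scenario)
        scan.insert(0, "local_population", n_pop)
        frames.append(scan)
    return pd.concat(frames, ignore_index=True)
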