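"""Covariate-adaptive allocation by Pocock–Simon minimisation.

Each incoming participant is assigned to the arm that minimises the total
marginal imbalance — the sum, over five balancing factors (gestational-age
stratum, postnatal-age stratum, sex, site, blood-test reason), of the
absolute difference in arm counts at the participant's factor levels after
a hypothetical assignment. The minimising arm is chosen with probability
``p_assign`` (biased coin, default 0.8); an exact tie falls back to a fair
coin. All factors carry equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from painrct.errors import InvalidArgumentError

__all__ = [
    "ARMS",
    "FACTORS",
    "MinimisationState",
    "stratify",
    "allocate",
    "frame_levels",
    "batch_minimisation_allocations",
]

ARMS = ("intervention", "control")

#: Balancing factors, in the order they enter the imbalance sum.
FACTORS = ("ga_stratum", "postnatal_stratum", "sex", "site", "blood_test_reason")

#: Gestational-age stratum edges in weeks: [35, 37), [37, 39), [39, inf).
DEFAULT_GA_STRATA = (37.0, 39.0)
#: Postnatal-age stratum edges in days: [0, 3), [3, 7].
DEFAULT_POSTNATAL_STRATA = (3,)


def stratify(
    participant,
    ga_strata: tuple[float, ...] = DEFAULT_GA_STRATA,
    postnatal_strata: tuple[int, ...] = DEFAULT_POSTNATAL_STRATA,
) -> dict[str, str]:
    """Map a participant record to its level on each balancing factor.

    Continuous covariates are binned: gestational age at birth into
    ``35–36+6 / 37–38+6 / >=39`` weeks by default, postnatal age into
    ``0–2 / 3–7`` days. Categorical covariates are used as recorded.

    Raises
    ------
    InvalidArgumentError
        If gestational or postnatal age is outside the eligibility range.
    """
    ga = float(participant.gestational_age_at_birth)
    pna = int(participant.postnatal_age)
    if ga < 35:
        raise InvalidArgumentError(f"gestational age {ga} wk is below eligibility (>= 35)")
    if not 0 <= pna <= 7:
        raise InvalidArgumentError(f"postnatal age {pna} d outside [0, 7]")

    edges = (35.0,) + tuple(ga_strata)
    idx = int(np.searchsorted(ga_strata, ga, side="right"))
    if idx < len(ga_strata):
        hi = ga_strata[idx]
        ga_level = f"[{edges[idx]:g},{hi:g})"
    else:
        ga_level = f">={edges[idx]:g}"

    p_edges = (0,) + tuple(postnatal_strata)
    pidx = int(np.searchsorted(postnatal_strata, pna, side="right"))
    if pidx < len(postnatal_strata):
        pna_level = f"[{p_edges[pidx]},{postnatal_strata[pidx]})"
    else:
        pna_level = f"[{p_edges[pidx]},7]"

    return {
        "ga_stratum": ga_level,
        "postnatal_stratum": pna_level,
        "sex": str(participant.sex),
        "site": str(participant.site),
        "blood_test_reason": str(participant.blood_test_reason),
    }


@dataclass
class MinimisationState:
    """Running per-arm counts at every factor level, plus the coin bias."""

    p_assign: float = 0.8
    ga_strata: tuple[float, ...] = DEFAULT_GA_STRATA
    postnatal_strata: tuple[int, ...] = DEFAULT_POSTNATAL_STRATA
    counts: dict = field(default_factory=dict)  # factor -> level -> arm -> count
    totals: dict = field(default_factory=lambda: {a: 0 for a in ARMS})

    def __post_init__(self) -> None:
        if not 0.5 < self.p_assign <= 1.0:
            raise InvalidArgumentError(
                f"p_assign must be in (0.5, 1], got {self.p_assign}"
            )
        for f in FACTORS:
            self.counts.setdefault(f, {})

    def level_counts(self, factor: str, level: str) -> dict[str, int]:
        return self.counts[factor].get(level, {a: 0 for a in ARMS})

    def imbalance_if(self, levels: Mapping[str, str], arm: str) -> int:
        """Total imbalance after hypothetically assigning ``levels`` to ``arm``."""
        total = 0
        for f in FACTORS:
            c = dict(self.level_counts(f, levels[f]))
            c[arm] += 1
            total += abs(c[ARMS[0]] - c[ARMS[1]])
        return total

    def record(self, levels: Mapping[str, str], arm: str) -> None:
        for f in FACTORS:
            lev = self.counts[f].setdefault(levels[f], {a: 0 for a in ARMS})
            lev[arm] += 1
        self.totals[arm] += 1


def frame_levels(
    frame,
    ga_strata: tuple[float, ...] = DEFAULT_GA_STRATA,
    postnatal_strata: tuple[int, ...] = DEFAULT_POSTNATAL_STRATA,
) -> tuple[list[np.ndarray], list[int]]:
    """Integer-coded factor levels for an analysis frame.

    Expects columns ``ga``, ``postnatal``, ``sex``, ``site``, ``reason``;
    returns one integer array per balancing factor plus the level counts,
    the compact inputs :func:`batch_minimisation_allocations` consumes.
    """
    ga = np.asarray(frame["ga"], float)
    pna = np.asarray(frame["postnatal"], int)
    levels = [
        np.searchsorted(np.asarray(ga_strata), ga, side="right"),
        np.searchsorted(np.asarray(postnatal_strata), pna, side="right"),
    ]
    n_levels = [len(ga_strata) + 1, len(postnatal_strata) + 1]
    for col in ("sex", "site", "reason"):
        codes, uniques = np.asarray(frame[col]), None
        uniques, idx = np.unique(codes, return_inverse=True)
        levels.append(idx)
        n_levels.append(len(uniques))
    return levels, n_levels


def batch_minimisation_allocations(
    levels: list[np.ndarray],
    n_levels: list[int],
    p_assign: float,
    rng: np.random.Generator,
    n_draws: int,
) -> np.ndarray:
    """``n_draws`` independent minimisation allocation sequences at once.

    Re-runs the Pocock–Simon rule for the same ordered cohort under fresh
    coin flips, vectorised across draws; returns an (n, n_draws) 0/1
    matrix (1 = intervention). This is the reference set for the exact
    randomisation test under covariate-adaptive allocation: the observed
    allocation and each redraw come from the identical mechanism, whereas
    free label permutation over-disperses the null statistic and is
    conservative.
    """
    n = len(levels[0])
    counts = [np.zeros((n_draws, L, 2), dtype=np.int32) for L in n_levels]
    alloc = np.empty((n, n_draws), dtype=np.int8)
    rows = np.arange(n_draws)
    for i in range(n):
        d_int = np.zeros(n_draws)
        d_con = np.zeros(n_draws)
        for f in range(len(levels)):
            c = counts[f][rows, levels[f][i], :]  # (n_draws, 2): [int, con]
            d_int += np.abs(c[:, 0] + 1 - c[:, 1])
            d_con += np.abs(c[:, 0] - (c[:, 1] + 1))
        u = rng.random(n_draws)
        tie = d_int == d_con
        best_int = d_int < d_con
        pick_int = np.where(tie, u < 0.5, np.where(best_int, u < p_assign, u >= p_assign))
        alloc[i] = pick_int
        for f in range(len(levels)):
            counts[f][rows, levels[f][i], np.where(pick_int, 0, 1)] += 1
    return alloc.astype(float)


def allocate(
    participant,
    state: MinimisationState,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Allocate one participant, updating the state in place.

    Returns the arm plus a log record with the pre-assignment imbalance of
    each candidate arm and the assignment probability actually used.
    """
    levels = stratify(participant, state.ga_strata, state.postnatal_strata)
    imb = {arm: state.imbalance_if(levels, arm) for arm in ARMS}
    if imb[ARMS[0]] == imb[ARMS[1]]:
        arm = ARMS[0] if rng.random() < 0.5 else ARMS[1]
        p_used = 0.5
    else:
        best = min(ARMS, key=lambda a: imb[a])
        other = ARMS[1] if best == ARMS[0] else ARMS[0]
        arm = best if rng.random() < state.p_assign else other
        p_used = state.p_assign
    state.record(levels, arm)
    info = {
        "imbalance_intervention": imb["intervention"],
        "imbalance_control": imb["control"],
        "p_used": p_used,
        "arm": arm,
    }
    return arm, info
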