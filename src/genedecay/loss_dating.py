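"""Dating gene inactivation on mixed branches from dN/dS decomposition.

A *mixed* branch of duration ``T`` (MY) carried a functional gene for its
first ``t_f`` MY and a pseudogene for its last ``t_p = T - t_f`` MY.  While
functional, nonsynonymous changes accrue at a fraction ``omega_f`` of the
synonymous rate; after inactivation the gene evolves neutrally
(``omega_p = 1``).  Writing ``s_f`` and ``s_p`` for the synonymous rates of
the two portions and ``r = s_p / s_f``, the dN/dS observed over the whole
branch, ``omega_m``, satisfies

    omega_m * (s_f * t_f + s_p * t_p) = omega_f * s_f * t_f + s_p * t_p

which solves to

    t_p = T * (omega_m - omega_f) / (r * (1 - omega_m) + (omega_m - omega_f)).

The *1ds* model assumes a single synonymous rate (``r = 1``), reducing to
``t_p = T * (omega_m - omega_f) / (1 - omega_f)``; the *2ds* model allows the
pseudogenic portion its own synonymous rate, with ``r`` estimated from fully
pseudogenic branches.  The inactivation age is ``child_age + t_p`` because the
pseudogenic portion is the most recent part of the branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from genedecay.event_inference import MIXED, LossEvent, StatusTree


@dataclass
class MixedBranchObservation:
    """Inputs for dating one mixed branch.

    T : branch duration in MY (> 0).
    omega_f : dN/dS of the functional class (0 <= omega_f < 1).
    omega_m : dN/dS observed on the mixed branch; values outside
        [omega_f, 1] are clamped into the interval and flagged.
    r : synonymous-rate ratio s_p / s_f (1 under the 1ds model).
    child_age : age of the branch's child node in MY.
    """

    T: float
    omega_f: float
    omega_m: float
    r: float = 1.0
    child_age: float = 0.0
    clamped: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("branch duration T must be positive")
        if self.r <= 0:
            raise ValueError("synonymous-rate ratio r must be positive")
        if not 0 <= self.omega_f < 1:
            raise ValueError("dating requires 0 <= omega_f < 1 (purifying selection)")
        if self.omega_m < self.omega_f:
            self.omega_m = self.omega_f
            self.clamped = True
        elif self.omega_m > 1.0:
            self.omega_m = 1.0
            self.clamped = True


@dataclass
class DatingResult:
    """Pseudogenic time and inactivation age under the 1ds and 2ds models."""

    event_id: str
    branch: object
    t_p: dict  # model name -> pseudogenic duration (MY)
    age: dict  # model name -> inactivation age (MYA)
    age_range: tuple
    clamped: bool
    status: str = "dated"  # dated | undatable


def pseudogenic_time(obs: MixedBranchObservation, r: float | None = None) -> float:
    """Duration of the pseudogenic portion of a mixed branch (MY).

    ``r`` overrides the observation's rate ratio (``r=1`` gives the 1ds
    model).  The result is exactly 0 when ``omega_m == omega_f`` and exactly
    ``T`` when ``omega_m == 1`` regardless of ``r``.
    """
    rr = obs.r if r is None else r
    if rr <= 0:
        raise ValueError("r must be positive")
    excess = obs.omega_m - obs.omega_f
    denom = rr * (1.0 - obs.omega_m) + excess
    if denom == 0.0:  # omega_m == 1 and omega_m == omega_f cannot co-occur
        return obs.T
    t_p = obs.T * excess / denom
    return min(max(t_p, 0.0), obs.T)


def inactivation_age(obs: MixedBranchObservation, t_p: float) -> float:
    """Age of the inactivation point in MYA: child age plus pseudogenic time."""
    if not 0 <= t_p <= obs.T * (1 + 1e-12):
        raise ValueError(f"t_p={t_p} outside [0, T={obs.T}]")
    return obs.child_age + t_p


def estimate_rate_ratio(
    tree: StatusTree, ds_per_branch: Mapping[object, float]
) -> float:
    """2ds rate ratio: mean synonymous rate (dS/MY) on pseudogenic branches
    over that on functional branches.  Defaults to 1 when either class is
    absent from the table."""
    rates: dict[str, list[float]] = {"functional": [], "pseudogenic": []}
    for key, label in tree.labels.items():
        if key in ds_per_branch and label in rates:
            duration = tree.branch_duration(key)
            if duration > 0:
                rates[label].append(ds_per_branch[key] / duration)
    if not rates["pseudogenic"] or not rates["functional"]:
        return 1.0
    num = sum(rates["pseudogenic"]) / len(rates["pseudogenic"])
    den = sum(rates["functional"]) / len(rates["functional"])
    return num / den if den > 0 else 1.0


def date_event(
    tree: StatusTree,
    event: LossEvent,
    omega_f: float,
    omega_m: float | None,
    r: float = 1.0,
) -> DatingResult:
    """Date one loss event from its mixed-branch dN/dS."""
    if omega_m is None or not math.isfinite(omega_m):
        return DatingResult(
            event_id=event.event_id,
            branch=event.branch,
            t_p={},
            age={},
            age_range=(math.nan, math.nan),
            clamped=False,
            status="undatable",
        )
    obs = MixedBranchObservation(
        T=tree.branch_duration(event.branch),
        omega_f=omega_f,
        omega_m=omega_m,
        r=r,
        child_age=tree.child_age(event.branch),
    )
    t_p = {"1ds": pseudogenic_time(obs, r=1.0), "2ds": pseudogenic_time(obs, r=r)}
    age = {model: inactivation_age(obs, tp) for model, tp in t_p.items()}
    return DatingResult(
        event_id=event.event_id,
        branch=event.branch,
        t_p=t_p,
        age=age,
        age_range=(min(age.values()), max(age.values())),
        clamped=obs.clamped,
    )


def bootstrap_ages(
    tree: StatusTree,
    aln,
    events: list[LossEvent],
    *,
    n_boot: int = 100,
    seed: int = 0,
    r: float = 1.0,
    pi_mode: str = "f3x4",
) -> dict:
    """Seeded codon-site bootstrap of inactivation ages.

    Resamples alignment columns with replacement, refits the branch-category
    omegas on ``tree`` (which must already carry labels), redates every
    event, and returns per event the 2.5/97.5 percentile age interval under
    the 1ds model.  Optional and costly: one full fit per replicate.
    """
    import numpy as np

    from genedecay.codon_ml import CodonAlignment, branch_omegas_for_dating

    rng = np.random.default_rng(seed)
    ages: dict[str, list[float]] = {e.event_id: [] for e in events}
    for _ in range(n_boot):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        resampled = CodonAlignment(aln.taxa, aln.codes[:, cols], aln.pseudogenic)
        table = branch_omegas_for_dating(tree, resampled, pi_mode=pi_mode)
        for result in date_all(
            tree, events, table.omega_functional, table.omega_mixed, r=r
        ):
            if result.status == "dated":
                ages[result.event_id].append(result.age["1ds"])
    return {
        event_id: (
            (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))
            if a
            else (math.nan, math.nan)
        )
        for event_id, a in ages.items()
    }


def date_all(
    tree: StatusTree,
    events: list[LossEvent],
    omega_f: float,
    omega_m_by_branch: Mapping[object, float],
    r: float = 1.0,
) -> list[DatingResult]:
    """One DatingResult per loss event; events without an omega_m are
    reported undatable rather than dropped."""
    results = []
    for event in events:
        if tree.labels.get(event.branch) != MIXED:
            raise ValueError(f"event {event.event_id} branch is not labeled mixed")
        results.append(
            date_event(tree, event, omega_f, omega_m_by_branch.get(event.branch), r=r)
        )
    return results
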