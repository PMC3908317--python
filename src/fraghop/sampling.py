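"""Basin-hopping search over the fragment-replacement move set.

The search hops between local minima of the energy surface: the current
minimum is perturbed by a single trimer fragment replacement (optionally
biased toward a target lRMSD jump distance D), the perturbed conformation
is mapped back to a nearby minimum by repeated fragment replacements
(greedy, or Metropolis Monte Carlo at temperature T), and the hop is
accepted or rejected by the Metropolis criterion at the hop temperature.
Every sampled minimum is recorded — rejected hops included, flagged — so
the downstream ensemble reduction can use either reading of the ensemble.

RNG discipline: one numpy Generator per run, seeded from the config.  Per
hop it is consumed in a fixed order: perturbation draws (target distance,
then window/configuration per candidate), minimization draws (window and
configuration per proposal, plus one uniform per uphill proposal when
T > 0), then one uniform for hop acceptance when the hop goes uphill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .chain import Conformation, Sequence, compute_lrmsd, extended_chain
from .energy import (BudgetExhausted, EnergyModel, EvaluationCounter,
                     TermVector, evaluate)
from .fragments import FragmentLibrary, apply_fragment, sample_config, sample_window


def metropolis_accept_probability(delta_e: float, temperature: float) -> float:
    """Metropolis acceptance probability min(1, exp(-dE/T)).

    At T = 0 the rule is strict descent: probability 1 for dE < 0 and 0
    otherwise (dE = 0 rejected, preventing neutral cycling), which makes
    the zero-temperature Metropolis search identical to the greedy search.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if delta_e < 0:
        return 1.0
    if temperature == 0.0:
        return 0.0
    return min(1.0, math.exp(-delta_e / temperature))


def temperature_from_acceptance(probability: float, delta_e: float) -> float:
    """The temperature at which an energy increase ``delta_e`` is accepted
    with the given probability: T = -dE / ln(p).

    Round trips exactly with :func:`metropolis_accept_probability`.
    """
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must lie strictly in (0, 1)")
    if delta_e <= 0:
        raise ValueError("delta_e must be positive")
    return -delta_e / math.log(probability)


#: Calibration energy increases (kcal/mol) accepted with probability 0.1 at
#: the three studied minimizer temperatures.
TEMPERATURE_PRESETS = {
    "T0": temperature_from_acceptance(0.1, 1.4),
    "T1": temperature_from_acceptance(0.1, 1.7),
    "T2": temperature_from_acceptance(0.1, 2.6),
}


@dataclass(frozen=True)
class BHConfig:
    """All knobs of a basin-hopping run.

    ``target_distance`` (D, Angstrom) switches the perturbation to the
    distance-biased mode; None keeps it unbiased.  ``min_temperature`` is
    the minimizer temperature T (0 = greedy).  ``k`` is the consecutive-
    failure termination count of the minimizer; None means "sequence
    length".  ``hop_temperature`` defaults to the T1-style calibration
    (probability 0.1 of accepting a 1.7 kcal/mol increase).
    """

    target_distance: Optional[float] = None
    distance_sd: float = 1.0
    tolerance: float = 0.5
    max_attempts: int = 20
    min_temperature: float = 0.0
    k: Optional[int] = None
    hop_temperature: float = TEMPERATURE_PRESETS["T1"]
    budget: int = 10_000_000
    max_hops: Optional[int] = None
    seed: int = 0
    revisit_threshold: float = 0.1

    def __post_init__(self):
        if self.target_distance is not None and self.target_distance <= 0:
            raise ValueError("target distance D must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_temperature < 0 or self.hop_temperature < 0:
            raise ValueError("temperatures must be >= 0")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.max_hops is not None and self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")


def perturb_unbiased(conf: Conformation, library: FragmentLibrary,
                     rng: np.random.Generator) -> Conformation:
    """One random trimer fragment replacement; no energy evaluation."""
    position = sample_window(conf.n_residues, rng)
    config = sample_config(library, position, rng)
    return apply_fragment(conf, position, config)


def perturb_biased(
    conf: Conformation,
    library: FragmentLibrary,
    target_distance: float,
    config: BHConfig,
    rng: np.random.Generator,
) -> Tuple[Conformation, float, float, int]:
    """Distance-biased perturbation.

    A target jump magnitude d is drawn from Normal(D, distance_sd),
    redrawing on d <= 0.  Up to ``max_attempts`` independent single-
    fragment candidates are generated (none energy-evaluated); the first
    whose lRMSD from ``conf`` is within ``tolerance`` of d is returned,
    otherwise the candidate coming closest to d.

    Returns (perturbed conformation, target d, achieved lRMSD, attempts).
    """
    if target_distance <= 0:
        raise ValueError("target distance must be positive")
    d = rng.normal(target_distance, config.distance_sd)
    while d <= 0:
        d = rng.normal(target_distance, config.distance_sd)
    best: Optional[Conformation] = None
    best_dist = math.inf
    for attempt in range(1, config.max_attempts + 1):
        candidate = perturb_unbiased(conf, library, rng)
        dist = compute_lrmsd(conf, candidate)
        if abs(dist - d) <= config.tolerance:
            return candidate, d, dist, attempt
        if abs(dist - d) < abs(best_dist - d):
            best, best_dist = candidate, dist
    assert best is not None
    return best, d, best_dist, config.max_attempts


def minimize(
    conf: Conformation,
    library: FragmentLibrary,
    model: EnergyModel,
    temperature: float,
    k: int,
    counter: EvaluationCounter,
    rng: np.random.Generator,
) -> Tuple[Conformation, int, bool]:
    """Map a conformation to a nearby local minimum by fragment moves.

    Proposes one random fragment replacement at a time, evaluates it (one
    budget unit each) and accepts by the Metropolis rule at ``temperature``
    (strict descent at T = 0).  Terminates after ``k`` consecutive
    rejections, or when the budget runs out (flagged truncated).

    ``conf`` must already carry its energy.  Returns (final accepted state,
    evaluations used, truncated flag).
    """
    if conf.terms is None:
        raise ValueError("conformation must be energy-evaluated before minimization")
    if k < 1:
        raise ValueError("k must be >= 1")
    current = conf
    current_total = conf.terms.total
    fails = 0
    used = 0
    truncated = False
    while fails < k:
        position = sample_window(current.n_residues, rng)
        config = sample_config(library, position, rng)
        candidate = apply_fragment(current, position, config)
        try:
            evaluate(model, candidate, counter)
        except BudgetExhausted:
            truncated = True
            break
        used += 1
        delta_e = candidate.terms.total - current_total
        if delta_e < 0:
            accept = True
        elif temperature == 0.0:
            accept = False
        else:
            accept = rng.random() < math.exp(-delta_e / temperature)
        if accept:
            current = candidate
            current_total = candidate.terms.total
            fails = 0
        else:
            fails += 1
    return current, used, truncated


def greedy_minimize(
    conf: Conformation,
    library: FragmentLibrary,
    model: EnergyModel,
    k: int,
    counter: EvaluationCounter,
    rng: np.random.Generator,
) -> Tuple[Conformation, int, bool]:
    """Strict-descent minimization: accept only energy-lowering moves.

    Implemented independently of :func:`minimize`; with the same seed it
    must produce byte-identical trajectories to ``minimize`` at T = 0
    (the zero-temperature Metropolis search *is* the greedy search).
    """
    if conf.terms is None:
        raise ValueError("conformation must be energy-evaluated before minimization")
    if k < 1:
        raise ValueError("k must be >= 1")
    current = conf
    fails = 0
    used = 0
    truncated = False
    while fails < k:
        position = sample_window(current.n_residues, rng)
        config = sample_config(library, position, rng)
        candidate = apply_fragment(current, position, config)
        try:
            evaluate(model, candidate, counter)
        except BudgetExhausted:
            truncated = True
            break
        used += 1
        if candidate.terms.total < current.terms.total:
            current = candidate
            fails = 0
        else:
            fails += 1
    return current, used, truncated


@dataclass
class LocalMinimumRecord:
    """One sampled local minimum of the basin-hopping trajectory."""

    hop: int
    angles: np.ndarray
    terms: TermVector
    accepted: bool
    mu_prev: float = math.nan          # lRMSD to the previously sampled minimum
    evaluations: int = 0
    truncated: bool = False
    d_target: float = math.nan         # biased mode only
    achieved_distance: float = math.nan
    attempts: int = 0
    lrmsd_native: float = math.nan

    @property
    def total(self) -> float:
        return self.terms.total


@dataclass
class Trajectory:
    """Ordered local-minimum records plus run bookkeeping."""

    sequence: Sequence
    records: List[LocalMinimumRecord]
    config: BHConfig
    term_names: Tuple[str, ...]
    hops: int = 0
    acceptances: int = 0
    evaluations: int = 0
    returns_to_previous: int = 0

    def conformation(self, index: int) -> Conformation:
        rec = self.records[index]
        conf = Conformation(sequence=self.sequence, angles=rec.angles.copy())
        conf.terms = rec.terms
        return conf


def run_basin_hopping(
    sequence: Sequence,
    library: FragmentLibrary,
    model: EnergyModel,
    config: BHConfig,
    native: Optional[Conformation] = None,
) -> Trajectory:
    """Run the full basin-hopping search until the budget is exhausted.

    The start state is the extended chain minimized once, recorded as hop 0.
    Each subsequent hop perturbs the current minimum, minimizes, records the
    sampled minimum (with its lRMSD to the previously *sampled* minimum, a
    mu_|MM| sample), and moves the current state by the Metropolis rule at
    the hop temperature.  Rejected-hop minima stay in the record, flagged.
    Fully reproducible from the seed.
    """
    L = len(sequence)
    library.check_covers(L)
    k = config.k if config.k is not None else L
    rng = np.random.default_rng(config.seed)
    counter = EvaluationCounter(budget=config.budget)

    start = extended_chain(sequence)
    evaluate(model, start, counter)
    current, used, truncated = minimize(
        start, library, model, config.min_temperature, k, counter, rng
    )

    def native_dist(c: Conformation) -> float:
        return math.nan if native is None else compute_lrmsd(c, native)

    records = [LocalMinimumRecord(
        hop=0, angles=current.angles.copy(), terms=current.terms,
        accepted=True, evaluations=used + 1, truncated=truncated,
        lrmsd_native=native_dist(current),
    )]
    traj = Trajectory(sequence=sequence, records=records, config=config,
                      term_names=tuple(model.term_names))
    previous_sampled = current

    while counter.remaining > 0 and not truncated and (
            config.max_hops is None or traj.hops < config.max_hops):
        if config.target_distance is None:
            perturbed = perturb_unbiased(current, library, rng)
            d_target = achieved = math.nan
            attempts = 1
        else:
            perturbed, d_target, achieved, attempts = perturb_biased(
                current, library, config.target_distance, config, rng
            )
        try:
            evaluate(model, perturbed, counter)
        except BudgetExhausted:
            break
        minimum, used, truncated = minimize(
            perturbed, library, model, config.min_temperature, k, counter, rng
        )
        traj.hops += 1
        mu_prev = compute_lrmsd(previous_sampled, minimum)
        revisit = compute_lrmsd(current, minimum) < config.revisit_threshold
        delta_e = minimum.terms.total - current.terms.total
        if delta_e < 0:
            accepted = True
        else:
            p = metropolis_accept_probability(delta_e, config.hop_temperature)
            accepted = rng.random() < p
        traj.records.append(LocalMinimumRecord(
            hop=traj.hops, angles=minimum.angles.copy(), terms=minimum.terms,
            accepted=accepted, mu_prev=mu_prev, evaluations=used + 1,
            truncated=truncated, d_target=d_target,
            achieved_distance=achieved, attempts=attempts,
            lrmsd_native=native_dist(minimum),
        ))
        if revisit:
            traj.returns_to_previous += 1
        if accepted:
            current = minimum
        previous_sampled = minimum

    traj.acceptances = sum(1 for r in traj.records[1:] if r.accepted)
    traj.evaluations = counter.count
    return traj
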