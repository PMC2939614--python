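"""Disease-allele frequency trajectories and controlled mating.

A genetic disease is simulated by pinning the frequency of each
disease-predisposing allele (DPA) to a pre-simulated per-generation
trajectory.  Trajectories are drawn either forward in time (for alleles
older than the expansion, restarting until the present-day frequency lands
in a desired range) or backward in time (for recent mutants, stepping back
from the present-day frequency until the allele is lost).  During the main
run a controlled mating scheme accepts or rejects offspring by genotype so
that the realised allele count at every controlled locus matches the
trajectory exactly in each generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evolve import (
    FitnessTriple,
    SelectionModel,
    _fitness_vector,
    _gametes_for,
    _parent_pools,
    mutate_haplotype,
)
from .popmodel import Population, SubPopulation

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "TrajectoryRequest",
    "TrajectoryError",
    "selection_response",
    "invert_selection_response",
    "marginal_fitness",
    "simulate_forward_trajectory",
    "simulate_backward_trajectory",
    "controlled_offspring_generation",
    "make_controlled_hook",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
]


class TrajectoryError(RuntimeError):
    """Raised when no acceptable trajectory is found within max_attempts.

    Carries a ``feasibility_report`` dict so simulation parameters can be
    adjusted: for forward mode the mean ending frequency over the failed
    attempts, for backward mode the mean trajectory length.
    """

    def __init__(self, msg: str, feasibility_report: dict):
        super().__init__(msg)
        self.feasibility_report = feasibility_report


@dataclass
class Trajectory:
    """Per-generation target frequencies for controlled loci.

    ``freqs[locus_index]`` is an array x_0 .. x_T; ``origin_gen`` records,
    per locus, the generation at which a backward-simulated mutant was
    introduced (None for forward-simulated trajectories).
    """

    freqs: dict[int, np.ndarray]
    origin_gen: dict[int, int | None] = field(default_factory=dict)
    attempts: dict[int, int] = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(next(iter(self.freqs.values()))) - 1

    def target_counts(self, t: int, n_diploid: int) -> dict[int, int]:
        """Integer allele-1 quotas at generation t for 2N alleles (round half up)."""
        return {
            l: int(np.floor(2 * n_diploid * x[t] + 0.5))
            for l, x in self.freqs.items()
        }


@dataclass(frozen=True)
class TrajectoryRequest:
    mode: str  # "forward" | "backward"
    fitness: FitnessTriple
    sizes: tuple[int, ...]  # diploid size per generation, length T+1
    x0: float | None = None  # forward: starting frequency
    x_T_range: tuple[float, float] | None = None  # forward acceptance interval
    x_T: float | None = None  # backward: present-day frequency
    max_attempts: int = 10000
    max_origin_gen: int | None = None  # backward: max age (generations) of mutant

    def __post_init__(self):
        if self.mode not in ("forward", "backward"):
            raise ValueError(f"unknown trajectory mode {self.mode!r}")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.mode == "forward":
            if self.x0 is None or not 0 < self.x0 <= 1:
                raise ValueError("forward mode needs starting frequency x0 > 0")
        else:
            if self.x_T is None or not 0 < self.x_T <= 1:
                raise ValueError("backward mode needs present-day frequency > 0")


def selection_response(x: float, f: FitnessTriple) -> float:
    """Deterministic one-generation change of the alt-allele frequency.

    Standard diploid viability selection under random mating:
    x' = (x^2 w22 + x(1-x) w12) / wbar, with
    wbar = x^2 w22 + 2x(1-x) w12 + (1-x)^2 w11.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("frequency must lie in [0, 1]")
    q = 1.0 - x
    wbar = x * x * f.w22 + 2.0 * x * q * f.w12 + q * q * f.w11
    if wbar == 0.0:
        raise ValueError("mean fitness is zero; selection response undefined")
    return (x * x * f.w22 + x * q * f.w12) / wbar


def invert_selection_response(
    x: float, f: FitnessTriple, tol: float = 1e-12
) -> float:
    """Solve selection_response(y, f) = x for y by bisection on [0, 1].

    The response is monotone increasing in the frequency for any positive
    fitness triple, so bisection converges; the neutral triple gives the
    identity.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("frequency must lie in [0, 1]")
    if x == 0.0 or x == 1.0:
        return x
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if selection_response(mid, f) < x:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def marginal_fitness(
    sel: SelectionModel, locus: int, other_freqs: dict[int, float]
) -> FitnessTriple:
    """Marginal fitness triple of one controlled locus in a multilocus model.

    Under the multiplicative model with unlinked loci the expectation of the
    multilocus fitness over Hardy-Weinberg genotype distributions at the
    other loci factorises into the locus's own triple times a constant (the
    product of mean fitnesses elsewhere); the constant cancels after
    normalising by w11, so relative selection pressure is preserved.
    """
    own = dict(sel.loci).get(locus)
    if own is None:
        raise ValueError(f"locus {locus} is not under selection")
    const = 1.0
    for l, f in sel.loci:
        if l == locus:
            continue
        if l not in other_freqs:
            raise ValueError(f"frequency at selected locus {l} required")
        p = other_freqs[l]
        q = 1.0 - p
        const *= q * q * f.w11 + 2.0 * p * q * f.w12 + p * p * f.w22
    w = own.as_array() * const
    if w[0] > 0:
        w = w / w[0] * own.w11  # normalise so the w11-relative scaling is kept
    return FitnessTriple(*w)


def simulate_forward_trajectory(
    req: TrajectoryRequest, rng: np.random.Generator
) -> Trajectory:
    """Forward trajectory with restart until the endpoint lands in range.

    Each generation applies the deterministic selection response followed by
    binomial drift at the scheduled size:
    x_{t+1} = Binomial(2 N_{t+1}, x'_t) / (2 N_{t+1}).  The whole path is
    re-drawn from x0 until x_T falls inside ``x_T_range``.  A ``sizes``
    entry of 0 or None disables drift for that step (deterministic limit).
    """
    if req.mode != "forward":
        raise ValueError("request is not forward mode")
    lo, hi = req.x_T_range if req.x_T_range is not None else (0.0, 1.0)
    T = len(req.sizes) - 1
    endings = []
    for attempt in range(1, req.max_attempts + 1):
        x = req.x0
        path = np.empty(T + 1)
        path[0] = x
        for t in range(1, T + 1):
            p = selection_response(x, req.fitness)
            n2 = 2 * req.sizes[t] if req.sizes[t] else 0
            x = rng.binomial(n2, p) / n2 if n2 else p
            path[t] = x
        endings.append(x)
        if lo <= x <= hi:
            return Trajectory(
                freqs={-1: path}, origin_gen={-1: None}, attempts={-1: attempt}
            )
    report = {
        "mode": "forward",
        "attempts": req.max_attempts,
        "mean_ending_frequency": float(np.mean(endings)),
    }
    logger.error(
        "forward trajectory infeasible; average ending frequency %.4f",
        report["mean_ending_frequency"],
    )
    raise TrajectoryError(
        f"no forward trajectory ended in [{lo}, {hi}] after "
        f"{req.max_attempts} attempts (mean ending frequency "
        f"{report['mean_ending_frequency']:.4f})",
        report,
    )


def simulate_backward_trajectory(
    req: TrajectoryRequest, rng: np.random.Generator
) -> Trajectory:
    """Backward trajectory for a recent mutant: step back until loss.

    From the present-day frequency x_T the path steps to earlier
    generations with x_{t-1} = Binomial(2 N_{t-1}, inv) / (2 N_{t-1}) where
    ``inv`` solves selection_response(inv) = x_t.  The path is accepted when
    it absorbs at 0 (the introduction generation); re-drawn if it absorbs at
    1, reaches generation 0 still segregating, or the mutant age exceeds
    ``max_origin_gen``.
    """
    if req.mode != "backward":
        raise ValueError("request is not backward mode")
    T = len(req.sizes) - 1
    max_age = req.max_origin_gen if req.max_origin_gen is not None else T
    lengths = []
    for attempt in range(1, req.max_attempts + 1):
        path = np.zeros(T + 1)
        path[T] = x = req.x_T
        ok = False
        for t in range(T - 1, -1, -1):
            inv = invert_selection_response(x, req.fitness)
            n2 = 2 * req.sizes[t]
            x = rng.binomial(n2, inv) / n2
            path[t] = x
            if x == 0.0:
                origin = t
                ok = T - origin <= max_age
                break
            if x == 1.0:
                break
        else:
            origin = 0
        lengths.append(T - t)
        if ok:
            return Trajectory(
                freqs={-1: path}, origin_gen={-1: origin}, attempts={-1: attempt}
            )
    report = {
        "mode": "backward",
        "attempts": req.max_attempts,
        "mean_trajectory_length": float(np.mean(lengths)),
    }
    logger.error(
        "backward trajectory infeasible; mean trajectory length %.1f",
        report["mean_trajectory_length"],
    )
    raise TrajectoryError(
        f"no backward trajectory was lost within {max_age} generations after "
        f"{req.max_attempts} attempts (mean length "
        f"{report['mean_trajectory_length']:.1f})",
        report,
    )


def controlled_offspring_generation(
    pop: Population,
    target_counts: dict[int, int],
    target_size: int,
    probs: np.ndarray,
    mu: float,
    rng: np.random.Generator,
    sel: SelectionModel | None = None,
    max_tries_multiplier: int = 200,
) -> Population:
    """One generation of mating with exact allele counts at controlled loci.

    Offspring are produced by the usual fitness-weighted mating scheme and
    accepted or rejected by genotype: with S slots and per-locus remaining
    quota R_l, a candidate carrying c_l copies of allele 1 is accepted iff
    c_l <= R_l and R_l - c_l <= 2 (S - 1) for every controlled locus, which
    guarantees every quota is met exactly when the generation fills.
    """
    if len(pop.subpops) != 1:
        raise ValueError("controlled mating expects a single subpopulation")
    sp = pop.subpops[0]
    ctrl = np.array(sorted(target_counts), dtype=np.int64)
    quota = np.array([target_counts[l] for l in ctrl], dtype=np.int64)
    if (quota < 0).any() or (quota > 2 * target_size).any():
        raise ValueError("target counts must lie in [0, 2N]")
    # quick feasibility: an absent allele cannot be produced (mu aside)
    if mu == 0.0:
        pool = sp.haps[:, ctrl].sum(axis=0)
        for l, q, have in zip(ctrl, quota, pool):
            if q > 0 and have == 0:
                raise ValueError(f"allele 1 absent at controlled locus {l}")
            if q < 2 * target_size and have == 2 * sp.size:
                raise ValueError(f"allele 0 absent at controlled locus {l}")
    w = _fitness_vector(sp, sel)
    males, pm, females, pf = _parent_pools(sp, w)
    S = target_size
    R = quota.copy()
    acc_f: list[np.ndarray] = []
    acc_m: list[np.ndarray] = []
    tries = 0
    max_tries = max_tries_multiplier * target_size
    batch = max(256, target_size)
    while S > 0:
        if tries >= max_tries:
            raise TrajectoryError(
                f"controlled mating exceeded {max_tries} offspring tries "
                f"with {S} slots and quotas {dict(zip(ctrl.tolist(), R.tolist()))}",
                {"remaining_slots": int(S), "remaining_quota": R.tolist()},
            )
        k = min(batch, max_tries - tries)
        fathers = rng.choice(males, size=k, p=pm)
        mothers = rng.choice(females, size=k, p=pf)
        gf = _gametes_for(sp.haps, fathers, probs, rng)
        gm = _gametes_for(sp.haps, mothers, probs, rng)
        if mu > 0.0:
            gf = mutate_haplotype(gf, mu, rng)
            gm = mutate_haplotype(gm, mu, rng)
        counts = gf[:, ctrl].astype(np.int64) + gm[:, ctrl]
        for i in range(k):
            tries += 1
            c = counts[i]
            if (c <= R).all() and (R - c <= 2 * (S - 1)).all():
                acc_f.append(gf[i])
                acc_m.append(gm[i])
                R -= c
                S -= 1
                if S == 0:
                    break
        if S == 0:
            break
    child = SubPopulation.empty(target_size, sp.haps.shape[1])
    child.haps[0::2] = np.vstack(acc_f)
    child.haps[1::2] = np.vstack(acc_m)
    child.sex[:] = rng.integers(0, 2, size=target_size)
    child.ancestry[:] = float(sp.ancestry.mean()) if sp.size else 0.0
    return Population([child], pop.loci, pop.generation + 1, pop.rng_state)


def make_controlled_hook(traj: Trajectory, loci: list[int]):
    """Adapt a Trajectory to the ``controlled`` hook of :func:`evolve.evolve`.

    ``loci`` maps the trajectory's frequency paths (in sorted key order) to
    locus indices of the evolving population.
    """
    keys = sorted(traj.freqs)
    if len(keys) != len(loci):
        raise ValueError("one locus index per trajectory path required")
    paths = {l: traj.freqs[k] for l, k in zip(loci, keys)}

    def hook(pop, t, target_size, probs, mu, sel, rng):
        targets = {
            l: int(np.floor(2 * target_size * paths[l][t + 1] + 0.5)) for l in paths
        }
        return controlled_offspring_generation(
            pop, targets, target_size, probs, mu, rng, sel
        )

    return hook


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("generation\tlocus\tfrequency\n")
        for l in sorted(traj.freqs):
            for t, x in enumerate(traj.freqs[l]):
                fh.write(f"{t}\t{l}\t{x:.10g}\n")


def read_trajectory_tsv(path) -> Trajectory:
    rows: dict[int, dict[int, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            t, l, x = line.split("\t")
            rows.setdefault(int(l), {})[int(t)] = float(x)
    freqs = {
        l: np.array([d[t] for t in sorted(d)]) for l, d in rows.items()
    }
    return Trajectory(freqs=freqs)
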