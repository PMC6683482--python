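"""Optimal-contribution mate selection under lethal-allele penalties.

The decision variable is a mating list: N ordered sire-dam pairs drawn from
the candidate cohorts, with per-sire usage capped and each dam used at most
once.  The key objective is the mean progeny index; long-term inbreeding is
controlled by steering the solution to a target angle on the normalized
gain-versus-parental-coancestry frontier (0 degrees = maximum index,
90 degrees = minimum coancestry), and lethality is discouraged by penalty
weights on LethalA (carrier avoidance) or LethalG (carrier-mating avoidance)
expressed in index dollars through the embryonic-mortality cost.

The inner search is a seeded evolutionary algorithm over (per-sire mating
counts, dam subset, dam-to-sire assignment) with elitist selection, so the
best penalized objective is non-decreasing over generations; an outer
bisection on a coancestry penalty multiplier hits the target angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lethal import transmission_prob
from .pedigree import Pedigree

__all__ = [
    "ObjectiveConfig",
    "Evaluation",
    "FrontierState",
    "MateSelContext",
    "validate_matings",
    "evaluate",
    "frontier_endpoints",
    "ea_optimize",
    "solve_at_degrees",
]


@dataclass
class ObjectiveConfig:
    """Mate-selection problem and search settings.

    Study defaults: 100 matings, at most 50 per sire, a 25-degree target
    compromise, and a $200 embryonic-mortality cost scaling the lethality
    penalties into index dollars.
    """

    n_matings: int = 100
    max_per_sire: int = 50
    target_degrees: float = 25.0
    w_a: float = 0.0
    w_g: float = 0.0
    mortality_cost: float = 200.0
    survivor_condition: bool = True
    pop_size: int = 64
    max_generations: int = 2000
    stall_generations: int = 100
    stall_tol: float = 1e-6
    angle_tol_degrees: float = 1.0
    max_outer_iterations: int = 24
    seed: int = 0


@dataclass(frozen=True)
class Evaluation:
    mean_index: float
    coancestry: float
    lethal_a: float
    lethal_g: float
    penalized: float


@dataclass(frozen=True)
class FrontierState:
    """Normalized-frontier bookkeeping for a solution."""

    index_max: float  # mean index at the max-index endpoint
    index_min: float  # mean index at the min-coancestry endpoint
    coancestry_max: float  # coancestry at the max-index endpoint
    coancestry_min: float  # minimum achievable coancestry
    angle_degrees: float
    converged: bool = True


class MateSelContext:
    """Candidate data bundled for fast mating-list evaluation.

    Holds candidate sires and dams in stable pedigree order, their index
    values, kinship among all candidates, and per-locus lethal-transmission
    and carrier probabilities derived from genotype probabilities.
    """

    def __init__(
        self,
        sires: list[str],
        dams: list[str],
        m_values: pd.Series,
        kinship: pd.DataFrame,
        probs: dict[str, np.ndarray],
        q: np.ndarray,
    ):
        if not sires or not dams:
            raise ValueError("need at least one candidate of each sex")
        self.sires = list(sires)
        self.dams = list(dams)
        self.m_sire = np.array([m_values[s] for s in sires], dtype=float)
        self.m_dam = np.array([m_values[d] for d in dams], dtype=float)
        order = self.sires + self.dams
        self.K = kinship.loc[order, order].to_numpy()
        self.q = np.asarray(q, dtype=float)
        L = len(self.q)

        def triples(a: str) -> np.ndarray:
            p = np.asarray(probs[a], dtype=float)
            return p[None, :] if p.ndim == 1 else p

        self.a_sire = np.stack([transmission_prob(triples(s)) for s in sires])
        self.a_dam = np.stack([transmission_prob(triples(d)) for d in dams])
        self.het_sire = np.stack([triples(s)[:, 1] for s in sires])
        if self.a_sire.shape[1] != L:
            raise ValueError("genotype probabilities and panel disagree on loci")

    @classmethod
    def from_pedigree(
        cls,
        ped: Pedigree,
        m_values: pd.Series,
        kinship: pd.DataFrame,
        probs: dict[str, np.ndarray],
        q: np.ndarray,
    ) -> "MateSelContext":
        sires = [a.id for a in ped.candidates("M")]
        dams = [a.id for a in ped.candidates("F")]
        return cls(sires, dams, m_values, kinship, probs, q)


# ---------------------------------------------------------------------------
# internal solution representation


@dataclass
class _Solution:
    counts: np.ndarray  # (n_sires,) matings per sire
    dam_idx: np.ndarray  # (N,) distinct dam indices, paired positionally

    def copy(self) -> "_Solution":
        return _Solution(self.counts.copy(), self.dam_idx.copy())


def _sire_vec(counts: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(counts)), counts)


def _evaluate_solution(
    ctx: MateSelContext, sol: _Solution, cfg: ObjectiveConfig
) -> Evaluation:
    N = cfg.n_matings
    sv = _sire_vec(sol.counts)
    mean_index = 0.5 * (
        float(sol.counts @ ctx.m_sire) / N + float(ctx.m_dam[sol.dam_idx].mean())
    )

    n_sires = len(ctx.sires)
    x = np.zeros(len(ctx.sires) + len(ctx.dams))
    x[:n_sires] = sol.counts / (2.0 * N)
    x[n_sires + sol.dam_idx] = 1.0 / (2.0 * N)
    used = np.nonzero(x)[0]
    xv = x[used]
    coan = float(xv @ ctx.K[np.ix_(used, used)] @ xv)

    a_s = ctx.a_sire[sv]
    a_d = ctx.a_dam[sol.dam_idx]
    p_aa = a_s * a_d
    lg = float(np.mean(1.0 - np.prod(1.0 - p_aa, axis=1)))
    p_carrier = a_s * (1 - a_d) + a_d * (1 - a_s)
    if cfg.survivor_condition:
        with np.errstate(invalid="ignore"):
            t = np.where(p_aa < 1.0, 0.5 * p_carrier / (1.0 - p_aa), 0.0)
    else:
        t = 0.5 * (a_s + a_d)
    la = float(1.0 - np.prod(1.0 - t.mean(axis=0) * ctx.q))

    pen = mean_index - cfg.mortality_cost * (cfg.w_a * la + cfg.w_g * lg)
    return Evaluation(mean_index, coan, la, lg, pen)


def _matings(ctx: MateSelContext, sol: _Solution) -> list[tuple[str, str]]:
    sv = _sire_vec(sol.counts)
    return [(ctx.sires[s], ctx.dams[d]) for s, d in zip(sv, sol.dam_idx)]


def _solution_from_matings(
    ctx: MateSelContext, matings: list[tuple[str, str]], cfg: ObjectiveConfig
) -> _Solution:
    validate_matings(ctx, matings, cfg)
    sire_pos = {s: i for i, s in enumerate(ctx.sires)}
    dam_pos = {d: i for i, d in enumerate(ctx.dams)}
    counts = np.zeros(len(ctx.sires), dtype=np.int64)
    for s, _ in matings:
        counts[sire_pos[s]] += 1
    # dams listed in expanded sire order so pairings are preserved
    pairs = sorted(range(len(matings)), key=lambda k: sire_pos[matings[k][0]])
    dam_idx = np.array([dam_pos[matings[k][1]] for k in pairs], dtype=np.int64)
    return _Solution(counts, dam_idx)


def validate_matings(
    ctx: MateSelContext, matings: list[tuple[str, str]], cfg: ObjectiveConfig
) -> None:
    """Raise ValueError unless the list satisfies every feasibility invariant."""
    if len(matings) != cfg.n_matings:
        raise ValueError(f"expected {cfg.n_matings} matings, got {len(matings)}")
    sire_set, dam_seen = set(ctx.sires), set()
    counts: dict[str, int] = {}
    for s, d in matings:
        if s not in sire_set:
            raise ValueError(f"{s!r} is not a candidate sire")
        if d not in set(ctx.dams):
            raise ValueError(f"{d!r} is not a candidate dam")
        if d in dam_seen:
            raise ValueError(f"dam {d!r} used more than once")
        dam_seen.add(d)
        counts[s] = counts.get(s, 0) + 1
    over = {s: c for s, c in counts.items() if c > cfg.max_per_sire}
    if over:
        raise ValueError(f"sires over the per-sire limit: {over}")


def evaluate(
    ctx: MateSelContext, matings: list[tuple[str, str]], cfg: ObjectiveConfig
) -> Evaluation:
    """Score a feasible mating list: index, coancestry, lethality, penalized objective.

    penalized = mean progeny index - mortality_cost * (w_a * LethalA + w_g * LethalG).
    """
    return _evaluate_solution(ctx, _solution_from_matings(ctx, matings, cfg), cfg)


# ---------------------------------------------------------------------------
# endpoints and angles


def _truncation_solution(ctx: MateSelContext, cfg: ObjectiveConfig) -> _Solution:
    """Top sires to their caps and the top N dams, by index value (stable ties)."""
    N = cfg.n_matings
    order_s = np.argsort(-ctx.m_sire, kind="stable")
    counts = np.zeros(len(ctx.sires), dtype=np.int64)
    left = N
    for s in order_s:
        take = min(cfg.max_per_sire, left)
        counts[s] = take
        left -= take
        if left == 0:
            break
    if left > 0:
        raise ValueError("not enough sire capacity for the requested matings")
    order_d = np.argsort(-ctx.m_dam, kind="stable")[:N]
    if len(order_d) < N:
        raise ValueError("not enough dams for the requested matings")
    return _Solution(counts, np.sort(order_d))


def _min_coancestry_solution(
    ctx: MateSelContext, cfg: ObjectiveConfig, n_iter: int = 300
) -> _Solution:
    """Frank-Wolfe minimization of x'Kx over feasible contributions, then rounding."""
    N = cfg.n_matings
    n_s, n_d = len(ctx.sires), len(ctx.dams)
    cap_s = cfg.max_per_sire / (2.0 * N)
    cap_d = 1.0 / (2.0 * N)

    def lp_vertex(grad: np.ndarray) -> np.ndarray:
        """Greedy fill of each sex's half-budget onto smallest-gradient entries."""
        v = np.zeros(n_s + n_d)
        for lo, hi, cap in ((0, n_s, cap_s), (n_s, n_s + n_d, cap_d)):
            budget = 0.5
            for j in np.argsort(grad[lo:hi], kind="stable"):
                take = min(cap, budget)
                v[lo + j] = take
                budget -= take
                if budget <= 1e-15:
                    break
        return v

    x = lp_vertex(np.zeros(n_s + n_d))  # feasible start: uniform-ish fill
    x = np.concatenate(
        [np.full(n_s, 0.5 / n_s), np.full(n_d, 0.5 / n_d)]
    )
    x[:n_s] = np.minimum(x[:n_s], cap_s)
    x[:n_s] *= 0.5 / x[:n_s].sum()
    for k in range(n_iter):
        grad = 2.0 * (ctx.K @ x)
        v = lp_vertex(grad)
        gamma = 2.0 / (k + 2.0)
        x = (1 - gamma) * x + gamma * v

    # round sire contributions to integer counts (largest remainder, capped)
    raw = x[:n_s] * 2.0 * N
    counts = np.minimum(np.floor(raw).astype(np.int64), cfg.max_per_sire)
    remainder = raw - np.floor(raw)
    while counts.sum() < N:
        order = np.argsort(-remainder, kind="stable")
        for j in order:
            if counts[j] < cfg.max_per_sire:
                counts[j] += 1
                remainder[j] = -1.0
                break
    while counts.sum() > N:
        j = int(np.argmin(np.where(counts > 0, remainder, np.inf)))
        counts[j] -= 1
    dam_idx = np.sort(np.argsort(-x[n_s:], kind="stable")[:N])
    return _Solution(counts, dam_idx.astype(np.int64))


def _angle(ev: Evaluation, fr: FrontierState) -> float:
    d_index = fr.index_max - fr.index_min
    d_coan = fr.coancestry_max - fr.coancestry_min
    g = (ev.mean_index - fr.index_min) / d_index if d_index > 1e-12 else 1.0
    r = (fr.coancestry_max - ev.coancestry) / d_coan if d_coan > 1e-12 else 0.0
    g, r = max(g, 0.0), max(r, 0.0)
    if g <= 0.0 and r <= 0.0:
        return 0.0
    return float(np.degrees(np.arctan2(r, g)))


def frontier_endpoints(ctx: MateSelContext, cfg: ObjectiveConfig) -> FrontierState:
    """Locate the frontier endpoints used to normalize the gain/coancestry axes.

    The max-index endpoint is the truncation-selection solution; the
    min-coancestry endpoint minimizes the contribution quadratic form x'Kx
    under the usage constraints.
    """
    ev_max = _evaluate_solution(ctx, _truncation_solution(ctx, cfg), cfg)
    ev_min = _evaluate_solution(ctx, _min_coancestry_solution(ctx, cfg), cfg)
    return FrontierState(
        index_max=ev_max.mean_index,
        index_min=ev_min.mean_index,
        coancestry_max=ev_max.coancestry,
        coancestry_min=ev_min.coancestry,
        angle_degrees=0.0,
    )


# ---------------------------------------------------------------------------
# the evolutionary algorithm


def _repair_counts(counts: np.ndarray, cfg: ObjectiveConfig, rng) -> None:
    np.clip(counts, 0, cfg.max_per_sire, out=counts)
    diff = cfg.n_matings - int(counts.sum())
    while diff != 0:
        if diff > 0:
            room = np.nonzero(counts < cfg.max_per_sire)[0]
            counts[room[rng.integers(len(room))]] += 1
            diff -= 1
        else:
            filled = np.nonzero(counts > 0)[0]
            counts[filled[rng.integers(len(filled))]] -= 1
            diff += 1


def _random_solution(ctx: MateSelContext, cfg: ObjectiveConfig, rng) -> _Solution:
    counts = np.zeros(len(ctx.sires), dtype=np.int64)
    _repair_counts(counts, cfg, rng)
    dam_idx = rng.choice(len(ctx.dams), size=cfg.n_matings, replace=False)
    return _Solution(counts, dam_idx.astype(np.int64))


def _mutate(sol: _Solution, ctx: MateSelContext, cfg: ObjectiveConfig, rng) -> None:
    if rng.random() < 0.8:  # move one mating between sires
        donors = np.nonzero(sol.counts > 0)[0]
        takers = np.nonzero(sol.counts < cfg.max_per_sire)[0]
        if len(donors) and len(takers):
            i = donors[rng.integers(len(donors))]
            j = takers[rng.integers(len(takers))]
            if i != j:
                sol.counts[i] -= 1
                sol.counts[j] += 1
    if rng.random() < 0.8 and cfg.n_matings >= 2:  # swap two dams (pairing change)
        i, j = rng.integers(cfg.n_matings, size=2)
        sol.dam_idx[i], sol.dam_idx[j] = sol.dam_idx[j], sol.dam_idx[i]
    if rng.random() < 0.5 and len(ctx.dams) > cfg.n_matings:  # swap in an unused dam
        unused = np.setdiff1d(np.arange(len(ctx.dams)), sol.dam_idx)
        i = rng.integers(cfg.n_matings)
        sol.dam_idx[i] = unused[rng.integers(len(unused))]


def _crossover(p1: _Solution, p2: _Solution, cfg: ObjectiveConfig, rng) -> _Solution:
    mask = rng.random(len(p1.counts)) < 0.5
    counts = np.where(mask, p1.counts, p2.counts).astype(np.int64)
    _repair_counts(counts, cfg, rng)
    dam_idx = (p1 if rng.random() < 0.5 else p2).dam_idx.copy()
    return _Solution(counts, dam_idx)


def _greedy_dam_assignment(ctx: MateSelContext, sol: _Solution) -> None:
    """Reorder the chosen dams so risky sires get low-risk mates (in place)."""
    sv = _sire_vec(sol.counts)
    risk_s = ctx.a_sire[sv].sum(axis=1)
    order = np.argsort(-risk_s, kind="stable")
    available = list(sol.dam_idx)
    new = np.empty_like(sol.dam_idx)
    for pos in order:
        a_s = ctx.a_sire[sv[pos]]
        costs = [1.0 - np.prod(1.0 - a_s * ctx.a_dam[d]) for d in available]
        k = int(np.argmin(costs))
        new[pos] = available.pop(k)
    sol.dam_idx = new


def _two_opt_dams(ctx: MateSelContext, sol: _Solution, cfg: ObjectiveConfig,
                  max_passes: int = 4) -> None:
    """Pairwise dam swaps that lower LethalG (only the pairing term changes)."""
    sv = _sire_vec(sol.counts)
    a_s = ctx.a_sire[sv]
    for _ in range(max_passes):
        a_d = ctx.a_dam[sol.dam_idx]
        mort = 1.0 - np.prod(1.0 - a_s * a_d, axis=1)
        improved = False
        N = cfg.n_matings
        for i in range(N - 1):
            for j in range(i + 1, N):
                new_i = 1.0 - np.prod(1.0 - a_s[i] * a_d[j])
                new_j = 1.0 - np.prod(1.0 - a_s[j] * a_d[i])
                if new_i + new_j < mort[i] + mort[j] - 1e-15:
                    sol.dam_idx[i], sol.dam_idx[j] = sol.dam_idx[j], sol.dam_idx[i]
                    a_d[[i, j]] = a_d[[j, i]]
                    mort[i], mort[j] = new_i, new_j
                    improved = True
        if not improved:
            break


def ea_optimize(
    ctx: MateSelContext,
    cfg: ObjectiveConfig,
    lam: float = 0.0,
    seed_solutions: list[_Solution] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[_Solution, Evaluation]:
    """Evolve a feasible mating list maximizing penalized - lam * coancestry.

    Elitism makes the best objective non-decreasing over generations; the run
    stops at the generation cap or after ``stall_generations`` without an
    improvement above ``stall_tol``.  Deterministic given the config seed.
    """
    if cfg.n_matings > len(ctx.dams):
        raise ValueError("infeasible: more matings than available dams")
    if cfg.n_matings > len(ctx.sires) * cfg.max_per_sire:
        raise ValueError("infeasible: insufficient sire capacity")
    rng = rng or np.random.default_rng(cfg.seed)

    def fitness(sol: _Solution) -> float:
        ev = _evaluate_solution(ctx, sol, cfg)
        return ev.penalized - lam * ev.coancestry

    pop: list[_Solution] = [_truncation_solution(ctx, cfg)]
    if cfg.w_g > 0:
        seeded = pop[0].copy()
        _greedy_dam_assignment(ctx, seeded)
        pop.append(seeded)
    if seed_solutions:
        pop.extend(s.copy() for s in seed_solutions)
    while len(pop) < cfg.pop_size:
        pop.append(_random_solution(ctx, cfg, rng))
    fits = np.array([fitness(s) for s in pop])

    best_fit = float(fits.max())
    stall = 0
    n_elite = max(2, cfg.pop_size // 16)
    for _ in range(cfg.max_generations):
        order = np.argsort(-fits, kind="stable")
        elite = [pop[i].copy() for i in order[:n_elite]]
        newpop = list(elite)
        while len(newpop) < cfg.pop_size:
            a, b = rng.integers(cfg.pop_size, size=2)
            p1 = pop[order[min(a, b)]]  # implicit rank-based tournament
            c, d = rng.integers(cfg.pop_size, size=2)
            p2 = pop[order[min(c, d)]]
            child = _crossover(p1, p2, cfg, rng)
            _mutate(child, ctx, cfg, rng)
            newpop.append(child)
        pop = newpop
        fits = np.array([fitness(s) for s in pop])
        gen_best = float(fits.max())
        if gen_best > best_fit + cfg.stall_tol:
            best_fit = gen_best
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall_generations:
                break

    best = pop[int(np.argmax(fits))].copy()
    if cfg.w_g > 0:  # polish the pairing, which only ever lowers LethalG
        _two_opt_dams(ctx, best, cfg)
    return best, _evaluate_solution(ctx, best, cfg)


def solve_at_degrees(
    ctx: MateSelContext, cfg: ObjectiveConfig
) -> tuple[list[tuple[str, str]], FrontierState, Evaluation]:
    """Find the mating list at the target angle on the normalized frontier.

    An outer bisection adjusts the coancestry penalty multiplier until the
    achieved angle is within ``angle_tol_degrees`` of the target (or the
    multiplier range is exhausted, flagged via ``converged=False``); the
    inner loop is the evolutionary algorithm.  Returns the mating list, the
    frontier state with the achieved angle, and the evaluation.
    """
    fr = frontier_endpoints(ctx, cfg)
    theta = cfg.target_degrees
    rng = np.random.default_rng(cfg.seed)

    if theta >= 90.0 - 1e-9:
        sol = _min_coancestry_solution(ctx, cfg)
        if cfg.w_g > 0:
            _two_opt_dams(ctx, sol, cfg)
        ev = _evaluate_solution(ctx, sol, cfg)
        fr = replace(fr, angle_degrees=_angle(ev, fr))
        return _matings(ctx, sol), fr, ev

    sol, ev = ea_optimize(ctx, cfg, lam=0.0, rng=rng)
    angle = _angle(ev, fr)
    if theta <= 1e-9 or angle >= theta - cfg.angle_tol_degrees:
        fr = replace(fr, angle_degrees=angle)
        return _matings(ctx, sol), fr, ev

    # grow the multiplier until the angle overshoots the target
    scale = max(abs(fr.index_max - fr.index_min), 1e-6)
    span = max(fr.coancestry_max - fr.coancestry_min, 1e-9)
    lam_lo, lam_hi = 0.0, scale / span
    best_lo = (sol, ev, angle)
    best_hi = None
    for _ in range(12):
        sol_h, ev_h = ea_optimize(ctx, cfg, lam=lam_hi, seed_solutions=[sol], rng=rng)
        ang_h = _angle(ev_h, fr)
        if ang_h >= theta:
            best_hi = (sol_h, ev_h, ang_h)
            break
        lam_lo, best_lo = lam_hi, (sol_h, ev_h, ang_h)
        lam_hi *= 4.0
    if best_hi is None:
        fr = replace(fr, angle_degrees=best_lo[2], converged=False)
        return _matings(ctx, best_lo[0]), fr, best_lo[1]

    best = best_hi if abs(best_hi[2] - theta) < abs(best_lo[2] - theta) else best_lo
    for _ in range(cfg.max_outer_iterations):
        if abs(best[2] - theta) <= cfg.angle_tol_degrees:
            break
        lam_mid = 0.5 * (lam_lo + lam_hi)
        sol_m, ev_m = ea_optimize(
            ctx, cfg, lam=lam_mid, seed_solutions=[best_lo[0], best_hi[0]], rng=rng
        )
        ang_m = _angle(ev_m, fr)
        if abs(ang_m - theta) < abs(best[2] - theta):
            best = (sol_m, ev_m, ang_m)
        if ang_m >= theta:
            lam_hi, best_hi = lam_mid, (sol_m, ev_m, ang_m)
        else:
            lam_lo, best_lo = lam_mid, (sol_m, ev_m, ang_m)

    converged = abs(best[2] - theta) <= cfg.angle_tol_degrees
    fr = replace(fr, angle_degrees=best[2], converged=converged)
    return _matings(ctx, best[0]), fr, best[1]
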