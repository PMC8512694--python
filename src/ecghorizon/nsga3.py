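"""NSGA-III many-objective evolutionary optimizer.

Reference-point based selection for problems with several (here four)
objectives: Das–Dennis simplex-lattice reference directions, fast
nondominated sorting, adaptive normalization by ideal point and extreme-
point intercepts, association of members to reference directions by
perpendicular distance, and niche-preserving truncation of the split
front.  Variation is real-coded: simulated binary crossover (SBX) and
polynomial mutation.  All internal math is minimization; maximization
problems negate their objectives at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable, Optional

import numpy as np


@dataclass
class ReferenceDirectionSet:
    """Das–Dennis points: all M-dim nonnegative lattice weights with denominator p."""

    M: int
    p: int
    points: np.ndarray

    def __len__(self) -> int:
        return self.points.shape[0]


def das_dennis(M: int, p: int) -> ReferenceDirectionSet:
    """All simplex-lattice points i/p with i summing to p; C(p+M-1, M-1) of them."""
    if M < 2 or p < 1:
        raise ValueError("need M >= 2 and p >= 1")

    def rec(prefix: list[int], remaining: int, slots: int):
        if slots == 1:
            yield prefix + [remaining]
            return
        for i in range(remaining + 1):
            yield from rec(prefix + [i], remaining - i, slots - 1)

    pts = np.array(list(rec([], p, M)), dtype=float) / p
    assert pts.shape[0] == comb(p + M - 1, M - 1)
    return ReferenceDirectionSet(M=M, p=p, points=pts)


# ---------------------------------------------------------------------------
# Nondominated sorting (minimization)
# ---------------------------------------------------------------------------


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def nondominated_mask(objs: np.ndarray) -> np.ndarray:
    """Boolean mask of points (minimization) not dominated by any other."""
    F = np.asarray(objs, dtype=float)
    n = F.shape[0]
    mask = np.ones(n, dtype=bool)
    chunk = 512
    for s in range(0, n, chunk):
        block = F[s : s + chunk]  # (b, M)
        le = np.all(F[:, None, :] <= block[None, :, :], axis=2)  # i dominates-eq j
        lt = np.any(F[:, None, :] < block[None, :, :], axis=2)
        dominated = np.any(le & lt, axis=0)
        mask[s : s + chunk] &= ~dominated
    return mask


def nondominated_sort(objs: np.ndarray) -> list[list[int]]:
    """Fast nondominated sort (minimization); fronts partition the indices."""
    F = np.asarray(objs, dtype=float)
    n = F.shape[0]
    if n == 0:
        raise ValueError("empty objective set")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        # vectorized pairwise dominance of i over all j
        le = np.all(F[i] <= F, axis=1)
        lt = np.any(F[i] < F, axis=1)
        dom = le & lt
        dominated_by[i] = np.nonzero(dom)[0].tolist()
        dom_count += dom
    fronts: list[list[int]] = []
    current = [i for i in range(n) if dom_count[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


# ---------------------------------------------------------------------------
# Normalization, association, niching
# ---------------------------------------------------------------------------


def _perpendicular_distance(point: np.ndarray, direction: np.ndarray) -> float:
    d = direction / np.linalg.norm(direction)
    proj = float(point @ d)
    return float(np.linalg.norm(point - proj * d))


def normalize_and_associate(
    objs: np.ndarray,
    front_indices: list[list[int]],
    refs: ReferenceDirectionSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Translate by the ideal point, scale by intercepts, associate to rays.

    Returns (association ref index per member, perpendicular distance per
    member, normalized objectives).  The intercepts come from the extreme
    points found by the achievement scalarizing function; when the
    resulting hyperplane system is singular or gives nonpositive
    intercepts, the per-objective maxima over the considered members are
    used instead.
    """
    F = np.asarray(objs, dtype=float)
    members = [i for front in front_indices for i in front]
    sub = F[members]
    M = F.shape[1]
    ideal = sub.min(axis=0)
    T = sub - ideal

    # extreme points via ASF with axis-weight epsilon
    weights = np.full((M, M), 1e-6) + np.eye(M)
    asf = (T[None, :, :] / weights[:, None, :]).max(axis=2)  # (M, n)
    extremes = T[asf.argmin(axis=1)]  # (M, M)

    intercepts = None
    try:
        b = np.linalg.solve(extremes, np.ones(M))
        cand = 1.0 / b
        if np.all(np.isfinite(cand)) and np.all(cand > 1e-12):
            intercepts = cand
    except np.linalg.LinAlgError:
        pass
    if intercepts is None:
        intercepts = T.max(axis=0)
    intercepts = np.where(intercepts > 1e-12, intercepts, 1.0)

    normalized = T / intercepts
    assoc = np.empty(len(members), dtype=int)
    dist = np.empty(len(members))
    dirs = refs.points / np.linalg.norm(refs.points, axis=1, keepdims=True)
    # distance of each member to each ray: ||z - (z·d)d||
    proj = normalized @ dirs.T  # (n, R)
    sq = (normalized ** 2).sum(axis=1, keepdims=True) - proj ** 2
    sq = np.maximum(sq, 0.0)
    d_all = np.sqrt(sq)
    assoc = d_all.argmin(axis=1)
    dist = d_all[np.arange(len(members)), assoc]

    # map back to full population order
    assoc_full = np.full(F.shape[0], -1, dtype=int)
    dist_full = np.full(F.shape[0], np.inf)
    norm_full = np.zeros_like(F)
    for k, i in enumerate(members):
        assoc_full[i] = assoc[k]
        dist_full[i] = dist[k]
        norm_full[i] = normalized[k]
    return assoc_full, dist_full, norm_full


def niching_select(
    last_front: list[int],
    niche_counts: np.ndarray,
    assoc: np.ndarray,
    dist: np.ndarray,
    needed: int,
    rng: np.random.Generator,
) -> list[int]:
    """Fill ``needed`` slots from the split front, preserving niche diversity.

    Repeatedly pick a reference direction with the minimal current niche
    count (random among ties); if it has no member yet, take its closest
    associated candidate, otherwise a random associated candidate; a
    direction with no remaining candidates is excluded for this
    generation.
    """
    if needed > len(last_front):
        raise ValueError("cannot select more members than the front holds")
    counts = niche_counts.copy()
    pool = set(last_front)
    selected: list[int] = []
    excluded: set[int] = set()
    by_ref: dict[int, list[int]] = {}
    for i in last_front:
        by_ref.setdefault(int(assoc[i]), []).append(i)
    while len(selected) < needed:
        candidates_refs = [r for r in range(counts.size)
                           if r not in excluded and by_ref.get(r)]
        if not candidates_refs:
            remaining = sorted(pool, key=lambda i: dist[i])
            selected.extend(remaining[: needed - len(selected)])
            break
        min_count = min(counts[r] for r in candidates_refs)
        tied = [r for r in candidates_refs if counts[r] == min_count]
        r = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else tied[0]
        members = [i for i in by_ref[r] if i in pool]
        if not members:
            excluded.add(r)
            continue
        if counts[r] == 0:
            pick = min(members, key=lambda i: dist[i])
        else:
            pick = members[int(rng.integers(len(members)))]
        selected.append(pick)
        pool.discard(pick)
        by_ref[r].remove(pick)
        counts[r] += 1
    return selected


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------


def sbx_crossover(p1: np.ndarray, p2: np.ndarray, eta: float,
                  rng: np.random.Generator, prob: float = 0.9
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0, 1]-bounded genomes."""
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for i in range(p1.size):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        lo, hi = min(p1[i], p2[i]), max(p1[i], p2[i])
        u = rng.random()
        beta = 1.0 + 2.0 * lo / (hi - lo) if hi > lo else 1.0
        alpha = 2.0 - beta ** -(eta + 1.0)
        if u <= 1.0 / alpha:
            bq = (u * alpha) ** (1.0 / (eta + 1.0))
        else:
            bq = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
        c1[i] = 0.5 * ((lo + hi) - bq * (hi - lo))
        c2[i] = 0.5 * ((lo + hi) + bq * (hi - lo))
        if rng.random() < 0.5:
            c1[i], c2[i] = c2[i], c1[i]
    return np.clip(c1, 0.0, 1.0), np.clip(c2, 0.0, 1.0)


def polynomial_mutation(x: np.ndarray, eta: float, rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Bounded polynomial perturbation on [0, 1] genes."""
    y = x.copy()
    for i in range(x.size):
        if rng.random() >= rate:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u + (1 - 2 * u) * (1 - y[i]) ** (eta + 1)) ** (
                1.0 / (eta + 1)) - 1.0
        else:
            delta = 1.0 - (2 * (1 - u) + (2 * u - 1) * y[i] ** (eta + 1)) ** (
                1.0 / (eta + 1))
        y[i] = np.clip(y[i] + delta, 0.0, 1.0)
    return y


# ---------------------------------------------------------------------------
# Generational loop
# ---------------------------------------------------------------------------


@dataclass
class Nsga3Config:
    pop_size: int = 92
    generations: int = 100
    divisions_p: int = 6
    sbx_eta: float = 30.0
    mutation_eta: float = 20.0
    mutation_rate: Optional[float] = None  # default 1/genome_length
    seed: int = 0


@dataclass
class Population:
    genomes: np.ndarray       # (pop, genome_len)
    objectives: np.ndarray    # (pop, M) in the caller's (maximization) scale
    generation: int
    seed: int


@dataclass
class EvolveResult:
    population: Population
    archive_genomes: np.ndarray
    archive_objectives: np.ndarray  # maximization scale
    log: list[dict] = field(default_factory=list)


def evolve(
    evaluate: Callable[[np.ndarray], np.ndarray],
    genome_length: int,
    n_objectives: int,
    config: Nsga3Config,
    initial_genomes: Optional[np.ndarray] = None,
) -> EvolveResult:
    """Run the generational NSGA-III loop (objectives are MAXIMIZED).

    ``evaluate`` maps a genome in [0,1]^genome_length to an n_objectives
    vector to maximize; it must be a pure function of the genome.  The
    archive collects all nondominated solutions ever evaluated.  Fully
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    if n_objectives == 1:  # degenerate single-objective run: one trivial ray
        refs = ReferenceDirectionSet(M=1, p=1, points=np.array([[1.0]]))
    else:
        refs = das_dennis(n_objectives, config.divisions_p)
    pop_size = config.pop_size
    if pop_size < len(refs):
        import warnings

        warnings.warn(
            f"pop_size {pop_size} below the {len(refs)} reference points",
            stacklevel=2,
        )
    mut_rate = config.mutation_rate or 1.0 / genome_length

    genomes = rng.random((pop_size, genome_length))
    if initial_genomes is not None:
        seeded = np.atleast_2d(np.asarray(initial_genomes, dtype=float))
        genomes[: seeded.shape[0]] = np.clip(seeded, 0.0, 1.0)
    objs_max = np.array([evaluate(g) for g in genomes])

    arch_g = genomes.copy()
    arch_f = objs_max.copy()
    log: list[dict] = []

    def prune_archive(g: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # keep unique nondominated points (minimization on -f)
        _, uniq = np.unique(np.round(f, 12), axis=0, return_index=True)
        g, f = g[np.sort(uniq)], f[np.sort(uniq)]
        keep = nondominated_mask(-f)
        return g[keep], f[keep]

    arch_g, arch_f = prune_archive(arch_g, arch_f)

    for gen in range(config.generations):
        # offspring: random parent pairing, SBX + polynomial mutation
        perm = rng.permutation(pop_size)
        children = []
        for k in range(0, pop_size - 1, 2):
            c1, c2 = sbx_crossover(genomes[perm[k]], genomes[perm[k + 1]],
                                   config.sbx_eta, rng)
            children.append(polynomial_mutation(c1, config.mutation_eta, mut_rate, rng))
            children.append(polynomial_mutation(c2, config.mutation_eta, mut_rate, rng))
        if pop_size % 2 == 1:
            c1, _ = sbx_crossover(genomes[perm[-1]], genomes[perm[0]],
                                  config.sbx_eta, rng)
            children.append(polynomial_mutation(c1, config.mutation_eta, mut_rate, rng))
        child_g = np.array(children)[:pop_size]
        child_f = np.array([evaluate(g) for g in child_g])

        merged_g = np.vstack([genomes, child_g])
        merged_f = np.vstack([objs_max, child_f])
        F_min = -merged_f  # minimize internally

        fronts = nondominated_sort(F_min)
        chosen: list[int] = []
        fi = 0
        while fi < len(fronts) and len(chosen) + len(fronts[fi]) <= pop_size:
            chosen.extend(fronts[fi])
            fi += 1
        if len(chosen) < pop_size:
            split = fronts[fi]
            consider = fronts[: fi + 1]
            assoc, dist, _ = normalize_and_associate(F_min, consider, refs)
            counts = np.zeros(len(refs), dtype=int)
            for i in chosen:
                counts[assoc[i]] += 1
            chosen.extend(
                niching_select(split, counts, assoc, dist,
                               pop_size - len(chosen), rng)
            )
        genomes = merged_g[chosen]
        objs_max = merged_f[chosen]

        arch_g, arch_f = prune_archive(
            np.vstack([arch_g, child_g]), np.vstack([arch_f, child_f])
        )
        log.append({
            "generation": gen,
            "front_sizes": [len(f) for f in fronts],
            "best_objectives": arch_f.max(axis=0).tolist(),
            "archive_size": int(arch_f.shape[0]),
        })

    pop = Population(genomes=genomes, objectives=objs_max,
                     generation=config.generations, seed=config.seed)
    return EvolveResult(population=pop, archive_genomes=arch_g,
                        archive_objectives=arch_f, log=log)
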