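"""Node-histogram-based sampling GA for forced-choice pair assembly.

An estimation-of-distribution genetic algorithm for permutation-coded
combinatorial problems, adapted to item pairing: a candidate questionnaire is
an involutive permutation delta of the pool indices (delta[i] = u means items
i and u form a block; delta[i] = i means item i is left out).  Offspring are
built by copying a random template segment from a parent and filling the rest
by sequential multinomial draws whose probabilities are proportional to the
pairing frequencies of the current population (the node histogram) plus a
mutation constant.  Hard block-content constraints live in a binary matrix C;
questionnaire-level quotas (blocks per dimension pair, block polarity mix)
are enforced inside the sampling operator.  Selection is elitist over the
union of parents and offspring; the run stops when the population has
collapsed to a single genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ItemPool, Item, Block, Questionnaire, ReliabilityObjective

__all__ = [
    "GAConfig",
    "GAResult",
    "InfeasibleConfigError",
    "build_constraints",
    "mutation_epsilon",
    "sampling_distribution",
    "node_histogram",
    "sample_candidate",
    "select_next_generation",
    "has_converged",
    "decode_phenotype",
    "run_ga",
]


class InfeasibleConfigError(ValueError):
    """The requested questionnaire cannot be assembled from this pool."""


def build_constraints(pool: ItemPool, forbid_same_dim: bool = True,
                      extra: np.ndarray | None = None) -> np.ndarray:
    """Binary N x N pairing-feasibility matrix C.

    ``c[i, u] = 1`` iff items i and u may share a block.  The default rule
    forbids same-trait pairs (hetero-dimensional blocks only); ``extra`` is an
    optional boolean matrix of additional user rules applied conjunctively
    (e.g. matched social desirability).
    """
    N = pool.N
    C = np.ones((N, N), dtype=bool)
    np.fill_diagonal(C, False)
    if forbid_same_dim:
        C &= pool.dims[:, None] != pool.dims[None, :]
    if extra is not None:
        extra = np.asarray(extra, dtype=bool)
        if extra.shape != (N, N):
            raise ValueError("extra constraint matrix must be N x N")
        C &= extra & extra.T
    return C


def mutation_epsilon(K: int, row_constraint_count: int, B_ratio: float) -> float:
    """Mutation constant for one item row: (K / sum_u c_iu) * B_ratio.

    Proportional to the average pairing frequency an item could show in a
    population of size K given its number of feasible partners.
    """
    if row_constraint_count <= 0:
        raise InfeasibleConfigError("item has no feasible partner")
    return K / row_constraint_count * B_ratio


def node_histogram(population: np.ndarray) -> np.ndarray:
    """Pairing-frequency matrix of a population of decision vectors.

    ``Dt[i, u]`` counts the population members in which delta[i] = u; rows sum
    to the population size and the matrix is symmetric because every member is
    an involution.
    """
    population = np.asarray(population)
    K, N = population.shape
    Dt = np.zeros((N, N), dtype=np.int64)
    rows = np.broadcast_to(np.arange(N), (K, N))
    np.add.at(Dt, (rows.ravel(), population.ravel()), 1)
    return Dt


def sampling_distribution(i: int, Cstar: np.ndarray, Dt: np.ndarray | None,
                          eps: float) -> np.ndarray:
    """Multinomial distribution over partners u for position i.

    Zero where the (current) constraint row is zero, otherwise proportional to
    the node-histogram count plus the mutation constant; a None histogram
    yields the uniform distribution over feasible partners.
    """
    row = np.asarray(Cstar[i], dtype=float)
    if Dt is None:
        w = row.copy()
    else:
        w = row * (np.asarray(Dt[i], dtype=float) + eps)
    tot = w.sum()
    if tot <= 0:
        raise InfeasibleConfigError(f"no feasible partner mass for item index {i}")
    return w / tot


@dataclass
class GAConfig:
    """Assembly settings.

    ``K`` defaults to the pool size and ``B_ratio`` to 2**-4.  ``h_max`` is
    the maximum number of blocks per (unordered) dimension pair; the string
    "equal" derives it as J / (D choose 2), the equal-pairs questionnaire
    constraint.  ``polarity_quota`` optionally fixes the numbers of
    (homo-polar, hetero-polar) blocks.
    """

    J: int
    K: int | None = None
    B_ratio: float = 2.0 ** -4
    h_max: int | str | None = "equal"
    polarity_quota: tuple[int, int] | None = None
    max_generations: int = 10_000
    restarts: int = 25

    def resolve_h_max(self, D: int) -> int | None:
        if self.h_max is None:
            return None
        if self.h_max == "equal":
            n_pairs = D * (D - 1) // 2
            if self.J % n_pairs != 0:
                raise InfeasibleConfigError(
                    f"J={self.J} blocks cannot be split equally over "
                    f"{n_pairs} dimension pairs")
            return self.J // n_pairs
        return int(self.h_max)


@dataclass
class _SamplerSpec:
    """Pre-resolved constants shared by every candidate build."""

    C: np.ndarray            # (N, N) bool, the immutable constraint matrix
    dims0: np.ndarray        # 0-based trait index per item
    keyed: np.ndarray        # +1 / -1 per item
    D: int
    J: int
    h_max: int | None
    polarity_quota: tuple[int, int] | None
    eps: np.ndarray          # per-item mutation constant
    restarts: int

    @classmethod
    def from_config(cls, pool: ItemPool, C: np.ndarray, cfg: GAConfig,
                    K: int) -> "_SamplerSpec":
        row_counts = C.sum(axis=1)
        if (row_counts == 0).any():
            bad = pool.ids[row_counts == 0].tolist()
            raise InfeasibleConfigError(f"items with no feasible partner: {bad}")
        if 2 * cfg.J > pool.N:
            raise InfeasibleConfigError(
                f"{cfg.J} blocks need {2 * cfg.J} items, pool has {pool.N}")
        eps = K / row_counts * cfg.B_ratio
        return cls(C=C, dims0=pool.dims - 1, keyed=pool.keyed, D=pool.D,
                   J=cfg.J, h_max=cfg.resolve_h_max(pool.D),
                   polarity_quota=cfg.polarity_quota, eps=eps,
                   restarts=cfg.restarts)


def _try_build(parent: np.ndarray | None, Dt: np.ndarray | None,
               spec: _SamplerSpec, rng: np.random.Generator) -> np.ndarray | None:
    """One attempt of the sampling operator; None on a quota dead-end."""
    N = spec.C.shape[0]
    delta = np.arange(N)
    avail = np.ones(N, dtype=bool)
    H = np.zeros((spec.D, spec.D), dtype=np.int64)
    pair_open = np.ones((spec.D, spec.D), dtype=bool)
    np.fill_diagonal(pair_open, False)
    pol_count = [0, 0]  # homo, hetero
    n_avail = [int((spec.keyed == 1).sum()), int((spec.keyed == -1).sum())]
    n_blocks = 0

    def polarity_completable(kind: int, sign_i: int, sign_u: int) -> bool:
        """Necessary counting condition that the polarity quota can still be
        met after forming a block of the given kind (0 homo, 1 hetero)."""
        pos = n_avail[0] - (sign_i > 0) - (sign_u > 0)
        neg = n_avail[1] - (sign_i < 0) - (sign_u < 0)
        homo_left = spec.polarity_quota[0] - pol_count[0] - (kind == 0)
        het_left = spec.polarity_quota[1] - pol_count[1] - (kind == 1)
        if homo_left < 0 or het_left < 0:
            return False
        if het_left > min(pos, neg):
            return False
        return homo_left <= (pos - het_left) // 2 + (neg - het_left) // 2

    def fix_pair(i: int, u: int) -> bool:
        """Record block (i, u); False if a quota is exceeded."""
        nonlocal n_blocks
        r, s = spec.dims0[i], spec.dims0[u]
        H[r, s] += 1
        if r != s:
            H[s, r] += 1
        if spec.h_max is not None and H[r, s] > spec.h_max:
            return False
        if spec.h_max is not None and H[r, s] == spec.h_max:
            pair_open[r, s] = pair_open[s, r] = False
        if spec.polarity_quota is not None:
            kind = 0 if spec.keyed[i] * spec.keyed[u] > 0 else 1
            pol_count[kind] += 1
            if pol_count[kind] > spec.polarity_quota[kind]:
                return False
        delta[i], delta[u] = u, i
        avail[i] = avail[u] = False
        n_avail[0] -= int(spec.keyed[i] > 0) + int(spec.keyed[u] > 0)
        n_avail[1] -= int(spec.keyed[i] < 0) + int(spec.keyed[u] < 0)
        n_blocks += 1
        return True

    if parent is not None:
        m1, m2 = np.sort(rng.choice(N, size=2, replace=False))
        for i in range(m1, m2 + 1):
            u = parent[i]
            if u == i:
                if avail[i]:  # template fixed point: item stays out
                    avail[i] = False
                    n_avail[0 if spec.keyed[i] > 0 else 1] -= 1
            elif avail[i] and avail[u]:
                if not fix_pair(i, u):
                    return None

    for i in range(N):
        if not avail[i]:
            continue
        mask = spec.C[i] & avail
        mask &= pair_open[spec.dims0[i], spec.dims0]
        if spec.polarity_quota is not None:
            sign_i = int(spec.keyed[i])
            same = spec.keyed * sign_i > 0
            # drop partners whose block kind could no longer complete the
            # homo/hetero quota given the remaining keyed-item counts
            if not polarity_completable(0, sign_i, sign_i):
                mask &= ~same
            if not polarity_completable(1, sign_i, -sign_i):
                mask &= same
        if not mask.any():
            avail[i] = False  # self-paired: left out of the questionnaire
            n_avail[0 if spec.keyed[i] > 0 else 1] -= 1
            continue
        if Dt is None:
            w = mask.astype(float)
        else:
            w = mask * (Dt[i] + spec.eps[i])
        cw = np.cumsum(w)
        u = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
        if not fix_pair(i, u):
            return None
        if n_blocks == spec.J:
            break

    return delta if n_blocks == spec.J else None


def _sample_vector(parent: np.ndarray | None, Dt: np.ndarray | None,
                   spec: _SamplerSpec, rng: np.random.Generator,
                   ) -> np.ndarray | None:
    """Sampling operator with bounded restarts on quota dead-ends."""
    for _ in range(spec.restarts):
        delta = _try_build(parent, Dt, spec, rng)
        if delta is not None:
            return delta
    return None


def sample_candidate(parent: np.ndarray, C: np.ndarray, Dt: np.ndarray,
                     pool: ItemPool, cfg: GAConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample one offspring decision vector from a parent template.

    Copies the parent's entries between two uniformly drawn cut points (with
    their mirror positions, preserving the involution), fills the remaining
    positions by sequential multinomial draws from the node-histogram model,
    and enforces the dimension-pair and polarity quotas while drawing.  On a
    dead-end the build restarts (fresh cut points); after the restart cap the
    parent is returned unchanged.
    """
    K = cfg.K if cfg.K is not None else pool.N
    spec = _SamplerSpec.from_config(pool, C, cfg, K)
    out = _sample_vector(np.asarray(parent), Dt, spec, rng)
    return np.asarray(parent).copy() if out is None else out


def select_next_generation(pop_t: np.ndarray, pop_t_star: np.ndarray,
                           objective_values: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Elitist selection over the union of parents and offspring.

    ``objective_values`` holds the objectives of the concatenated union
    (parents first).  Returns the K best vectors and their objectives; ties
    break in stable union order (parents before offspring, then index), so a
    fixed seed reproduces the run exactly.
    """
    union = np.concatenate([pop_t, pop_t_star], axis=0)
    objective_values = np.asarray(objective_values, dtype=float)
    if union.shape[0] != objective_values.size:
        raise ValueError("one objective value per union member required")
    K = pop_t.shape[0]
    order = np.argsort(-objective_values, kind="stable")[:K]
    return union[order], objective_values[order]


def has_converged(population: np.ndarray) -> bool:
    """True iff every decision vector in the population is identical."""
    population = np.asarray(population)
    return bool((population == population[0]).all())


def decode_phenotype(delta: np.ndarray, pool: ItemPool) -> Questionnaire:
    """Questionnaire encoded by an involutive decision vector.

    One block per pair {i, delta[i]} with the lower pool index first (the
    within-block order only flips the response-coding sign convention and
    leaves information and reliability invariant); self-paired items are
    dropped.
    """
    delta = np.asarray(delta)
    if not (delta[delta] == np.arange(delta.size)).all():
        raise ValueError("decision vector is not an involution")
    blocks = []
    for i in range(delta.size):
        u = int(delta[i])
        if i < u:
            blocks.append(Block.from_items(pool.items[i], pool.items[u], pool.D))
    return Questionnaire(blocks=blocks)


def _pairs_array(population: np.ndarray, J: int) -> np.ndarray:
    """(K, J, 2) index pairs (i < delta[i]) of each population member."""
    K, N = population.shape
    out = np.empty((K, J, 2), dtype=np.int64)
    idx = np.arange(N)
    for k in range(K):
        i = idx[population[k] > idx]
        out[k, :, 0] = i
        out[k, :, 1] = population[k][i]
    return out


@dataclass
class GAResult:
    """Outcome of one GA run."""

    best_delta: np.ndarray
    best_objective: float
    questionnaire: Questionnaire
    trace: np.ndarray            # per-generation best objective (monotone)
    n_generations: int
    n_evaluations: int           # objective evaluations incl. the initial pop
    n_parent_fallbacks: int
    converged: bool


def run_ga(pool: ItemPool, Phi: np.ndarray, cfg: GAConfig,
           rng: np.random.Generator,
           C: np.ndarray | None = None,
           objective: ReliabilityObjective | None = None) -> GAResult:
    """Assemble a questionnaire maximizing average posterior marginal
    reliability with the node-histogram sampling GA.

    The initial population is drawn uniformly over feasible pairings; each
    generation samples K offspring from the node-histogram model (one per
    parent template), scores their decoded questionnaires, and keeps the K
    best of the union.  The loop stops when all genotypes are identical or at
    the ``max_generations`` safety cap.
    """
    if C is None:
        C = build_constraints(pool)
    if objective is None:
        objective = ReliabilityObjective(pool, Phi)
    K = cfg.K if cfg.K is not None else pool.N
    if K < 2:
        raise InfeasibleConfigError("population size must be at least 2")
    spec = _SamplerSpec.from_config(pool, C, cfg, K)

    pop = np.empty((K, pool.N), dtype=np.int64)
    for k in range(K):
        delta = _sample_vector(None, None, spec, rng)
        tries = 0
        while delta is None:
            tries += 1
            if tries > 40:
                raise InfeasibleConfigError(
                    "could not draw a feasible initial population; "
                    "check quotas against the pool composition")
            delta = _sample_vector(None, None, spec, rng)
        pop[k] = delta
    obj = objective.evaluate_pairs(_pairs_array(pop, cfg.J))
    n_eval = K
    order = np.argsort(-obj, kind="stable")
    pop, obj = pop[order], obj[order]

    trace = [float(obj.max())]
    fallbacks = 0
    gen = 0
    converged = has_converged(pop)
    while not converged and gen < cfg.max_generations:
        gen += 1
        Dt = node_histogram(pop)
        offspring = np.empty_like(pop)
        for k in range(K):
            child = _sample_vector(pop[k], Dt, spec, rng)
            if child is None:
                child = pop[k].copy()
                fallbacks += 1
            offspring[k] = child
        off_obj = objective.evaluate_pairs(_pairs_array(offspring, cfg.J))
        n_eval += K
        pop, obj = select_next_generation(pop, offspring,
                                          np.concatenate([obj, off_obj]))
        trace.append(float(obj[0]))
        converged = has_converged(pop)

    best = pop[0]
    return GAResult(
        best_delta=best,
        best_objective=float(obj[0]),
        questionnaire=decode_phenotype(best, pool),
        trace=np.array(trace),
        n_generations=gen,
        n_evaluations=n_eval,
        n_parent_fallbacks=fallbacks,
        converged=converged,
    )
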