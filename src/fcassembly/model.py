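"""MUPP-2PL measurement model for pairwise forced-choice blocks.

The multi-unidimensional pairwise preference model with dominance (2PL)
statements reduces, for a pair of statements, to a multidimensional
compensatory logistic model: the probability of endorsing the *first*
statement of block ``j`` is

    P(y_j = 1 | theta) = expit(s_j' theta + c_j),

where ``s_j`` has the first item's discrimination ``+a_1`` at that item's
trait and the second item's ``-a_2`` at its trait, and the block threshold is
``c_j = c_1 - c_2`` with per-item intercepts ``c = -a b``.  From this follow
the block Fisher information matrix ``I_j = s_j s_j' P_j Q_j``, the test
information as its sum over blocks, and the posterior marginal reliability
objective used for questionnaire assembly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import multivariate_normal

__all__ = [
    "Item",
    "ItemPool",
    "Block",
    "Questionnaire",
    "QuadratureGrid",
    "item_endorse_prob",
    "block_prob",
    "block_info",
    "test_info",
    "build_quadrature",
    "objective_reliability",
    "ReliabilityObjective",
    "count_assemblies",
    "ipsativity_bound",
]


@dataclass(frozen=True)
class Item:
    """A single dominance statement with 2PL parameters.

    ``dim`` is the 1-based trait index; the intercept is tied to the
    slope/difficulty parameterization by ``c = -a * b``.
    """

    id: int
    dim: int
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError(f"item {self.id}: non-finite parameters")
        if self.dim < 1:
            raise ValueError(f"item {self.id}: dim must be >= 1, got {self.dim}")

    @property
    def c(self) -> float:
        """Intercept in slope-intercept form, c = -a*b."""
        return -self.a * self.b

    @property
    def keyed(self) -> int:
        """Keyed direction: +1 for positively, -1 for negatively keyed."""
        return 1 if self.a >= 0 else -1


class ItemPool:
    """A pool of single statements measuring ``D`` traits.

    Parameters are mirrored into flat numpy arrays (``a``, ``b``, ``c``,
    ``dims``, ``keyed``) for vectorized use by the assembler.
    """

    def __init__(self, items: list[Item], D: int | None = None):
        if not items:
            raise ValueError("empty item pool")
        ids = [it.id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        self.items = list(items)
        self.D = int(D) if D is not None else max(it.dim for it in items)
        for it in items:
            if it.dim > self.D:
                raise ValueError(f"item {it.id}: dim {it.dim} out of range 1..{self.D}")
        if set(it.dim for it in items) != set(range(1, self.D + 1)):
            missing = sorted(set(range(1, self.D + 1)) - {it.dim for it in items})
            raise ValueError(f"traits with no items: {missing}")
        self.ids = np.array(ids, dtype=np.int64)
        self.dims = np.array([it.dim for it in items], dtype=np.int64)
        self.a = np.array([it.a for it in items], dtype=float)
        self.b = np.array([it.b for it in items], dtype=float)
        self.c = -self.a * self.b
        self.keyed = np.where(self.a >= 0, 1, -1).astype(np.int64)

    @property
    def N(self) -> int:
        return len(self.items)

    def index_of(self, item_id: int) -> int:
        """Position of an item id in the pool arrays."""
        hits = np.flatnonzero(self.ids == item_id)
        if hits.size == 0:
            raise KeyError(f"unknown item id {item_id}")
        return int(hits[0])

    def __len__(self) -> int:
        return self.N

    def __repr__(self) -> str:
        return f"ItemPool(N={self.N}, D={self.D})"


@dataclass(frozen=True)
class Block:
    """An ordered forced-choice pair with its scale vector and threshold.

    The D-length scale vector carries ``+a`` of the first item at the first
    item's trait and ``-a`` of the second at its trait (sign convention for
    responses coded 1 = first statement endorsed).
    """

    first: int
    second: int
    s: np.ndarray
    c_j: float

    @classmethod
    def from_items(cls, first: Item, second: Item, D: int) -> "Block":
        if first.id == second.id:
            raise ValueError("a block needs two distinct items")
        s = np.zeros(D)
        s[first.dim - 1] += first.a
        s[second.dim - 1] -= second.a
        return cls(first=first.id, second=second.id, s=s, c_j=first.c - second.c)


@dataclass
class Questionnaire:
    """A set of forced-choice blocks; no item may appear twice."""

    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            for i in (b.first, b.second):
                if i in seen:
                    raise ValueError(f"item {i} appears in more than one block")
                seen.add(i)

    @property
    def J(self) -> int:
        return len(self.blocks)

    def scale_matrix(self, D: int) -> tuple[np.ndarray, np.ndarray]:
        """(J, D) matrix of block scale vectors and the J thresholds."""
        if not self.blocks:
            return np.zeros((0, D)), np.zeros(0)
        S = np.vstack([b.s for b in self.blocks])
        c = np.array([b.c_j for b in self.blocks])
        return S, c


def item_endorse_prob(item: Item, theta_d: float) -> float:
    """Probability of agreement with a single statement (2PL logistic)."""
    if not np.isfinite(theta_d):
        raise ValueError("non-finite trait value")
    return float(expit(item.a * theta_d + item.c))


def block_prob(block: Block, theta: np.ndarray) -> float:
    """Probability of endorsing the first statement of the block."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != block.s.shape:
        raise ValueError(f"theta has length {theta.size}, expected {block.s.size}")
    return float(expit(block.s @ theta + block.c_j))


def block_info(block: Block, theta: np.ndarray) -> np.ndarray:
    """Fisher information matrix of one block: s s' P Q (rank <= 1, PSD)."""
    p = block_prob(block, theta)
    return np.outer(block.s, block.s) * (p * (1.0 - p))


def test_info(q: Questionnaire, theta: np.ndarray, D: int | None = None) -> np.ndarray:
    """Test information matrix: sum of block information (assumes conditional
    independence between blocks, hence no shared items)."""
    theta = np.asarray(theta, dtype=float)
    if D is None:
        D = theta.size
    info = np.zeros((D, D))
    for b in q.blocks:
        info += block_info(b, theta)
    return info


@dataclass(frozen=True)
class QuadratureGrid:
    """Full factorial grid over trait space with normalized MVN weights."""

    points: np.ndarray  # (L, D)
    weights: np.ndarray  # (L,)

    @property
    def L(self) -> int:
        return self.points.shape[0]


def build_quadrature(D: int, points: list[float] | np.ndarray,
                     Phi: np.ndarray) -> QuadratureGrid:
    """Full factorial quadrature grid of ``len(points)**D`` trait vectors.

    Each grid point is weighted by the MVN(0, Phi) density, normalized so the
    weights sum to one; with per-dimension points {-2, 0, +2} and D = 5 this
    is the 243-point grid of the reliability objective.
    """
    pts = np.asarray(points, dtype=float)
    grid = np.array(list(itertools.product(pts, repeat=D)), dtype=float)
    Phi = np.asarray(Phi, dtype=float)
    dens = multivariate_normal(mean=np.zeros(D), cov=Phi).pdf(grid)
    dens = np.atleast_1d(dens)
    w = dens / dens.sum()
    return QuadratureGrid(points=grid, weights=w)


class ReliabilityObjective:
    """Average posterior marginal reliability of a questionnaire.

    At every grid point the posterior information matrix
    ``M_l = I(theta_l) + Phi^{-1}`` is inverted; its d-th diagonal element is
    the conditional posterior variance of trait d.  Averaging over the grid
    with the normalized MVN weights gives the marginal posterior error
    variance, and ``rho2_d = 1 - var_d``.  The assembly objective is the mean
    of ``rho2_d`` over traits, which is inversely related to A-optimality of
    the posterior information.

    This class precomputes the grid, the prior precision and pool parameter
    arrays so whole offspring populations can be scored in one vectorized
    pass (`evaluate_pairs`).
    """

    def __init__(self, pool: ItemPool, Phi: np.ndarray,
                 grid: QuadratureGrid | None = None,
                 quad_points: tuple[float, ...] = (-2.0, 0.0, 2.0)):
        self.pool = pool
        self.Phi = np.asarray(Phi, dtype=float)
        if self.Phi.shape != (pool.D, pool.D):
            raise ValueError("Phi shape does not match the pool dimensionality")
        if not np.allclose(self.Phi, self.Phi.T):
            raise ValueError("Phi must be symmetric")
        # Cholesky doubles as the positive-definiteness check
        np.linalg.cholesky(self.Phi)
        self.Phi_inv = np.linalg.inv(self.Phi)
        self.grid = grid if grid is not None else build_quadrature(
            pool.D, quad_points, self.Phi)

    def evaluate_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Mean reliability for a batch of questionnaires given as index pairs.

        ``pairs`` has shape (K, J, 2): pool *indices* of the first and second
        item of each block for K candidate questionnaires.
        """
        pairs = np.asarray(pairs)
        if pairs.ndim == 2:
            pairs = pairs[None]
        K, J, _ = pairs.shape
        D = self.pool.D
        if J == 0:
            return np.full(K, self._reliability_from_info(
                np.zeros((1, self.grid.L, D, D)))[0])
        i1 = pairs[..., 0]
        i2 = pairs[..., 1]
        a1, a2 = self.pool.a[i1], self.pool.a[i2]
        d1, d2 = self.pool.dims[i1] - 1, self.pool.dims[i2] - 1
        s = np.zeros((K, J, D))
        kk, jj = np.meshgrid(np.arange(K), np.arange(J), indexing="ij")
        np.add.at(s, (kk, jj, d1), a1)
        np.add.at(s, (kk, jj, d2), -a2)
        cj = self.pool.c[i1] - self.pool.c[i2]
        logits = np.einsum("kjd,ld->kjl", s, self.grid.points) + cj[..., None]
        p = expit(logits)
        pq = p * (1.0 - p)  # (K, J, L)
        info = np.einsum("kjl,kjd,kje->klde", pq, s, s)
        return self._reliability_from_info(info)

    def _reliability_from_info(self, info: np.ndarray) -> np.ndarray:
        M = info + self.Phi_inv  # (K, L, D, D)
        var = np.diagonal(np.linalg.inv(M), axis1=-2, axis2=-1)  # (K, L, D)
        var_bar = np.einsum("kld,l->kd", var, self.grid.weights)
        return (1.0 - var_bar).mean(axis=1)

    def per_dimension(self, q: Questionnaire) -> np.ndarray:
        """Per-trait posterior marginal reliabilities of a questionnaire."""
        S, cj = q.scale_matrix(self.pool.D)
        logits = S @ self.grid.points.T + cj[:, None]
        pq = expit(logits) * (1.0 - expit(logits))
        info = np.einsum("jl,jd,je->lde", pq, S, S)
        M = info + self.Phi_inv
        var = np.diagonal(np.linalg.inv(M), axis1=-2, axis2=-1)
        var_bar = self.grid.weights @ var
        return 1.0 - var_bar

    def __call__(self, q: Questionnaire) -> float:
        return float(self.per_dimension(q).mean())


def objective_reliability(q: Questionnaire, Phi: np.ndarray,
                          grid: QuadratureGrid | None = None,
                          pool: ItemPool | None = None,
                          ) -> tuple[np.ndarray, float]:
    """Per-trait posterior marginal reliabilities and their mean.

    Convenience wrapper around :class:`ReliabilityObjective` for a single
    questionnaire; pass ``pool`` to reuse its dimensionality, otherwise D is
    taken from Phi.
    """
    Phi = np.asarray(Phi, dtype=float)
    D = Phi.shape[0]
    if grid is None:
        grid = build_quadrature(D, (-2.0, 0.0, 2.0), Phi)
    Phi_inv = np.linalg.inv(Phi)
    S, cj = q.scale_matrix(D)
    if q.J:
        logits = S @ grid.points.T + cj[:, None]
        pq = expit(logits) * (1.0 - expit(logits))
        info = np.einsum("jl,jd,je->lde", pq, S, S)
    else:
        info = np.zeros((grid.L, D, D))
    M = info + Phi_inv
    var = np.diagonal(np.linalg.inv(M), axis1=-2, axis2=-1)
    var_bar = grid.weights @ var
    rho2 = 1.0 - var_bar
    return rho2, float(rho2.mean())


def count_assemblies(N: int, J: int, V: int = 2) -> int:
    """Exact number of distinct questionnaires of J blocks of V items from a
    pool of N: N! / (J! (N - J V)! V!^J)."""
    if N < J * V:
        raise ValueError(f"pool of {N} cannot fill {J} blocks of {V}")
    num = math.factorial(N)
    den = math.factorial(J) * math.factorial(N - J * V) * math.factorial(V) ** J
    return num // den


def ipsativity_bound(D: int) -> float:
    """Expected inter-trait correlation of fully ipsative scores, -1/(D-1).

    Serves as the reference magnitude against which observed trait-correlation
    biases of normatively scored forced-choice questionnaires are compared.
    """
    if D < 2:
        raise ValueError("need at least two traits")
    return -1.0 / (D - 1)
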