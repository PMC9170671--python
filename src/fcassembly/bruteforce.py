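"""Constrained-random (quasi-brute-force) assembly baseline.

Candidate questionnaires are drawn by the same stepwise sampling machinery as
the GA's operator, but with an empty template and uniform probabilities over
the feasible partners at every draw, so the search is memoryless.  Run under
a computation budget matched to a GA run, the best and the average candidate
quality bracket what unguided (structural-constraints-only) assembly can
achieve on a given pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ga import GAConfig, _SamplerSpec, _sample_vector, _pairs_array, \
    build_constraints, decode_phenotype, InfeasibleConfigError
from .model import ItemPool, Questionnaire, ReliabilityObjective

__all__ = ["BFResult", "random_feasible_assembly", "bf_search"]


def random_feasible_assembly(C: np.ndarray, pool: ItemPool, cfg: GAConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """One uniformly sampled feasible decision vector.

    Stepwise constrained random sampling: positions are filled in index order
    with a uniform draw over the partners still feasible under the pairing
    matrix and the questionnaire quotas; quota dead-ends restart the build.
    """
    K = cfg.K if cfg.K is not None else pool.N
    spec = _SamplerSpec.from_config(pool, C, cfg, K)
    delta = _sample_vector(None, None, spec, rng)
    tries = 0
    while delta is None:
        tries += 1
        if tries > 40:
            raise InfeasibleConfigError(
                "could not draw a feasible assembly; check quotas")
        delta = _sample_vector(None, None, spec, rng)
    return delta


@dataclass
class BFResult:
    """Outcome of a budgeted constrained-random search."""

    best_delta: np.ndarray
    best_objective: float
    questionnaire: Questionnaire
    mean_objective: float
    n_evaluated: int
    sample_deltas: list = field(default_factory=list)  # uniform subsample


def bf_search(pool: ItemPool, Phi: np.ndarray, cfg: GAConfig, budget: int,
              rng: np.random.Generator,
              C: np.ndarray | None = None,
              objective: ReliabilityObjective | None = None,
              subsample: int = 0,
              chunk: int = 256) -> BFResult:
    """Evaluate ``budget`` random feasible questionnaires; track the best and
    the running mean objective.

    ``subsample`` > 0 additionally keeps a uniform reservoir sample of the
    evaluated decision vectors (used to score the average-candidate benchmark
    on a manageable number of questionnaires).
    """
    if budget <= 0:
        raise ValueError("budget must be a positive number of evaluations")
    if C is None:
        C = build_constraints(pool)
    if objective is None:
        objective = ReliabilityObjective(pool, Phi)
    K = cfg.K if cfg.K is not None else pool.N
    spec = _SamplerSpec.from_config(pool, C, cfg, K)

    best_obj = -np.inf
    best_delta: np.ndarray | None = None
    total = 0.0
    n_done = 0
    reservoir: list[np.ndarray] = []

    while n_done < budget:
        m = min(chunk, budget - n_done)
        batch = np.empty((m, pool.N), dtype=np.int64)
        for k in range(m):
            delta = _sample_vector(None, None, spec, rng)
            while delta is None:
                delta = _sample_vector(None, None, spec, rng)
            batch[k] = delta
            if subsample > 0:
                seen = n_done + k + 1
                if len(reservoir) < subsample:
                    reservoir.append(delta)
                elif rng.random() < subsample / seen:
                    reservoir[rng.integers(subsample)] = delta
        obj = objective.evaluate_pairs(_pairs_array(batch, cfg.J))
        total += float(obj.sum())
        i = int(np.argmax(obj))
        if obj[i] > best_obj:
            best_obj = float(obj[i])
            best_delta = batch[i].copy()
        n_done += m

    assert best_delta is not None
    return BFResult(
        best_delta=best_delta,
        best_objective=best_obj,
        questionnaire=decode_phenotype(best_delta, pool),
        mean_objective=total / n_done,
        n_evaluated=n_done,
        sample_deltas=reservoir,
    )
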