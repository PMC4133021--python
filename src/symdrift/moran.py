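"""Continuous-time, constant-size Moran-type simulator for small pools.

Constant population size is enforced at every event.  A fraction ``s`` of
divisions is symmetric; since symmetric renewals must balance symmetric
differentiations, symmetric divisions enter as *coupled pair events* at rate
``s*N/2`` per cell cycle: one fitness-weighted divider renews into two stem
daughters, and one uniformly chosen *other* cell is removed (its symmetric
differentiation balances the renewal; each pair event therefore accounts for
two symmetric divisions, and the freshly created daughters are not at risk
within the same event).  Asymmetric divisions occur at rate ``(1-s)*N``.
With this parameterization every cell divides once per cycle on average, the
fraction ``s`` of divisions is symmetric, and a rare lineage gains and loses
cells at rate ``s/2`` per cycle — exactly matching the discrete branching
model, so the two simulators agree at large ``N`` (they differ only through
whole-pool extinctions, which the Moran constraint forbids).  In the
degenerate ``N = 1`` pool a pair event keeps one uniformly chosen daughter.

Selection enters through per-stage fitness weights ``w_i`` that bias the
choice of divider only; the division clock is normalized so that the mean
fitness-normalized division rate stays at one per cell per cycle.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .branching import FirstPassageResult, _seed_from
from .config import GenotypeChain, MutationPathway, PopulationParams, build_chain

__all__ = ["simulate_moran", "moran_event", "fixation_probability_mc"]

DEFAULT_MAX_EVENTS = 200_000_000


def _state_fitness(chain: GenotypeChain, params: PopulationParams) -> np.ndarray:
    w_stage = params.stage_fitness(int(chain.stage.max()))
    return w_stage[chain.stage]


def simulate_moran(
    pathway: MutationPathway,
    params: PopulationParams,
    rng: np.random.Generator | int | None = None,
    chain: GenotypeChain | None = None,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> FirstPassageResult:
    """One first-passage run of the Moran model.

    Events that provably leave the composition unchanged are collapsed
    analytically, so runs dominated by a resident wild-type stage cost far
    fewer random draws than ``N*L``.
    """
    chain = chain or build_chain(pathway)
    w = _state_fitness(chain, params)
    status, T = _kernels.moran_run_kernel(
        int(params.N), chain.indptr, chain.targets, chain.rates,
        chain.total_rate, chain.absorbing, w, params.s, float(params.L),
        params.both_daughter_mutation, _seed_from(rng), max_events,
    )
    return FirstPassageResult(
        success=status == _kernels.STATUS_SUCCESS,
        T_K=T,
        budget_exceeded=status == _kernels.STATUS_BUDGET,
    )


def moran_event(
    counts: np.ndarray,
    pathway: MutationPathway,
    params: PopulationParams,
    rng: np.random.Generator | int | None = None,
    chain: GenotypeChain | None = None,
) -> np.ndarray:
    """Apply a single state-changing Moran event to a composition.

    Exposed for inspection and unit tests; the run-level kernel collapses
    no-op events, so this returns the composition after the next event that
    actually changes it (totals are conserved by construction).
    """
    chain = chain or build_chain(pathway)
    counts = np.asarray(counts, dtype=np.int64).copy()
    N = int(counts.sum())
    if N == 0:
        return counts
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w = _state_fitness(chain, params)
    U = chain.total_rate

    def daughter_state(i: int) -> int:
        """Genotype of one daughter of a state-i divider."""
        if U[i] > 0 and rng.random() < U[i]:
            edges = slice(chain.indptr[i], chain.indptr[i + 1])
            probs = chain.rates[edges] / U[i]
            return int(rng.choice(chain.targets[edges], p=probs))
        return i

    # divider sampled proportional to stage fitness
    weights = w * counts
    i = int(rng.choice(chain.n_states, p=weights / weights.sum()))
    # pair events at rate s*N/2, asymmetric at (1-s)*N: a division is part
    # of a pair with probability (s/2) / (s/2 + 1-s)
    s = params.s
    if s > 0 and rng.random() < (0.5 * s) / (1.0 - 0.5 * s):
        d1, d2 = daughter_state(i), daughter_state(i)
        if not params.both_daughter_mutation and d1 != i and d2 != i:
            # baseline: at most one daughter advances; keep one uniformly
            if rng.random() < 0.5:
                d2 = i
            else:
                d1 = i
        if N == 1:
            counts[:] = 0
            counts[d1 if rng.random() < 0.5 else d2] = 1
            return counts
        # removal among the N-1 other pre-division cells
        pre = counts.copy()
        pre[i] -= 1
        j = int(rng.choice(chain.n_states, p=pre / pre.sum()))
        counts[i] -= 1
        counts[d1] += 1
        counts[d2] += 1
        counts[j] -= 1
    else:
        d1 = daughter_state(i)
        counts[i] -= 1
        counts[d1] += 1
    return counts


def fixation_probability_mc(
    N: int, n_rep: int = 100_000, s: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """MC estimate of the fixation probability of one labeled neutral cell."""
    return _kernels.neutral_drift_fixation(int(N), float(s), int(n_rep),
                                           _seed_from(rng))
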