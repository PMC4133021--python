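"""Discrete-time branching-process simulator for large stem-cell pools.

Each cell divides once per generation (one stem-cell cycle), producing two
stem daughters with probability ``s/2``, none with probability ``s/2`` and
exactly one otherwise, so renewal and extinction balance on average and the
expected pool size is constant.  Each surviving stem daughter advances one
genotype step with its state's per-division probability.  A run ends when a
fully mutated cell appears (success), when the whole pool dies out
(extinction, a risk-reducing outcome), or at the organism lifetime ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import GenotypeChain, MutationPathway, PopulationParams, build_chain

__all__ = ["FirstPassageResult", "branching_generation", "simulate_branching"]


@dataclass
class FirstPassageResult:
    success: bool
    T_K: float          # first-passage time in cell cycles (valid if success)
    extinct: bool = False
    budget_exceeded: bool = False
    trajectory: np.ndarray | None = None   # (t+1, n_states) counts, optional

    def __post_init__(self):
        if self.success and self.extinct:
            raise ValueError("success and extinct are mutually exclusive")


def _seed_from(rng: np.random.Generator | int | None) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) & 0x7FFFFFFF
    if rng is None:
        rng = np.random.default_rng()
    return int(rng.integers(0, 2**31 - 1))


def branching_generation(
    counts: np.ndarray,
    pathway: MutationPathway,
    params: PopulationParams,
    rng: np.random.Generator | int | None = None,
    chain: GenotypeChain | None = None,
) -> np.ndarray:
    """Advance a count vector by one synchronous generation."""
    chain = chain or build_chain(pathway)
    counts = np.asarray(counts, dtype=np.int64)
    return _kernels.branching_generation_kernel(
        counts, chain.indptr, chain.targets, chain.rates,
        chain.total_rate, params.s, params.both_daughter_mutation,
        _seed_from(rng),
    )


def simulate_branching(
    pathway: MutationPathway,
    params: PopulationParams,
    rng: np.random.Generator | int | None = None,
    record_trajectory: bool = False,
    chain: GenotypeChain | None = None,
) -> FirstPassageResult:
    """One first-passage run of the branching model."""
    chain = chain or build_chain(pathway)
    status, T, traj = _kernels.branching_run_kernel(
        int(params.N), chain.indptr, chain.targets, chain.rates,
        chain.total_rate, chain.absorbing, params.s, float(params.L),
        params.both_daughter_mutation, _seed_from(rng), record_trajectory,
    )
    return FirstPassageResult(
        success=status == _kernels.STATUS_SUCCESS,
        T_K=T,
        extinct=status == _kernels.STATUS_EXTINCT,
        trajectory=np.asarray(traj) if record_trajectory else None,
    )
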