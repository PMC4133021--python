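"""Exact first-passage probabilities on small state spaces.

These are deterministic linear-algebra computations on the *same* stochastic
models the simulators implement, used (a) to validate both simulators and the
Protection Factor statistic on tiny configurations, and (b) as the rare-event
engine for per-crypt risks far below Monte-Carlo reach.

The Moran chain is embedded at events: with the division clock normalized,
events occur at the constant rate ``N (1 - s/2)`` per cell cycle, so the
number of events in ``t`` cycles is Poisson and absorption by time ``t``
follows by uniformization.  Transient states are the compositions of ``N``
cells over the *non*-absorbing genotypes — any division that creates a fully
mutated daughter absorbs immediately (before the coupled removal), matching
the simulator's success convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse
from scipy.stats import poisson

from .config import GenotypeChain, MutationPathway, PopulationParams, build_chain

__all__ = [
    "enumerate_compositions",
    "moran_event_matrix",
    "moran_absorption_probability",
    "branching_absorption_probability",
    "exact_first_passage",
    "oracle_pf",
    "StateSpaceError",
]


class StateSpaceError(ValueError):
    """State space exceeds the configured cap."""


def enumerate_compositions(N: int, parts: int) -> list[tuple]:
    """All compositions of N into `parts` nonnegative ordered parts."""
    out = []
    for cuts in combinations(range(N + parts - 1), parts - 1):
        prev = -1
        comp = []
        for c in cuts:
            comp.append(c - prev - 1)
            prev = c
        comp.append(N + parts - 2 - prev)
        out.append(tuple(comp))
    return out


def _chain_for(pathway_or_rates) -> GenotypeChain:
    if isinstance(pathway_or_rates, GenotypeChain):
        return pathway_or_rates
    if isinstance(pathway_or_rates, MutationPathway):
        return build_chain(pathway_or_rates)
    return build_chain(MutationPathway(rates=tuple(pathway_or_rates)))


def moran_event_matrix(pathway_or_rates, N: int, s: float,
                       fitness=None, both_daughter: bool = False,
                       state_cap: int = 200_000):
    """One-event transition matrix of the Moran chain.

    Returns ``(states, P, absorb)`` where ``P`` (CSR) maps transient
    compositions to transient compositions and ``absorb[x]`` is the
    per-event probability of creating a fully mutated daughter from state
    ``x``.  Rows of ``P`` plus ``absorb`` sum to one.
    """
    chain = _chain_for(pathway_or_rates)
    trans_states = [i for i in range(chain.n_states) if not chain.absorbing[i]]
    n_parts = len(trans_states)
    if comb(N + n_parts - 1, n_parts - 1) > state_cap:
        raise StateSpaceError("composition space exceeds cap")
    # remap chain onto transient genotypes; edges to absorbing targets noted
    remap = {g: k for k, g in enumerate(trans_states)}
    edges = [[] for _ in range(n_parts)]          # (target_or_-1, rate)
    for k, g in enumerate(trans_states):
        for e in range(chain.indptr[g], chain.indptr[g + 1]):
            tgt = chain.targets[e]
            edges[k].append((remap.get(tgt, -1), chain.rates[e]))
    U = np.array([sum(r for _, r in edges[k]) for k in range(n_parts)])
    if fitness is None:
        w = np.ones(n_parts)
    else:
        w_stage = np.asarray(fitness, dtype=float)
        w = w_stage[chain.stage[trans_states]]

    states = enumerate_compositions(N, n_parts)
    index = {st: i for i, st in enumerate(states)}
    lam_pair = 0.5 * s * N
    lam_asym = (1.0 - s) * N
    lam_tot = lam_pair + lam_asym

    rows, cols, vals = [], [], []
    absorb = np.zeros(len(states))

    def add(x, st, prob):
        rows.append(x)
        cols.append(index[st])
        vals.append(prob)

    for x, st in enumerate(states):
        n = np.array(st)
        W = float(np.dot(w, n))
        if W == 0.0:
            add(x, st, 1.0)
            continue
        for i in range(n_parts):
            if n[i] == 0:
                continue
            phi = w[i] * n[i] / W
            # asymmetric division events
            pa = (lam_asym / lam_tot) * phi
            if pa > 0.0:
                stay = 1.0 - U[i]
                add(x, st, pa * stay)
                for tgt, r in edges[i]:
                    if r == 0.0:
                        continue
                    if tgt < 0:
                        absorb[x] += pa * r
                    else:
                        st2 = list(st)
                        st2[i] -= 1
                        st2[tgt] += 1
                        add(x, tuple(st2), pa * r)
            # symmetric pair events
            pp = (lam_pair / lam_tot) * phi
            if pp == 0.0:
                continue
            outcomes = []  # (daughter1, daughter2, prob); -1 = absorbing
            q0 = (1.0 - U[i]) ** 2
            outcomes.append((i, i, q0))
            if both_daughter:
                for tgt, r in edges[i]:
                    outcomes.append((i, tgt, 2.0 * (1.0 - U[i]) * r))
                    for tgt2, r2 in edges[i]:
                        outcomes.append((tgt, tgt2, r * r2))
            else:
                for tgt, r in edges[i]:
                    outcomes.append((i, tgt, r * (2.0 - U[i])))
            for d1, d2, pout in outcomes:
                if pout == 0.0:
                    continue
                if d1 < 0 or d2 < 0:
                    absorb[x] += pp * pout
                    continue
                n2 = list(st)
                n2[i] -= 1
                n2[d1] += 1
                n2[d2] += 1
                if N == 1:
                    # degenerate pool: keep one of the two daughters
                    for keep in (d1, d2):
                        st3 = [0] * n_parts
                        st3[keep] = 1
                        add(x, tuple(st3), pp * pout * 0.5)
                    continue
                # removal among the N-1 other pre-division cells
                for j in range(n_parts):
                    pre_j = st[j] - 1 if j == i else st[j]
                    if pre_j == 0:
                        continue
                    st3 = list(n2)
                    st3[j] -= 1
                    add(x, tuple(st3), pp * pout * pre_j / (N - 1.0))
    P = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(states), len(states))
    )
    return states, P, absorb


def moran_absorption_probability(pathway_or_rates, N: int, t: float, s: float,
                                 fitness=None, both_daughter: bool = False,
                                 state_cap: int = 200_000) -> float:
    """Exact P(first fully mutated cell by time t) for the Moran model.

    Uniformized at the constant event rate ``N (1 - s/2)`` per cycle.
    """
    states, P, absorb = moran_event_matrix(
        pathway_or_rates, N, s, fitness, both_daughter, state_cap
    )
    lam = N * (1.0 - 0.5 * s)
    mu = lam * float(t)
    if mu == 0.0 or absorb.sum() == 0.0:
        return 0.0
    kmax = int(mu + 12.0 * np.sqrt(mu) + 30)
    pmf = poisson.pmf(np.arange(kmax + 1), mu)
    v = np.zeros(len(states))
    # initial state: all cells wild type
    init = tuple([N] + [0] * (len(states[0]) - 1))
    v[states.index(init)] = 1.0
    absorbed = 0.0
    total = 0.0
    for k in range(kmax + 1):
        total += pmf[k] * absorbed
        if pmf[k + 1 :].sum() < 1e-14 and k > mu:
            break
        absorbed += float(v @ absorb)
        v = v @ P
    # events beyond kmax: bound by current absorbed mass
    total += poisson.sf(kmax, mu) * absorbed
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# branching chain (generation-embedded, truncated)
# ---------------------------------------------------------------------------

def _cell_outcomes(i, edges_i, U_i, s, both_daughter):
    """Per-cell offspring outcome distribution: (daughters tuple, prob)."""
    outs = []
    half = 0.5 * s
    # zero daughters
    if half > 0:
        outs.append(((), half))
    # one daughter
    p1 = 1.0 - s
    if p1 > 0:
        outs.append(((i,), p1 * (1.0 - U_i)))
        for tgt, r in edges_i:
            outs.append(((tgt,), p1 * r))
    # two daughters
    if half > 0:
        q0 = (1.0 - U_i) ** 2
        outs.append(((i, i), half * q0))
        if both_daughter:
            for tgt, r in edges_i:
                outs.append(((i, tgt), half * 2.0 * (1.0 - U_i) * r))
                for tgt2, r2 in edges_i:
                    outs.append(((tgt, tgt2), half * r * r2))
        else:
            for tgt, r in edges_i:
                outs.append(((i, tgt), half * r * (2.0 - U_i)))
    return [(d, p) for d, p in outs if p > 0.0]


def branching_absorption_probability(pathway_or_rates, N: int, t: float,
                                     s: float, both_daughter: bool = False,
                                     total_cap: int = 40,
                                     state_cap: int = 200_000):
    """P(first fully mutated cell by generation t), branching model.

    Exact on the truncated space of compositions with total population
    ``<= total_cap``; probability mass that overflows the cap is tracked and
    returned as an error certificate.  Returns ``(prob, overflow_mass)``.
    """
    chain = _chain_for(pathway_or_rates)
    trans = [i for i in range(chain.n_states) if not chain.absorbing[i]]
    remap = {g: k for k, g in enumerate(trans)}
    edges = [[] for _ in trans]
    for k, g in enumerate(trans):
        for e in range(chain.indptr[g], chain.indptr[g + 1]):
            edges[k].append((remap.get(chain.targets[e], -1), chain.rates[e]))
    U = [sum(r for _, r in edges[k]) for k in range(len(trans))]
    outcomes = [
        _cell_outcomes(k, edges[k], U[k], s, both_daughter)
        for k in range(len(trans))
    ]
    n_parts = len(trans)
    if N > total_cap:
        raise StateSpaceError("initial population exceeds total cap")

    init = tuple([N] + [0] * (n_parts - 1))
    dist = {init: 1.0}
    absorbed = 0.0
    overflow = 0.0
    for _ in range(int(np.ceil(t))):
        new: dict = {}
        for st, p0 in dist.items():
            # convolve per-cell outcome distributions across all cells
            partial = {((0,) * n_parts, False): 1.0}
            for i in range(n_parts):
                for _ in range(st[i]):
                    nxt: dict = {}
                    for (acc, hit), pp in partial.items():
                        for daughters, po in outcomes[i]:
                            acc2 = list(acc)
                            hit2 = hit
                            for d in daughters:
                                if d < 0:
                                    hit2 = True
                                else:
                                    acc2[d] += 1
                            key = (tuple(acc2), hit2)
                            nxt[key] = nxt.get(key, 0.0) + pp * po
                    partial = nxt
            for (acc, hit), pp in partial.items():
                p = p0 * pp
                if hit:
                    absorbed += p
                elif sum(acc) > total_cap:
                    overflow += p
                else:
                    new[acc] = new.get(acc, 0.0) + p
        dist = new
        if len(dist) > state_cap:
            raise StateSpaceError("branching state space exceeds cap")
    return absorbed, overflow


def exact_first_passage(pathway, params: PopulationParams, t: float,
                        **kwargs) -> float:
    """Absorption probability by time t for either model (dispatch)."""
    if params.model == "moran":
        return moran_absorption_probability(
            pathway, params.N, t, params.s,
            fitness=params.fitness, both_daughter=params.both_daughter_mutation,
            **kwargs,
        )
    prob, overflow = branching_absorption_probability(
        pathway, params.N, t, params.s,
        both_daughter=params.both_daughter_mutation, **kwargs
    )
    return prob


@dataclass
class OraclePF:
    PF: float
    R_A: float
    R_S: float


def oracle_pf(pathway_or_rates, N: int, t: float, s_target: float = 1.0,
              model: str = "moran", **kwargs) -> OraclePF:
    """Exact Protection Factor: asymmetric vs target-symmetry risk at t."""
    if model == "moran":
        ra = moran_absorption_probability(pathway_or_rates, N, t, 0.0, **kwargs)
        rs = moran_absorption_probability(pathway_or_rates, N, t, s_target,
                                          **kwargs)
    else:
        ra, _ = branching_absorption_probability(pathway_or_rates, N, t, 0.0,
                                                 **kwargs)
        rs, _ = branching_absorption_probability(pathway_or_rates, N, t,
                                                 s_target, **kwargs)
    pf = ra / rs if rs > 0 else np.inf
    return OraclePF(PF=float(pf), R_A=float(ra), R_S=float(rs))
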