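"""Mutation pathways and population parameters.

A *pathway* describes how heritable damage accumulates: ``K`` mutations are
collected one locus at a time, and a cell's genotype is the set of loci it has
already mutated.  Three modes are supported:

``ordered``
    Mutations occur in a fixed order; the stage-``i`` to stage-``i+1``
    transition fires with per-division probability ``u_i``.
``unordered_independent``
    Each un-mutated locus may fire next, at its own locus-specific rate,
    so routes through genotype space differ only in the order of the rates.
``background_dependent``
    The rate of each locus may depend on which loci are already mutated
    (e.g. a genetic-stability locus that accelerates later mutations).

Rates are per-division probabilities per daughter cell, so time is measured
in stem-cell cycles throughout the package.  Mutation is irreversible and at
most one locus fires per daughter per division.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "MutationPathway",
    "PopulationParams",
    "GenotypeChain",
    "Route",
    "ConfigurationError",
    "validate_pathway",
    "expand_routes",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
]

MODES = ("ordered", "unordered_independent", "background_dependent")


class ConfigurationError(ValueError):
    """Raised when a pathway or parameter set violates an invariant."""


def _genotype_key(genotype: frozenset) -> str:
    return ",".join(sorted(genotype))


@dataclass(frozen=True)
class MutationPathway:
    """K-stage mutation pathway.

    Parameters
    ----------
    mode:
        One of ``ordered``, ``unordered_independent``, ``background_dependent``.
    rates:
        Ordered mode: sequence ``u_0 .. u_{K-1}``.
    locus_rates:
        Unordered mode: mapping locus name -> per-division rate.
    rate_table:
        Background-dependent mode: mapping genotype (frozenset of locus
        names) -> {locus: rate} for every un-mutated locus of every
        reachable genotype.
    """

    mode: str = "ordered"
    rates: tuple = ()
    locus_rates: Mapping[str, float] | None = None
    rate_table: Mapping[frozenset, Mapping[str, float]] | None = None

    @property
    def K(self) -> int:
        if self.mode == "ordered":
            return len(self.rates)
        return len(self.loci)

    @property
    def loci(self) -> tuple:
        if self.mode == "unordered_independent":
            return tuple(sorted(self.locus_rates))
        if self.mode == "background_dependent":
            return tuple(sorted(self.rate_table[frozenset()]))
        return tuple(f"G{i + 1}" for i in range(len(self.rates)))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"mode": self.mode, "K": self.K}
        if self.mode == "ordered":
            d["rates"] = list(map(float, self.rates))
        elif self.mode == "unordered_independent":
            d["locus_rates"] = {k: float(v) for k, v in self.locus_rates.items()}
        else:
            d["rate_table"] = {
                _genotype_key(g): {k: float(v) for k, v in row.items()}
                for g, row in self.rate_table.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MutationPathway":
        mode = d.get("mode", "ordered")
        if mode == "ordered":
            return cls(mode=mode, rates=tuple(d["rates"]))
        if mode == "unordered_independent":
            return cls(mode=mode, locus_rates=dict(d["locus_rates"]))
        table = {}
        for key, row in d["rate_table"].items():
            genotype = frozenset(x for x in key.split(",") if x)
            table[genotype] = dict(row)
        return cls(mode=mode, rate_table=table)


@dataclass(frozen=True)
class PopulationParams:
    """Simulation parameters for one homeostatic stem-cell pool.

    ``N`` initial stem-cell count; ``s`` fraction of divisions that are
    symmetric (renewals and differentiations balance on average); ``L``
    organism lifetime in stem-cell cycles; ``model`` in {"branching",
    "moran"}; ``fitness`` per-stage division weights ``w_0..w_K``;
    ``both_daughter_mutation`` lets both daughters of a symmetric renewal
    mutate independently (baseline: at most one advances); ``M`` number of
    independent, identically parameterized compartments (crypts).
    """

    N: int
    s: float
    L: float
    model: str = "branching"
    fitness: tuple | None = None
    both_daughter_mutation: bool = False
    M: int = 1

    def stage_fitness(self, K: int) -> np.ndarray:
        if self.fitness is None:
            return np.ones(K + 1)
        w = np.asarray(self.fitness, dtype=float)
        if w.size != K + 1:
            raise ConfigurationError(
                f"fitness must have K+1={K + 1} entries, got {w.size}"
            )
        return w

    def to_dict(self) -> dict:
        return {
            "N": int(self.N),
            "s": float(self.s),
            "L": float(self.L),
            "model": self.model,
            "fitness": None if self.fitness is None else list(map(float, self.fitness)),
            "both_daughter_mutation": bool(self.both_daughter_mutation),
            "M": int(self.M),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationParams":
        fit = d.get("fitness")
        return cls(
            N=int(d["N"]),
            s=float(d["s"]),
            L=float(d["L"]),
            model=d.get("model", "branching"),
            fitness=None if fit is None else tuple(fit),
            both_daughter_mutation=bool(d.get("both_daughter_mutation", False)),
            M=int(d.get("M", 1)),
        )


@dataclass(frozen=True)
class Route:
    """One ordered path through genotype space with its per-step rates."""

    order: tuple
    rates: tuple


@dataclass
class GenotypeChain:
    """Flattened genotype transition structure used by both simulators.

    ``n_states`` genotypes; CSR-style arrays ``indptr``/``targets``/``rates``
    give, for each state, the reachable genotypes and their per-division
    probabilities; ``stage`` is the number of accumulated mutations per
    state; ``absorbing`` marks fully mutated genotypes (stage == K).
    """

    n_states: int
    indptr: np.ndarray
    targets: np.ndarray
    rates: np.ndarray
    stage: np.ndarray
    absorbing: np.ndarray
    genotypes: list

    @property
    def total_rate(self) -> np.ndarray:
        out = np.zeros(self.n_states)
        for i in range(self.n_states):
            out[i] = self.rates[self.indptr[i] : self.indptr[i + 1]].sum()
        return out


def _check_rate(u: float, where: str) -> None:
    if not (0.0 <= u < 1.0):
        raise ConfigurationError(f"rate {u!r} at {where} outside [0, 1)")


def build_chain(pathway: MutationPathway) -> GenotypeChain:
    """Enumerate reachable genotypes and their one-step transitions."""
    if pathway.mode == "ordered":
        K = pathway.K
        genotypes = [frozenset(pathway.loci[:i]) for i in range(K + 1)]
        indptr = [0]
        targets, rates = [], []
        for i, u in enumerate(pathway.rates):
            targets.append(i + 1)
            rates.append(float(u))
            indptr.append(len(targets))
        indptr.append(len(targets))  # absorbing final state
        stage = np.arange(K + 1)
    else:
        loci = pathway.loci
        K = len(loci)
        genotypes = [
            frozenset(c)
            for r in range(K + 1)
            for c in itertools.combinations(loci, r)
        ]
        index = {g: i for i, g in enumerate(genotypes)}
        indptr = [0]
        targets, rates = [], []
        for g in genotypes:
            for locus in loci:
                if locus in g:
                    continue
                if pathway.mode == "unordered_independent":
                    u = pathway.locus_rates[locus]
                else:
                    try:
                        u = pathway.rate_table[g][locus]
                    except KeyError as exc:
                        raise ConfigurationError(
                            f"background_dependent table missing rate for locus "
                            f"{locus!r} on genotype {set(g) or '{}'}"
                        ) from exc
                targets.append(index[g | {locus}])
                rates.append(float(u))
            indptr.append(len(targets))
        stage = np.array([len(g) for g in genotypes])
    chain = GenotypeChain(
        n_states=len(genotypes),
        indptr=np.asarray(indptr, dtype=np.int64),
        targets=np.asarray(targets, dtype=np.int64),
        rates=np.asarray(rates, dtype=np.float64),
        stage=stage.astype(np.int64),
        absorbing=(stage == K),
        genotypes=genotypes,
    )
    return chain


def validate_pathway(
    pathway: MutationPathway, params: PopulationParams | None = None
) -> MutationPathway:
    """Check all pathway (and optionally population) invariants.

    Returns the pathway unchanged on success so it can be used inline.
    """
    if pathway.mode not in MODES:
        raise ConfigurationError(f"unknown mode {pathway.mode!r}")
    if pathway.mode == "ordered":
        if len(pathway.rates) < 1:
            raise ConfigurationError("ordered pathway needs K >= 1 rates")
        for i, u in enumerate(pathway.rates):
            _check_rate(u, f"u_{i}")
    elif pathway.mode == "unordered_independent":
        if not pathway.locus_rates:
            raise ConfigurationError("unordered pathway needs >= 1 locus")
        for locus, u in pathway.locus_rates.items():
            _check_rate(u, f"locus {locus}")
    else:
        if pathway.rate_table is None or frozenset() not in pathway.rate_table:
            raise ConfigurationError(
                "background_dependent table must include the wild-type genotype"
            )
        for g, row in pathway.rate_table.items():
            for locus, u in row.items():
                _check_rate(u, f"locus {locus} on {set(g) or '{}'}")
    chain = build_chain(pathway)  # raises on missing genotype entries
    # at most one locus fires per daughter per division, so the per-division
    # probabilities out of each genotype must sum below 1
    tot = chain.total_rate
    if np.any(tot >= 1.0):
        raise ConfigurationError(
            "total per-division mutation probability >= 1 for some genotype"
        )
    if params is not None:
        if params.N < 1:
            raise ConfigurationError("N must be >= 1")
        if not (0.0 <= params.s <= 1.0):
            raise ConfigurationError("s must lie in [0, 1]")
        if params.L <= 0:
            raise ConfigurationError("L must be positive")
        if params.M < 1:
            raise ConfigurationError("M must be >= 1")
        w = params.stage_fitness(pathway.K)
        if np.any(w <= 0):
            raise ConfigurationError("all fitness weights must be positive")
        if params.model not in ("branching", "moran"):
            raise ConfigurationError(f"unknown model {params.model!r}")
    return pathway


def expand_routes(pathway: MutationPathway) -> list[Route]:
    """List every ordered route through the pathway with its rate sequence.

    For unordered loci every permutation of firing order appears once, with
    the rate sequence permuted accordingly; for background-dependent tables
    the rate of each step is looked up on the genotype accumulated so far.
    Ordered pathways yield their single trivial route.
    """
    if pathway.mode == "ordered":
        return [Route(order=pathway.loci, rates=tuple(pathway.rates))]
    routes = []
    for perm in itertools.permutations(pathway.loci):
        seq = []
        acquired: frozenset = frozenset()
        for locus in perm:
            if pathway.mode == "unordered_independent":
                seq.append(float(pathway.locus_rates[locus]))
            else:
                seq.append(float(pathway.rate_table[acquired][locus]))
            acquired = acquired | {locus}
        routes.append(Route(order=perm, rates=tuple(seq)))
    return routes


# -- whole-configuration (pathway + population + run) serialization ---------

def config_to_dict(pathway: MutationPathway, params: PopulationParams,
                   run: Mapping | None = None) -> dict:
    return {
        "pathway": pathway.to_dict(),
        "population": params.to_dict(),
        "run": dict(run or {}),
    }


def config_from_dict(d: Mapping) -> tuple[MutationPathway, PopulationParams, dict]:
    pathway = MutationPathway.from_dict(d["pathway"])
    params = PopulationParams.from_dict(d["population"])
    validate_pathway(pathway, params)
    return pathway, params, dict(d.get("run", {}))


def load_config(path) -> tuple[MutationPathway, PopulationParams, dict]:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


def dump_config(path, pathway, params, run=None) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(pathway, params, run), fh, indent=2, sort_keys=True)
        fh.write("\n")
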