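"""Named parameter presets for the worked examples.

Rates are per locus per stem-cell cycle; lifetimes in stem-cell cycles.
The intestinal presets model slow biallelic inactivation of a genetic
stability gene (loci A1, A2) followed by rapid mutation of a downstream
gene B once instability has set in.
"""

from __future__ import annotations

from .config import MutationPathway, PopulationParams

__all__ = ["PRESETS", "get_preset", "list_presets"]


def _ordered(rates, **pop):
    return {
        "pathway": MutationPathway(rates=tuple(rates)),
        "population": PopulationParams(**pop),
    }


PRESETS: dict[str, dict] = {
    # ~60,000-cell pool accumulating three mutations
    "three_step_pool": _ordered(
        (5e-8, 1e-3, 5e-3), N=60_000, s=1.0, L=6000.0, model="branching"
    ),
    # two-stage pool where simulation and the analytic risk curves cross-check
    "two_step_reference": _ordered(
        (1e-6, 1e-3), N=1000, s=1.0, L=1000.0, model="moran"
    ),
    # modest (10%) symmetry in the same pool
    "two_step_mixed_symmetry": _ordered(
        (1e-6, 1e-3), N=1000, s=0.1, L=1000.0, model="moran"
    ),
    # two independent loci, fast and slow, mutating in either order
    "unordered_fast_slow": {
        "pathway": MutationPathway(
            mode="unordered_independent",
            locus_rates={"A": 1e-6, "B": 1e-2},
        ),
        "population": PopulationParams(N=10_000, s=1.0, L=2000.0,
                                       model="branching"),
    },
    # genetic stability gene: B mutates rapidly only once A is inactivated
    "stability_gene": {
        "pathway": MutationPathway(
            mode="background_dependent",
            rate_table={
                frozenset(): {"A": 1e-6, "B": 1e-6},
                frozenset({"A"}): {"B": 1e-2},
                frozenset({"B"}): {"A": 1e-6},
            },
        ),
        "population": PopulationParams(N=10_000, s=1.0, L=2000.0,
                                       model="moran"),
    },
    # mouse small intestine: 1e6 crypts x ~10 Lgr5+ stem cells x ~1e3 cycles
    "mouse_intestine": _ordered(
        (1e-6, 1e-6, 1e-3), N=10, s=1.0, L=1000.0, model="moran", M=1_000_000
    ),
    # human colon, 100-fold accelerated late rates, ages 30 and 60
    # (1e7 crypts x 20 stem cells x 100 divisions/year)
    "human_colon_age30_100x": _ordered(
        (5e-7, 5e-7, 5e-5, 5e-5), N=20, s=1.0, L=3000.0, model="moran",
        M=10_000_000
    ),
    "human_colon_age60_100x": _ordered(
        (5e-7, 5e-7, 5e-6, 5e-5), N=20, s=1.0, L=6000.0, model="moran",
        M=10_000_000
    ),
    # human colon, 1000-fold accelerated late rates
    "human_colon_age30_1000x": _ordered(
        (5e-7, 5e-7, 5e-6, 5e-4), N=20, s=1.0, L=3000.0, model="moran",
        M=10_000_000
    ),
    "human_colon_age60_1000x": _ordered(
        (5e-7, 5e-7, 5e-7, 5e-4), N=20, s=1.0, L=6000.0, model="moran",
        M=10_000_000
    ),
}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> dict:
    try:
        entry = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
    return {"pathway": entry["pathway"], "population": entry["population"]}
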