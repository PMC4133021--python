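"""Random-parameter ensemble screens over the mutation-accumulation model.

Parameter sets are sampled broadly (K uniform on an integer interval; N, L
and each mutation rate log-uniform), admitted only if the closed-form
asymmetric lifetime risk falls in a biologically sensible window, and then
simulated under purely asymmetric and purely symmetric division to measure
the Protection Factor.  Optional monotonicity constraints sort the rate
sequence ascending (or descending), emulating pathways in which genetic
instability acquired part-way accelerates every later step — sorted
log-uniform draws accelerate after whichever stage the fast rates land on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytics import asymmetric_risk_closed_form, scaled_metrics, stage_means
from .config import MutationPathway, PopulationParams
from .risk import estimate_risk_curve, protection_factor

__all__ = [
    "ScreenRanges",
    "ScreenRecord",
    "sample_parameter_set",
    "run_screen",
    "classify_stages",
    "screen_to_frame",
]


@dataclass(frozen=True)
class ScreenRanges:
    """Sampling ranges; N, L and rates are log-uniform, K uniform integer."""

    K: tuple = (1, 10)
    N: tuple = (1e2, 1e6)
    L: tuple = (1e2, 1e4)
    u: tuple = (1e-8, 1e-2)
    admit: tuple = (0.10, 0.99996)   # window for predicted R_A(L)


@dataclass
class ScreenRecord:
    set_id: int
    K: int
    N: int
    L: float
    rates: tuple
    RA_pred: float
    model: str = ""
    RA_sim: float = np.nan
    RS_sim: float = np.nan
    PF: float = np.nan
    PF_SE: float = np.nan
    t_star: float = np.nan
    theta: tuple = ()
    n_stochastic: int = 0
    type_label: int = 0
    rejections: int = 0
    incomplete: bool = False


def _loguniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_parameter_set(
    ranges: ScreenRanges,
    rng: np.random.Generator,
    monotonic_mode: str = "none",
    max_tries: int = 100_000,
) -> ScreenRecord:
    """Rejection-sample one admitted parameter set.

    Admission requires the predicted (closed-form) asymmetric lifetime risk
    to lie inside ``ranges.admit``.  Monotonic modes resort the sampled
    rates ascending (increasing) or descending (decreasing).
    """
    if monotonic_mode not in ("none", "increasing", "decreasing"):
        raise ValueError(f"unknown monotonic mode {monotonic_mode!r}")
    lo, hi = ranges.admit
    for attempt in range(max_tries):
        K = int(rng.integers(ranges.K[0], ranges.K[1] + 1))
        N = max(1, int(round(_loguniform(rng, *ranges.N))))
        L = _loguniform(rng, *ranges.L)
        u = np.array([_loguniform(rng, *ranges.u) for _ in range(K)])
        if monotonic_mode != "none" and K > 1:
            # whole-sequence monotonicity: log-uniform order statistics
            # accelerate (decelerate) naturally after whichever stage the
            # sorted draws place the fast rates
            u = np.sort(u)
            if monotonic_mode == "decreasing":
                u = u[::-1]
        ra = asymmetric_risk_closed_form(u, N, L)
        if lo < ra < hi:
            return ScreenRecord(
                set_id=-1, K=K, N=N, L=L, rates=tuple(u), RA_pred=float(ra),
                rejections=attempt,
            )
    raise RuntimeError(
        "admission rate below floor: adjust sampling ranges or the "
        "admission window"
    )


def _moran_workload_estimate(record: ScreenRecord) -> float:
    """Rough count of state-changing Moran events in a symmetric run.

    Changing events accrue at roughly ``s * (N - max_i n_i)`` per cycle, so
    the deterministic stage means give a cheap upper-bound estimate used
    only to dispatch between simulators.
    """
    grid = np.linspace(0.0, record.L, 33)
    means = stage_means(record.rates, record.N, grid)
    minority = record.N - means.max(axis=1)
    return float(2.0 * np.trapezoid(minority, grid))


def classify_stages(record: ScreenRecord, s: float = 1.0) -> ScreenRecord:
    """Attach scaled stage sizes and the stochastic-stage type label.

    The type label counts stochastic intermediate stages (scaled stage size
    below one), capped at 3; across an ensemble the mean PF increases with
    the number of stochastic stages, and significant protection requires
    the penultimate stage to be stochastic.
    """
    m = scaled_metrics(record.rates, record.N, record.L, s=s)
    record.theta = tuple(np.round(m.theta, 6))
    record.n_stochastic = m.n_stochastic
    record.type_label = min(m.n_stochastic, 3)
    return record


def run_screen(
    n_sets: int,
    ranges: ScreenRanges | None = None,
    monotonic_mode: str = "none",
    rng: np.random.Generator | int | None = None,
    n_success_target: int = 100,
    max_runs: int = 800,
    moran_N_max: int = 10_000,
    moran_event_cap: int = 20_000_000,
    workload_cap: float = 5e6,
) -> tuple[list[ScreenRecord], dict]:
    """Sample, simulate and classify ``n_sets`` admitted parameter sets.

    Pools below ``moran_N_max`` cells are simulated with the Moran model,
    larger ones with the branching model; sets whose predicted Moran
    workload exceeds ``workload_cap`` state-changing events per run are
    dispatched to the branching model instead (their minority stages are
    macroscopic, which is exactly where the two models agree).  Runs that
    exhaust the event budget mark the set incomplete; incomplete sets are
    excluded from the summary and counted there.
    """
    ranges = ranges or ScreenRanges()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    records: list[ScreenRecord] = []
    for set_id in range(n_sets):
        rec = sample_parameter_set(ranges, rng, monotonic_mode)
        rec.set_id = set_id
        pathway = MutationPathway(rates=rec.rates)
        model = "moran" if rec.N < moran_N_max else "branching"
        if model == "moran" and _moran_workload_estimate(rec) > workload_cap:
            model = "branching"
        rec.model = model
        kwargs = {"max_events": moran_event_cap} if model == "moran" else {}
        asym = estimate_risk_curve(
            pathway,
            PopulationParams(N=rec.N, s=0.0, L=rec.L, model=model),
            n_success_target=n_success_target, max_runs=max_runs,
            rng=rng, **kwargs,
        )
        sym = estimate_risk_curve(
            pathway,
            PopulationParams(N=rec.N, s=1.0, L=rec.L, model=model),
            n_success_target=n_success_target, max_runs=max_runs,
            rng=rng, **kwargs,
        )
        pf = protection_factor(asym, sym)
        rec.RA_sim, rec.RS_sim = pf.R_A, pf.R_S
        rec.PF, rec.PF_SE, rec.t_star = pf.PF, pf.SE, pf.t_star
        rec.incomplete = bool(asym.flagged_runs or sym.flagged_runs)
        classify_stages(rec)
        records.append(rec)
    complete = [r for r in records if not r.incomplete]
    pf_vals = np.array([r.PF for r in complete])
    by_type: dict[int, float] = {}
    for tlab in sorted({r.type_label for r in complete}):
        vals = [r.PF for r in complete if r.type_label == tlab]
        by_type[tlab] = float(np.mean(vals))
    summary = {
        "n_sets": n_sets,
        "n_complete": len(complete),
        "n_incomplete": len(records) - len(complete),
        "fraction_pf_gt_2": float(np.mean(pf_vals > 2.0)) if complete else np.nan,
        "mean_pf_by_type": by_type,
        "monotonic_mode": monotonic_mode,
    }
    return records, summary


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "set_id": r.set_id, "K": r.K, "N": r.N, "L": r.L,
            "RA_pred": r.RA_pred, "RA_sim": r.RA_sim, "RS_sim": r.RS_sim,
            "PF": r.PF, "PF_SE": r.PF_SE, "t_star": r.t_star,
            "model": r.model, "n_stochastic": r.n_stochastic,
            "type": r.type_label, "incomplete": r.incomplete,
        }
        for i, u in enumerate(r.rates):
            row[f"u{i}"] = u
        rows.append(row)
    return pd.DataFrame(rows)
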