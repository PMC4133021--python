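"""Closed-form and approximate results for ordered mutation accumulation.

The central object is the fate of a *single fresh mutant clone* inside a
homeostatic pool in which a fraction ``s`` of divisions is symmetric.  Such a
clone performs critical birth-death with birth and death rates ``s/2`` per
cell cycle, and each of its divisions hands the next mutation (rate ``u`` per
daughter) a chance to fire.  Writing ``g(t)`` for the probability that the
clone has produced no next-stage cell by time ``t``, the backward equation is
the Riccati ODE

    dg/dt = (s/2) g^2 - (s + u) g + s/2,       g(0) = 1,

whose logistic solution is used throughout.  Its fixed point gives the
lineage mutation probability

    p = [sqrt(u^2 + 2 s u) - u] / s  ~  sqrt(2 u / s)   (u << s),

so a fresh clone almost surely extinguishes before progressing whenever the
mutation rate is small compared with the symmetric-division rate.  The
conditional time a successful clone drifts before progressing is

    tau = ln 2 * sqrt(2 / (s u))        (to leading order),

obtained exactly from the same logistic solution.  Population-level risks
follow by compounding over the ``N u0`` fresh clones arising per cycle:
the cumulative hazard of the first fully mutated cell is
``N u0 * integral_0^t g-complement``, evaluated in closed form below.  In
the ``s -> 0`` limit the same expressions collapse onto the asymmetric-
lineage results, so one family of formulas covers pure asymmetry, mixed
symmetry and pure symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .config import GenotypeChain, MutationPathway, build_chain

__all__ = [
    "stage_means",
    "ScaledStageMetrics",
    "scaled_metrics",
    "scaling_curve",
    "lineage_mutation_probability",
    "clonal_drift_time",
    "lineage_success_by",
    "success_hazard_integral",
    "asymmetric_risk_closed_form",
    "lineage_first_passage",
    "two_stage_symmetric_risk",
    "sequential_fixation_risk",
    "RegimeLabel",
    "classify_regimes",
    "progression_time",
    "piecewise_pf",
    "PiecewisePF",
    "unordered_two_locus_risk",
    "compartment_analytic_risk",
    "CompartmentRisk",
    "latency_distribution",
]


# ---------------------------------------------------------------------------
# deterministic stage means
# ---------------------------------------------------------------------------

def stage_means(rates, N, t):
    """Expected per-stage cell counts ``<n_i(t)>`` under balanced dynamics.

    Renewal and extinction cancel in expectation, so the means obey the
    linear flux equations ``d<n_i>/dt = u_{i-1}<n_{i-1}> - u_i <n_i>`` with
    ``<n_0(0)> = N``; at early times ``<n_i(t)> ~ N u_0...u_{i-1} t^i / i!``.

    Parameters
    ----------
    rates : sequence of per-division mutation probabilities u_0..u_{K-1}
    N : initial pool size
    t : scalar or array of times (cell cycles)

    Returns
    -------
    array of shape ``(K+1,)`` or ``(len(t), K+1)``.
    """
    u = np.asarray(rates, dtype=float)
    K = u.size
    A = np.zeros((K + 1, K + 1))
    for i in range(K):
        A[i, i] -= u[i]
        A[i + 1, i] += u[i]
    n0 = np.zeros(K + 1)
    n0[0] = float(N)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((ts.size, K + 1))
    for k, tk in enumerate(ts):
        out[k] = expm(A * tk) @ n0
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# single-clone fate (lineage mutation probability, drift time, hazards)
# ---------------------------------------------------------------------------

def _riccati_parts(u: float, s: float):
    """Roots and decay rate of the clone-fate Riccati equation."""
    disc = np.sqrt(u * u + 2.0 * s * u)
    g_minus = ((s + u) - disc) / s
    g_plus = ((s + u) + disc) / s
    r = disc  # (s/2) * (g_plus - g_minus)
    c0 = (1.0 - g_minus) / (1.0 - g_plus)  # negative
    return g_minus, g_plus, r, c0


def lineage_mutation_probability(u: float, s: float) -> float:
    """Probability that a fresh mutant clone progresses before extinction.

    Exact fixed point ``p = [sqrt(u^2 + 2su) - u]/s``; for ``u << s`` this is
    ``sqrt(2u/s)``, so clones almost surely extinguish when ``u << s``.
    ``s = 0`` lies outside the critical-clone domain (an asymmetric lineage
    is immortal and progresses with probability 1 eventually); a warning is
    emitted and 1.0 returned.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must lie in [0, 1)")
    if u == 0.0:
        return 0.0
    if s == 0.0:
        warnings.warn(
            "s=0 is outside the critical-clone domain; an immortal asymmetric "
            "lineage eventually progresses with probability 1",
            stacklevel=2,
        )
        return 1.0
    # exact fixed point of the per-generation recursion
    #   q = s/2 + (1-s)(1-u) q + (s/2)(1-u)^2 q^2
    # (q = P(clone extinguishes without progressing)); expanding for u << s
    # recovers the continuous-limit form [sqrt(u^2+2su)-u]/s ~ sqrt(2u/s).
    a = 0.5 * s * (1.0 - u) ** 2
    lin = 1.0 - (1.0 - s) * (1.0 - u)
    q = (lin - np.sqrt(lin * lin - 2.0 * a * s)) / (2.0 * a)
    return float(1.0 - q)


def clonal_drift_time(u: float, s: float) -> float:
    """Mean drift time of a clone *conditioned on progressing*.

    Exact value ``(g+ - g-) ln(1 - c0) / (r p)`` from the logistic solution;
    to leading order ``ln 2 * sqrt(2/(s u))`` cell cycles.
    """
    if u <= 0.0 or s <= 0.0:
        raise ValueError("drift time requires u > 0 and s > 0")
    g_minus, g_plus, r, c0 = _riccati_parts(u, s)
    p = 1.0 - g_minus
    return float((g_plus - g_minus) * np.log1p(-c0) / (r * p))


def lineage_success_by(t, u: float, s: float):
    """P(a fresh clone has produced a next-stage cell by time t)."""
    t = np.asarray(t, dtype=float)
    if u == 0.0:
        return np.zeros_like(t)
    if s == 0.0:
        return -np.expm1(-u * t)
    g_minus, g_plus, r, c0 = _riccati_parts(u, s)
    e = c0 * np.exp(-r * t)
    g = (g_minus - g_plus * e) / (1.0 - e)
    return 1.0 - g


def success_hazard_integral(t, u: float, s: float):
    """``I(t) = integral_0^t P(clone born at 0 progressed by tau) dtau``.

    New clones arise continuously; the population-level cumulative hazard of
    the first next-stage cell is (arrival rate) * I(t).  Closed form from the
    logistic solution; limits: ``u t^2 / 2`` for early times and
    ``p (t - tau_drift)`` for ``t >> tau_drift``.
    """
    t = np.asarray(t, dtype=float)
    if u == 0.0:
        return np.zeros_like(t)
    if s == 0.0:
        return t - (-np.expm1(-u * t)) / u
    g_minus, g_plus, r, c0 = _riccati_parts(u, s)
    p = 1.0 - g_minus
    return p * t + ((g_plus - g_minus) / r) * (
        np.log1p(-c0 * np.exp(-r * t)) - np.log1p(-c0))


# ---------------------------------------------------------------------------
# asymmetric closed form (per-lineage chain, exact)
# ---------------------------------------------------------------------------

def lineage_first_passage(chain_or_rates, t_max: int) -> np.ndarray:
    """Exact P(single asymmetric lineage fully mutated by generation t).

    One cell per lineage; per generation it advances one genotype step with
    its state's per-division probability.  Returns ``q[0..t_max]``.
    """
    if isinstance(chain_or_rates, GenotypeChain):
        chain = chain_or_rates
    else:
        chain = build_chain(MutationPathway(rates=tuple(chain_or_rates)))
    n = chain.n_states
    P = np.zeros((n, n))
    for i in range(n):
        U = 0.0
        for e in range(chain.indptr[i], chain.indptr[i + 1]):
            P[i, chain.targets[e]] = chain.rates[e]
            U += chain.rates[e]
        P[i, i] = 1.0 - U
    v = np.zeros(n)
    v[0] = 1.0
    absorbing = chain.absorbing
    q = np.empty(int(t_max) + 1)
    q[0] = float(v[absorbing].sum())
    for g in range(1, int(t_max) + 1):
        v = v @ P
        q[g] = v[absorbing].sum()
    return q


def asymmetric_risk_closed_form(rates, N, t, M: int = 1):
    """Exact asymmetric risk ``R_A(t) = 1 - (1 - q(t))^(N M)``.

    ``q(t)`` is the single-lineage first-passage probability computed by
    matrix iteration over ``t`` generations; numerically stable for risks
    down to ~1e-300 via log1p/expm1.
    """
    ts = np.atleast_1d(np.asarray(t))
    tm = int(np.ceil(ts.max()))
    q = lineage_first_passage(rates, tm)
    qt = np.minimum(q[np.floor(ts).astype(int)], 1.0 - 1e-16)
    out = -np.expm1(float(N) * M * np.log1p(-qt))
    return float(out[0]) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# scaled stage metrics
# ---------------------------------------------------------------------------

@dataclass
class ScaledStageMetrics:
    """Dimensionless stage diagnostics at the end of life.

    ``theta[i]`` (scaled stage size) compares the time the largest stage-i
    clone needs to extinguish (~ its size) with the time it would need to
    progress (~ 1/(size * u_i)): ``theta_i = <n_i(L)> sqrt(2 u_i / s)``.
    Stages with ``theta_i < 1`` are *stochastic* — extinction-prone
    fluctuations dominate and the stage repeatedly empties; stages with
    ``theta_i >= 1`` track the deterministic means.  ``u_hat[i] = s u_i
    L^2/2`` is the scaled mutation rate: along the ~50%-lifetime-risk
    surface the two obey ``theta ~ K ln2 / sqrt(u_hat)``, so protected
    (``theta < 1``) stages require ``u_hat >> 1``, i.e. fast late mutations
    in rapidly cycling tissue.
    """

    theta: np.ndarray          # index i = 0..K-1 (stage with out-rate u_i)
    u_hat: np.ndarray
    mean_end_of_life: np.ndarray   # <n_i(L)>, i = 0..K
    n_stochastic: int          # stochastic count among intermediate stages
    stochastic: np.ndarray     # bool per stage 1..K-1


def scaled_metrics(rates, N, L, s: float = 1.0) -> ScaledStageMetrics:
    u = np.asarray(rates, dtype=float)
    means = stage_means(u, N, float(L))
    with np.errstate(divide="ignore"):
        theta = means[: u.size] * np.sqrt(2.0 * u / max(s, 1e-300))
    u_hat = s * u * float(L) ** 2 / 2.0
    inter = slice(1, u.size)  # intermediate stages 1..K-1
    stoch = theta[inter] < 1.0
    return ScaledStageMetrics(
        theta=theta,
        u_hat=u_hat,
        mean_end_of_life=means,
        n_stochastic=int(stoch.sum()),
        stochastic=stoch,
    )


def scaling_curve(u_hat, K: int):
    """Scaled stage size predicted on the ~50% asymmetric-risk surface."""
    u_hat = np.asarray(u_hat, dtype=float)
    return K * np.log(2.0) / np.sqrt(u_hat)


# ---------------------------------------------------------------------------
# two-stage risks, regimes, piecewise PF
# ---------------------------------------------------------------------------

def two_stage_symmetric_risk(N, u0, u1, L, s=1.0, t=None):
    """Risk of the first double mutant via clone-fate compounding.

    ``R(t) = 1 - exp(-N u0 I(t))`` with the hazard integral ``I`` of the
    secondary rate; valid while single-mutant clones stay rare (the
    stochastic-tunneling side of parameter space).  Reduces to the exact
    asymmetric forms at ``s = 0``.
    """
    t = L if t is None else t
    lam = float(N) * u0
    return -np.expm1(-lam * success_hazard_integral(t, u1, s))


def _hypoexponential_cdf(rates, t):
    """P(sum of independent Exp(rate_k) <= t) via a small matrix exponential."""
    rates = [r for r in rates if np.isfinite(r)]
    m = len(rates)
    Q = np.zeros((m + 1, m + 1))
    for k, r in enumerate(rates):
        Q[k, k] = -r
        Q[k, k + 1] = r
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(ts.size)
    for j, tj in enumerate(ts):
        out[j] = expm(Q * tj)[0, m]
    return out[0] if np.ndim(t) == 0 else out


def sequential_fixation_risk(rates, N, L, s=1.0, t=None):
    """Symmetric risk in a small pool that progresses by clonal fixations.

    From a pool fixed for stage ``i``, clones destined to fix arise at rate
    ``u_i`` per cycle (arrival ``N u_i`` times fixation probability ``1/N``),
    then drift to fixation in ``~2N/s`` cycles; the final stage needs only a
    single cell, at rate ``N u_{K-1}`` once stage ``K-1`` has fixed.  A
    stochastic-tunneling shortcut for the last transition (rate
    ``N u_{K-2} p(u_{K-1}, s)`` with its drift delay) is included, since
    small pools sit near the fixation/tunneling crossover.  Absorption CDF
    of the resulting phase-type chain, by matrix exponential.
    """
    u = np.asarray(rates, dtype=float)
    K = u.size
    t = L if t is None else t
    fix_rate = s / (2.0 * float(N))
    # states: F_0, (D_1, F_1), ..., (D_{K-1}, F_{K-1}), [T_drift], A
    n_fix = K - 1
    n_states = 1 + 2 * n_fix + (1 if K >= 2 else 0)  # + tunneling drift state
    A = n_states  # absorbing index
    Q = np.zeros((n_states + 1, n_states + 1))

    def idx_F(i):
        return 0 if i == 0 else 2 * i

    def idx_D(i):
        return 2 * i - 1

    for i in range(K - 1):
        Q[idx_F(i), idx_D(i + 1)] += u[i]
    for i in range(1, K):
        Q[idx_D(i), idx_F(i)] += fix_rate
    Q[idx_F(K - 1), A] += float(N) * u[K - 1]
    if K >= 2:
        T = n_states - 1
        p_tun = lineage_mutation_probability(u[K - 1], s) if s > 0 else 1.0
        Q[idx_F(K - 2), T] += float(N) * u[K - 2] * p_tun
        Q[T, A] += 1.0 / clonal_drift_time(u[K - 1], s) if u[K - 1] > 0 else 0.0
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(ts.size)
    for j, tj in enumerate(ts):
        out[j] = expm(Q * tj)[0, -1]
    res = np.clip(out, 0.0, 1.0)
    return float(res[0]) if np.ndim(t) == 0 else res


@dataclass
class RegimeLabel:
    """Which approximations govern a two-stage parameter point.

    Asymmetric axis: ``S`` (secondary step unlikely within the window,
    quadratic-in-time risk) vs ``D`` (secondary step saturates, linear
    risk).  Symmetric axis: ``ST`` (stochastic tunneling, ``N p >= 1``) vs
    ``SF`` (sequential fixation, ``N p < 1``).  Boundaries are smooth
    crossovers; ``asym_margin``/``sym_margin`` are log10 distances to them.
    """

    asymmetric: str
    symmetric: str
    asym_margin: float
    sym_margin: float

    @property
    def crossover(self) -> bool:
        return min(abs(self.asym_margin), abs(self.sym_margin)) < 0.25


def classify_regimes(N, u0, u1, L, s=1.0, t_eval=None) -> RegimeLabel:
    t_eval = L if t_eval is None else t_eval
    p = lineage_mutation_probability(u1, s) if s > 0 else 1.0
    x_asym = u1 * t_eval
    x_sym = float(N) * p
    # sequential fixation requires both an unlikely tunnel (N p < 1) and
    # room for the ~2N/s-cycle fixation era inside the evaluation window;
    # otherwise clone fates (the tunneling composite) govern the window
    fix_reachable = s * t_eval > 4.0 * float(N)
    return RegimeLabel(
        asymmetric="S" if x_asym < 1.0 else "D",
        symmetric="SF" if (x_sym < 1.0 and fix_reachable) else "ST",
        asym_margin=float(np.log10(x_asym)) if x_asym > 0 else -np.inf,
        sym_margin=float(np.log10(x_sym)) if x_sym > 0 else -np.inf,
    )


def progression_time(N, u_next, s=1.0, regime: str | None = None) -> float:
    """Mean time for a symmetric single-mutant clone to reach the next stage.

    Tunneling regime: the conditional drift time ``~ ln2 sqrt(2/(s u))`` —
    a successful clone grows, mutates and collapses without ever fixing.
    Sequential-fixation regime: the clone first fixes (``~2N/s`` cycles) and
    the fixed pool then waits ``1/(N u)`` cycles for the next mutation.
    """
    if regime is None:
        raise ValueError("regime label required: 'ST' (tunneling) or 'SF'")
    if regime == "ST":
        return clonal_drift_time(u_next, s)
    if regime == "SF":
        return 2.0 * float(N) / s + 1.0 / (float(N) * u_next)
    raise ValueError(f"unknown regime {regime!r}")


@dataclass
class PiecewisePF:
    PF: float
    t_star: float
    R_A: float
    R_S: float
    regimes: RegimeLabel
    approximate: bool


def _asym_two_stage_approx(N, u0, u1, t):
    """Per-lineage hazard integral ``H_2(t) = t - (1 - e^{-u1 t})/u1``.

    Smoothly bridges the two asymmetric regimes: ``u0 u1 t^2/2`` while the
    secondary step is unlikely in the window (S) and ``u0 (t - 1/u1)`` once
    it saturates (D); regime labels report which limit governs.
    """
    lam = float(N) * u0 * (t - (-np.expm1(-u1 * t)) / u1)
    return -np.expm1(-lam)


def piecewise_pf(N, u0, u1, L, s=1.0) -> PiecewisePF:
    """Analytic Protection Factor for two-stage accumulation.

    Evaluates the regime-matched approximations at the time the *exact*
    asymmetric risk first reaches 50% (or at ``L`` if it never does),
    mirroring how simulated PFs are ascertained.  Accuracy degrades near
    the smooth regime crossovers, where ``approximate`` is set.
    """
    Lint = int(np.ceil(L))
    q = lineage_first_passage((u0, u1), Lint)
    RA_exact = -np.expm1(float(N) * np.log1p(-q))
    hit = np.nonzero(RA_exact >= 0.5)[0]
    t_star = float(hit[0]) if hit.size else float(Lint)
    reg = classify_regimes(N, u0, u1, L, s, t_eval=t_star)
    R_A = _asym_two_stage_approx(N, u0, u1, t_star)
    if reg.symmetric == "ST":
        R_S = two_stage_symmetric_risk(N, u0, u1, L, s, t=t_star)
    else:
        R_S = sequential_fixation_risk((u0, u1), N, L, s, t=t_star)
    pf = float(R_A / R_S) if R_S > 0 else np.inf
    return PiecewisePF(PF=pf, t_star=t_star, R_A=float(R_A), R_S=float(R_S),
                       regimes=reg, approximate=reg.crossover)


# ---------------------------------------------------------------------------
# unordered loci, compartments, latency
# ---------------------------------------------------------------------------

def _route_hazard(x, y, N, t, s, S):
    """Cumulative double-mutant hazard of the x-first, y-second route.

    Wild-type cells deplete at total rate ``S = a + b``, so x-mutants arise
    at rate ``N x exp(-S t')``.  If the x-stage is *deterministic* (scaled
    size >= 1) its abundance tracks the mean and the second mutation fires
    at rate ``y <n_x>`` — division symmetry cannot help, since means are
    division-pattern independent.  If it is *stochastic*, each x-clone must
    produce a y-mutation before extinction, giving the clone-fate composite
    integral instead.
    """
    if x == 0.0 or y == 0.0:
        return 0.0
    mean_x = (N * x / S) * -np.expm1(-S * t)
    p_y = lineage_mutation_probability(y, s)
    if mean_x * p_y >= 1.0:
        # deterministic first stage: mean-field production
        return y * (N * x / S) * (t - (-np.expm1(-S * t)) / S)
    # stochastic first stage: compound over clone fates (numeric convolution)
    tp = np.linspace(0.0, t, 257)
    integrand = np.exp(-S * tp) * lineage_success_by(t - tp, y, s)
    return N * x * np.trapezoid(integrand, tp)


def unordered_two_locus_risk(rate_a, rate_b, N, L, s=1.0, t=None):
    """Risk that one cell mutates both of two independent loci (either order).

    ``s = 0``: exact per-lineage product form through the genotype chain.
    ``s > 0``: the slow-fast and fast-slow routes compound.  A fast first
    locus saturates the pool, making its route deterministic and
    unprotected; only routes whose first stage stays stochastic benefit
    from clonal extinctions.  With very unequal rates the fast-slow route
    therefore dominates and little protection survives.
    """
    t = L if t is None else t
    a, b = float(rate_a), float(rate_b)
    if s == 0.0:
        pathway = MutationPathway(
            mode="unordered_independent", locus_rates={"A": a, "B": b}
        )
        return asymmetric_risk_closed_form(build_chain(pathway), N, t)
    S = a + b
    lam = (_route_hazard(a, b, N, t, s, S)
           + _route_hazard(b, a, N, t, s, S))
    return -np.expm1(-lam)


@dataclass
class CompartmentRisk:
    tissue_risk: float
    per_crypt_risk: float
    M: int
    engine: str


def compartment_analytic_risk(rates, N, L, s, M, engine: str = "auto",
                              state_cap: int = 20000) -> CompartmentRisk:
    """Tissue-level risk for ``M`` independent crypts of ``N`` stem cells.

    Per-crypt lifetime risks are far too small for direct Monte Carlo
    (down to ~1e-8), so they are computed deterministically and aggregated
    as ``1 - (1 - r)^M`` (log1p/expm1 stable).  Engines:

    ``exact``  first-passage probability of the full Moran event chain on
               the crypt composition space (uniformized; no approximation
               beyond floating point) — the default whenever the state
               space is modest;
    ``sf``     sequential-fixation/tunneling building-block formula
               (`sequential_fixation_risk`), usable at any ``N``.

    The asymmetric (``s = 0``) crypt is always evaluated by the exact
    lineage closed form.
    """
    from math import comb

    from .oracle import moran_absorption_probability  # local: avoid cycle

    rates = tuple(float(u) for u in rates)
    K = len(rates)
    if M < 1:
        raise ValueError("M must be >= 1")
    if s == 0.0:
        r = asymmetric_risk_closed_form(rates, N, L)
        engine_used = "closed_form"
    else:
        if engine == "auto":
            engine = "exact" if comb(int(N) + K, K) <= state_cap else "sf"
        if engine == "exact":
            r = moran_absorption_probability(rates, int(N), float(L), s)
            engine_used = "exact"
        elif engine == "sf":
            r = sequential_fixation_risk(rates, N, L, s)
            engine_used = "sf"
        else:
            raise ValueError(f"unknown engine {engine!r}")
    tissue = float(-np.expm1(M * np.log1p(-min(r, 1.0 - 1e-16))))
    return CompartmentRisk(tissue_risk=tissue, per_crypt_risk=float(r),
                           M=int(M), engine=engine_used)


def latency_distribution(N, u0, u1, L, regime: str, s: float = 1.0):
    """PMF of the first double-mutant time over integer cell cycles.

    Hazard per cycle: ``u1 <n_1(t)>`` in the deterministic regime (the
    single-mutant stage tracks its mean) and ``N u0 h(t)`` in the
    stochastic-tunneling regime (``h`` the time-dependent clone success
    probability).  Returns ``(t, pmf)``; mass not assigned by time ``L``
    is the no-event probability.  With matched means, the tunneling
    (increasing-rates) distribution is the wider one.
    """
    t = np.arange(0, int(L) + 1, dtype=float)
    if regime == "deterministic":
        n1 = stage_means((u0, u1), N, t)[:, 1]
        hazard = u1 * n1
    elif regime == "ST":
        hazard = float(N) * u0 * lineage_success_by(t, u1, s)
    else:
        raise ValueError("regime must be 'deterministic' or 'ST'")
    cum = np.concatenate([[0.0], np.cumsum(hazard[1:])])
    survival = np.exp(-cum)
    pmf = survival[:-1] - survival[1:]
    return t[1:], pmf
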