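"""Numba kernels shared by the branching and Moran simulators.

Both models track cell counts per genotype state of a ``GenotypeChain``
(CSR arrays ``indptr``/``targets``/``rates``).  Time is measured in stem-cell
cycles.  Status codes returned by run kernels::

    0  lifetime reached without a fully mutated cell
    1  success (first fully mutated cell at time T)
    2  whole population extinct (branching only)
    3  event budget exhausted (Moran only; callers must flag the run)
"""

import numpy as np
from numba import njit

STATUS_ALIVE = 0
STATUS_SUCCESS = 1
STATUS_EXTINCT = 2
STATUS_BUDGET = 3


@njit(cache=True, inline="always")
def _distribute(m, i, indptr, targets, rates, total, new):
    """Multinomially split m mutating daughters of state i over its targets."""
    remaining = total
    left = m
    for e in range(indptr[i], indptr[i + 1]):
        if left == 0:
            break
        r = rates[e]
        if r >= remaining:
            x = left
        else:
            x = np.random.binomial(left, r / remaining)
        new[targets[e]] += x
        left -= x
        remaining -= r


@njit(cache=True)
def branching_generation_kernel(counts, indptr, targets, rates, total_rate,
                                s, both_daughter, seed):
    """Advance one synchronous generation; every cell divides once.

    Offspring per division: 2 w.p. s/2, 0 w.p. s/2, 1 w.p. 1-s.  Each
    surviving stem daughter advances one genotype step with its state's
    per-division probability; in the baseline model at most one daughter of
    a symmetric renewal advances (ties broken uniformly), in the
    both-daughter variant the daughters mutate independently.
    """
    if seed >= 0:
        np.random.seed(seed)
    n_states = counts.shape[0]
    new = np.zeros(n_states, dtype=np.int64)
    half = 0.5 * s
    for i in range(n_states):
        n = counts[i]
        if n == 0:
            continue
        U = total_rate[i]
        if indptr[i] == indptr[i + 1]:
            # absorbing state: carry through (still divides, no mutation)
            U = 0.0
        if s > 0.0:
            d2 = np.random.binomial(n, half)
            rem = n - d2
            d0 = np.random.binomial(rem, half / (1.0 - half)) if rem > 0 else 0
            singles = rem - d0
        else:
            d2 = 0
            singles = n
        if singles > 0:
            if U > 0.0:
                m = np.random.binomial(singles, U)
            else:
                m = 0
            new[i] += singles - m
            if m > 0:
                _distribute(m, i, indptr, targets, rates, U, new)
        if d2 > 0:
            if U > 0.0:
                if both_daughter:
                    adv = np.random.binomial(2 * d2, U)
                else:
                    adv = np.random.binomial(d2, 2.0 * U - U * U)
            else:
                adv = 0
            new[i] += 2 * d2 - adv
            if adv > 0:
                _distribute(adv, i, indptr, targets, rates, U, new)
    return new


@njit(cache=True)
def branching_run_kernel(N, indptr, targets, rates, total_rate, absorbing,
                         s, L, both_daughter, seed, record):
    """Run a branching population to success, extinction or lifetime L.

    Returns (status, T, trajectory) where trajectory has one row per
    generation (only filled when ``record`` is true).
    """
    np.random.seed(seed)
    n_states = total_rate.shape[0]
    n_gen = int(np.ceil(L))
    counts = np.zeros(n_states, dtype=np.int64)
    counts[0] = N
    if record:
        traj = np.zeros((n_gen + 1, n_states), dtype=np.int64)
        traj[0] = counts
    else:
        traj = np.zeros((1, n_states), dtype=np.int64)
    for t in range(1, n_gen + 1):
        counts = branching_generation_kernel(
            counts, indptr, targets, rates, total_rate, s, both_daughter, -1
        )
        if record:
            traj[t] = counts
        total = 0
        hit = False
        for i in range(n_states):
            total += counts[i]
            if absorbing[i] and counts[i] > 0:
                hit = True
        if hit:
            return STATUS_SUCCESS, float(t), traj[: t + 1]
        if total == 0:
            return STATUS_EXTINCT, float(t), traj[: t + 1]
    return STATUS_ALIVE, float(n_gen), traj


@njit(cache=True)
def moran_run_kernel(N, indptr, targets, rates, total_rate, absorbing, w,
                     s, L, both_daughter, seed, max_events):
    """Continuous-time constant-N Moran run with no-op collapsing.

    Event structure per cell cycle: symmetric pair events at rate s*N/2
    (a fitness-weighted divider renews into two stem daughters, and one of
    the N-1 *other* cells is removed uniformly — its symmetric
    differentiation balances the renewal; the freshly created daughters are
    not themselves at risk in the same event) and asymmetric division
    events at rate (1-s)*N (single stem daughter).  Each retained stem
    daughter advances a genotype step with its state's per-division
    probability.  With this coupling a rare lineage gains and loses cells
    at rate s/2 per cycle, exactly as in the discrete branching model.
    Events that provably leave the state unchanged (no mutation, removal
    from the divider's own stage) are collapsed analytically, so waiting
    times are drawn from the state-changing rate only.  Success is scored
    the moment a fully mutated daughter is created, before any coupled
    removal.  Degenerate N=1 pools keep one uniformly chosen daughter.
    """
    np.random.seed(seed)
    n_states = total_rate.shape[0]
    counts = np.zeros(n_states, dtype=np.int64)
    counts[0] = N
    t = 0.0
    lam_pair_tot = 0.5 * s * N
    lam_asym_tot = (1.0 - s) * N
    events = 0
    while True:
        events += 1
        if events > max_events:
            return STATUS_BUDGET, t
        # fitness normalization: mean division rate is 1 per cell per cycle
        W = 0.0
        for i in range(n_states):
            W += w[i] * counts[i]
        # state-changing rate
        Rc = 0.0
        for i in range(n_states):
            if counts[i] == 0:
                continue
            phi = w[i] * counts[i] / W
            U = total_rate[i]
            if both_daughter:
                q0 = (1.0 - U) * (1.0 - U)
            else:
                q0 = (1.0 - U) * (1.0 - U)
            # asymmetric division changes state only via mutation
            Rc += lam_asym_tot * phi * U
            # pair event: no-advance is a no-op unless removal hits another stage
            lam_p = lam_pair_tot * phi
            Rc += lam_p * (1.0 - q0)
            if N > 1:
                Rc += lam_p * q0 * (N - counts[i]) / (N - 1.0)
        if Rc <= 0.0:
            return STATUS_ALIVE, L
        t += np.random.exponential(1.0 / Rc)
        if t > L:
            return STATUS_ALIVE, L
        # select the state-changing event
        r = np.random.random() * Rc
        done = False
        for i in range(n_states):
            if done or counts[i] == 0:
                continue
            phi = w[i] * counts[i] / W
            U = total_rate[i]
            q0 = (1.0 - U) * (1.0 - U)
            lam_p = lam_pair_tot * phi
            # --- asymmetric division with mutation
            wgt = lam_asym_tot * phi * U
            if r < wgt:
                rr = np.random.random() * U
                acc = 0.0
                tgt = targets[indptr[i + 1] - 1]
                for e in range(indptr[i], indptr[i + 1]):
                    acc += rates[e]
                    if rr < acc:
                        tgt = targets[e]
                        break
                if absorbing[tgt]:
                    return STATUS_SUCCESS, t
                counts[i] -= 1
                counts[tgt] += 1
                done = True
                break
            r -= wgt
            # --- pair event with at least one advancing daughter
            wgt = lam_p * (1.0 - q0)
            if r < wgt:
                # choose how many daughters advance
                if both_daughter:
                    p1 = 2.0 * U * (1.0 - U)
                    p2 = U * U
                    x = np.random.random() * (p1 + p2)
                    n_adv = 1 if x < p1 else 2
                else:
                    n_adv = 1
                # daughter targets
                tgt1 = -1
                tgt2 = -1
                for k in range(n_adv):
                    rr = np.random.random() * U
                    acc = 0.0
                    tg = targets[indptr[i + 1] - 1]
                    for e in range(indptr[i], indptr[i + 1]):
                        acc += rates[e]
                        if rr < acc:
                            tg = targets[e]
                            break
                    if k == 0:
                        tgt1 = tg
                    else:
                        tgt2 = tg
                if absorbing[tgt1] or (tgt2 >= 0 and absorbing[tgt2]):
                    return STATUS_SUCCESS, t
                if N == 1:
                    # degenerate pool: keep one of the two daughters
                    d2s = tgt2 if n_adv == 2 else i
                    keep = tgt1 if np.random.random() < 0.5 else d2s
                    counts[i] -= 1
                    counts[keep] += 1
                    done = True
                    break
                # removal among the N-1 other pre-division cells
                rr = np.random.random() * (N - 1.0)
                acc = 0.0
                jrem = i
                for j in range(n_states):
                    c = counts[j] - 1 if j == i else counts[j]
                    acc += c
                    if rr < acc:
                        jrem = j
                        break
                # apply division: divider -> two daughters, then removal
                counts[i] -= 1
                counts[tgt1] += 1
                if n_adv == 2:
                    counts[tgt2] += 1
                else:
                    counts[i] += 1
                counts[jrem] -= 1
                done = True
                break
            r -= wgt
            # --- pair event, no advance, removal from another stage
            wgt = lam_p * q0 * (N - counts[i]) / (N - 1.0) if N > 1 else 0.0
            if r < wgt:
                # removal target: uniform over cells not in stage i
                rr = np.random.random() * (N - counts[i])
                acc = 0.0
                for j in range(n_states):
                    if j == i:
                        continue
                    acc += counts[j]
                    if rr < acc:
                        counts[i] += 1
                        counts[j] -= 1
                        break
                done = True
                break
            r -= wgt
        if not done:
            # numerical fall-through (r ~ Rc); treat as no-op
            continue


@njit(cache=True)
def neutral_drift_fixation(N, s, n_rep, seed):
    """MC fixation frequency of one labeled cell under neutral Moran drift.

    Uses the same pair-event semantics as the full kernel (two neutral types,
    no mutation); returns the fraction of replicates in which the labeled
    lineage took over the pool.
    """
    np.random.seed(seed)
    fixed = 0
    for rep in range(n_rep):
        k = 1  # labeled count
        while 0 < k < N:
            # divider labeled w.p. k/N; removal among the N-1 other cells
            divider_labeled = np.random.random() < k / N
            x = k + 1 if divider_labeled else k
            pre_labeled = k - 1 if divider_labeled else k
            if np.random.random() < pre_labeled / (N - 1.0):
                x -= 1
            k = x
        if k == N:
            fixed += 1
    return fixed / n_rep
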