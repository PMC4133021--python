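# symdrift

Stochastic modeling of heritable-damage accumulation in homeostatic
stem-cell pools, and of how **symmetric stem-cell division** — balanced
symmetric renewal and symmetric differentiation — protects against it.

Adult stem-cell pools in many fast-renewing vertebrate tissues (intestinal
crypts, epidermis, testis, blood) divide mostly symmetrically.  Because a
symmetric differentiation extinguishes a stem lineage together with every
mutation it carries, symmetric division "flushes" damaged clones: a freshly
mutated clone in a pool with symmetry fraction `s` progresses to its next
mutation before extinction only with probability `p ≈ sqrt(2u/s)`, so
phenotypically silent multi-hit pathways (the prelude to cancer) are slowed
whenever late mutation rates are fast — the genetic-instability scenario.
`symdrift` is for quantitative/computational biologists who want to
simulate and analyze that effect: it provides

* a **discrete-time branching simulator** (large pools: each cell divides
  once per cycle into 2/0/1 stem daughters w.p. `s/2`, `s/2`, `1-s`) and a
  **constant-size continuous-time Moran simulator** (small pools, coupled
  renewal/differentiation pair events, optional stage fitness), both over
  ordered, unordered or genotype-dependent K-step mutation pathways;
* the **Protection Factor** `PF = R_A(t*) / R_S(t*)`: the ratio of
  asymmetric to symmetric cumulative risks of harboring at least one
  K-fold mutant, evaluated where the asymmetric risk is near 50% (or at
  the end of life);
* **closed forms and approximations**: exact asymmetric risk by lineage
  matrix iteration; clone-fate (stochastic tunneling) composites; scaled
  stage sizes `theta_i = <n_i(L)> sqrt(2 u_i/s)` separating deterministic
  from extinction-dominated stages; a piecewise analytic PF for two-stage
  pathways; sequential-fixation building blocks; rare-event engines for
  compartmentalized tissues (`1 - (1-r)^M` over `M` independent crypts);
* **exact small-system oracles** (uniformized Moran event chains, truncated
  branching chains) validating both simulators;
* **random-parameter screens** (log-uniform `N`, `L`, rates; `K ~ 1..10`;
  admission by predicted lifetime risk) with stochastic-stage
  classification and optional monotone-rate constraints.

See `docs/methods.md` for the model, formulas and conventions.

## Worked example

Protection in a pool of 1000 stem cells accumulating two mutations
(`u0 = 1e-6`, then `u1 = 1e-3` per division) over 1000 stem-cell cycles:

```bash
$ symdrift analytics pf --N 1000 --u0 1e-6 --u1 1e-3 --L 1000
{
  "PF": 7.416039541361682,
  "t_star": 1000.0,
  "R_A": 0.3077993724446536,
  "R_S": 0.04150454844906849,
  "regime_asym": "D",
  "regime_sym": "ST",
  "approximate": true
}
```

By the end of life an asymmetrically dividing pool has a 31% chance of
containing a double mutant, a fully symmetric one only 4.2% — a 7.4-fold
protection.  The labels say the asymmetric risk is in its saturated ("D")
regime and the symmetric pool progresses by stochastic tunneling ("ST"):
single-mutant clones mutate (probability `≈ sqrt(2 u1) = 4.4%`) or, far
more often, extinguish.  Monte Carlo (`symdrift pf --config ...`) agrees
within sampling error.

The same machinery at tissue scale — the mouse small intestine as 10^6
independent crypts of 10 stem cells, cycling 10^3 times, with two slow
mutations (1e-6) inactivating a genetic-stability gene followed by one fast
(1e-3) mutation:

```python
>>> from symdrift.analytics import compartment_analytic_risk
>>> for s in (0.0, 1.0):
...     r = compartment_analytic_risk((1e-6, 1e-6, 1e-3), 10, 1000.0, s, 10**6)
...     print(f"s={s:.0%}: per-crypt {r.per_crypt_risk:.3e}  intestine {r.tissue_risk:.4f}")
s=0%: per-crypt 1.317e-06  intestine 0.7322
s=100%: per-crypt 4.377e-07  intestine 0.3545
```

Per-crypt lifetime risks (~1e-6–1e-7, far beyond Monte Carlo) come from the
exact first-passage computation on the crypt's Moran event chain; fully
symmetric division cuts the whole-intestine risk of a triple-mutant stem
cell from 73% to 35%, a 2.07-fold reduction, even though crypt
compartmentalization forces progression through clonal fixations.

Other entry points: `symdrift simulate` (per-run first-passage CSV),
`symdrift pf` (paired risk curves + PF JSON), `symdrift screen`
(random-parameter ensembles), `symdrift oracle` (exact small-system
first passage), `symdrift presets list|show` (tissue presets, including
the human-colon scenarios).

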