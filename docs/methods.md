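# Methods

## The model

A homeostatic pool of `N` stem cells accumulates `K` heritable alterations
("mutations" throughout, standing for any heritable damage, genetic or
epigenetic).  A cell's *stage* is the number of mutations it carries; the
event of interest is the first appearance of a stage-`K` cell anywhere in
the tissue within the organism lifetime `L`, measured in stem-cell cycles.
Mutation is irreversible, at most one locus fires per daughter per division,
and rates `u_i` are per-division probabilities per daughter cell (so all
times are in units of the stem-cell cycle).  Pathways may be an ordered
chain, a set of independent loci firing in any order, or a
background-dependent table in which a locus's rate depends on the genotype
(the genetic-instability scenario); internally all three are compiled to a
genotype transition graph, and the simulators operate on cell counts per
genotype.

Divisions are *asymmetric* (one stem daughter) or *symmetric* (two stem
daughters, or two differentiating daughters that extinguish the stem
lineage).  Homeostasis demands that symmetric renewals and symmetric
extinctions balance on average; `s` is the fraction of divisions that are
symmetric.

### Branching model (large pools)

Discrete synchronous generations: every cell divides once per cycle,
leaving 2 stem daughters with probability `s/2`, 0 with probability `s/2`,
and 1 otherwise.  Each surviving stem daughter advances one genotype step
with its state's per-division probability.  In the baseline model at most
one daughter of a symmetric renewal advances (ties broken uniformly); the
`both_daughter_mutation` variant lets the daughters mutate independently.
Whole-pool extinction ends a run as a failure (it genuinely reduces risk in
small pools).  Generations are advanced with aggregate binomial/multinomial
draws per genotype state, which is distributionally identical to per-cell
simulation.

### Moran model (small pools)

Small pools that hold their size tightly are modeled with a constant-`N`
continuous-time process.  Because renewals and extinctions must balance,
symmetric divisions enter as coupled *pair events* at rate `s N / 2` per
cycle: a divider (chosen proportional to stage fitness `w_i`) renews into
two stem daughters, and one uniformly chosen *other* cell is removed — its
symmetric differentiation balances the renewal, so each pair event accounts
for two symmetric divisions.  Asymmetric division events occur at rate
`(1 - s) N`.  Every cell then divides once per cycle on average, a fraction
`s` of divisions is symmetric, and a rare lineage gains and loses cells at
rate `s/2` per cycle — identical to the branching model, which is why the
two simulators agree wherever whole-pool extinction is negligible
(`N >> s L / 2`).

Two coupling details are deliberate choices, and they matter at `O(1/N)`:

* the removed cell is drawn from the `N - 1` cells *other than the divider*
  (its daughters are not at risk within the same event).  The alternative —
  removal among the `N + 1` cells present after the division — makes rare
  lineages slightly subcritical relative to the branching model and raises
  small-crypt protection ratios by 5–15%;
* a run succeeds the moment a fully mutated daughter is created, before the
  coupled removal is applied.  The exact oracle uses the same convention.

The degenerate `N = 1` pool keeps one uniformly chosen daughter of a pair
event.  Fitness biases only the choice of divider; the division clock is
normalized so the mean fitness-normalized division rate stays at one per
cell per cycle.  Event loops analytically collapse provable no-ops (no
mutation, removal from the divider's own stage), so runs dominated by a
resident stage cost far fewer draws than `N * L`; a per-run event budget
(default 2e8) guards the rare pathological corner, and budget-hit runs are
flagged, never silently dropped.

## Clone fates and derived formulas

The analytic layer rests on the fate of one fresh mutant clone whose next
mutation fires at rate `u` per daughter.  In the continuous limit the
probability `g(t)` that the clone has produced no next-stage cell by `t`
obeys the Riccati equation `dg/dt = (s/2) g^2 - (s+u) g + s/2`, solved in
closed (logistic) form.  From it:

* **lineage mutation probability** `p`: for the discrete-generation model
  the exact fixed point of
  `q = s/2 + (1-s)(1-u) q + (s/2)(1-u)^2 q^2` is used
  (`p = 1 - q ~ sqrt(2u/s)` for `u << s`) — a clone almost surely
  extinguishes before progressing whenever `u << s`;
* **conditional drift time** `tau = ln 2 * sqrt(2/(s u))` to leading order
  (exact logistic integral in code);
* **hazard integral** `I(t) = ∫ (1 - g)`: compounding over the `N u0`
  fresh clones arising per cycle gives the two-stage symmetric risk
  `R_S(t) = 1 - exp(-N u0 I(t))`; its limits are `N u0 u1 t^2 / 2`
  (early/fluctuation regime) and `N u0 p (t - tau)` (steady tunneling).
  At `s = 0` the same expressions collapse to the asymmetric forms, so one
  family covers pure asymmetry, mixed symmetry and pure symmetry.

The exact asymmetric risk never needs approximation: a single lineage is a
`(K+1)`-state Markov chain, `q(t)` follows by matrix iteration, and
`R_A(t) = 1 - (1-q)^{N M}` (log1p/expm1-stable down to ~1e-300).

### Scaled stage sizes

A stage is *stochastic* when clonal extinction outcompetes progression:
its largest clone (of order the stage's mean size) extinguishes faster than
it would progress.  This yields the scaled stage size
`theta_i = <n_i(L)> sqrt(2 u_i / s)`, with `<n_i(L)>` from the linear flux
equations (`d<n_i>/dt = u_{i-1}<n_{i-1}> - u_i <n_i>`; means are
division-pattern independent).  `theta_i < 1` marks a stochastic stage;
stages with `theta_i >= 1` track their means.  With the scaled mutation
rate `u_hat_i = s u_i L^2 / 2`, parameter sets whose lifetime asymmetric
risk sits near 50% obey the collapse `theta ~ K ln 2 / sqrt(u_hat)`, so a
protected (stochastic) penultimate stage forces `u_hat >> 1` — fast late
mutations in rapidly cycling tissue.

### Regimes and the piecewise PF

For two-stage accumulation the symmetric risk has two channels: *stochastic
tunneling* (a clone mutates without fixing; dominant when `N p >= 1`) and
*sequential fixation* (the clone first fixes, in ~`2N/s` cycles, and the
fixed pool then waits `1/(N u1)`; dominant when `N p < 1` *and* the
fixation era fits in the window, `s t > 4N`).  The piecewise analytic PF
evaluates the channel selected by those rules at the time the exact
asymmetric risk first reaches 50% (or at `L`), mirroring how simulated PFs
are ascertained; the asymmetric side uses the smooth hazard
`N u0 (t - (1 - e^{-u1 t})/u1)`, whose limits are the quadratic ("S") and
linear ("D") regimes.  Regime boundaries are smooth crossovers; the label
carries log-distances to both boundaries and results near them are flagged
approximate.

### Compartments and rare events

Tissue risk over `M` independent crypts is `1 - (1 - r)^M` (log1p/expm1
stable).  Per-crypt risks in the tissue presets are of order 1e-8 — far
beyond Monte Carlo — so they are computed deterministically:

* **exact engine** (default for modest state spaces): the Moran event chain
  on crypt compositions over non-absorbing genotypes, uniformized at the
  constant event rate `N (1 - s/2)` per cycle with Poisson event-count
  mixing (series truncated at `mu + 12 sqrt(mu) + 30` terms).  This is the
  simulator's own model solved exactly; the intestinal presets use state
  spaces of 66–1771 compositions;
* **building-block engine** (`sf`, any `N`): a phase-type chain of
  fixation waits (`u_i` per cycle), fixation delays (`2N/s`), a final
  single-cell wait (`N u_{K-1}`), and a last-transition tunneling shortcut;
  absorption CDF by matrix exponential.  It is accurate to a few tens of
  percent near the fixation/tunneling crossover and is cross-checked
  against the exact engine in the tests.

## Protection Factor

`PF = R_A(t*) / R_S(t*)`, a risk ratio at a single time — the quantity
organism-level selection acts on — rather than a mean-first-passage
displacement, which is biologically irrelevant outside the lifespan.  The
default policy sets `t*` to the earliest grid time with `R_A >= 0.5`
(grids have 256 uniform points plus the lifetime endpoint; `t*` snaps to
the grid), falling back to `t* = L`; compartmentalized/rare-risk settings
use the lifetime endpoint, where asymmetric risks are far below 50%.
Monte-Carlo curves run until a success target or a run cap (risk updated
after each run); with ~1e3 successes the lifetime risk is accurate to ~3%,
and the PF standard error follows by the delta method.  When the symmetric
curve records no successes the PF is reported as a rule-of-three lower
bound and flagged.

## Screens

Parameter sets sample `K ~ U{1..10}`, `N ~ logU[1e2, 1e6]`,
`L ~ logU[1e2, 1e4]`, each `u_i ~ logU[1e-8, 1e-2]`, and are admitted when
the closed-form asymmetric lifetime risk lies in (10%, 99.996%) —
rejection-sampled, with the rejection count recorded.  Monotonic modes
resort the sampled rates ascending (or descending); sorted log-uniform
draws accelerate after whichever stage the fast rates land on, emulating
instability acquired part-way along a pathway.  An earlier variant that
sorted only after a random pivot left the decreasing screen substantially
protected, contradicting the defining property of decelerating pathways,
and was discarded.  Pools below 1e4 cells are simulated with the Moran model,
larger ones with the branching model; sets whose predicted Moran workload
(estimated from the deterministic stage means) exceeds 5e6 state-changing
events per run are dispatched to the branching model instead — their
minority stages are macroscopic, which is precisely where the two models
agree.  Records carry the scaled-stage classification (type = number of
stochastic intermediate stages, capped at 3); summaries report the PF > 2
fraction and mean PF by type over complete sets, with incomplete
(budget-hit) sets counted separately.

## What the simulations do and do not emulate

The simulators are the data source for every claim in the package.  They
capture division-pattern stochasticity, multi-stage mutation, selection on
stages, and crypt compartmentalization.  They do not model spatial
structure within a compartment, cell-cycle length variability, feedback
control of pool size (the Moran constraint stands in for it), back
mutation, or phenotypes of intermediate stages beyond a division-rate
fitness.  Conclusions drawn from green tests therefore speak to this
idealized homeostatic regime, not to niche geometry or microenvironmental
effects in real tissue.

## Problem sizes and reproducibility

Unit and acceptance tests use reduced ensembles chosen to keep the full
suite within a desktop-scale run: ~60–100 successful runs per Monte-Carlo
risk curve, screens of 40–150 parameter sets (binomial confidence intervals
at the ensemble level), and 10–12 grid points for the piecewise-formula
accuracy check; `scripts/acceptance.py` uses 150/120-set screens.  All
stochastic entry points take either an integer seed or a
`numpy.random.Generator`; a single master seed makes screen summaries
reproducible bit for bit.  Exact-engine results are deterministic and
seed-independent.

## Known limitations

* Moran coupling conventions (who is at risk of the balancing removal) are
  physically underdetermined at `O(1/N)`; the choice here is fixed,
  documented above, and matched to the branching model's lineage dynamics.
  Small-crypt (`N ~ 10`) risk ratios shift by several percent under the
  alternatives.
* The piecewise PF is an asymptotic patchwork; inside the protected zone
  its fractional error against simulation stays within a few tens of
  percent, but near regime crossovers it is only indicative (and flagged).
* The unordered-loci composite treats the two routes independently and the
  first stage as either fully deterministic or fully stochastic; mid-curve
  accuracy at strongly unequal rates is ~15%.
* The branching exact oracle truncates total population; it returns the
  leaked mass as an error certificate and is intended for toy sizes only.
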