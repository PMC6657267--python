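# Methods

## Model

A cell's state is `σ = {d, m_n, m_m, k}` with `d ∈ {0,1}^m̄_d` the driver
loci, `m_n ≤ m̄_n` the passenger count, `m_m ≤ m̄_m` the metabolic count and
`k ∈ {1..k̄}` the compartment. Three assumptions structure the dynamics:

1. **Mutations are persistent and unique.** A driver locus never reverts;
   each passenger and metabolic mutation is counted once. Every
   proliferation event carries exactly one driver-or-passenger mutation and
   one metabolic mutation, so `m_m` doubles as the lineage's mutational
   age. Proliferation without any mutation is excluded; when a cell has no
   driver or passenger locus left (or `m_m` is at its bound), its division
   attempts are rejected.
2. **Order acts through effectiveness, not acquisition.** Cells mutate
   blindly and uniformly over free loci; the compartment path only decides
   which acquired drivers are *effective*. Effective drivers are counted by
   block-prefix scan over the ordered blocks (S''₁, S''₂, …): complete
   blocks count fully, the first incomplete block counts its acquired loci,
   later blocks count zero. Migration out of compartment `k` requires
   `m_e ≥ |S'_k|`. This keeps the process Markovian in `σ`.
3. **Metabolic mutations accelerate the clock.** The waiting time to a
   cell's next event is exponential with rate `α(r + m_m)`; `1/(αr)` is the
   unmutated cell-cycle mean time.

Action choice is a normalized competition of four channels,
`P_act ∝ A_act · χ_act(s) · k_act(m_e, k)`, with indicator stemness windows
`χ` for the divisions and apoptosis (`χ_pass = 1`) and the migration filter
`k_pass` (`k_asym = k_sym = k_apop = 1`). Stemness is
`s = s̄·m_d/√(1+m_n)`, clipped to `[0, s̄]`: the clip honours the declared
codomain where the raw surface would exceed it; monotonicity (strictly
increasing in drivers, decreasing in passengers) then holds strictly below
the ceiling and weakly at it. The window centers must satisfy
`c_asym < c_sym < c_apop < s̄`; windows may overlap, in which case
amplitudes set the mix.

The driver-vs-passenger split at a division is proportional to the loci
remaining in each class, `p_driver = (m̄_d−m_d)/((m̄_d−m_d)+β(m̄_n−m_n))`.
The model only constrains this split to depend on the accumulated counts;
the proportional form with a single weight β is this package's choice — it
exhausts both classes together for β ≈ m̄_n/m̄_d and lets a scenario slow
driver acquisition with larger β.

## Simulator and its oracle

The simulator is asynchronous and self-clocked: each cell draws its action
at birth (the reactions do not compete, so this is distributionally
equivalent to drawing at firing time) and its timer from the metabolic
clock. Constraint violations "put back" the event: the parent survives
unchanged and redraws timer and action. Because the redraw is memoryless,
a blocked channel contributes zero flux while the others keep their rates —
the simulator is exactly a continuous-time Markov jump process with
per-action rates `α(r+m_m)·P_act` and blocked channels zeroed. The
`reaction_consistent` master-equation generator is built from that
equivalence, which is what makes the simulator-vs-ODE agreement check
well-posed rather than approximate.

The generator's `as_printed` mode instead transcribes the published
physical-time equation term for term (fixed `1/m̄_d` locus prefactor, no
explicit parent loss for asymmetric division). It is retained for fidelity
and documentation; all quantitative checks use `reaction_consistent`.
Boundary handling in both modes suppresses (rather than leaks) mutation
flux that would leave the truncated space, mirroring event rejection.

Integration uses LSODA with rtol 1e-8 / atol 1e-12 and a dense Jacobian
for state spaces up to 2000 states (the packaged oracle scenario has 168).
A guard refuses state spaces beyond a configurable limit (default 2·10⁵).

Randomness: a master seed spawns per-replicate `SeedSequence` children;
within a replicate, draws occur in event order (action, then timer, at
each spawn; mutation type, then locus, at each division). Runs are
bit-reproducible for a fixed seed and replicate count. Ties in event time
are broken FIFO; a drug administration at time t fires before any cell
event scheduled at the same instant, and a record-grid point coinciding
with t_drug reports the post-drug census.

## Constraints

Two admission constraints act per event (all daughters in, or the event is
put back): a capacity on each (compartment, driver-count) class, and an
energy budget `E = Σ_j e(j)·N(j) ≤ E_max` per compartment, with `E_max`
scalar or per-compartment. With unit energies `e(j) = 1` the budget is a
compartment-level carrying capacity; the packaged scenarios use both a
class capacity (20) and a circulatory-system budget (12).

## Packaged scenarios and what they emulate

The three fixtures share the breast → circulatory system → bone chain,
the driver order EPCAM | CD47, CD44 | MET with exit thresholds (1, 3, 4),
and one drug each: case 1 kills every CTC with exactly one driver, case 2
with exactly two drivers, case 3 every CTC carrying CD47. The compartment
chain, driver genes, ordered blocks and drug signatures follow the
published case study; **every kinetic number is calibrated, not
literature-derived** (no amplitudes, windows, rates, capacities or times
are published), and the scenario files say so in their provenance field.

Calibration targets the qualitative regimes at desk scale (tens of cells,
a few simulated time units): α = r = 1; amplitudes 1.0 / 0.8 / 0.25 / 2.0
(asym / sym / apop / pass); windows centred at 0.25 / 0.5 / 0.8 with width
1.0 (jointly covering s ∈ [0,1], so no reachable state is action-free);
β = 6 so driver acquisition is the slow timescale; bounds (4, 20, 15, 3);
N₀ = 15 cells; drug at t = 4 of a 5.5-unit horizon. The load-bearing
mechanism is carrying-capacity competition in the blood: order-free
dynamics floods the circulatory compartment with one-driver cells until
the energy budget rejects its own progression events, while ordered
dynamics admits only EPCAM-bearing cells, stays under budget, and keeps
drug-immune wrong-order reservoirs (high-stemness cells missing only
EPCAM, or blood cells whose third driver is ineffective). Killing the
two-driver CTC pool therefore suppresses bone colonisation under
order-free dynamics — the typical replicate seeds no bone cell at all —
while ordered dynamics keeps seeding, and at matched times ordered
dynamics always carries fewer CTCs because intravasation requires EPCAM.

These are *ordinal* claims, verified as paired sign tests over
100-replicate ensembles; effect sizes are moderate (the case-2 sign test
is significant at 0.05 for typical seeds but not bulletproof for every
seed at n = 100). The desk-scale populations do not emulate absolute
tumour burdens, timescales in days, spatial structure within a tissue, or
immune interactions; passing tests show internal consistency of the
dynamics and the direction of the order-dependence, not clinical
magnitudes.

## Numerical and design choices

* Closed support windows (boundary inclusive); the second step-function
  argument in the window definition is read as `Θ(w/2 − s + c_act)`,
  giving the symmetric interval around `c_act`.
* The ordered-set increment is `S''_k = S'_k \ S'_{k−1}` (the cumulative
  complement), which reproduces the published blocks and makes
  `S''_k = S_k` exactly when the per-compartment sets are disjoint.
* `fraction_targeted` uses exact `fractions.Fraction` arithmetic over the
  enumerated hypercube; viability in ordered mode means "contains every
  locus required to have entered the compartment".
* Monte-Carlo vs ODE comparisons use 3 standard errors with a Poisson
  floor `√(expected/R)` so that groups the ensemble happens to leave empty
  are still comparable.
* Stuck states (no action with positive rate) raise immediately with the
  offending state — they indicate a mis-specified scenario, not a
  recoverable condition. In the ODE generator the same states become
  zero columns (absorbing), since a generator must be total.
* Event rejection is side-effect-free: it does not age the cell or
  penalize it beyond the redrawn waiting time.

## Limitations

* No spatial lattice: cells interact only through compartment-level
  constraints, as the rule set defines no neighbourhood geometry.
* Driver blocks must be disjoint; per-driver gene *sets* sharing genes
  across blocks are not supported.
* The `as_printed` generator is a documentation artefact; its missing
  asymmetric-division loss makes it non-conservative and it should not be
  used for quantitative work.
* Database-driven annotation of metabolic mutations (mutation-impact
  scoring, enrichment analysis) is out of scope; metabolic mutations enter
  only through the clock rate.
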