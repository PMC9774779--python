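# Methods

## Model

One culture is a well-mixed volume containing free phage, infected cells
and uninfected cells.  The dynamics are deterministic mass-action ODEs:
adsorption (`k_ij P_i C_j`) converts a free phage and an uninfected cell
into an infected cell; lysis (rate `λ_ij`) destroys the infected cell and
releases `b_ij` progeny; uninfected cells grow exponentially at rate `r_j`.
The assumptions this encodes, and their limits:

* **Exponentially distributed latent periods.**  Lysis is a first-order
  decay, so latent periods are exponential rather than the near-fixed
  delays of real phages.  Early-lysing infections contribute
  disproportionately while the population is expanding.
* **No phage decay, no desorption.**  A phage in a culture without a
  permissive host keeps its density exactly (`k = 0` for non-permissive
  pairs), matching the heuristic convention of "survival without growth".
* **Unbounded exponential bacterial growth** within a cycle: no resource
  limitation, no stationary phase, no wall populations, and no evolution
  of resistance.
* **Deterministic densities.**  Competition outcomes are selective or
  demographic, never drift; a density can become arbitrarily small without
  being lost (see the extinction floor below).

A phage strain is characterized entirely by its burst sizes per host; all
strains share `λ = 1.0` per time unit and `k = 1e-9` volume per phage per
time.  One time unit is conveniently read as one hour, but all quantities
are dimensionless and no unit conversion is performed.  Burst size is used
as the single stand-in for overall growth-rate differences.

### Serial transfer

A protocol run repeats: build cultures (per the presentation mode), grow
for `cycle_length` (default 20) time units, pool free phage across
equal-volume cultures by summing densities, dilute, reseed with fresh
cells at `cell_renewal_density` (default 1e7 per host).  Defaults are 50
cycles and 1000 total starting phage split equally among the three
strains; the starting total is not critical under fixed-count dilution
(which resets it anyway) and was chosen equal to the fixed-count target so
cycle 1 behaves like later cycles.

* **Parallel**: one culture per host, each seeded with the *full* incoming
  phage density map.
* **Sequential**: one culture; the host alternates each cycle, starting
  from `sequential_first_host` (default A — the convention is arbitrary
  and configurable; for symmetric summaries over full alternation periods
  the choice is immaterial).
* **Mixed**: one culture containing both hosts, each at the renewal
  density.  Hosts are renewed only at cycle boundaries, not continuously.

Dilution modes: `fixed_count` rescales the pool so its total density is
`dilution_count` (default 1000), preserving proportions exactly (it also
rescales *up* if the pool is below target — concentration of the lysate);
`fixed_volume` multiplies every density by `transfer_fraction` (default
0.05); `fixed_count_by_host` (Parallel only) rescales each host culture's
pool to the target separately, then sums, so the combined seed totals
2×1000 — the per-host normalization is the point of the protocol, and no
convention for the combined total changes the relative composition within
either host's contribution.

Infected cells are discarded at transfer by default (phage recovery yields
cell-free lysate).  With `carry_infected`, infected densities are diluted
by the same factor as the free phage of their source culture and seeded
into the next cycle's culture containing that host; infected cells of a
host absent from every next-cycle culture (possible only under Sequential)
are dropped, since the state space tracks infections only for hosts
present.  In practice carrying infected cells does not change retention
outcomes (they are a vanishing share of the pool whenever anything grew).

A density below `extinction_floor` (1e-30) is zeroed after dilution to
avoid denormal drift; an all-zero pool sets an extinction flag on the run
and the remaining cycles proceed trivially.

### Final classification

Final frequencies are each phage's share of the pooled free phage at the
end of the last growth phase, before the final dilution (fixed-mode
dilutions preserve ratios, so the choice does not affect classification).
A phage is *retained* when its final frequency is at or above a threshold,
default 0.01.  The threshold stands in for the detection floor of a
heat-map colour scale; because final frequencies cluster near 0 or well
above 5%, classifications agree across thresholds from 0.001 to 0.05 at
essentially every grid point (the suite measures this).

## Numerics

Two integrators:

* **Fixed-step explicit Euler**, step 0.001 (default).  This mirrors the
  simulation method the scenarios were defined with and is fast enough
  (numba-compiled) to run full burst-size sweeps.  Densities that
  undershoot zero by less than 1e-12 of the current total are clamped to
  zero (roundoff near exhaustion); larger undershoots raise an error
  advising a smaller step.
* **Adaptive LSODA** (`scipy.integrate.solve_ivp`), rtol 1e-8 / atol 1e-6
  by default, rtol 1e-10 as the test-suite reference.  Euler and LSODA
  endpoints agree well within 1% relative error across all canonical
  scenarios; a session-time cross-check against R's `deSolve::lsoda` gave
  identical endpoints to the displayed precision.

Trajectories are sampled at every whole time unit plus the endpoint — fine
enough for the within-cycle dynamics plots, coarse enough to keep output
small.  The constant-cell-density eigenvalue (the positive root of
`s² + (kC+λ)s − kCλ(b−1) = 0`) is exposed as
`exponential_invasion_rate` and matches simulated early-phase log-slopes
to within 2%; it is the growth rate that governs the low-`r` regime in
which cells are never exhausted.

## Sweeps and scenario sizes

Sweeps vary the generalist's two burst sizes over a grid (default 5–25
step 1, from the standard burst-size range) with everything else fixed,
one independent deterministic protocol run per point.  The packaged test
suite uses reduced grids chosen to keep the full suite fast while
preserving the measured quantities: an 11×11 grid (5–25 step 2) for the
retained-fraction measurement — the retained fraction is a ratio of areas
and is stable under this coarsening — and 5×5 grids (step 5) for
qualitative pattern checks.  The acceptance script's quantities are single
50-cycle runs and use the full cycle count.

## Known deviations of printed summary values

The low-growth fixed-count plateau (total phage just above 1e6), the
fixed-volume stationary fold growth (exactly 1/0.05 = 20), and the
fixed-volume peak density (approaching but not exceeding 1e9 per culture)
all reproduce.  The often-quoted "~10^6-fold growth per cycle" for
fixed-count dilution at `r = 0.3` does **not**: exact integration of the
model (Euler, LSODA and an external deSolve check agree) gives per-culture
end-of-cycle densities near 1.5e10 and a pooled fold near 10^7.5.
Analytically, the end-of-cycle phage density is approximately burst ×
cells consumed, and with `r = 0.3` the cell population reaches ~6.5e8
before crashing (around t ≈ 14), giving ~20 × 6.5e8 ≈ 1.3e10; an end
density of 1e9 would require the crash at a cell density these phage
growth rates cannot reach by then.  The package reports the computed
value.

## Design choices where the design was open

* Pooling across equal-volume Parallel cultures is implemented as summing
  densities; under fixed-count dilution only ratios matter, so the
  alternative (averaging) would change nothing downstream except the
  nominal pool density.
* The heuristic ratio functions require the canonical two-host structure
  (two single-host specialists, one two-host generalist) and raise
  otherwise, rather than guessing a generalization.
* `measure_growth_numbers` refuses Mixed-presentation records: a
  generalist's growth on the two hosts of a shared culture is not
  separable, and returning a combined number would silently change the
  meaning of `N_i|j`.
* The "tyranny" report flags hosts where the specialist beats the
  generalist locally (`N_spec > N_gen` on that host) yet has a pooled
  ratio below 1 — the case where Parallel presentation sacrifices the
  poor host's best phage to the generalist's output on the good host.
* The sequential-vs-parallel ratio comparison is encoded with its exact
  validity condition: the generalist's multiplicative advantage dominates
  whenever `(N_AB|A − 1)(N_AB|B − 1) ≥ 1` (in particular whenever it at
  least doubles on each host); when the generalist barely grows on both
  hosts the inequality can reverse.
* Omitting the `kinetics` section of a YAML config selects the symmetric
  baseline (all bursts 15, `r = 0.3`) so that a minimal config naming only
  the presentation mode is runnable with the standard defaults.

## What the simulations do and do not show

All inputs are generated by the scenario fixtures; there is no empirical
data anywhere in the pipeline.  Passing tests show that the implementation
integrates the stated model correctly and that the protocol-level
conclusions (Sequential ≫ Mixed ≫ Parallel in favouring generalists;
demographic purging under fixed-count dilution with slow bacterial growth;
its rescue by longer cycles, fixed-volume dilution, or per-host dilution)
follow from that model.  They say nothing about real cultures, where
discrete lysis times, resource limitation, resistance evolution, spatial
structure and stochastic loss of rare mutants all operate.
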