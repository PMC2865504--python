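# Methods

## The model

`foldevo` simulates the evolution of a protein-coding gene in the
origin-fixation (monomorphic) regime: the product of population size and
mutation rate is small, so the population is a single genotype almost all
of the time and evolution proceeds as a chain of propose-and-fix events.
A mutation arising in one individual either sweeps or is lost; for a
haploid Moran population of size `N` the fixation probability of a mutant
with fitness ratio `r = f_mut / f_wt` is

    p_fix(r, N) = (1 - 1/r) / (1 - r^(-N)),      p_fix -> 1/N  as r -> 1,

and the simulation uses this closed form directly as the per-proposal
acceptance probability.  Time is therefore indexed by proposal events and
trajectories by accepted substitutions.

**Mutation.**  Nucleotide mutations follow the HKY process with
transition/transversion ratio `kappa` (default 4, the conventional
estimate).  Chargaff's second parity rule is imposed on the stationary
base frequencies, `f_A = f_T = (1-gc)/2` and `f_C = f_G = gc/2`, so the
mutation model has a single compositional parameter: the **GC usage**
`gc`.  Each proposal draws a site with probability proportional to the
total outflow rate of its resident base, then a target base proportional
to the corresponding rate.  Proposals creating a stop codon are assigned
fitness 0 and are therefore never accepted; this keeps the proposal
measure exactly HKY rather than silently redrawing.

**Phenotype.**  The phenotype of a sequence threaded on a fixed native
contact map (heavy-atom cutoff 4.5 Å, minimum chain separation 3 by
default) is a pair of folding stabilities:

* unfolding stability `dG_unf = -(E_nat + s_conf * L)`, with
  `E_nat = sum_contacts U(a_i, a_j)` the native contact energy and
  `s_conf` the conformational entropy per residue;
* normalized energy gap `alpha = (E_REM - E_nat) / |E_REM|`, where
  `E_REM = N_c * Ubar - sigma_U * sqrt(2 * N_c * omega * L)` is the
  random-energy-model estimate of the lowest-lying misfolded compact
  conformation, built from the mean and standard deviation of `U` over
  *all* residue pairs at chain separation >= 3 (native and non-native),
  with `omega` the log-number of alternative compact conformations per
  residue.  The normalizer is switchable to `|E_nat|`
  (`EnergyModel.gap_normalizer`).

The two stabilities respond oppositely to amino-acid composition: a more
hydrophobic composition deepens the native energy (raising `dG_unf`) but
deepens the misfolded ensemble even faster (lowering `alpha`).  Because
AT-rich codons encode the strongly hydrophobic residues, GC usage tunes
this trade-off — the central mechanism of the whole model.

**Fitness.**  Stabilities are normalized by neutral thresholds anchored
to the reference (native) protein, `x = dG_unf / (c_dG * dG_ref)` and
`y = alpha / (c_alpha * alpha_ref)`, and mapped to fitness through a
neutrality exponent `beta`.  Any state with `x <= 0` or `y <= 0` is
lethal (the protein does not fold).  Five functional forms are
implemented:

| form            | definition (viable states)                         |
|-----------------|----------------------------------------------------|
| `power_clipped` | `(min(x,1) * min(y,1))^beta`                       |
| `power`         | `min((x*y)^beta, 1)`                               |
| `exponential`   | `exp(-beta * [(1-min(x,1)) + (1-min(y,1))])`       |
| `min_only`      | `min(x, y, 1)^beta`                                |
| `hill`          | `[x^b/(1+x^b)] * [y^b/(1+y^b)]`                    |

All forms recover threshold (neutral) models in both limits `beta -> 0`
and `beta -> inf`.  The forms with a hard ceiling are exactly flat above
the thresholds, which makes the stationary stability approach a
beta-independent plateau monotonically.  The `hill` form instead
saturates smoothly: its above-threshold selection gradient scales as
`beta * x^(-beta-1)`, vanishing in both beta limits and maximal at
intermediate beta.  Only a smoothly saturating form can produce the
regime structure in which mean stability *peaks* at intermediate
neutrality exponent and declines again when selection differentials
between stable variants become too small to beat drift; the `hill` form
is therefore the default for the package's own toy-system studies, with
the clipped forms retained as variants.

## The statistical-mechanics layer

The origin-fixation chain with HKY proposals is reversible, and the
identity `p_fix(r) / p_fix(1/r) = r^(N-1)` pins its stationary law to a
Boltzmann measure

    P(seq)  ∝  pi_HKY(seq) * f(seq)^(N-1),

with population size in the role of inverse temperature.  Projected on
`(x, y)` this reads `P(x,y) ∝ exp[(N-1) * log f(x,y) + S(x,y)]`, where
the **mutational entropy** `S` is the log-density of the stabilities
under mutation alone — the entropic force pulling the protein toward
what random sequences typically achieve.  The maximizer `(x*, y*)` of
the exponent solves the maximum-likelihood equations and predicts the
stationary means when the distribution is narrowly peaked;
`ml_solve` locates it on a grid, refines it with a local quadratic fit,
and checks that the Hessian is negative definite (reporting the Gaussian
approximation's covariance `-H^{-1}`).

Two estimators of `S` are provided.  `estimate_entropy` is a plain 2-D
histogram (40x40 by default, empty cells masked) and is adequate in the
bulk.  The stationary region at moderate `N`, however, lies several
standard deviations into the mutation-only tail where no direct sample
lands; `umbrella_entropy` therefore combines the mutation-only sample
with runs of the evolutionary dynamics at smaller population sizes,
whose stationary laws tilt the mutation measure by the *known* factor
`exp[(N'-1) log f]`, and removes the bias with the standard
multiple-histogram (WHAM) estimator.  Trajectory samples enter weighted
by their residence time in proposal events, so they follow the chain's
occupancy measure.  A parametric Gaussian extrapolation of `S` was
evaluated and rejected: the true entropy is truncated by the achievable
Pareto front of the two stabilities and a Gaussian tail overshoots the
predicted stabilities badly.

**Exact oracle.**  On toy genes of at most 3 codons the full sequence
space is enumerable; `enumerate_stationary` builds the origin-fixation
transition matrix explicitly as a uniformized chain, `P = I + Q/Lambda`
with rates `q_HKY(a->b) * p_fix`, solves for its stationary vector by
linear algebra, and compares with the analytic
`pi_HKY * f^(N-1)` form.  The per-proposal simulation chain normalizes
site choice by the sequence-dependent total mutational outflow `R(s)`;
its occupancy law carries an extra `R(s)` weight, which is constant (and
hence immaterial) at `gc = 0.5`.  Simulation-versus-oracle frequency
comparisons are therefore run at `gc = 0.5`; the uniformized chain is
exact at every `gc`.

**Optimal GC usage.**  For fixed `(N, beta)` the stationary mean fitness
is simulated over a grid of 9 GC usages (0.1 to 0.9), fitted with a
cubic, and the optimum taken at the interior root of the derivative that
is a maximum; monotone fits return the boundary GC with a flag.
`fixability_gap` reports `N * |delta mean log-fitness|` between two
mutation biases — above 1, the advantage of the better bias exceeds the
drift barrier and is itself selectable.

## The standard synthetic study system

All package-level analyses run on one fixed system
(`foldevo.study.make_study_system`):

* **Structure**: a 30-residue compact self-avoiding chain on the cubic
  lattice (generator seed 1), 28 contacts at chain separation >= 3.
  The generator grows chains with a compactness bias and regrows until
  the contact density is within 25% of the requested value
  (1.0 contacts/residue by default); it stands in for a PDB structure so
  that everything runs without downloads.
* **Energetics**: the synthetic hydrophobicity outer-product potential
  `U(a,b) = -h'_a * h'_b`, with `h'` the Kyte-Doolittle scale affinely
  rescaled to [0.5, 1.5]; `s_conf = 0.85`, `omega = 0.03`.  The affine
  offset gives every contact the uniform attractive background that
  knowledge-based potentials have.  These three constants were fixed
  once, at the unique region of parameter space where the model's
  qualitative premises all hold simultaneously in this toy: under
  mutation alone, mean `dG_unf` is positive only at small GC and
  decreases with GC while mean `alpha` is negative everywhere and
  increases with GC; under selection at fixed `N`, the evolved ensemble
  shows the same trade-off; and the viable region `alpha > 0` is
  reachable by mutation-only sampling (probability ~3e-2 at gc 0.5), so
  the mutational entropy is estimable.  With larger offsets the selected
  hydrophobic-core/hydrophilic-surface sequences *raise* the pair-energy
  heterogeneity `sigma_U` and invert the evolved gap-versus-GC direction.
* **Reference**: a designed sequence standing in for the PDB native
  (synthetic; greedy two-phase hill-climb that first locates the
  separately achievable maxima of the two stabilities on this map, then
  maximizes the balanced minimum).  Native sequences sit near the
  achievable Pareto front, and anchoring the thresholds to such a
  reference is what puts the evolving population *below* threshold where
  selection acts.
* **Fitness**: `hill` form, `beta = 3`, threshold coefficients
  `(c_dG, c_alpha) = (0.5, 0.95)`.  The asymmetry implements the
  model's requirement that the misfolding margin be the selectively
  binding coordinate as `N` grows (the selective pressure is stronger on
  the smaller normalized stability); with symmetric coefficients the
  binding coordinate in this 30-residue toy is unfolding at every `N`
  and the optimal GC stays pinned at the AT boundary.

**What the toy does and does not show.**  Passing tests on this system
demonstrate the model's internal structure — exact fixation
probabilities, the Boltzmann stationary law, the hydrophobicity link,
monotone responses to `N`, the stability trade-off in GC, the
intermediate-`beta` stability peak, ML-theory consistency, and the
rise of the optimal GC usage from strongly AT at small `N` toward and
beyond parity at large `N`.  They do not calibrate any real protein:
the contact potential is synthetic, a 30-residue lattice chain is far
smaller than real domains, and selection coefficients (hence the `N`
scale of every transition) depend on both.  Real-sequence work should
supply a PDB structure and a published 20x20 contact matrix
(`load_energy_matrix`), recalibrating `s_conf` so mean unfolding free
energies match — the package's supported recipe for swapping energy
parameter sets.

## Problem sizes and numerical choices

Simulation analyses use 400-800 accepted substitutions per replica after
a burn-in of 150-300 (the default burn-in is `5 * L` accepted
substitutions, a few protein lengths), with 3-8 replicas seeded
`seed + replica`; standard errors are computed across replica means.
These sizes were chosen so the full analysis battery runs on a desk
machine in minutes; the trends they test are all large compared with the
resulting standard errors.  The engine maintains per-position tables of
contact-energy and pair-statistic sums, giving O(1) stability queries
per proposal and O(L) updates per (rare) acceptance; agreement with
from-scratch recomputation to 1e-9 is a tested invariant.  Fixation
probabilities are evaluated in log space to avoid overflow for strongly
deleterious mutants; the neutral point uses the exact `1/N` value inside
a 1e-12 window around `r = 1`.  WHAM iterations run to a 1e-9 tolerance
on the component log-normalizers; lethal grid cells enter with a large
finite negative log-fitness so that zero-tilt components remain
well-defined.  Degenerate inputs (empty contact sets, single eligible
pairs, zero-variance samples, monotone GC scans) either take documented
special values or raise; the 2-codon oracle toy uses a fitness variant
(`use_gap=False`) that ignores the gap coordinate, because a 2-residue
map has a single eligible pair and its REM gap is identically zero.

## Known limitations

* Monomorphic limit only: polymorphism, hitch-hiking and quasi-species
  effects at `N*mu >~ 1` are outside the model.
* The mutational entropy is estimated, not derived; ML predictions
  inherit histogram resolution and the narrow-peak approximation.
* The optimal-GC curve is resolved up to `N ~ 10^3` at the default
  problem sizes; its expected return to parity at still larger `N`
  (where stabilities saturate and the GC dependence of fitness flattens)
  is increasingly expensive to measure because acceptance rates scale
  as `1/N`.
* The genomic survey consumes user-supplied TSV tables; reproducing
  published survey values requires the corresponding published tables,
  which the fixtures only emulate structurally.
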