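# Methods

## State model

A system is a reaction network over species that are either *dynamic*
(simulated counts) or *clamped* (chemostatted boundary conditions).  The
microscopic state is the vector of dynamic counts.  Its unnormalized log
mass density, in units of k_BT, is

    log w(n) = log N! − Σ_j log n_j! − Σ_j n_j μ̂_j

with N the total dynamic count and μ̂_j = μ⁰_j/RT the reduced standard
chemical potential (internal degrees of freedom are disregarded, so
log q_j = −μ̂_j).  The identity log w = S_config − E/k_BT, with
S_config = log(N!/Π n_j!) the configurational (Boltzmann) entropy and
E/k_BT = Σ n_j μ̂_j, holds exactly and is asserted on every pathway-profile
step.  In the normalized mode the Boltzmann factors are replaced by the
probabilities θ_j = e^(−μ̂_j)/Σ e^(−μ̂_k); the resulting weights sum to one
over all compositions of N and define the closed-system ensemble used for
Gibbs entropy, equilibrium identities and sampling tests.  Factorials are
evaluated through log-gamma everywhere in production code; exact
big-integer factorial arithmetic appears only in test oracles.

### Clamped species as reservoirs

Clamped species are ideal chemostats: they contribute chemical-potential
terms only, not combinatorial ones, and their counts are reset to
`clamp_count` after every move (`clamp_count` also bounds how much of a
clamped species one firing may consume).  The likelihood ratio of a move is
evaluated on the raw post-move state *before* re-clamping, so a reaction
that converts NAD⁺ to NADH picks up the full μ̂_NADH − μ̂_NAD⁺ even though
the counts are immediately restored.  This is what turns fixed cofactor
levels into a sustained non-equilibrium driving force.  A consequence used
throughout: around any full cycle traversal the cumulative Δ𝒜 telescopes
exactly to the net clamped-species potential change of the overall
reaction, independent of the intermediate counts.  The alternative —
keeping clamped counts inside the multinomial coefficient — breaks that
telescoping identity and makes the boundary force depend on the arbitrary
clamp level, which is why the reservoir idealization was chosen.

## Markov simulation

Chain time is the event count; no physical-time calibration is attempted,
since absolute rates would require exactly the rate constants the method
avoids.  Moves are single reaction firings (compound moves are never
proposed; this is also what keeps the summed TCA intermediate count within
±1 — here exactly constant, since every cycle reaction converts one
intermediate into one intermediate).

Two kernels:

- **metropolis** — propose uniformly among the 2R directed reactions,
  accept with min(1, e^(−ΔS_g)); infeasible proposals count as rejected
  self-transitions.  In a closed system this satisfies detailed balance
  with respect to the multinomial-Boltzmann mass (verified exactly on the
  enumerated N = 6 toy system) and is used for all equilibrium checks.
- **odds** — select among the feasible directed reactions with probability
  proportional to e^(−ΔS_g); the chain always moves.  This implements
  rates proportional to the thermodynamic driving force and is the kernel
  used for driven steady-state work.  It does not leave the equilibrium
  distribution exactly invariant (it is an always-move kernel), which is
  the recorded trade-off for being driving-force-proportional.

Randomness comes from a single seeded PCG64 generator per trajectory;
identical inputs give byte-identical output files.  A state with no
feasible event raises a deadlock error naming the step, never a silent
loop.

## Equilibrium identities

With the symmetric uniform proposal kernel, the equilibrium average of
e^(−ΔS_g) over proposed transitions is exactly 1 *provided* infeasible
proposals are counted as identity transitions (ΔS_g = 0); dropping them
breaks the identity at boundary states, so they are included.  The average
of ΔS_g over realized Metropolis transitions is exactly 0 because the
stationary pair measure is swap-symmetric under detailed balance.  Both
are computed by exact enumeration and hold to 1e-10.

## Maximum-entropy steady states

The path entropy of a traversal Γ of Z reactions from state S is
−Σ Pr(S_{i−1}+δS_i) log Pr(S_{i−1}+δS_i), with the chained reading
(successive terms update the state) as the default and a `shared_base`
flag for the fixed-base alternative.

The steady-state optimizer asks: which composition of a fixed dynamic pool
makes every reaction as close to equally likely as the boundary conditions
allow?  Each reaction is applied in both directions to the shared candidate
state (the equal-likelihood criterion is direction-symmetric), giving a
likelihood per directed reaction; the objective is the entropy of the
*normalized* likelihood distribution, which attains its maximum log Z
exactly on the equal-likelihood manifold.  The raw −Σ P log P objective
was rejected because its −p log p weighting pulls the optimum slightly off
the equal-likelihood point whenever the likelihoods sit below 1/e (for the
symmetric three-species chain it prefers (3.98, 4.04, 3.98) over
(4, 4, 4) while leaving a spurious 0.015 residual); the normalized form
recovers the symmetric optima exactly and reports the raw path entropy of
the optimal neighborhood alongside.  The continuous relaxation uses
log Γ(n+1) — the exact smooth extension of log n!, preferred over
Stirling's approximation because it stays accurate at the small counts the
pool scans probe.  Optimization is multi-start SLSQP (8 seeded Dirichlet
starts plus the uniform start) under the pool equality constraint, with
lower bounds keeping every directed reaction applicable.  The result
reports the equal-likelihood residual (max |log P_i − mean|, tolerance
1e-6) and a convergence flag; non-convergence returns the best iterate,
never an exception.

## Analysis conventions

- **Flux statistics**: ΔS_g per reaction is evaluated in the forward
  direction at a single reference state (default: the rounded trajectory
  mean, recorded in the output); odds J₊/J₋ are reported as NaN when
  J₋ = 0 rather than as infinities.
- **Flux–free-energy diagnostic**: reports Δ𝒜/k_BT next to −log(J₊/J₋)
  and their difference; the relation is an assumption, not an identity,
  and the diagnostic makes no equality claim.  It is most concordant for
  reactions closest to equilibrium, which the tests verify by a median
  split on |Δ𝒜|.
- **Reversal odds**: passages K→J and J→K are counted over densely
  recorded snapshots within a window; the log odds uses +1 Laplace
  smoothing (raw counts reported) and is computed as
  log(f+1) − log(r+1) so that swapping the pair negates it bit-exactly.
- **Concentration scans**: the dynamic pool is rescaled per fold by
  largest-remainder apportionment, the driven chain is run with a
  deterministic per-fold child seed (fold 0 reuses the parent seed), and
  stationarity is approximated by discarding a fixed 20 % burn-in —
  deterministic and reproducible, in preference to a convergence test.
  Profiles at the stationary mean use the dilute (mole-fraction) limit
  ΔG_r/RT = Σ δ_j μ̂_j + Σ δ_j log x_j with x floored at 1e-9, because at
  the smallest pools the rounded mean state makes integer traversals
  infeasible.  A fold whose pool rounds to zero particles is flagged, not
  simulated.

## Fixtures and the synthetic-data choices

The A⇄B⇄C fixture is the closed three-species chain used for every exact
enumeration (its N = 6 state space has C(8,2) = 28 compositions).

The TCA fixtures place eight dynamic intermediates (citrate → oxaloacetate)
in an eight-reaction cycle with clamped AcCoA, CoA, NAD⁺/NADH, Q/QH₂, CO₂,
H₂O and, per variant, ADP/ATP/Pi or a ferredoxin pair.  One oxidative turn
reproduces the overall reaction AcCoA + ADP + 3 NAD⁺ + Pi + Q + 2 H₂O →
CoA + ATP + 3 NADH + 2 CO₂ + QH₂, and this stoichiometry is pinned by a
packaged test.  Intermediates start at 20 particles each under the default
volume scale of 1 particle ≙ 1 μM (a bookkeeping choice, not a physical
claim; `pool_scale` and `particles_per_uM` rescale it).  Clamp counts
default to 100 and act only as feasibility bounds.

No measured potentials are shipped: all μ̂ values are synthetic, chosen
once for qualitative fidelity and tagged SYNTHETIC in file headers.  The
choices encode: strong oxidative boundary driving for the heterotroph
(−17 k_BT per turn) and the cyanobacterial variant (−19 k_BT), reversed
driving for the green-sulfur variant (+18.5 k_BT, so the cycle runs
oxaloacetate → citrate); citrate and succinyl-CoA lowest among the
intermediates, so that small total pools condense onto them; and a
ferredoxin pair replacing the NAD⁺/ADP couple in the cyanobacterial
2-oxoglutarate → succinate segment, with no adenylates in that network at
all.  What passing tests show is therefore the *structure* of the physics
— driving directions, conservation laws, compensation identities, pooling
and spread trends — not organism-specific numbers, which would require
measured potentials the fixtures do not contain.

## Problem sizes and defaults

Exact enumeration is used up to a configurable cap (default 2×10⁶ states).
Sampling checks use 10⁶ Metropolis events on the N = 10 toy system
(total-variation distance < 0.02 against the enumerated distribution);
driven TCA runs use 2×10⁴–10⁵ events; pool scans use 2×10⁴ events per fold
at pool_scale 10 (1600 particles at fold 1, 2 at fold 0.001).  Default
temperature is 298.15 K; thermal-energy checks against the room-temperature
value 2.45 kJ/mol set T = 295 K explicitly.

## Known limitations

- The odds kernel is one concrete reading of "rates proportional to the
  thermodynamic driving force"; the underlying scheme is not fully
  specified and other normalizations are possible.  The dual-mode design
  records this ambiguity instead of hiding it.
- Event-count time cannot be converted to wall-clock kinetics.
- Clamped reservoirs are ideal: no depletion, no fluctuation in cofactor
  pools.
- The maxent objective is not guaranteed concave for clamped networks;
  multi-start local ascent reports the best iterate and its residual, not
  a global certificate.
- Continuous (concentration-valued) partition functions, activity
  coefficients, pH/ionic-strength transforms and SBML i/o are out of
  scope.
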