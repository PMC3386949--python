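# Methods

This note records the models implemented in `cutoffmd`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know about.

## Units and constants

Lengths in Å, time in fs, mass in amu, energy in kcal/mol, charge in units
of the elementary charge. `k_B = 0.0019872041 kcal/mol/K`; the Coulomb
constant is fixed at `k_e = 332.0636 kcal·Å/mol/e²` (the conventional MD
value; alternatives differ in the fifth decimal and would shift nothing at
the accuracy considered here). One amu·Å²/fs² is 2390.0574 kcal/mol; this
factor converts forces to accelerations and velocities to kinetic energy.

## Periodic geometry

The box is cubic with the origin at a corner. Positions may drift outside
`[0, L)` during dynamics and are wrapped only inside distance computations
(`d -> d - L*floor(d/L + 1/2)`, putting every component in `[-L/2, L/2)`),
never destructively — trajectories stay continuous for analysis. Pair
enumeration is a vectorized O(N²) minimum-image scan; at the intended scale
(N ≲ a few hundred) a cell list would not pay for itself. All cutoffs must
satisfy `r_c < L/2` (minimum-image validity) and are enforced.

## Nonbonded schemes

* **LJ**: hard truncation at the cutoff, no switching function and no
  long-range dispersion correction. The truncation discontinuity is a
  deliberate property of the scheme under study, not an artifact to smooth
  away; its energetic signature shows up in the NVE drift numbers below.
* **TRUNC**: `k_e q_i q_j/r` inside the cutoff, zero outside.
* **SHIFT**: the pair force is `k_e q_i q_j (1/r² - 1/r_c²)` — zero at the
  cutoff by construction. The scheme is defined on forces; the energy used
  for bookkeeping and integration is the integral of that force with
  `U(r_c) = 0`, i.e. `k_e q_i q_j (1/r + r/r_c² - 2/r_c)`, making the
  implementation conservative by construction.
* **EWALD**: the exact classical sum — erfc-screened real space over pairs
  within the cutoff, a reciprocal sum over integer wave-vectors with every
  `|n_i| <= kmax`, the self term, and an analytic erf correction removing
  excluded pairs from the (all-pairs) reciprocal contribution. A mesh-based
  k-space variant would only approximate this sum; at desk scale the exact
  sum is both cheaper to verify and strictly more accurate, and the mesh
  resolution of mesh methods maps onto `kmax` as an accuracy dial. Systems
  with nonzero net charge are rejected rather than background-corrected:
  the uniform-background convention is untestable against any fixture used
  here, and every built-in generator produces neutral systems.

`tune_ewald(system, cutoff, target_rms)` searches kmax ascending (1..16 by
default) over a fixed grid of splitting parameters
`alpha ∈ {2.5, 3.0, 3.5, 4.0}/r_c`, accepting the first candidate whose rms
force error against a high-accuracy reference (same alpha, kmax doubled,
real-space cutoff just under L/2) meets the target. Ascending kmax makes
the search deterministic and monotone: a tighter target can never return a
smaller kmax.

## Integrator stack

Velocity Verlet underneath a two-tier RESPA split: the Ewald reciprocal and
self terms (the long-range component) are kicked on the outer step (default
5.0 fs), while real-space electrostatics, the exclusion correction, LJ and
bonded terms advance on the inner step (default 2.5 fs). For TRUNC/SHIFT
there is no long-range component and the integrator degenerates to plain
velocity Verlet at the inner timestep. `n_steps` counts outer steps.

The thermostat is a single Nosé-Hoover chain with mass
`Q = N_df k_B T τ²`, `τ` defaulting to 10 ps at 360 K; the friction
variable is integrated with quarter-step updates around the velocity
scaling, applied as half-kicks on either side of each outer step. Degrees
of freedom are `3N - (number of rigid bonds) - 3` (center-of-mass momentum
is removed at velocity initialization). Chain length 1 is a design choice:
nothing here requires the ergodicity repair of longer chains, and the
extended-system conserved quantity
`KE + PE + Q ξ²/2 + N_df k_B T η` is tracked per frame as a diagnostic
(drift ≈ 0.06% over 100 ps at 1 fs on a smooth bonded-only system; on LJ
fluids the truncation discontinuity dominates it).

Constraints use iterative SHAKE (corrections along the pre-step bond
vectors, convergence to a relative tolerance, default 1e-8, with an
explicit failure naming the worst constraint) plus RATTLE-style velocity
projection after each step. A direct matrix solve would converge in one
pass for the small constraint sets used here; the iterative form satisfies
the same contract and is simpler to verify against the analytic two-body
solution.

Velocity initialization is a Maxwell-Boltzmann draw with COM momentum
removed, deterministic given the seed; `run_simulation` performs it
automatically when handed a system with all-zero velocities.

## Trajectory analysis

* **State assignment** is dual-threshold hysteresis on the RMSD series:
  crossing below the folded threshold (default 2.5 Å) enters FOLDED,
  above the unfolded threshold (default 6.0 Å) enters UNFOLDED; the band
  between them never changes the state, so rapid recrossings are
  suppressed. Frames before the first crossing are TRANSIT. One event is
  recorded per state change, spanning from the last frame beyond the old
  threshold to the first frame beyond the new one; the initial entry into
  a state is not an event. The default thresholds are explicit package
  choices for the synthetic emitter's scales, not measured constants.
* **Free energy**: `ΔG = -k_B T ln(P_f/P_u)` over non-TRANSIT frames, so a
  destabilized folded state gives a larger positive ΔG. The standard error
  comes from blocking on the per-frame folded indicator, propagated as
  `k_B T · sem(p)/(p(1-p))`.
* **Blocking** follows Flyvbjerg-Petersen pair averaging down to 16 blocks.
  The SEM estimate at each level carries uncertainty `sem/sqrt(2(n-1))`;
  the reported value is the largest SEM among levels whose increase over
  the previous level lies within that level's own uncertainty (the
  plateau). If no level qualifies the deepest estimate is returned and
  flagged unconverged. Stopping at 16 blocks keeps the level uncertainty
  itself meaningful; against closed forms the estimator lands within ~10%
  for iid noise (n = 4096) and AR(1), ρ = 0.9 (n = 2¹⁶), seed-averaged.
* **Helicity** is a φ/ψ-window rule: a residue is helical iff
  φ ∈ [-100, -30], ψ ∈ [-67, -7] and it belongs to a run of ≥ 4
  consecutive such residues; turns are helical residues / 3.6. This
  replaces a full secondary-structure assignment program on purpose — only
  helix detection is needed — and will disagree with such programs at helix
  termini and for distorted helices.
* **KL divergence** uses fixed shared bin edges spanning both samples
  (12 bins over the Rg span, 6 per turn axis by default) and a pseudocount
  of 1/(reference count) in every bin of both histograms before
  normalization, so empty reference bins cannot produce infinities. The
  histogram estimator is biased upward for finite samples — hence the
  "statistical floor" reading of same-generator divergences (~0.015 nats at
  ~7·10⁴ unfolded frames).
* **Helix formation order**: within each folding event window, a helix
  forms at the first frame where its turn count reaches ≥ 80% of its
  folded-state mean and stays there through the event's end; ties break by
  helix index; events where some helix never forms are excluded and
  counted. The 80%-sustained rule is this package's operational definition.

## Synthetic two-state generator

The folding-trajectory stand-in is a hidden two-state Markov chain
(per-frame transition probabilities, defaults `k_fold = 0.0009`,
`k_unfold = 0.0021`, stationary folded fraction 0.3 — a mildly
destabilized folded state, ~120 completed events per 10⁵ frames) emitting:

* RMSD and Rg as state-conditional Gaussians (folded 1.8 ± 0.4 Å vs
  unfolded 8.0 ± 0.8 Å RMSD; Rg 9.0 ± 0.4 vs 11.0 ± 1.0 Å, mirroring a
  compact folded state below a modestly expanded unfolded one);
* at every hidden switch, a transit window (48 frames) over which the
  emission means and sds relax from their *current* values toward the new
  state's — with a square-root-in-time profile (fast initial relaxation,
  slow settling), which keeps rapid recrossings continuous and places both
  threshold crossings well inside the window;
* three helix-turn channels ramping linearly (10 frames) from baseline
  (0.2 turns) to per-helix plateaus (2.2/1.7/1.9 turns) with prescribed
  per-helix lags inside each folding window — defaults (6, 20, 13) frames,
  i.e. order "132" — or a per-event lag-set mixture when a whole order
  distribution is prescribed.

Ground truth records the per-frame labels, the true ΔG, and — read off the
noiseless emission curves with the same sustained-80% rule the analysis
uses — the per-event order labels. True events count only *completed*
transitions: a switch whose transit window finishes before the next switch.
Micro-excursions shorter than the window never reach the other state's
emission levels, and no transition-based assignment could (or should)
count them; the hysteresis detector's recall is therefore measured against
resolvable events.

What the generator does **not** emulate: real RMSD/Rg distributions are
neither Gaussian nor state-homogeneous; real transition paths are not
monotone relaxations; helix formation is stochastic per event rather than
lag-deterministic; and channel noises are uncorrelated here but strongly
coupled in real trajectories. Passing recovery tests therefore demonstrates
the estimators' correctness and calibration on a controlled model — not
that real trajectories satisfy the model.

## Problem sizes and defaults used in validation

The validation and acceptance runs use desk-scale systems chosen so the
full suite completes in minutes on one core: an 8-ion rock-salt cell for
the Madelung check (relative accuracy ~3·10⁻⁷ at α = 2.0/Å, kmax = 14), a
100-particle random neutral box (40 Å) for force-error sweeps, 32-particle
argon-like LJ fluids for conservation/thermostat checks (20 000 NVE steps
at 1 fs; three 50 ps thermostat runs), a two-particle constrained diatomic
for SHAKE (10⁴ steps), 10⁵-frame synthetic trajectories for the analysis
chain, and 100 ps NVT runs of a 50-particle charged box (ion-like LJ cores,
σ = 3.0 Å, ε = 0.2 kcal/mol, so contact ion pairs have physically stiff
but integrable wells) for the end-to-end smoke chain.

## Known limitations

* O(N²) pair enumeration and an exact Ewald sum bound practical system
  sizes to a few thousand particles.
* Cubic boxes only; no pressure/virial, no barostat.
* Hard LJ truncation injects energy at cutoff crossings; NVE conservation
  on LJ fluids is limited by the scheme itself (~0.01 kcal/mol/particle
  over 20 000 steps), not by the integrator.
* The PDB/XYZ readers recover coordinates and topology hints only; no
  force-field assignment is attempted — nonbonded parameters always come
  from a JSON system file or a generator.
* The helicity rule and the formation-order detector are operational
  definitions; their outputs are comparable within this package but not
  interchangeable with STRIDE/DSSP-based numbers.
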