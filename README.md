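# cutoffmd

Quantify what cutoff-based approximations of nonbonded interactions do to
molecular-dynamics simulations — at desk scale.

Biomolecular MD spends most of its time on pairwise electrostatics and van
der Waals forces, and production codes routinely approximate them: ignore
every interaction beyond a cutoff `r_c`, shift the Coulomb force so it
vanishes continuously at `r_c`, or split the Coulomb sum into a short-range
part plus an Ewald long-range part. These choices measurably shift folding
free energies and, more strongly, the structural properties of unfolded
protein ensembles. `cutoffmd` packages both halves of that investigation in
a small, fully testable form:

* a minimal periodic NVT engine in which the three electrostatics
  treatments can be swapped while everything else is held fixed, and
* the trajectory analytics used to compare folding simulations —
  transition-based state assignment, population free energies with blocking
  errors, unfolded-state structure, ensemble divergences, and
  helix-formation-order statistics —

together with synthetic builders (ionic lattices, LJ fluids, random neutral
charge boxes, toy backbone chains, two-state folding emitters) so that every
claim is validated against a known ground truth. It is a library first
(`import cutoffmd`, see `examples/`), with a thin `cutoffmd` CLI for
shell-driven runs.

## The models

**Nonbonded schemes.** Lennard-Jones interactions
`4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6]` are hard-truncated at `r_c`
(Lorentz-Berthelot combining). Electrostatics is one of:

* `TRUNC` — `k_e q_i q_j / r` for `r <= r_c`, nothing beyond;
* `SHIFT` — pair force `k_e q_i q_j (1/r^2 - 1/r_c^2)`, exactly zero at the
  cutoff, with the conservative energy
  `k_e q_i q_j (1/r + r/r_c^2 - 2/r_c)`;
* `EWALD` — the classic decomposition
  `sum_pairs k_e q_i q_j erfc(alpha r)/r`
  `+ (2 pi k_e / V) sum_{k != 0} exp(-|k|^2/4 alpha^2)/|k|^2 |S(k)|^2`
  `- k_e alpha/sqrt(pi) sum_i q_i^2`, with an analytic correction for
  excluded pairs; accuracy is a dial (`tune_ewald` picks `alpha`, `kmax`
  for a requested rms force error).

**Integrator stack.** Velocity Verlet with a two-tier RESPA split (Ewald
reciprocal + self terms on the outer 5.0 fs step, everything else on the
inner 2.5 fs step), a single-chain Nosé-Hoover thermostat
(`Q = N_df k_B T tau^2`, default 360 K / 10 ps), and iterative SHAKE with
RATTLE velocity projection for rigid bonds.

**Analytics.** Cα-RMSD time series are segmented with a dual-threshold
hysteresis rule (below 2.5 Å ⇒ folded, above 6.0 Å ⇒ unfolded, band
excursions suppressed); `ΔG = -k_B T ln(P_f/P_u)` with a
Flyvbjerg–Petersen blocking standard error; the unfolded ensemble is
projected into (Rg, helical turns in helices 1–3) and compared between
simulations by histogram Kullback–Leibler divergence; helix formation order
within each folding event is labeled `"132"`-style (helix 1 first, helix 3
second, helix 2 third).

## Worked example

`examples/02_force_errors_vs_cutoff.py` measures the accuracy of the cutoff
schemes against a converged Ewald reference on a fixed 100-particle random
neutral charge box:

```
rms force error vs converged Ewald (kcal/mol/A):
  cutoff      SHIFT      TRUNC
     8.0     9.6755     7.6261
    10.0     8.1038     6.0011
    12.0     6.8441     4.4889

tuned Ewald at 10 A cutoff: alpha=0.350/A, kmax=14 -> rms error 3.30e-05 (target 1e-04)
```

Both cutoff schemes get strictly more accurate as the cutoff grows from 8 to
12 Å, but a finite error always remains — the neglected long-range tail.
Ewald accuracy, in contrast, is limited only by how many reciprocal-space
vectors you buy. `examples/04_folding_analysis.py` runs the analysis chain
on a synthetic two-state trajectory with known thermodynamics:

```
true events: 116   detected: 131
folding dG: +0.544 +- 0.137 kcal/mol (ground truth +0.606)
unfolded-state frames projected into (Rg, turns 1-3): 68149
mean unfolded Rg: 10.95 A
KL divergence between independent replicates: 0.0148 nats
helix formation order frequencies: {'132': 1.0}
```

The recovered free energy sits within one blocking standard error of the
generator's ground truth, the replicate-to-replicate KL divergence (~0.015
nats) sets the statistical floor for ensemble comparisons at this sampling
depth, and the prescribed helix formation order is recovered exactly.

## Command line

```sh
cutoffmd generate lj-fluid --n 50 --out fluid
cutoffmd simulate --system fluid.json --elec shift --cutoff 10 --steps 2000 --out run
cutoffmd eval-forces --system box.json --schemes trunc,shift --cutoffs 8,10,12 --out errors.csv
cutoffmd analyze --features run.features.csv --out-prefix report
cutoffmd sweep --system box.json --cutoffs 8,10,12 --elec shift,ewald --out sweep.csv
```

Every run logs its fully resolved configuration (including defaults and
seeds) to stderr, so any result is reproducible from the log alone.

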