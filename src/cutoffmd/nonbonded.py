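"""Nonbonded energies and forces for the cutoff schemes under comparison.

Three treatments of periodic electrostatics are implemented:

* TRUNC — hard truncation: k_e q_i q_j / r for r <= r_c, nothing beyond.
* SHIFT — force shifting: a constant is added to each pair force so the net
  force is exactly zero at the cutoff, and interactions beyond the cutoff are
  dropped. The energy is the integral of the shifted force with U(r_c) = 0:
  U(r) = k_e q_i q_j (1/r + r/r_c^2 - 2/r_c).
* EWALD — the classic Ewald decomposition into an erfc-screened real-space
  sum over pairs within the cutoff, a reciprocal-space sum over wave-vectors
  k = 2*pi*n/L with |n_i| <= kmax, a self term, and an analytic correction
  removing the screened-complement interaction for excluded pairs.

Van der Waals interactions are Lennard-Jones terms hard-truncated at the same
cutoff (no switching function, no long-range dispersion correction), with
Lorentz-Berthelot combining rules.

The force rms-error metric quantifies each scheme's deviation from a
converged Ewald reference, mirroring how mesh-Ewald accuracy is usually
characterized; :func:`tune_ewald` picks (alpha, kmax) to meet a requested
rms force-error target.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy.special import erf, erfc

from .core import (
    Electrostatics,
    ForceReport,
    NonbondedScheme,
    ParticleSystem,
    excluded_pair_table,
    pair_table,
)

_OVERLAP = 1e-6  # A; interacting pairs closer than this are rejected
_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


class OverlapError(ValueError):
    """Two interacting particles are (numerically) on top of each other."""


@dataclass
class ForceErrorResult:
    """RMS over all 3n force components of (test - reference), the maximum
    per-particle force-vector deviation norm, and the per-particle norms."""

    rms_error: float
    max_error: float
    per_particle_errors: np.ndarray


def _check_overlap(r: np.ndarray) -> None:
    if r.size and float(r.min()) < _OVERLAP:
        raise OverlapError(
            f"interacting pair at r = {r.min():.3g} A (< {_OVERLAP} A)"
        )


def _pair_report(
    system: ParticleSystem,
    i: np.ndarray,
    dvec: np.ndarray,
    j: np.ndarray,
    energies: np.ndarray,
    f_over_r: np.ndarray,
    name: str,
) -> ForceReport:
    """Assemble a ForceReport from per-pair energies and radial force/r."""
    forces = np.zeros((system.n_particles, 3))
    fvec = f_over_r[:, None] * dvec
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    e = float(energies.sum())
    return ForceReport(forces=forces, potential_energy=e, components={name: e})


def lj_truncated(system: ParticleSystem, cutoff: float) -> ForceReport:
    """Lennard-Jones energy/forces, hard-truncated at the cutoff.

    Pair energy 4*eps_ij*[(sig_ij/r)^12 - (sig_ij/r)^6] for r <= cutoff and
    exactly zero beyond; sigma combines arithmetically, epsilon geometrically.
    """
    i, j, dvec, r = pair_table(system, cutoff)
    eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
    act = eps > 0
    i, j, dvec, r, eps = i[act], j[act], dvec[act], r[act], eps[act]
    _check_overlap(r)
    sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
    sr6 = (sig / r) ** 6
    energies = 4.0 * eps * (sr6 * sr6 - sr6)
    f_over_r = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / (r * r)
    return _pair_report(system, i, dvec, j, energies, f_over_r, "lj")


def _charged_pairs(system: ParticleSystem, cutoff: float):
    i, j, dvec, r = pair_table(system, cutoff)
    qq = system.charges[i] * system.charges[j]
    act = qq != 0
    return i[act], j[act], dvec[act], r[act], qq[act]


def coulomb_truncated(system: ParticleSystem, cutoff: float) -> ForceReport:
    """Hard-truncated Coulomb: k_e q_i q_j / r inside the cutoff, 0 beyond."""
    i, j, dvec, r, qq = _charged_pairs(system, cutoff)
    _check_overlap(r)
    ke = NonbondedScheme(Electrostatics.TRUNC, cutoff).coulomb_constant
    energies = ke * qq / r
    f_over_r = ke * qq / r**3
    return _pair_report(system, i, dvec, j, energies, f_over_r, "coulomb")


def coulomb_shift(system: ParticleSystem, cutoff: float) -> ForceReport:
    """Force-shifted Coulomb.

    Pair force magnitude k_e q_i q_j (1/r^2 - 1/r_c^2) — zero at the cutoff
    by construction — with the conservative energy
    k_e q_i q_j (1/r + r/r_c^2 - 2/r_c), which vanishes at r_c.
    """
    i, j, dvec, r, qq = _charged_pairs(system, cutoff)
    _check_overlap(r)
    ke = NonbondedScheme(Electrostatics.SHIFT, cutoff).coulomb_constant
    rc = cutoff
    energies = ke * qq * (1.0 / r + r / rc**2 - 2.0 / rc)
    f_over_r = ke * qq * (1.0 / r**2 - 1.0 / rc**2) / r
    return _pair_report(system, i, dvec, j, energies, f_over_r, "coulomb")


def _recip_nvectors(kmax: int) -> np.ndarray:
    """Integer wave-vector indices over half of reciprocal space (the other
    half is recovered by symmetry), every |n_i| <= kmax, n != 0."""
    rng = np.arange(-kmax, kmax + 1)
    n = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = (
        (n[:, 0] > 0)
        | ((n[:, 0] == 0) & (n[:, 1] > 0))
        | ((n[:, 0] == 0) & (n[:, 1] == 0) & (n[:, 2] > 0))
    )
    return n[keep]


def ewald_reciprocal(
    system: ParticleSystem, alpha: float, kmax: int, coulomb_constant: float
) -> ForceReport:
    """Reciprocal-space part of the Ewald sum (structure-factor form)."""
    L = system.box_edge
    V = L**3
    q = system.charges
    pos = system.positions
    kvecs = 2.0 * np.pi / L * _recip_nvectors(kmax)
    pref = 2.0 * np.pi * coulomb_constant / V
    energy = 0.0
    forces = np.zeros_like(pos)
    # chunk over wave-vectors to bound the (M, N) phase matrix
    for start in range(0, kvecs.shape[0], 8192):
        K = kvecs[start : start + 8192]
        k2 = np.einsum("ij,ij->i", K, K)
        A = np.exp(-k2 / (4.0 * alpha * alpha)) / k2
        phase = K @ pos.T  # (M, N)
        c, s = np.cos(phase), np.sin(phase)
        C = c @ q
        S = s @ q
        energy += 2.0 * pref * float(np.dot(A, C * C + S * S))
        # F_i = 4*pref*q_i * sum_k A k (C sin(k.r_i) - S cos(k.r_i))
        w = A[:, None] * (s * C[:, None] - c * S[:, None])  # (M, N)
        forces += 4.0 * pref * q[:, None] * (w.T @ K)
    return ForceReport(
        forces=forces, potential_energy=energy, components={"coulomb_recip": energy}
    )


def _check_ewald(system: ParticleSystem, scheme: NonbondedScheme) -> None:
    if scheme.electrostatics is not Electrostatics.EWALD:
        raise ValueError("scheme is not EWALD")
    if abs(system.total_charge) > 1e-9:
        raise ValueError(
            f"Ewald requires a neutral system (net charge {system.total_charge:g} e)"
        )


def ewald_real_space(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """Short-range Ewald terms: the erfc-screened real-space sum over
    non-excluded pairs within the cutoff, plus the analytic correction
    removing the screened-complement (erf) interaction for excluded pairs
    (which the reciprocal sum includes with the full 1/r kernel)."""
    _check_ewald(system, scheme)
    alpha = scheme.ewald_alpha
    ke = scheme.coulomb_constant

    i, j, dvec, r, qq = _charged_pairs(system, scheme.cutoff)
    _check_overlap(r)
    e_real = ke * qq * erfc(alpha * r) / r
    f_over_r = (
        ke
        * qq
        * (erfc(alpha * r) / r**2 + _TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * r) ** 2) / r)
        / r
    )
    real = _pair_report(system, i, dvec, j, e_real, f_over_r, "coulomb_real")

    ei, ej, edvec, er = excluded_pair_table(system)
    eqq = system.charges[ei] * system.charges[ej]
    act = eqq != 0
    ei, ej, edvec, er, eqq = ei[act], ej[act], edvec[act], er[act], eqq[act]
    _check_overlap(er)
    e_corr = -ke * eqq * erf(alpha * er) / er
    # u(r) = -k q q erf(ar)/r  ->  F = -du/dr along the pair axis
    f_corr_over_r = (
        ke
        * eqq
        * (_TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * er) ** 2) / er - erf(alpha * er) / er**2)
        / er
    )
    corr = _pair_report(
        system, ei, edvec, ej, e_corr, f_corr_over_r, "coulomb_excl_correction"
    )
    return real + corr


def ewald_long_range(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """Long-range Ewald terms: the reciprocal-space sum and the self term."""
    _check_ewald(system, scheme)
    ke = scheme.coulomb_constant
    recip = ewald_reciprocal(system, scheme.ewald_alpha, scheme.ewald_kmax, ke)
    e_self = (
        -ke * scheme.ewald_alpha / np.sqrt(np.pi)
        * float(np.dot(system.charges, system.charges))
    )
    return recip + ForceReport(
        forces=np.zeros_like(system.positions),
        potential_energy=e_self,
        components={"coulomb_self": e_self},
    )


def coulomb_ewald(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """Full Ewald electrostatics: real + reciprocal + self + exclusion terms.

    Requires a charge-neutral system (no uniform background correction is
    applied) and scheme.ewald_alpha / ewald_kmax set.
    """
    return ewald_real_space(system, scheme) + ewald_long_range(system, scheme)


def bonded(system: ParticleSystem) -> ForceReport:
    """Harmonic energy k/2 (r - r0)^2 over non-constrained bonds."""
    from .core import minimum_image

    constrained = {b.pair() for b in system.constrained_bonds}
    bonds = [b for b in system.bonds if b.pair() not in constrained]
    forces = np.zeros_like(system.positions)
    energy = 0.0
    for b in bonds:
        d = minimum_image(
            system.positions[b.i] - system.positions[b.j], system.box_edge
        )
        r = float(np.linalg.norm(d))
        energy += 0.5 * b.k * (r - b.length) ** 2
        f = -b.k * (r - b.length) / r * d
        forces[b.i] += f
        forces[b.j] -= f
    return ForceReport(
        forces=forces, potential_energy=energy, components={"bonded": energy}
    )


def _electrostatics_report(
    system: ParticleSystem, scheme: NonbondedScheme
) -> ForceReport:
    if scheme.electrostatics is Electrostatics.TRUNC:
        return coulomb_truncated(system, scheme.cutoff)
    if scheme.electrostatics is Electrostatics.SHIFT:
        return coulomb_shift(system, scheme.cutoff)
    return coulomb_ewald(system, scheme)


def evaluate(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """Total nonbonded + bonded forces and energy for the selected scheme."""
    return (
        lj_truncated(system, scheme.cutoff)
        + _electrostatics_report(system, scheme)
        + bonded(system)
    )


def evaluate_fast(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """The fast (inner-timestep) tier: LJ, bonded, and for EWALD the
    real-space erfc electrostatics plus the exclusion correction. For
    TRUNC/SHIFT this is the full evaluation."""
    if scheme.electrostatics is not Electrostatics.EWALD:
        return evaluate(system, scheme)
    return (
        lj_truncated(system, scheme.cutoff)
        + ewald_real_space(system, scheme)
        + bonded(system)
    )


def evaluate_slow(system: ParticleSystem, scheme: NonbondedScheme) -> ForceReport:
    """The slow (outer-timestep) tier: Ewald reciprocal + self terms; zero
    for the purely short-ranged TRUNC/SHIFT schemes."""
    if scheme.electrostatics is not Electrostatics.EWALD:
        return ForceReport(
            forces=np.zeros_like(system.positions), potential_energy=0.0, components={}
        )
    return ewald_long_range(system, scheme)


def evaluate_split(
    system: ParticleSystem, scheme: NonbondedScheme
) -> tuple[ForceReport, ForceReport]:
    """(fast, slow) force decomposition for multiple-timestep integration.

    For EWALD the slow tier holds the reciprocal-space and self terms (the
    long-range component); real-space erfc electrostatics, the exclusion
    correction, LJ and bonded terms are fast. For TRUNC/SHIFT everything is
    fast and the slow report is zero. fast + slow == evaluate() exactly.
    """
    return evaluate_fast(system, scheme), evaluate_slow(system, scheme)


def force_rms_error(test: ForceReport, reference: ForceReport) -> ForceErrorResult:
    """RMS (over all 3n components) and max per-particle deviation of a test
    force set from a reference; the metric used to rank scheme accuracy."""
    if test.forces.shape != reference.forces.shape:
        raise ValueError(
            f"force shapes differ: {test.forces.shape} vs {reference.forces.shape}"
        )
    dev = test.forces - reference.forces
    rms = float(np.sqrt(np.mean(dev**2)))
    per = np.linalg.norm(dev, axis=1)
    return ForceErrorResult(
        rms_error=rms, max_error=float(per.max()), per_particle_errors=per
    )


class EwaldTuneError(RuntimeError):
    """No (alpha, kmax) within the ceiling met the requested force accuracy."""


def reference_scheme(
    system: ParticleSystem, alpha: float, kmax: int
) -> NonbondedScheme:
    """High-accuracy Ewald reference: same alpha, kmax doubled, real-space
    cutoff pushed to just under box_edge/2."""
    return NonbondedScheme(
        Electrostatics.EWALD,
        cutoff=system.box_edge / 2 - 1e-6,
        ewald_alpha=alpha,
        ewald_kmax=2 * kmax,
    )


def tune_ewald(
    system: ParticleSystem,
    cutoff: float,
    target_rms: float,
    kmax_ceiling: int = 16,
) -> NonbondedScheme:
    """Choose (alpha, kmax) meeting a requested rms force-error target.

    For ascending kmax, a small deterministic grid of splitting parameters
    (scaled by 1/cutoff) is tried; the measured rms error of the candidate's
    Coulomb forces against the high-accuracy reference (same alpha, doubled
    kmax, near-half-box cutoff) decides acceptance. The ascending-kmax order
    guarantees a tighter target never returns a smaller kmax.
    """
    if not target_rms > 0:
        raise ValueError("target_rms must be positive")
    alphas = [x / cutoff for x in (2.5, 3.0, 3.5, 4.0)]
    best = None
    for kmax in range(1, kmax_ceiling + 1):
        for alpha in alphas:
            cand = NonbondedScheme(
                Electrostatics.EWALD, cutoff=cutoff, ewald_alpha=alpha, ewald_kmax=kmax
            )
            test = coulomb_ewald(system, cand)
            ref = coulomb_ewald(system, reference_scheme(system, alpha, kmax))
            err = force_rms_error(test, ref).rms_error
            if best is None or err < best[0]:
                best = (err, cand)
            if err <= target_rms:
                return cand
    raise EwaldTuneError(
        f"target rms {target_rms:g} unreachable with kmax <= {kmax_ceiling}; "
        f"best achieved {best[0]:g}"
    )
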