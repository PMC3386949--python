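"""NVT molecular dynamics: velocity-Verlet core, two-tier RESPA timestep
split, single-chain Nose-Hoover thermostat, and iterative SHAKE constraints.

The integrator stack mirrors common practice for explicit-solvent folding
simulations: slow (Ewald reciprocal + self) forces advance on the outer
timestep (default 5.0 fs), everything else — real-space electrostatics,
Lennard-Jones and bonded terms — on the inner timestep (default 2.5 fs),
with the whole system coupled to a Nose-Hoover thermostat (default 360 K,
relaxation time 10 ps) and selected bonds held rigid by SHAKE.

``n_steps`` counts *outer* steps, so simulated time is n_steps * dt_outer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Electrostatics,
    K_B,
    KCAL_PER_AMU_A2_FS2,
    NonbondedScheme,
    ParticleSystem,
    degrees_of_freedom,
    instantaneous_temperature,
    kinetic_energy,
    minimum_image,
)
from .nonbonded import evaluate, evaluate_fast, evaluate_slow, evaluate_split


@dataclass
class IntegratorConfig:
    dt_inner: float = 2.5  # fs
    dt_outer: float = 5.0  # fs
    temperature: float = 360.0  # K
    thermostat_tau: float = 10_000.0  # fs (10 ps relaxation time)
    thermostat: bool = True
    shake_tolerance: float = 1e-8  # relative bond-length tolerance
    shake_max_iter: int = 500
    n_steps: int = 0  # outer steps
    seed: int = 0
    save_interval: int = 100  # outer steps between saved frames

    def __post_init__(self) -> None:
        if min(self.dt_inner, self.dt_outer, self.thermostat_tau) <= 0:
            raise ValueError("timesteps and thermostat_tau must be positive")
        ratio = self.dt_outer / self.dt_inner
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_outer must be an integer multiple of dt_inner")

    @property
    def inner_per_outer(self) -> int:
        return int(round(self.dt_outer / self.dt_inner))


@dataclass
class Trajectory:
    """Time-ordered frames with named per-frame scalar feature channels.

    positions/velocities are (n_frames, n, 3) stacks when the trajectory
    carries coordinates, or None for feature-only trajectories (e.g. the
    synthetic folding emitter).
    """

    times: np.ndarray
    positions: np.ndarray | None = None
    velocities: np.ndarray | None = None
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        n = self.times.size
        for name in ("positions", "velocities"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 3 or arr.shape[0] != n or arr.shape[2] != 3:
                    raise ValueError(f"{name} must be an ({n}, m, 3) stack")
                setattr(self, name, arr)
        self.features = {k: np.asarray(v, dtype=float) for k, v in self.features.items()}
        for k, v in self.features.items():
            if v.shape != (n,):
                raise ValueError(f"feature {k!r} must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class ThermostatState:
    """Nose-Hoover friction xi (fs^-1) and its time integral eta (used in the
    extended-system conserved quantity)."""

    xi: float = 0.0
    eta: float = 0.0


class ShakeConvergenceError(RuntimeError):
    pass


class SimulationDivergedError(RuntimeError):
    pass


def initialize_velocities(
    system: ParticleSystem, temperature: float, seed: int
) -> ParticleSystem:
    """Maxwell-Boltzmann velocity draw at the target temperature with the
    total linear momentum removed; deterministic given the seed."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    out = system.copy()
    if temperature == 0:
        out.velocities = np.zeros_like(out.velocities)
        return out
    rng = np.random.default_rng(seed)
    sd = np.sqrt(K_B * temperature / (system.masses * KCAL_PER_AMU_A2_FS2))
    v = rng.normal(size=(system.n_particles, 3)) * sd[:, None]
    v -= (system.masses @ v) / system.masses.sum()  # remove COM drift
    out.velocities = v
    return out


def _accel(forces: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Force (kcal/mol/A) to acceleration (A/fs^2)."""
    return forces / (masses[:, None] * KCAL_PER_AMU_A2_FS2)


def shake_constrain(
    positions_before: np.ndarray,
    positions_after: np.ndarray,
    system: ParticleSystem,
    config: IntegratorConfig,
) -> np.ndarray:
    """Iterative SHAKE: correct positions_after so every constrained bond is
    at its equilibrium length within config.shake_tolerance (relative),
    corrections directed along the pre-step bond vectors."""
    if not system.constrained_bonds:
        return positions_after
    pos = positions_after.copy()
    box = system.box_edge
    m = system.masses
    cons = system.constrained_bonds

    def worst_violation():
        worst, worst_bond = 0.0, None
        for b in cons:
            r_new = minimum_image(pos[b.i] - pos[b.j], box)
            rel = abs(np.linalg.norm(r_new) - b.length) / b.length
            if rel > worst:
                worst, worst_bond = rel, b
        return worst, worst_bond

    for _ in range(config.shake_max_iter):
        worst, _ = worst_violation()
        if worst <= config.shake_tolerance:
            return pos
        for b in cons:
            r_new = minimum_image(pos[b.i] - pos[b.j], box)
            r2 = float(r_new @ r_new)
            if abs(np.sqrt(r2) - b.length) / b.length <= config.shake_tolerance:
                continue
            r_old = minimum_image(
                positions_before[b.i] - positions_before[b.j], box
            )
            inv_mu = 1.0 / m[b.i] + 1.0 / m[b.j]
            g = (r2 - b.length**2) / (2.0 * inv_mu * float(r_old @ r_new))
            pos[b.i] -= g / m[b.i] * r_old
            pos[b.j] += g / m[b.j] * r_old
    worst, worst_bond = worst_violation()
    if worst <= config.shake_tolerance:
        return pos
    raise ShakeConvergenceError(
        f"SHAKE did not converge in {config.shake_max_iter} iterations; "
        f"worst constraint {worst_bond} violated by {worst:.3g} (relative)"
    )


def rattle_velocities(
    positions: np.ndarray, velocities: np.ndarray, system: ParticleSystem,
    tolerance: float = 1e-10, max_iter: int = 500,
) -> np.ndarray:
    """Project velocities onto the constraint surface: relative velocity
    along every constrained bond is removed (RATTLE velocity stage)."""
    if not system.constrained_bonds:
        return velocities
    v = velocities.copy()
    m = system.masses
    box = system.box_edge
    for _ in range(max_iter):
        worst = 0.0
        for b in system.constrained_bonds:
            r = minimum_image(positions[b.i] - positions[b.j], box)
            rv = float(r @ (v[b.i] - v[b.j]))
            worst = max(worst, abs(rv) / float(r @ r))
            k = rv / (float(r @ r) * (1.0 / m[b.i] + 1.0 / m[b.j]))
            v[b.i] -= k / m[b.i] * r
            v[b.j] += k / m[b.j] * r
        if worst <= tolerance:
            break
    return v


def velocity_verlet_step(
    system: ParticleSystem,
    scheme: NonbondedScheme,
    dt: float,
    config: IntegratorConfig | None = None,
) -> ParticleSystem:
    """One half-kick/drift/half-kick step with the full force; applies SHAKE
    and the RATTLE velocity projection when constraints are present."""
    cfg = config or IntegratorConfig(dt_inner=dt, dt_outer=dt)
    out = system.copy()
    f = evaluate(out, scheme).forces
    out.velocities = out.velocities + 0.5 * dt * _accel(f, out.masses)
    before = out.positions.copy()
    drifted = before + dt * out.velocities
    out.positions = shake_constrain(before, drifted, out, cfg)
    if out.constrained_bonds:
        out.velocities = out.velocities + (out.positions - drifted) / dt
    f = evaluate(out, scheme).forces
    out.velocities = out.velocities + 0.5 * dt * _accel(f, out.masses)
    if out.constrained_bonds:
        out.velocities = rattle_velocities(out.positions, out.velocities, out)
    return out


def nose_hoover_step(
    system: ParticleSystem,
    state: ThermostatState,
    config: IntegratorConfig,
    dt: float | None = None,
) -> tuple[ParticleSystem, ThermostatState]:
    """Half-step single-chain Nose-Hoover update (friction integration plus
    velocity scaling) over dt (default dt_outer/2).

    Thermostat mass Q = N_df * k_B * T * tau^2; the friction variable xi
    relaxes the kinetic energy toward N_df * k_B * T / 2.
    """
    if config.temperature <= 0:
        raise ValueError("thermostat temperature must be positive")
    h = (config.dt_outer / 2.0) if dt is None else dt
    out = system.copy()
    ndf = degrees_of_freedom(out)
    kt = K_B * config.temperature
    q = ndf * kt * config.thermostat_tau**2
    xi, eta = state.xi, state.eta

    g = (2.0 * kinetic_energy(out) - ndf * kt) / q
    xi += 0.5 * h * g
    out.velocities = out.velocities * np.exp(-xi * h)
    eta += xi * h
    g = (2.0 * kinetic_energy(out) - ndf * kt) / q
    xi += 0.5 * h * g
    return out, ThermostatState(xi=xi, eta=eta)


def nose_hoover_conserved(
    system: ParticleSystem,
    state: ThermostatState,
    config: IntegratorConfig,
    potential_energy: float,
) -> float:
    """Extended-system conserved quantity
    KE + PE + Q xi^2 / 2 + N_df k_B T eta (kcal/mol)."""
    ndf = degrees_of_freedom(system)
    kt = K_B * config.temperature
    q = ndf * kt * config.thermostat_tau**2
    return (
        kinetic_energy(system)
        + potential_energy
        + 0.5 * q * state.xi**2
        + ndf * kt * state.eta
    )


def _respa_once(
    system: ParticleSystem,
    scheme: NonbondedScheme,
    config: IntegratorConfig,
    fast: np.ndarray,
    slow: np.ndarray,
):
    """One outer RESPA step in place on a working copy; returns updated
    (system, fast_forces, slow_forces, potential_energy)."""
    m = system.masses
    has_slow = scheme.electrostatics is Electrostatics.EWALD
    system.velocities = system.velocities + 0.5 * config.dt_outer * _accel(slow, m)
    dt = config.dt_inner
    for _ in range(config.inner_per_outer):
        system.velocities = system.velocities + 0.5 * dt * _accel(fast, m)
        before = system.positions.copy()
        drifted = before + dt * system.velocities
        system.positions = shake_constrain(before, drifted, system, config)
        if system.constrained_bonds:
            system.velocities = system.velocities + (system.positions - drifted) / dt
        fast_rep = evaluate_fast(system, scheme)
        fast = fast_rep.forces
        e_fast = fast_rep.potential_energy
        system.velocities = system.velocities + 0.5 * dt * _accel(fast, m)
        if system.constrained_bonds:
            system.velocities = rattle_velocities(system.positions, system.velocities, system)
    if has_slow:
        slow_rep = evaluate_slow(system, scheme)
        slow = slow_rep.forces
        e_slow = slow_rep.potential_energy
    else:
        slow = np.zeros_like(fast)
        e_slow = 0.0
    system.velocities = system.velocities + 0.5 * config.dt_outer * _accel(slow, m)
    return system, fast, slow, e_fast + e_slow


def respa_step(
    system: ParticleSystem, scheme: NonbondedScheme, config: IntegratorConfig
) -> ParticleSystem:
    """One outer multiple-timestep step: slow (Ewald reciprocal + self)
    forces kicked at dt_outer, fast forces and drifts at dt_inner. For
    TRUNC/SHIFT there is no slow component and this is plain velocity-Verlet
    at dt_inner, repeated dt_outer/dt_inner times."""
    out = system.copy()
    if scheme.electrostatics is Electrostatics.EWALD:
        fast_rep, slow_rep = evaluate_split(out, scheme)
        fast, slow = fast_rep.forces, slow_rep.forces
    else:
        fast = evaluate(out, scheme).forces
        slow = np.zeros_like(fast)
    out, _, _, _ = _respa_once(out, scheme, config, fast, slow)
    return out


def run_simulation(
    system: ParticleSystem, scheme: NonbondedScheme, config: IntegratorConfig
) -> Trajectory:
    """NVT (or NVE with config.thermostat=False) trajectory generation.

    Composes the RESPA step, the Nose-Hoover half-kicks around it, and SHAKE.
    If the input system has all-zero velocities and config.temperature > 0,
    velocities are drawn from the Maxwell-Boltzmann distribution at
    config.temperature using config.seed. Frames (with potential_energy and
    temperature channels, plus the thermostat conserved quantity under NVT)
    are saved every save_interval outer steps. Fully deterministic.
    """
    sys_ = system.copy()
    if config.temperature > 0 and not np.any(sys_.velocities):
        sys_ = initialize_velocities(sys_, config.temperature, config.seed)
    if sys_.constrained_bonds:
        sys_.positions = shake_constrain(
            sys_.positions, sys_.positions.copy(), sys_, config
        )
        sys_.velocities = rattle_velocities(sys_.positions, sys_.velocities, sys_)

    has_slow = scheme.electrostatics is Electrostatics.EWALD
    if has_slow:
        fast_rep, slow_rep = evaluate_split(sys_, scheme)
        fast, slow = fast_rep.forces, slow_rep.forces
        pe = fast_rep.potential_energy + slow_rep.potential_energy
    else:
        rep = evaluate(sys_, scheme)
        fast, slow = rep.forces, np.zeros_like(rep.forces)
        pe = rep.potential_energy

    nh = ThermostatState()
    times = [0.0]
    pos_frames = [sys_.positions.copy()]
    vel_frames = [sys_.velocities.copy()]
    feats: dict[str, list[float]] = {
        "potential_energy": [pe],
        "temperature": [instantaneous_temperature(sys_)],
        "conserved": [
            nose_hoover_conserved(sys_, nh, config, pe)
            if config.thermostat
            else kinetic_energy(sys_) + pe
        ],
    }
    for step in range(1, config.n_steps + 1):
        if config.thermostat:
            sys_, nh = nose_hoover_step(sys_, nh, config)
        sys_, fast, slow, pe = _respa_once(sys_, scheme, config, fast, slow)
        if config.thermostat:
            sys_, nh = nose_hoover_step(sys_, nh, config)
        if not (np.all(np.isfinite(sys_.positions)) and np.isfinite(pe)):
            raise SimulationDivergedError(
                f"non-finite coordinates or energy at outer step {step}"
            )
        if step % config.save_interval == 0 or step == config.n_steps:
            times.append(step * config.dt_outer)
            pos_frames.append(sys_.positions.copy())
            vel_frames.append(sys_.velocities.copy())
            feats["potential_energy"].append(pe)
            feats["temperature"].append(instantaneous_temperature(sys_))
            feats["conserved"].append(
                nose_hoover_conserved(sys_, nh, config, pe)
                if config.thermostat
                else kinetic_energy(sys_) + pe
            )
    return Trajectory(
        times=np.array(times),
        positions=np.stack(pos_frames),
        velocities=np.stack(vel_frames),
        features={k: np.array(v) for k, v in feats.items()},
    )
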