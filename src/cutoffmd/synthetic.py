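"""Synthetic input builders: every system and trajectory the tests need.

Builders cover the validation fixtures for the force schemes (ionic lattices
with a known Madelung energy, Lennard-Jones fluids, random neutral charge
boxes), dihedral fixtures for the helicity analysis (toy backbone chains),
and ground-truth-known folding trajectories (a hidden two-state Markov chain
emitting RMSD/Rg/helix-turn channels) standing in for long protein-folding
simulations. All builders are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Bond, K_B, ParticleSystem


def build_nacl_lattice(
    n_cells_per_edge: int, nearest_neighbor: float = 2.82
) -> ParticleSystem:
    """Rock-salt lattice of alternating +-1 point charges, no LJ.

    The box holds ``(2*n_cells_per_edge)**3`` ions on a simple cubic grid of
    spacing ``nearest_neighbor`` (A), charge alternating with site parity;
    one conventional cell (n_cells_per_edge=1) gives 8 ions. Periodic Ewald
    energy per ion pair equals the Madelung value -1.747565*k_e/a, making
    this the standard electrostatics correctness fixture.
    """
    if n_cells_per_edge < 1:
        raise ValueError("n_cells_per_edge must be >= 1")
    a = nearest_neighbor
    m = 2 * n_cells_per_edge
    idx = np.indices((m, m, m)).reshape(3, -1).T
    positions = idx * a
    charges = np.where(idx.sum(axis=1) % 2 == 0, 1.0, -1.0)
    return ParticleSystem(
        positions=positions,
        box_edge=m * a,
        charges=charges,
        masses=23.0,
        labels=["NA" if q > 0 else "CL" for q in charges],
    )


def _place_without_overlap(
    rng: np.random.Generator, n: int, box: float, min_sep: float, max_tries: int = 200
) -> np.ndarray:
    """Rejection-sample n points in the periodic box with a minimum
    pairwise (minimum-image) separation."""
    from .core import minimum_image

    pos = np.empty((n, 3))
    placed = 0
    tries = 0
    while placed < n:
        cand = rng.uniform(0.0, box, size=3)
        if placed:
            d = minimum_image(pos[:placed] - cand, box)
            if float(np.min(np.linalg.norm(d, axis=1))) < min_sep:
                tries += 1
                if tries > max_tries * n:
                    raise RuntimeError(
                        f"could not place {n} particles with separation "
                        f">= {min_sep} A in a {box} A box"
                    )
                continue
        pos[placed] = cand
        placed += 1
    return pos


def build_lj_fluid(
    n: int,
    density: float = 0.008,
    sigma: float = 3.4,
    epsilon: float = 0.238,
    mass: float = 39.948,
    seed: int = 0,
) -> ParticleSystem:
    """Uncharged Lennard-Jones fluid at the requested number density
    (particles/A^3); defaults are argon-like. Placement forbids pairs closer
    than 0.85*sigma."""
    box = (n / density) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    pos = _place_without_overlap(rng, n, box, 0.85 * sigma)
    return ParticleSystem(
        positions=pos,
        box_edge=box,
        lj_sigma=sigma,
        lj_epsilon=epsilon,
        masses=mass,
    )


def build_random_neutral_box(
    n_pairs: int, box_edge: float = 40.0, seed: int = 0
) -> ParticleSystem:
    """n_pairs +1e and n_pairs -1e charges at uniform positions with a
    2.4 A minimum separation, ion-like LJ cores, net charge exactly zero.
    Substrate for force rms-error sweeps across cutoffs and for charged-box
    dynamics."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    pos = _place_without_overlap(rng, n, box_edge, 2.4)
    charges = np.concatenate([np.ones(n_pairs), -np.ones(n_pairs)])
    return ParticleSystem(
        positions=pos,
        box_edge=box_edge,
        charges=charges,
        lj_sigma=3.0,
        lj_epsilon=0.2,
        masses=20.0,
    )


# -- toy backbone chains ------------------------------------------------------

_HELIX_PHI_PSI = (-57.0, -47.0)
_EXTENDED_PHI_PSI = (-120.0, 120.0)
# idealized backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.46, 1.52, 1.33
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 117.0, 121.0


def _next_atom(p1, p2, p3, length, angle_deg, dihedral_deg):
    """Natural-extension place: atom at given internal coordinates from the
    last three chain atoms."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(dih),
            -length * np.sin(ang) * np.sin(dih),  # right-handed (IUPAC) sign
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def build_toy_chain(
    n_residues: int, geometry: str = "helix", seed: int = 0
) -> ParticleSystem:
    """Backbone-like chain (N, CA, C pseudo-atoms per residue) with dihedrals
    set to ideal helical (-57, -47), extended (-120, +120), or per-residue
    randomly mixed values; omega fixed trans. Bonds and 1-2/1-3 exclusions
    are populated; the box is sized generously around the chain."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if geometry not in ("helix", "extended", "mixed"):
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    per_res = []
    for _ in range(n_residues):
        if geometry == "helix":
            per_res.append(_HELIX_PHI_PSI)
        elif geometry == "extended":
            per_res.append(_EXTENDED_PHI_PSI)
        else:
            per_res.append(
                _HELIX_PHI_PSI if rng.random() < 0.5 else _EXTENDED_PHI_PSI
            )

    # seed atoms: N0, CA0, C0 in a plane
    atoms = [np.zeros(3)]
    atoms.append(atoms[0] + np.array([_B_N_CA, 0.0, 0.0]))
    ang = np.radians(_A_N_CA_C)
    atoms.append(
        atoms[1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    )
    for res in range(1, n_residues):
        phi, psi = per_res[res]
        psi_prev = per_res[res - 1][1]
        # N(res): dihedral psi of previous residue about N(prev)-CA(prev)-C(prev)
        atoms.append(
            _next_atom(atoms[-3], atoms[-2], atoms[-1], _B_C_N, _A_CA_C_N, psi_prev)
        )
        # CA(res): omega = 180 about CA(prev)-C(prev)-N(res)
        atoms.append(
            _next_atom(atoms[-3], atoms[-2], atoms[-1], _B_N_CA, _A_C_N_CA, 180.0)
        )
        # C(res): phi about C(prev)-N(res)-CA(res)
        atoms.append(
            _next_atom(atoms[-3], atoms[-2], atoms[-1], _B_CA_C, _A_N_CA_C, phi)
        )
    positions = np.array(atoms)
    positions -= positions.min(axis=0)
    box = float(positions.max() + 20.0)
    positions += 5.0

    n_atoms = 3 * n_residues
    bonds = []
    for k in range(n_atoms - 1):
        length = (_B_N_CA, _B_CA_C, _B_C_N)[k % 3]
        bonds.append(Bond(k, k + 1, length))
    exclusions = {(k, k + 1) for k in range(n_atoms - 1)}
    exclusions |= {(k, k + 2) for k in range(n_atoms - 2)}
    labels = [("N", "CA", "C")[k % 3] for k in range(n_atoms)]
    residue_index = np.repeat(np.arange(n_residues), 3)
    return ParticleSystem(
        positions=positions,
        box_edge=box,
        lj_sigma=3.0,
        lj_epsilon=0.1,
        masses=[14.0, 12.0, 12.0] * n_residues,
        bonds=bonds,
        exclusions=exclusions,
        labels=labels,
        residue_index=residue_index,
    )


# -- synthetic two-state folding trajectories ---------------------------------


@dataclass
class TwoStateSpec:
    """Parameters of the hidden two-state (folded/unfolded) Markov emitter.

    k_fold / k_unfold are per-frame transition probabilities; the stationary
    folded fraction is k_fold/(k_fold+k_unfold) and must match p_folded when
    both are given. RMSD and Rg are emitted as state-conditional Gaussians,
    linearly interpolated across a transit window of ``transit_frames`` at
    each hidden switch so transitions have finite duration. Helix-turn
    channels ramp from their unfolded baseline to their folded plateau over
    ``helix_rise_frames``, starting ``helix_formation_lags[h]`` frames into
    each folding window — defining a known helix formation order. An
    optional ``lag_mixture`` [(lags, probability), ...] draws a lag set per
    folding event, prescribing a whole distribution of formation orders.
    """

    n_frames: int = 100_000
    k_fold: float = 0.0009
    k_unfold: float = 0.0021
    p_folded: float | None = None
    temperature: float = 360.0
    rmsd_means: tuple[float, float] = (1.8, 8.0)  # (folded, unfolded), A
    rmsd_sds: tuple[float, float] = (0.4, 0.8)
    rg_means: tuple[float, float] = (9.0, 11.0)  # mirrors a compact folded state
    rg_sds: tuple[float, float] = (0.4, 1.0)
    helix_plateaus: tuple[float, ...] = (2.2, 1.7, 1.9)  # folded turns/helix
    helix_baseline: float = 0.2
    turn_sd: float = 0.08
    helix_formation_lags: tuple[int, ...] = (6, 20, 13)  # frames; order "132"
    lag_mixture: list[tuple[tuple[int, ...], float]] | None = None
    transit_frames: int = 48
    helix_rise_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.k_fold < 1 and 0 < self.k_unfold < 1):
            raise ValueError("transition probabilities must lie in (0, 1)")
        stationary = self.k_fold / (self.k_fold + self.k_unfold)
        if self.p_folded is None:
            self.p_folded = stationary
        elif abs(self.p_folded - stationary) > 1e-9:
            raise ValueError(
                f"p_folded {self.p_folded} inconsistent with k_fold/k_unfold "
                f"(stationary {stationary})"
            )
        if any(s <= 0 for s in self.rmsd_sds + self.rg_sds):
            raise ValueError("emission standard deviations must be positive")
        if self.lag_mixture is not None:
            total = sum(p for _, p in self.lag_mixture)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("lag_mixture probabilities must sum to 1")


@dataclass
class TwoStateGroundTruth:
    """What the generator actually did: per-frame true labels (0 folded,
    1 unfolded, 2 transit), the true event list, the stationary folded
    fraction and its free energy, and the per-folding-event order labels."""

    labels: np.ndarray
    events: list[tuple[str, int, int]]
    p_folded: float
    delta_g: float
    temperature: float
    order_labels: list[str] = field(default_factory=list)


def _order_label(lags) -> str:
    order = np.argsort(np.asarray(lags), kind="stable")
    return "".join(str(h + 1) for h in order)


def generate_two_state_trajectory(spec: TwoStateSpec):
    """Simulate the hidden chain and emit a feature Trajectory.

    Returns (trajectory, ground_truth); the trajectory carries feature
    channels rmsd, rg, turns_h1..turns_h3 and no coordinates.
    """
    from .dynamics import Trajectory

    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    FOLDED, UNFOLDED, TRANSIT = 0, 1, 2

    # hidden chain, started from its stationary distribution
    states = np.empty(n, dtype=int)
    states[0] = FOLDED if rng.random() < spec.p_folded else UNFOLDED
    u = rng.random(n)
    for t in range(1, n):
        if states[t - 1] == FOLDED:
            states[t] = UNFOLDED if u[t] < spec.k_unfold else FOLDED
        else:
            states[t] = FOLDED if u[t] < spec.k_fold else UNFOLDED

    switches = [int(t) for t in np.flatnonzero(states[1:] != states[:-1]) + 1]

    mf, mu = spec.rmsd_means
    gf, gu = spec.rg_means
    sf, su = spec.rmsd_sds
    gsf, gsu = spec.rg_sds
    w = spec.transit_frames
    rise = spec.helix_rise_frames
    n_h = len(spec.helix_plateaus)
    plateau = np.asarray(spec.helix_plateaus, dtype=float)
    base = spec.helix_baseline

    # per-switch metadata: lag set drawn per folding event
    lags_at: dict[int, tuple[int, ...]] = {}
    for t0 in switches:
        if states[t0] == FOLDED:
            if spec.lag_mixture is not None:
                lag_sets = [tuple(l) for l, _ in spec.lag_mixture]
                probs = [p for _, p in spec.lag_mixture]
                lags_at[t0] = lag_sets[rng.choice(len(lag_sets), p=probs)]
            else:
                lags_at[t0] = tuple(spec.helix_formation_lags)

    # Ground-truth events count only *completed* transitions: a switch whose
    # transit ramp finishes before the next switch. Micro-excursions shorter
    # than the transit window never reach the other state's emission means
    # and are not events (hysteresis-based assignment rightly ignores them).
    events: list[tuple[str, int, int]] = []
    last_completed = states[0]
    for idx, t0 in enumerate(switches):
        t_next = switches[idx + 1] if idx + 1 < len(switches) else n
        if t_next - t0 < w:
            continue
        target = states[t0]
        if target != last_completed:
            events.append(
                ("folding" if target == FOLDED else "unfolding", t0, t0 + w - 1)
            )
            last_completed = target

    # Sequential frame walk: every channel ramps linearly from its *current*
    # value toward the new state's target, so rapid recrossings (switches
    # inside an unfinished transit window) stay continuous.
    class _Ramp:
        __slots__ = ("start", "end", "v0", "target", "sqrt_shape")

        def __init__(self, start, length, v0, target, sqrt_shape=False):
            self.start, self.end = start, start + length
            self.v0, self.target = v0, target
            self.sqrt_shape = sqrt_shape

        def value(self, t):
            if t >= self.end:
                return self.target
            frac = (t - self.start) / (self.end - self.start)
            if self.sqrt_shape:  # fast initial relaxation, slow settling
                frac = np.sqrt(frac)
            return self.v0 + (self.target - self.v0) * frac

    folded0 = states[0] == FOLDED
    cur = {
        "rmsd_m": mf if folded0 else mu,
        "rmsd_s": sf if folded0 else su,
        "rg_m": gf if folded0 else gu,
        "rg_s": gsf if folded0 else gsu,
    }
    cur_turn = plateau.copy() if folded0 else np.full(n_h, base)
    scalar_ramp: dict[str, _Ramp | None] = {k: None for k in cur}
    turn_ramp: list = [None] * n_h
    turn_pending: list = [None] * n_h  # (start_frame, target) before ramp begins

    switch_set = dict((t0, states[t0]) for t0 in switches)
    rmsd_mean = np.empty(n)
    rg_mean = np.empty(n)
    rmsd_sd_arr = np.empty(n)
    rg_sd_arr = np.empty(n)
    turn_mean = np.empty((n, n_h))
    labels = np.empty(n, dtype=int)

    for t in range(n):
        if t in switch_set:
            folding = switch_set[t] == FOLDED
            targets = {
                "rmsd_m": mf if folding else mu,
                "rmsd_s": sf if folding else su,
                "rg_m": gf if folding else gu,
                "rg_s": gsf if folding else gsu,
            }
            for key, tgt in targets.items():
                scalar_ramp[key] = _Ramp(t, w, cur[key], tgt, sqrt_shape=True)
            for h in range(n_h):
                if folding:
                    turn_ramp[h] = None
                    turn_pending[h] = (t + int(lags_at[t][h]), plateau[h])
                else:
                    turn_pending[h] = None
                    turn_ramp[h] = _Ramp(t, rise, cur_turn[h], base)
        for key, ramp in scalar_ramp.items():
            if ramp is not None:
                cur[key] = ramp.value(t)
                if t >= ramp.end:
                    scalar_ramp[key] = None
        for h in range(n_h):
            if turn_pending[h] is not None and t >= turn_pending[h][0]:
                start, tgt = turn_pending[h]
                turn_ramp[h] = _Ramp(start, rise, cur_turn[h], tgt)
                turn_pending[h] = None
            if turn_ramp[h] is not None:
                cur_turn[h] = turn_ramp[h].value(t)
                if t >= turn_ramp[h].end:
                    turn_ramp[h] = None
        rmsd_mean[t] = cur["rmsd_m"]
        rmsd_sd_arr[t] = cur["rmsd_s"]
        rg_mean[t] = cur["rg_m"]
        rg_sd_arr[t] = cur["rg_s"]
        turn_mean[t] = cur_turn
        in_transit = any(r is not None for r in scalar_ramp.values())
        labels[t] = TRANSIT if in_transit else (
            FOLDED if states[t] == FOLDED else UNFOLDED
        )

    rmsd = rmsd_mean + rng.normal(0.0, 1.0, n) * rmsd_sd_arr
    rg = np.maximum(rg_mean + rng.normal(0.0, 1.0, n) * rg_sd_arr, 0.1)
    turns = np.maximum(
        turn_mean + rng.normal(0.0, spec.turn_sd, turn_mean.shape), 0.0
    )

    # ground-truth formation order per folding event, read off the noiseless
    # turn curves with the same sustained-80%-of-plateau rule the analysis
    # uses; events where some helix never forms are skipped
    order_labels: list[str] = []
    for typ, t0, t1 in events:
        if typ != "folding":
            continue
        window = turn_mean[t0 : t1 + 1]
        thr = 0.8 * plateau
        times = np.full(n_h, -1)
        for h in range(n_h):
            above = window[:, h] >= thr[h]
            below = np.flatnonzero(~above)
            first = (below[-1] + 1) if below.size else 0
            if first < len(above):
                times[h] = first
        if np.all(times >= 0):
            order_labels.append(
                "".join(str(h + 1) for h in np.argsort(times, kind="stable"))
            )

    features = {
        "rmsd": rmsd,
        "rg": rg,
        **{f"turns_h{h + 1}": turns[:, h] for h in range(n_h)},
    }
    traj = Trajectory(times=np.arange(n, dtype=float), features=features)
    delta_g = -K_B * spec.temperature * np.log(spec.p_folded / (1.0 - spec.p_folded))
    truth = TwoStateGroundTruth(
        labels=labels,
        events=events,
        p_folded=spec.p_folded,
        delta_g=float(delta_g),
        temperature=spec.temperature,
        order_labels=order_labels,
    )
    return traj, truth
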