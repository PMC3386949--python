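"""Folding-trajectory analytics.

Given a time series of C-alpha RMSD from a reference structure, frames are
partitioned into folded and unfolded segments with a transition-based
(dual-threshold hysteresis) rule; the folded/unfolded population ratio gives
the folding free energy dG = -k_B T ln(P_f/P_u), with its standard error
estimated by Flyvbjerg-Petersen blocking. The unfolded ensemble is
characterized by the radius of gyration and residual helicity, projected
into the 4D space (Rg, helical turns in each of three helices) for
Kullback-Leibler comparison between simulations, and by the order in which
the three helices form during folding events.

Helicity is assigned with a phi/psi-window rule (phi in [-100, -30], psi in
[-67, -7], runs of >= 4 consecutive residues) rather than a full
secondary-structure program: only helix detection is needed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import K_B, ParticleSystem
from .dynamics import Trajectory

FOLDED, UNFOLDED, TRANSIT = 0, 1, 2
STATE_NAMES = {FOLDED: "folded", UNFOLDED: "unfolded", TRANSIT: "transit"}

#: state-assignment RMSD thresholds (A); explicit defaults, configurable
DEFAULT_FOLDED_THRESHOLD = 2.5
DEFAULT_UNFOLDED_THRESHOLD = 6.0

RESIDUES_PER_TURN = 3.6

_PHI_WINDOW = (-100.0, -30.0)
_PSI_WINDOW = (-67.0, -7.0)
_MIN_HELIX_RUN = 4


@dataclass
class Event:
    """A folding or unfolding transition, spanning from the last departure
    of the old state's threshold to the first arrival at the new one."""

    type: str  # "folding" | "unfolding"
    start: int
    end: int


@dataclass
class StateSegmentation:
    labels: np.ndarray  # per-frame FOLDED/UNFOLDED/TRANSIT
    events: list[Event]
    thresholds: tuple[float, float]  # (folded_rmsd, unfolded_rmsd)

    @property
    def n_folded(self) -> int:
        return int(np.sum(self.labels == FOLDED))

    @property
    def n_unfolded(self) -> int:
        return int(np.sum(self.labels == UNFOLDED))


@dataclass
class FoldingThermo:
    p_folded: float
    delta_g: float  # kcal/mol
    delta_g_stderr: float
    temperature: float
    n_events: int


@dataclass
class UnfoldedFeatureTable:
    """Per-frame (rg, turns_h1..3) rows restricted to UNFOLDED frames; the
    DataFrame index holds the source frame numbers."""

    data: pd.DataFrame
    helix_definitions: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        required = ["rg", "turns_h1", "turns_h2", "turns_h3"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        self.data = self.data[required]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


class ZeroPopulationError(RuntimeError):
    """One of the two states has no frames; the free energy is unbounded."""


# -- geometry -----------------------------------------------------------------


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid rotations and
    translations (Kabsch superposition, proper rotations only)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need matching (m, 3) arrays with m >= 3")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T  # reflection-corrected
    resid = a @ rot.T - b
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the center of mass (A)."""
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    m = np.ones(c.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = (m @ c) / m.sum()
    d2 = np.sum((c - com) ** 2, axis=1)
    return float(np.sqrt((m @ d2) / m.sum()))


def backbone_dihedrals(positions: np.ndarray, n_residues: int) -> np.ndarray:
    """(phi, psi) per residue (degrees) for a 3-atoms-per-residue (N, CA, C)
    backbone chain; NaN where undefined (phi of the first residue, psi of
    the last)."""
    p = np.asarray(positions, dtype=float)
    if p.shape != (3 * n_residues, 3):
        raise ValueError("positions must be (3*n_residues, 3)")

    def dihedral(a, b, c, d):
        b1, b2, b3 = b - a, c - b, d - c
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return np.degrees(np.arctan2(m1 @ n2, n1 @ n2))

    out = np.full((n_residues, 2), np.nan)
    for r in range(n_residues):
        n_, ca, c_ = p[3 * r], p[3 * r + 1], p[3 * r + 2]
        if r > 0:
            out[r, 0] = dihedral(p[3 * r - 1], n_, ca, c_)  # phi: C(r-1)-N-CA-C
        if r < n_residues - 1:
            out[r, 1] = dihedral(n_, ca, c_, p[3 * r + 3])  # psi: N-CA-C-N(r+1)
    return out


def assign_helicity(phi_psi: np.ndarray) -> np.ndarray:
    """Helical flags per residue: phi/psi inside the alpha window and part
    of a run of >= 4 consecutive in-window residues."""
    pp = np.asarray(phi_psi, dtype=float)
    with np.errstate(invalid="ignore"):
        in_window = (
            (pp[:, 0] >= _PHI_WINDOW[0])
            & (pp[:, 0] <= _PHI_WINDOW[1])
            & (pp[:, 1] >= _PSI_WINDOW[0])
            & (pp[:, 1] <= _PSI_WINDOW[1])
        )
    flags = np.zeros(len(pp), dtype=bool)
    run_start = None
    for idx in range(len(pp) + 1):
        inside = idx < len(pp) and in_window[idx]
        if inside and run_start is None:
            run_start = idx
        elif not inside and run_start is not None:
            if idx - run_start >= _MIN_HELIX_RUN:
                flags[run_start:idx] = True
            run_start = None
    return flags


def helical_turns(helical_flags: np.ndarray, helix_range: tuple[int, int]) -> float:
    """Helical residues inside [start, stop) divided by 3.6 residues/turn."""
    start, stop = helix_range
    if not 0 <= start < stop <= len(helical_flags):
        raise ValueError(f"invalid helix range {helix_range}")
    return float(np.sum(helical_flags[start:stop])) / RESIDUES_PER_TURN


# -- state assignment and thermodynamics --------------------------------------


def transition_assign(
    rmsd_series: np.ndarray,
    folded_threshold: float = DEFAULT_FOLDED_THRESHOLD,
    unfolded_threshold: float = DEFAULT_UNFOLDED_THRESHOLD,
) -> StateSegmentation:
    """Dual-threshold (hysteresis) state assignment on an RMSD time series.

    The state at each frame is set by the most recently crossed threshold:
    dropping below folded_threshold enters FOLDED, rising above
    unfolded_threshold enters UNFOLDED. Excursions into the band between the
    thresholds never change the state, so rapid recrossings are suppressed.
    Frames before the first crossing are TRANSIT. One event is recorded per
    state change, spanning from the last frame the series was beyond the old
    state's threshold to the first frame beyond the new one; the initial
    entry into a state is not an event (there is no prior state).
    """
    if not folded_threshold < unfolded_threshold:
        raise ValueError("folded_threshold must be below unfolded_threshold")
    x = np.asarray(rmsd_series, dtype=float)
    labels = np.full(x.size, TRANSIT)
    events: list[Event] = []
    state = None
    last_departure = 0
    for t in range(x.size):
        if x[t] < folded_threshold:
            new = FOLDED
        elif x[t] > unfolded_threshold:
            new = UNFOLDED
        else:
            new = state
        if new is not None and new != state:
            if state is not None:
                events.append(
                    Event(
                        type="folding" if new == FOLDED else "unfolding",
                        start=last_departure,
                        end=t,
                    )
                )
            state = new
        if state is not None:
            labels[t] = state
        if state == FOLDED and x[t] < folded_threshold:
            last_departure = t
        elif state == UNFOLDED and x[t] > unfolded_threshold:
            last_departure = t
    return StateSegmentation(
        labels=labels, events=events, thresholds=(folded_threshold, unfolded_threshold)
    )


def blocking_analysis(series: np.ndarray):
    """Flyvbjerg-Petersen blocking: SEM estimates and their uncertainties at
    every pair-averaging level (down to 16 blocks).

    Returns (sems, uncertainties, chosen_sem, converged). The chosen level is
    the maximum SEM estimate among levels whose increase over the previous
    level lies within that level's own uncertainty (the plateau); if no
    level qualifies, the deepest level is returned and converged is False.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise ValueError("blocking needs at least 16 points")
    sems, uncert = [], []
    while x.size >= 16:
        n = x.size
        var = float(np.var(x, ddof=1))
        sem = np.sqrt(var / n)
        sems.append(sem)
        uncert.append(sem / np.sqrt(2.0 * (n - 1)))
        half = n // 2
        x = 0.5 * (x[: 2 * half : 2] + x[1 : 2 * half : 2])
    sems = np.array(sems)
    uncert = np.array(uncert)
    plateau = [
        k for k in range(1, len(sems)) if sems[k] - sems[k - 1] <= uncert[k]
    ]
    if plateau:
        chosen = float(max(sems[k] for k in plateau))
        return sems, uncert, chosen, True
    return sems, uncert, float(sems[-1]), False


def blocking_error(series: np.ndarray) -> float:
    """Standard error of the mean of a (possibly correlated) series, from
    the blocking plateau."""
    _, _, sem, _ = blocking_analysis(series)
    return sem


def folding_free_energy(seg: StateSegmentation, temperature: float) -> FoldingThermo:
    """dG = -k_B T ln(P_folded / P_unfolded) over non-TRANSIT frames, with
    the standard error propagated from a blocking estimate on the per-frame
    folded-indicator series."""
    nf, nu = seg.n_folded, seg.n_unfolded
    if nf == 0 or nu == 0:
        raise ZeroPopulationError(
            f"unbounded free energy: {nf} folded / {nu} unfolded frames"
        )
    p = nf / (nf + nu)
    delta_g = -K_B * temperature * np.log(p / (1.0 - p))
    indicator = (seg.labels[seg.labels != TRANSIT] == FOLDED).astype(float)
    sem_p = blocking_error(indicator)
    stderr = K_B * temperature * sem_p / (p * (1.0 - p))
    return FoldingThermo(
        p_folded=float(p),
        delta_g=float(delta_g),
        delta_g_stderr=float(stderr),
        temperature=temperature,
        n_events=len(seg.events),
    )


# -- unfolded-state structure --------------------------------------------------

_TURN_CHANNELS = ("turns_h1", "turns_h2", "turns_h3")


def _frame_features(
    traj: Trajectory,
    helix_ranges: list[tuple[int, int]] | None,
    system: ParticleSystem | None,
) -> pd.DataFrame:
    """Per-frame (rg, turns_h1..3) for all frames: from feature channels if
    present, otherwise computed from coordinates."""
    have = all(c in traj.features for c in ("rg",) + _TURN_CHANNELS)
    if have:
        return pd.DataFrame(
            {c: traj.features[c] for c in ("rg",) + _TURN_CHANNELS}
        )
    if traj.positions is None or system is None or helix_ranges is None:
        raise ValueError(
            "trajectory lacks rg/turns channels; need coordinates, a system "
            "and helix_ranges to compute them"
        )
    n_res = int(system.residue_index.max()) + 1
    rows = []
    for pos in traj.positions:
        flags = assign_helicity(backbone_dihedrals(pos, n_res))
        rows.append(
            [radius_of_gyration(pos, system.masses)]
            + [helical_turns(flags, hr) for hr in helix_ranges]
        )
    return pd.DataFrame(rows, columns=["rg", *_TURN_CHANNELS])


def unfolded_features(
    traj: Trajectory,
    seg: StateSegmentation,
    helix_ranges: list[tuple[int, int]] | None = None,
    system: ParticleSystem | None = None,
) -> UnfoldedFeatureTable:
    """Project the unfolded ensemble into (Rg, turns_h1, turns_h2, turns_h3);
    FOLDED and TRANSIT frames are excluded."""
    if seg.labels.size != traj.n_frames:
        raise ValueError("segmentation and trajectory lengths differ")
    df = _frame_features(traj, helix_ranges, system)
    mask = seg.labels == UNFOLDED
    if not mask.any():
        raise ZeroPopulationError("no unfolded frames to project")
    return UnfoldedFeatureTable(
        data=df[mask], helix_definitions=helix_ranges
    )


def molten_globule_filter(
    table: UnfoldedFeatureTable, helical_flags: np.ndarray
) -> UnfoldedFeatureTable:
    """Keep only rows whose frame has zero helical residues anywhere in the
    chain (molten-globule conformations). helical_flags is an
    (n_frames_total, n_residues) boolean array indexed like the trajectory
    the table came from."""
    flags = np.asarray(helical_flags, dtype=bool)
    frames = table.data.index.to_numpy()
    keep = ~flags[frames].any(axis=1)
    return UnfoldedFeatureTable(
        data=table.data[keep], helix_definitions=table.helix_definitions
    )


# -- ensemble comparison -------------------------------------------------------


def kl_divergence_histogram(
    p_counts: np.ndarray, q_counts: np.ndarray, pseudocount: float = 0.0
) -> float:
    """KL divergence (nats) between two histograms on a shared grid, with an
    optional pseudocount added to every bin of both before normalizing."""
    p = np.asarray(p_counts, dtype=float).ravel() + pseudocount
    q = np.asarray(q_counts, dtype=float).ravel() + pseudocount
    if p.shape != q.shape:
        raise ValueError("histograms must share a grid")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("q has zero mass where p is positive; use a pseudocount")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def shared_bin_edges(
    sample: UnfoldedFeatureTable,
    reference: UnfoldedFeatureTable,
    n_rg_bins: int = 12,
    n_turn_bins: int = 6,
) -> list[np.ndarray]:
    """Common 4D bin edges spanning both tables (pad avoids edge effects)."""
    both = np.vstack([sample.values, reference.values])
    edges = []
    for dim in range(4):
        lo, hi = both[:, dim].min(), both[:, dim].max()
        pad = 1e-9 + 1e-9 * (hi - lo)
        nb = n_rg_bins if dim == 0 else n_turn_bins
        edges.append(np.linspace(lo - pad, hi + pad, nb + 1))
    return edges


def kl_divergence_4d(
    sample: UnfoldedFeatureTable,
    reference: UnfoldedFeatureTable,
    bin_spec: list[np.ndarray] | tuple[int, int] | None = None,
) -> float:
    """KL divergence (nats) of the sample's 4D unfolded-state density from
    the reference's, on a shared histogram grid with a pseudocount of
    1/(reference count) in every bin."""
    if len(sample) == 0 or len(reference) == 0:
        raise ValueError("both feature tables must be nonempty")
    if bin_spec is None:
        edges = shared_bin_edges(sample, reference)
    elif isinstance(bin_spec, tuple):
        edges = shared_bin_edges(sample, reference, *bin_spec)
    else:
        edges = list(bin_spec)
    p, _ = np.histogramdd(sample.values, bins=edges)
    q, _ = np.histogramdd(reference.values, bins=edges)
    return kl_divergence_histogram(p, q, pseudocount=1.0 / len(reference))


# -- helix formation order -----------------------------------------------------


@dataclass
class HelixOrderResult:
    """Per-folding-event order labels ("132" = helix 1 first, helix 3
    second, helix 2 third), their frequencies with binomial standard errors
    (events treated as independent), and the count of events in which some
    helix never formed."""

    labels: list[str]
    frequencies: dict[str, float]
    stderr: dict[str, float]
    n_incomplete: int = 0


def helix_formation_order(
    traj: Trajectory,
    seg: StateSegmentation,
    helix_ranges: list[tuple[int, int]] | None = None,
    system: ParticleSystem | None = None,
    formation_fraction: float = 0.8,
) -> HelixOrderResult:
    """Order of helix formation within each folding event.

    A helix "forms" at the first frame inside the event window where its turn
    count reaches >= formation_fraction of its folded-state mean and stays
    at or above that level through the event's end. Ties are broken by helix
    index. Events in which some helix never forms are labeled incomplete and
    excluded from the frequencies.
    """
    fold_events = [e for e in seg.events if e.type == "folding"]
    if not fold_events:
        raise ValueError("no folding events in segmentation")
    df = _frame_features(traj, helix_ranges, system)
    turns = df[list(_TURN_CHANNELS)].to_numpy()
    folded_mask = seg.labels == FOLDED
    if not folded_mask.any():
        raise ValueError("no folded frames to define folded-state turn means")
    thresholds = formation_fraction * turns[folded_mask].mean(axis=0)

    labels: list[str] = []
    n_incomplete = 0
    for ev in fold_events:
        window = turns[ev.start : ev.end + 1]
        times = np.full(3, -1)
        for h in range(3):
            above = window[:, h] >= thresholds[h]
            # earliest start of a run of "above" lasting to the window end
            below = np.flatnonzero(~above)
            first = (below[-1] + 1) if below.size else 0
            if first < len(above):
                times[h] = first
        if np.any(times < 0):
            n_incomplete += 1
            continue
        labels.append("".join(str(h + 1) for h in np.argsort(times, kind="stable")))
    freq: dict[str, float] = {}
    err: dict[str, float] = {}
    n = len(labels)
    for lab in sorted(set(labels)):
        f = labels.count(lab) / n
        freq[lab] = f
        err[lab] = float(np.sqrt(f * (1.0 - f) / n))
    return HelixOrderResult(
        labels=labels, frequencies=freq, stderr=err, n_incomplete=n_incomplete
    )
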