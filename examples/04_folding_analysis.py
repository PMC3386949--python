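"""Folding-trajectory analytics on a ground-truth-known synthetic trajectory.

Generates a hidden two-state (folded/unfolded) trajectory with known folding
free energy and helix-formation order, then runs the full analysis chain:
transition-based state assignment, population free energy with a blocking
standard error, unfolded-state projection, Kullback-Leibler divergence
against an independent replicate, and helix-formation-order statistics.
"""

from cutoffmd import TwoStateSpec, generate_two_state_trajectory
from cutoffmd.analysis import (
    folding_free_energy,
    helix_formation_order,
    kl_divergence_4d,
    transition_assign,
    unfolded_features,
)

traj, truth = generate_two_state_trajectory(TwoStateSpec(n_frames=100_000, seed=11))
seg = transition_assign(traj.features["rmsd"])  # hysteresis at 2.5 / 6.0 A

print(f"true events: {len(truth.events)}   detected: {len(seg.events)}")
thermo = folding_free_energy(seg, truth.temperature)
print(
    f"folding dG: {thermo.delta_g:+.3f} +- {thermo.delta_g_stderr:.3f} kcal/mol "
    f"(ground truth {truth.delta_g:+.3f})"
)
# dG > 0 because the unfolded state is more populated (p_folded = 0.3); the
# blocking standard error accounts for the frame-to-frame correlation of the
# folded-indicator series.

table = unfolded_features(traj, seg)
print(f"unfolded-state frames projected into (Rg, turns 1-3): {len(table)}")
print(f"mean unfolded Rg: {table.data['rg'].mean():.2f} A")

replicate, _ = generate_two_state_trajectory(TwoStateSpec(n_frames=100_000, seed=12))
seg2 = transition_assign(replicate.features["rmsd"])
table2 = unfolded_features(replicate, seg2)
kl = kl_divergence_4d(table, table2)
print(f"KL divergence between independent replicates: {kl:.4f} nats")
# This same-generator divergence (~0.01-0.02 nats) is the statistical floor:
# smaller differences between two simulations cannot be resolved at this
# sampling depth.

order = helix_formation_order(traj, seg)
print(f"helix formation order frequencies: {order.frequencies}")
print(f"(generator prescribed helix 1 -> helix 3 -> helix 2, label '132')")
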