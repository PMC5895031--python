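"""RMSD / RMSF / radius-of-gyration statistics on synthetic trajectories.

Generates two trajectories of a 169-residue helical chain — a quiet
"wild-type" and a "mutant" with doubled fluctuations — then compares their
post-equilibration backbone RMSD with a normality-gated two-sample test.
"""

import numpy as np

from varstab import synth, traj

reference = synth.helical_reference(169, atoms="backbone")
systems = {
    "wt": synth.gen_trajectory(reference, n_frames=600, sigma=0.5, seed=1),
    "mutant": synth.gen_trajectory(reference, n_frames=600, sigma=1.0, seed=2),
}

equil_start_ns = 5.0  # 600 frames x 25 ps = 15 ns of sampling
samples = {}
for label, sim in systems.items():
    t = sim.trajectory.times_ns
    rmsd = traj.rmsd_series(sim.trajectory, selection="backbone")
    stats = traj.equilibrium_stats(t, rmsd, equil_start_ns)
    rmsf = traj.rmsf_profile(sim.trajectory, equil_start_ns=equil_start_ns)
    rg = traj.rg_series(sim.trajectory)
    rg_stats = traj.equilibrium_stats(t, rg, equil_start_ns)
    samples[label] = rmsd[t >= equil_start_ns]
    print(f"{label:>7}: backbone RMSD {stats.mean:.2f} ({stats.sd:.2f}) A | "
          f"Ca-RMSF {np.median(rmsf.values):.2f} A | "
          f"Rg {rg_stats.mean:.2f} ({rg_stats.sd:.2f}) A")

result = traj.compare_groups(samples["wt"], samples["mutant"])
print(f"wt vs mutant backbone RMSD: {result.test_name}, "
      f"p = {result.pvalue:.3g} -> {'significant' if result.significant else 'n.s.'}")
print(f"model-quality Z-score example (1, 1, 1): {traj.model_zscore(1, 1, 1):.4f}")

# Larger equilibrium RMSD/RMSF at unchanged Rg is the signature of a more
# flexible but similarly compact structure.
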