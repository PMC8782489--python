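"""Multi-duplex condensation metrics: ΔCOM, axis alignment and diffusion.

Generates two 15-duplex Brownian ensembles — one isotropic (like a charge-
screened control) and one partially aligned (like a condensing system) —
and reports the three observables used to characterize pseudo-fiber
formation.
"""

import numpy as np

import groovetherm as gt

iso = gt.gen_duplex_ensemble(gt.EnsembleSpec(
    n_duplexes=15, order_parameter=0.5, diffusion_D=0.01,
    n_frames=4000, dt=1.0, seed=7))
aligned = gt.gen_duplex_ensemble(gt.EnsembleSpec(
    n_duplexes=15, order_parameter=0.9, diffusion_D=0.002,
    n_frames=4000, dt=1.0, seed=8))

for label, ens in (("isotropic control", iso), ("aligned system", aligned)):
    corr = gt.axis_correlation(ens, windows={"first 10 ns": (0.0, 10.0),
                                             "last 10 ns": (3989.0, 3999.0)})
    print(f"{label}:")
    print(f"  mean pairwise |cos| = {corr.order_parameter:.3f} "
          f"(0.5 isotropic, 1.0 parallel fiber)")
    print(f"  window means: " + ", ".join(
        f"{k}: {v:.3f}" for k, v in corr.window_means.items()))
    msd = gt.msd_diffusion(ens, fit_window=(100.0, 1000.0))
    print(f"  diffusion D = {msd.D:.4f} A^2/ns "
          f"(fit r^2 = {msd.linear_r2:.3f})")

dcom = gt.com_series(aligned, iso)
print(f"\nDelta-COM (aligned minus control), last frame: {dcom[-1]:+.1f} A")
print("A negative Delta-COM with rising axis correlation indicates the "
      "duplexes are packing closer and more parallel than the control — "
      "the condensation signature.")
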