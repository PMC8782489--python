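"""Alchemical free energies by the Crooks intersection and thermodynamic
cycles.

Draws forward/reverse work ensembles (184 runs each, as in the alchemical
protocol) satisfying the Crooks fluctuation theorem with known ΔG,
estimates ΔG from the crossing of the work densities, cross-checks with
the Bennett acceptance ratio, and combines single-strand and duplex legs
into the salt effect on folding per A·T→G·C substitution.
"""

import numpy as np

import groovetherm as gt

kT = gt.kBT_kJ(300.0)

ws = gt.gen_work_set(gt.WorkModelSpec(dG=10.0, sigma=np.sqrt(2.0),
                                      n_forward=184, n_reverse=184, seed=5))
ck = gt.crooks_intersection(ws, seed=5)
br = gt.bar_estimate(ws, seed=5)
print(f"Ground truth          dG = 10.000 kBT")
print(f"Crooks intersection   dG = {ck.dG_kBT:.3f} +- {ck.stderr_kBT:.3f} kBT")
print(f"BAR cross-check       dG = {br.dG_kBT:.3f} +- {br.stderr_kBT:.3f} kBT")
print(f"Bandwidth sensitivity (x0.5/x1/x2 Scott): "
      + ", ".join(f"{v / kT:.3f}" for v in
                  ck.bandwidth_sensitivity.values()) + " kBT")

# thermodynamic cycle: A->G / T->C mutations in ss tetramer and ds decamer,
# in the NaCl reference and in an organic salt; a positive overall value
# means the organic salt favours folding of AT-rich duplexes
print("\nThermodynamic cycles per mutation context:")
overall = []
rng = np.random.default_rng(6)
for ctx in gt.MUTATION_CONTEXTS:
    legs = {}
    for leg, base in (("ss", 40.0), ("ds", 80.0)):
        vals = {}
        for salt, shift in (("NaCl", 0.0), ("ArgCl", 1.2 if leg == "ds"
                                            else 0.2)):
            spec = gt.WorkModelSpec(
                dG=(base + shift + rng.normal(0, 0.1)) * 1.0, sigma=1.5,
                seed=int(rng.integers(1 << 31)))
            est = gt.crooks_intersection(gt.gen_work_set(spec), n_boot=0)
            vals[salt] = est.dG
        legs[leg] = vals
    cyc = gt.combine_cycle(legs["ss"], legs["ds"], "ArgCl", n_subs=2,
                           contexts=[ctx])
    overall.append(cyc.ddG_overall / kT)
    print(f"  {ctx:10s} ddG_ss = {cyc.ddG_ss / kT:+.2f}  "
          f"ddG_ds = {cyc.ddG_ds / kT:+.2f}  "
          f"overall = {cyc.ddG_overall / kT:+.2f} kBT per substitution")

t, p = gt.significance(overall)
print(f"\nOne-sample t-test of the overall values: t = {t:.2f}, p = {p:.3f}")
print("overall > 0 with small p: switching NaCl -> ArgCl shifts folding "
      "stability toward the AT-rich duplex.")
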