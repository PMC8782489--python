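# groovetherm

Analysis toolkit for the question of how basic amino-acid cations (Arg⁺,
Lys⁺, ornithine, DABA) reshape the stability landscape of DNA duplexes.
AT-rich and GC-rich duplexes differ strongly in stability under ordinary
inorganic salts — a problem for any non-enzymatic, sequence-agnostic
replication scenario — and organic cations that bind the grooves can
shrink that gap. `groovetherm` implements, as a tested Python library,
every computation needed to quantify this from UV-melting experiments and
MD trajectories:

- **Melting thermodynamics** — melting temperature from the smoothed first
  derivative of absorbance curves, and van 't Hoff parameters from the
  concentration dependence: 1/Tm = (R/Δ<sub>r</sub>H⁰)·ln(C<sub>t</sub>/2) +
  Δ<sub>r</sub>S⁰/Δ<sub>r</sub>H⁰, with ΔG⁰(300 K) = Δ<sub>r</sub>H⁰ −
  300·Δ<sub>r</sub>S⁰.
- **Helicoidal ion densities** — particles mapped to curvilinear
  coordinates (D, R, A) about the instantaneous helical axis; the minor
  groove is the azimuthal window [33°, 147°), the inner-groove radius
  10.25 Å and the radial cutoff 20.5 Å; densities are reported as
  molarities and enrichments over bulk.
- **Mechanics** — the twelve Cambridge-convention helical parameters by the
  mid-frame construction; elastic force constants K = k<sub>B</sub>T·C⁻¹
  from the parameter covariance C; Kullback–Leibler divergence between
  conditions; groove widths from cross-strand P–P distances; WC
  hydrogen-bond counts; essential dynamics (positional-covariance
  eigenvalues and subspace overlap).
- **Non-equilibrium free energies** — the Crooks fluctuation theorem
  P<sub>F</sub>(W)/P<sub>R</sub>(−W) = e^{β(W−ΔG)} locates ΔG at the
  crossing of the forward and mirrored-reverse work densities (Gaussian
  KDE); the Bennett acceptance ratio is the built-in cross-check; ss/ds
  mutation legs combine through thermodynamic cycles into
  ΔΔG<sub>XCl/NaCl</sub> per A·T→G·C substitution, with a one-sample
  t-test.
- **Condensation metrics** — for many-duplex systems: mean pairwise COM
  distance relative to a reference (ΔCOM), nematic axis alignment
  (pairwise |cos θ|), and diffusion from the MSD.

Every estimator is paired with a synthetic generator of known ground truth
(`groovetherm.synthetic`), so the whole pipeline is testable by parameter
recovery without multi-microsecond trajectories.

## Worked example

```python
import groovetherm as gt

tm_by_ct = {}
for j, ct in enumerate((1e-6, 5e-6, 20e-6, 57e-6)):     # mol/L strands
    spec = gt.MeltingModelSpec(dH_assoc=-100.0, dS_assoc=-0.270, Ct=ct,
                               noise_sd=0.003, seed=10 + j)
    tm_by_ct[ct] = gt.find_tm(gt.gen_melting_curve(spec))
fit = gt.fit_vant_hoff(tm_by_ct)
print(fit.dH, fit.dS, fit.dG300, fit.r2)
```

Running `python examples/melting_thermodynamics.py` (which does the above
for an AT-rich-like and a GC-rich-like duplex) prints:

```
AT-rich duplex (true dH=-100.0, dS=-0.27):
  Ct =   1.0 uM   Tm =  334.34 K
  Ct =   5.0 uM   Tm =  338.13 K
  Ct =  20.0 uM   Tm =  341.30 K
  Ct =  57.0 uM   Tm =  343.80 K
  fitted dH =   -97.83 kcal/mol, dS =  -0.2637 kcal/mol/K, dG(300 K) = -18.71 kcal/mol, r^2 = 0.9999
```

Tm rises with strand concentration as a bimolecular transition must; the
linear fit of 1/Tm against ln(Ct/2) recovers the generating association
enthalpy and entropy to ~2% under 0.3% absorbance noise, and ΔG⁰(300 K)
is the duplex stability that the different salt conditions shift.

The other `examples/` scripts exercise one capability each: groove-resolved
ion densities (`ion_density_maps.py`), stiffness/KL/essential dynamics
(`stiffness_and_flexibility.py`), Crooks free energies with thermodynamic
cycles (`crooks_free_energy.py`), duplex geometry
(`duplex_geometry.py`) and multi-duplex condensation
(`condensation_metrics.py`).

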