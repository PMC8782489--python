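# Methods

This note documents the models, conventions and numerical choices behind
`groovetherm`, and what the synthetic generators do and do not emulate.

## Two-state melting model and van 't Hoff analysis

A non-self-complementary duplex A+B ⇌ AB with total strand concentration
C_t melts in the all-or-none approximation with unfolded fraction

    θ(T) = 1 / (1 + K_assoc(T)·C_t/2),
    ln K_assoc(T) = −ΔH/(R T) + ΔS/R,

where ΔH < 0 and ΔS < 0 are the association enthalpy (kcal/mol) and
entropy (kcal/mol/K) and R = 1.987204×10⁻³ kcal/(mol K).  θ(Tm) = 1/2
exactly when 1/Tm = (R/ΔH)·ln(C_t/2) + ΔS/ΔH, which is the linear
relation the fitter inverts: ordinary least squares of 1/Tm on
ln(C_t/2), ΔH = R/slope, ΔS = intercept·ΔH, ΔG(300 K) = ΔH − 300·ΔS.
Parameters are stored in the association direction with a flag; condition
comparisons (ΔΔH, ΔΔS, ΔΔG) are reported with melting-direction signs.

Two deliberate conventions:

- **C_t/2, not C_t/4.**  The generator and the fitter share the ln(C_t/2)
  convention, so round trips are exact.  The textbook non-self-
  complementary convention ln(C_t/4) is available via `ct_divisor=4`; it
  changes only the intercept (hence ΔS), never ΔH.
- **Pseudo-first-order θ.**  With the full bimolecular quotient
  f/((1−f)²·C_t) the maximum of dθ/dT sits ≈1 K above the van 't Hoff Tm,
  biasing the recovered ΔS by ~0.3%.  The all-or-none form above — the
  approximation the C_t/2 convention itself encodes — keeps the
  derivative maximum within 0.06 K of Tm and the round-trip errors in ΔH
  and ΔS below 0.05%.

Tm is located on the Savitzky–Golay-smoothed curve (default window 11,
order 3; endpoints by the filter's polynomial end-fit) as the grid maximum
of dA/dT refined by three-point quadratic interpolation, removing the
~grid-resolution bias.  A maximum on the grid boundary, or a flat
derivative (relative spread ≤1e−9), is reported as "transition not
captured".  Temperatures are kelvin internally; CSV readers accept °C
with an explicit unit.

The melting-curve generator adds linear baselines (intercept+slope pairs)
and i.i.d. Gaussian absorbance noise.  Real instruments drift and real
baselines curve; linear baselines are an assumption of the generator, not
a claim about spectrophotometers, so the recovery tests speak to the
analysis pipeline, not to instrument artifacts.  Default grid: 20–100 °C
in 0.5 K steps, matching a 1 °C/min scan sampled twice per degree.

## Helicoidal coordinates and ion densities

Base-pair frames: origin at the midpoint of the paired C1′ atoms; y along
Watson C1′ → Crick C1′; z the helical advance (central differences of
consecutive origins, orthogonalized against y); x = y × z, pointing into
the major groove.  The instantaneous helical axis is a cubic
(optionally smoothing) spline through the bp origins against bp index —
deliberately simpler than a full optimal-axis refinement; every placement
and read-back in this package goes through the same convention, and on
straight axes the mapping is an exact inverse (≤1e−6 Å/deg; ≤0.1 Å/1° on
gently curved axes).

A particle maps to (D, R, A): D the arclength at the foot of its
projection onto the axis polyline (the end segments extend as infinite
lines so D can leave the duplex span), R the perpendicular distance, and
A the azimuth of the radial vector from the local reference axis toward
the local y, plus a fixed −90° calibration chosen so minor-groove probes
of the canonical fixture land at ≈90°, inside the minor-groove window.
Region labels partition space totally: minor iff A ∈ [33°, 147°)
(half-open resolves boundary ties), inner iff R ≤ 10.25 Å, outer iff
10.25 < R ≤ 20.5 Å, bulk beyond the cutoff or outside the bp-level span.
A particle exactly on the axis gets the sentinel (R=0, A=0).

Densities: per-cell molarity = (mean count per frame) / (N_A·V_cell·10⁻²⁷ L/Å³)
with the curvilinear cell volume ΔD·R̄·ΔR·ΔA(rad) at bin mid-radius —
exact for annular sectors, since (R₁²−R₀²)/2 = R̄·ΔR.  Bulk molarity uses
the box volume minus the cutoff cylinder.  Convergence is monitored by
the running mean of per-frame region occupancy and 10-block averages; a
drift flag fires when first and last blocks differ by >3 combined SE.
Radial profiles are shell-normalized per groove sector.

Reference atoms for amino-acid tracking default to the side-chain charge
carriers (NZ for Lys, CZ for Arg) alongside Cα; for synthetic clouds the
particles are point ions.

## Helical parameters, stiffness and essential dynamics

Step parameters (shift, slide, rise, tilt, roll, twist) use the symmetric
mid-frame construction: the two bp triads are rotated by ±Γ/2 about their
hinge (Γ from atan2 of the cross and dot of the z axes — full precision
at near-parallel z, which keeps rigid-motion invariance at 1e−8), the
twist is the signed x-to-x angle about the common z, translations are the
origin difference on the mid-frame axes, and (roll, tilt) = Γ·(cos φ,
sin φ) with φ the hinge phase.  Intra-bp parameters (shear, stretch,
stagger, buckle, propeller, opening) apply the same algorithm between the
Watson base triad and the Crick base triad flipped 180° about its x.
This is the mid-frame family of conventions, not a curvilinear-axis
parameterization; all recovery tests are internal round trips against the
same convention.

Stiffness: K = k_B·T·C⁻¹ with C the 6×6 covariance of step parameters;
k_B·T(300 K) = 2.494 kJ/mol; units kJ/mol/Å², kJ/mol/deg² and mixed.  A
covariance with condition number >1e12 falls back to the pseudo-inverse
with a warning flag.  At least 10 frames per parameter are required.
"Overall stiffness" has no unique definition; the package reports, per
step, the arithmetic mean of the six diagonal constants plus separate
translational and rotational means and a z-scored profile mean, and the
molecule value as the mean over steps — all side by side, so the choice
is visible rather than buried.

KL divergence uses shared-bin histograms (50 bins over the pooled range,
pseudocount 1e−6 per bin before normalization), reported in nats; the
pseudocount keeps disjoint supports finite.

Groove widths follow the cross-strand phosphate convention: minor width
at level i is the minimum over offsets i−3…i−1 of |P_W(i) − P_C(j)| minus
a 5.8 Å phosphate-radius correction; major widths use the opposing
offsets i+1…i+3.  Terminal levels without partners are NaN.  Hydrogen
bonds count WC donor–acceptor pairs at ≤3.5 Å with a D–H···A angle ≥150°
(a common MD convention); an optional tail window restricts statistics to
the last fraction of frames.

Essential dynamics: frames are least-squares superposed (Kabsch) onto a
shared reference, the 3N×3N positional covariance is eigendecomposed,
eigenvalues are reported descending with the sum of the first k = 10, and
conditions are compared by that sum and by the covariance overlap
(1/k)·Σ_{i,j≤k}(v_i·w_j)² — 1 for identical essential subspaces, 0 for
orthogonal ones.  Whether to include all atoms or a backbone subset is
left to the caller's selection; the algorithm is agnostic.

## Crooks intersection and thermodynamic cycles

Work sets store forward and reverse works in kJ/mol at a stated
temperature.  The Crooks estimator builds Gaussian KDEs of W_F and −W_R
(Scott's rule by default; a float overrides the bandwidth as a Scott
multiplier) and takes ΔG as the root of their difference nearest the
midpoint of the two sample means, refined to 1e−6 kJ/mol; a sensitivity
report across ×{0.5, 1, 2} bandwidth is attached to every estimate.
Errors are a seeded 200-resample bootstrap.  Degenerate inputs
(W_F ≡ −W_R as multisets) return the midpoint with zero error;
non-overlapping densities raise an error that points to BAR.

The BAR cross-check solves the Bennett self-consistency equation
Σ_F f(β(M + W_F − ΔG)) = Σ_R f(β(−M + W_R + ΔG)), M = k_BT·ln(n_F/n_R),
by bracketed root finding to 1e−8 kJ/mol (the two sides are monotone in
ΔG, so the root is unique).  On Gaussian, Crooks-consistent work pairs at
n = 184/184 the two estimators agree within their combined standard
errors; the KDE-crossing estimate carries an intrinsic per-seed scatter
of ≈0.13 k_BT from pointwise density noise at the crossing, so individual
seeds can differ from BAR by more than that while the mean disagreement
stays near 0.1 k_BT.

Cycles: ΔΔG_ss = ΔG_mut(ss, XCl) − ΔG_mut(ss, NaCl), ΔΔG_ds analogous,
and the overall salt effect per A·T→G·C substitution is
(ΔΔG_ds − ΔΔG_ss)/n_subs with n_subs = 2 for the double-mutated decamer;
the ss tetramer leg enters whole by default (a `normalize_ss` flag exposes
the alternative, since the convention for the ss leg is ambiguous).
Positive overall values mean the organic salt favours folding of AT-rich
duplexes.  Significance is a two-sided one-sample t-test over the
mutation contexts; zero-variance input with nonzero mean is flagged as
degenerate (t = ∞, p = 0).

The work generator draws W_F ~ N(ΔG + βσ²/2, σ²) and
W_R ~ N(−ΔG + βσ²/2, σ²) (k_BT units, β = 1), which satisfies the Crooks
relation exactly in distribution — the mean forward plus mean reverse
work equals the dissipation βσ², an identity the tests check.

## Condensation metrics

ΔCOM compares the per-frame mean over duplex pairs of minimum-image COM
distances between a system and a reference (series interpolated to common
times); a displacement-from-start variant sits behind a flag because the
verbal definition admits both readings.  Axis alignment uses |cos θ| of
pairwise axis angles — the nematic convention, since duplex axes are
head–tail symmetric — with signed cosines also reported, window means
(e.g. first/last 10 ns) and the ensemble order parameter (0.5 isotropic,
1 parallel).  Diffusion comes from the MSD over duplexes and all time
origins on unwrapped COMs (unwrapping by accumulated minimum-image
displacements), with D = slope/6 by OLS over a stated lag window; a
linear-fit R² below 0.98 raises a non-diffusive flag (ballistic drift
trips it, Brownian motion does not).

The ensemble generator moves COMs by independent Gaussian steps of
variance 2·D·dt per dimension under periodic wrapping and draws axes from
a mixture of perfectly aligned (probability p) and isotropic directions;
E[mean pairwise |cos|] = 0.5 + 0.5p², so p = √(2S−1) targets order
parameter S, and redraws (up to 500) bring the realized mean within 0.02.
Axes are constant in time — the generator controls alignment, it does not
model rotational diffusion.

## The ideal-duplex fixture

The geometry fixture is an idealized, fiber-like B-DNA on a straight
axis: per bp at rise·i and phase φ = twist·i, antipodal C1′ atoms at
radius 5.2 Å (so bp origins lie exactly on the axis), phosphates at
radius 8.9 Å and phase φ∓54°, which makes the cross-strand pinch of the
backbones fall on the minor-groove face at its own axial height and makes
the minor groove the i−3…i−1 offset window; WC-edge pseudo-atoms
(donor/hydrogen on the Watson base, acceptor on the Crick base, 2 bonds
for A·T and 3 for G·C, 2.9 Å apart and collinear) plus an edge-centre
atom per base and minor/major groove marker atoms.  Curved-axis tests
bend this fixture's coordinates onto circular arcs; there is no
atomistic realism, sequence-dependent base geometry, solvation or
electrostatics.  Consequently the recovery tests demonstrate correctness
of the estimators under their stated models — not agreement with any
particular force field or with Curves+ output.

## Problem sizes and determinism

Statistical recovery tests use the sizes at which their tolerances are
meaningful: 1e5 samples for stiffness/KL recovery (sampling error ~0.5%),
184+184 works per Crooks set (the alchemical protocol's ensemble size)
with 100-seed replication, 500 frames for uniform-cloud density checks
(≥1e3 counts per cell), and 1e4 frames for diffusion recovery.  Every
stochastic routine takes one integer seed and uses a private
`numpy.random.Generator`; identical calls are bit-reproducible and no
global random state is touched.  The pipeline manifest records the
configuration, per-stage seeds and input hashes, and is byte-identical
across reruns apart from its timestamp.
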