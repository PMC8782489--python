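"""Synthetic-data generators with known ground truth.

Every input class the analysis stages consume can be generated here with
controlled parameters, so each downstream estimator is testable by
parameter recovery: two-state melting curves with linear baselines, ideal
B-DNA duplex trajectories, multivariate-Gaussian helical-parameter series
with a prescribed stiffness, helicoidally placed ion clouds, Gaussian work
pairs satisfying the Crooks relation exactly in distribution, and
Brownian multi-duplex ensembles with controlled axis alignment.

All randomness flows from one integer seed per generator call; no global
state is touched, and identical calls are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .condensation import DuplexEnsemble
from .constants import N_AVOGADRO, R_GAS_KCAL, kBT_kJ
from .crooks import WorkSet
from .helix import (HelicalAxis, RegionSpec, helicoidal_to_cartesian,
                    straight_axis, to_helicoidal)
from .mechanics import HelParSeries
from .melting import MeltingCurve
from .trajectory import Trajectory

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_N_WC_BONDS = {"A": 2, "T": 2, "G": 3, "C": 3}

#: Paper sequences (Watson strands): AT-rich Seq.1 and GC-rich Seq.2.
SEQ1_AT_RICH = "TATGTATATTTTGTAATTAA"
SEQ2_GC_RICH = "GTCCACGCCCGGTGCGACGG"


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

@dataclass
class MeltingModelSpec:
    """Two-state duplex melting model with linear absorbance baselines.

    dH_assoc / dS_assoc are the association enthalpy (kcal/mol) and entropy
    (kcal/mol/K), both negative; Ct is the total strand concentration
    (mol/L).  Baselines are (intercept, slope) pairs in absorbance units;
    the folded baseline applies at low temperature.
    """

    dH_assoc: float
    dS_assoc: float
    Ct: float
    T_grid: np.ndarray = field(
        default_factory=lambda: np.arange(293.15, 373.16, 0.5))
    baseline_low: tuple[float, float] = (0.0, 0.0)
    baseline_high: tuple[float, float] = (1.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if self.dH_assoc >= 0 or self.dS_assoc >= 0:
            raise ValueError("association dH and dS must be negative")
        if self.Ct <= 0:
            raise ValueError("strand concentration must be positive")
        if np.any(np.diff(self.T_grid) <= 0):
            raise ValueError("T_grid must be strictly increasing")

    @property
    def tm(self) -> float:
        """Closed-form melting temperature of the model (K)."""
        return 1.0 / ((R_GAS_KCAL / self.dH_assoc) * np.log(self.Ct / 2)
                      + self.dS_assoc / self.dH_assoc)


def two_state_unfolded_fraction(T, dH, dS, Ct) -> np.ndarray:
    """Unfolded fraction θ(T) = 1/(1 + K_assoc(T)·Ct/2).

    The all-or-none form consistent with the ln(Ct/2) concentration
    convention: θ(Tm) = 1/2 exactly when 1/Tm = (R/ΔH)ln(Ct/2) + ΔS/ΔH.
    """
    T = np.asarray(T, dtype=float)
    lnQ = -dH / (R_GAS_KCAL * T) + dS / R_GAS_KCAL + np.log(Ct / 2)
    return 1.0 / (1.0 + np.exp(lnQ))


def gen_melting_curve(spec: MeltingModelSpec, condition: str = "",
                      sequence_id: str = "") -> MeltingCurve:
    """Synthetic UV melting curve: baselines + two-state transition + noise."""
    T = spec.T_grid
    theta = two_state_unfolded_fraction(T, spec.dH_assoc, spec.dS_assoc,
                                        spec.Ct)
    b_lo = spec.baseline_low[0] + spec.baseline_low[1] * T
    b_hi = spec.baseline_high[0] + spec.baseline_high[1] * T
    A = b_lo + theta * (b_hi - b_lo)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        A = A + rng.normal(0.0, spec.noise_sd, size=T.shape)
    return MeltingCurve(T, A, spec.Ct, condition, sequence_id)


# ---------------------------------------------------------------------------
# helical-parameter fluctuations
# ---------------------------------------------------------------------------

@dataclass
class StiffnessSpec:
    """Ground-truth harmonic stiffness for Gaussian parameter sampling.

    K is a symmetric positive-definite matrix of force constants (kJ/mol
    per Å², per deg², or mixed); samples are drawn with covariance
    C = k_B·T·K⁻¹ about ``means``.
    """

    K: np.ndarray
    means: np.ndarray
    T: float = 300.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if not np.allclose(self.K, self.K.T):
            raise ValueError("K must be symmetric")
        if np.any(np.linalg.eigvalsh(self.K) <= 0):
            raise ValueError("K must be positive-definite")
        if self.n_frames < 2:
            raise ValueError("need n_frames >= 2")

    @property
    def covariance(self) -> np.ndarray:
        return kBT_kJ(self.T) * np.linalg.inv(self.K)


def gen_helpar_traj(spec: StiffnessSpec) -> HelParSeries:
    """Multivariate-Gaussian helical-parameter series with stiffness K."""
    C = spec.covariance
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, len(spec.means)))
    vals = spec.means + z @ L.T
    return HelParSeries(vals[:, None, :], None, ["step_0"], None)


# ---------------------------------------------------------------------------
# ion clouds
# ---------------------------------------------------------------------------

@dataclass
class IonCloudSpec:
    """Ion placement at target molarities per helicoidal region.

    ``region_molarity`` maps region labels (minor_inner, major_inner,
    minor_outer, major_outer) to mol/L within the axis span;
    ``bulk_molarity`` fills the box outside the radial cutoff.  The default
    axis is straight, centred in the orthorhombic ``box``.
    """

    region_molarity: dict[str, float] = field(default_factory=dict)
    bulk_molarity: float = 0.0
    box: tuple[float, float, float] = (120.0, 120.0, 120.0)
    axis: HelicalAxis | None = None
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.region_molarity.values()) \
                or self.bulk_molarity < 0:
            raise ValueError("molarities must be non-negative")
        if self.axis is None:
            n_pts, spacing = 20, 3.38
            length = (n_pts - 1) * spacing
            origin = (self.box[0] / 2, self.box[1] / 2,
                      (self.box[2] - length) / 2)
            self.axis = straight_axis(n_pts, spacing, origin)
        if len(self.axis.points) < 2:
            raise ValueError("axis needs at least 2 points")


@dataclass
class IonCloud:
    """Per-frame ion coordinate arrays plus the generating axis and box."""

    frames: list[np.ndarray]
    axis: HelicalAxis
    box: np.ndarray
    spec: IonCloudSpec


_LITRE_PER_A3 = 1e-27


def _region_geometry(region: str, spec: RegionSpec):
    """((R_lo, R_hi), (A_lo, A_hi)) of a groove region."""
    minor = region.startswith("minor")
    inner = region.endswith("inner")
    r = (0.0, spec.inner_R) if inner else (spec.inner_R, spec.cutoff_R)
    a = (spec.minor_lo, spec.minor_hi) if minor \
        else (spec.minor_hi, spec.minor_lo + 360.0)
    return r, a


def region_volume(region: str, spec: RegionSpec, length: float) -> float:
    """Curvilinear volume (Å³) of a groove region over an axis span."""
    (r0, r1), (a0, a1) = _region_geometry(region, spec)
    vol = length * 0.5 * (r1 ** 2 - r0 ** 2) * np.radians(a1 - a0)
    if vol <= 0:
        raise ValueError(f"region {region!r} has zero volume")
    return vol


def gen_ion_cloud(spec: IonCloudSpec) -> IonCloud:
    """Poisson ion counts per region at the target molarity, positions
    uniform within each curvilinear region; bulk uniform outside the
    cutoff cylinder."""
    rng = np.random.default_rng(spec.seed)
    axis = spec.axis
    L = axis.length
    rspec = spec.region_spec
    box = np.asarray(spec.box, dtype=float)
    v_box = float(np.prod(box))
    v_bulk = v_box - np.pi * rspec.cutoff_R ** 2 * L

    frames = []
    for _ in range(spec.n_frames):
        pts = []
        for region, mol in spec.region_molarity.items():
            vol = region_volume(region, rspec, L)
            lam = mol * N_AVOGADRO * vol * _LITRE_PER_A3
            n = rng.poisson(lam)
            if n == 0:
                continue
            (r0, r1), (a0, a1) = _region_geometry(region, rspec)
            D = rng.uniform(0.0, L, n)
            R = np.sqrt(rng.uniform(r0 ** 2, r1 ** 2, n))
            A = np.mod(rng.uniform(a0, a1, n), 360.0)
            pts.append(helicoidal_to_cartesian(axis, D, R, A))
        if spec.bulk_molarity > 0:
            lam = spec.bulk_molarity * N_AVOGADRO * v_bulk * _LITRE_PER_A3
            n = rng.poisson(lam)
            got = []
            while sum(len(g) for g in got) < n:
                cand = rng.uniform(0.0, 1.0, (max(n, 64), 3)) * box
                hc = to_helicoidal(axis, cand)
                keep = (hc.R > rspec.cutoff_R) | (hc.D < 0) | (hc.D > L)
                got.append(cand[keep])
            pts.append(np.concatenate(got)[:n])
        frames.append(np.concatenate(pts) if pts
                      else np.empty((0, 3)))
    return IonCloud(frames, axis, box, spec)


# ---------------------------------------------------------------------------
# work sets
# ---------------------------------------------------------------------------

@dataclass
class WorkModelSpec:
    """Gaussian work pairs satisfying the Crooks relation with known ΔG.

    ΔG and σ are in units of k_BT; forward works are N(ΔG + σ²/2, σ²) and
    reverse works N(−ΔG + σ²/2, σ²), so P_F(W)/P_R(−W) = exp(W − ΔG) holds
    exactly in distribution (β = 1 in k_BT units).
    """

    dG: float
    sigma: float
    n_forward: int = 184
    n_reverse: int = 184
    T: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_forward < 2 or self.n_reverse < 2:
            raise ValueError("need at least 2 works per direction")


def gen_work_set(spec: WorkModelSpec, label: str = "") -> WorkSet:
    rng = np.random.default_rng(spec.seed)
    kt = kBT_kJ(spec.T)
    mu_f = spec.dG + spec.sigma ** 2 / 2.0
    mu_r = -spec.dG + spec.sigma ** 2 / 2.0
    wf = rng.normal(mu_f, spec.sigma, spec.n_forward) * kt
    wr = rng.normal(mu_r, spec.sigma, spec.n_reverse) * kt
    return WorkSet(wf, wr, spec.T, label)


# ---------------------------------------------------------------------------
# multi-duplex ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Brownian rigid-duplex ensemble with controlled axis alignment.

    ``order_parameter`` is the target ensemble-mean pairwise |cos θ| of the
    axis vectors, from 0.5 (isotropic) to 1 (parallel); ``diffusion_D`` is
    the translational diffusion coefficient in Å²/ns.
    """

    n_duplexes: int = 15
    order_parameter: float = 0.5
    diffusion_D: float = 0.01
    n_frames: int = 1000
    dt: float = 1.0
    box: tuple[float, float, float] = (200.0, 200.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duplexes < 2:
            raise ValueError("need at least 2 duplexes")
        if not (0.5 <= self.order_parameter <= 1.0):
            raise ValueError("order_parameter must lie in [0.5, 1]")


def _pairwise_abs_cos(axes: np.ndarray) -> float:
    i, j = np.triu_indices(len(axes), k=1)
    return float(np.abs(np.sum(axes[i] * axes[j], axis=1)).mean())


def gen_duplex_ensemble(spec: EnsembleSpec,
                        tolerance: float = 0.02) -> DuplexEnsemble:
    """COMs follow independent Brownian steps (variance 2·D·dt per
    dimension, wrapped); axes mix perfectly aligned and isotropic duplexes
    so the realized mean pairwise |cos| matches the target within
    ``tolerance`` (rejection over redraws, best draw kept)."""
    rng = np.random.default_rng(spec.seed)
    n, nf = spec.n_duplexes, spec.n_frames
    box = np.asarray(spec.box, dtype=float)

    # mixture weight: fraction p aligned exactly along z, rest isotropic;
    # E[mean pairwise |cos|] = 0.5 + 0.5 p^2
    p = np.sqrt(max(2.0 * spec.order_parameter - 1.0, 0.0))
    best, best_err = None, np.inf
    for _ in range(500):
        aligned = rng.uniform(size=n) < p
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        v[aligned] = np.array([0.0, 0.0, 1.0])
        err = abs(_pairwise_abs_cos(v) - spec.order_parameter)
        if err < best_err:
            best, best_err = v, err
        if err <= tolerance:
            break
    axes = np.broadcast_to(best, (nf, n, 3)).copy()

    start = rng.uniform(0.0, 1.0, (n, 3)) * box
    steps = rng.normal(0.0, np.sqrt(2.0 * spec.diffusion_D * spec.dt),
                       (nf - 1, n, 3)) if nf > 1 else np.empty((0, n, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps,
                                                                     axis=0)])
    wrapped = np.mod(unwrapped, box)
    return DuplexEnsemble(wrapped, axes, spec.dt, box,
                          [f"duplex_{k}" for k in range(n)],
                          com_unwrapped=unwrapped)


# ---------------------------------------------------------------------------
# ideal duplex fixture
# ---------------------------------------------------------------------------

#: Fixture geometry (Å / deg): C1' ring radius, phosphate ring radius and
#: angular offset from the bp phase, WC-bond atom spacing and groove-marker
#: radius.  Idealized fiber-like B-DNA on a straight axis.
_R_C1 = 5.2
_R_P = 8.9
_P_OFFSET_DEG = 54.0
_BOND_HALF_SEP = 1.45     # donor/acceptor at ±1.45 Å about the bp centre
_BOND_SPREAD = 1.0        # in-plane spacing between WC bonds
_MARKER_R = 4.0           # minor/major groove marker radius


def complement_strand(sequence: str) -> str:
    """Watson–Crick complement, 5'->3' of the Crick strand."""
    return "".join(COMPLEMENT[b] for b in reversed(sequence))


def wc_pairing(n_bp: int) -> list[tuple[int, int]]:
    """(watson_resid, crick_resid) pairs for the fixture numbering."""
    return [(i, n_bp + i) for i in range(n_bp)]


def _unit(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([np.cos(a), np.sin(a), 0.0])


def gen_ideal_duplex_traj(sequence: str, twist_deg: float = 36.0,
                          rise_A: float = 3.38, n_frames: int = 1,
                          jitter_sd: float = 0.0, seed: int = 0) -> Trajectory:
    """Coarse ideal duplex on a straight axis with given twist and rise.

    Each residue carries a phosphate P, a sugar C1', a WC-edge centre
    pseudo-atom WCC, per-bond donor/hydrogen (WDk/WHk, strand-assigned to
    Watson) or acceptor (WAk, on Crick) pseudo-atoms, and the Watson
    residue additionally carries minor-/major-groove marker pseudo-atoms
    (MIN/MAJ).  The complementary strand is generated by Watson–Crick
    pairing, antiparallel.  Gaussian positional jitter of sd ``jitter_sd``
    is applied independently per frame and atom.

    The trajectory's ``meta`` holds the pairing list, sequence and the
    generating parameters.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if len(seq) < 4:
        raise ValueError("sequence must have length >= 4")
    n_bp = len(seq)

    names, resids, resnames, segids, xyz = [], [], [], [], []

    def add(res, name, resname, segid, pos):
        names.append(name)
        resids.append(res)
        resnames.append(resname)
        segids.append(segid)
        xyz.append(pos)

    for i, base in enumerate(seq):
        phi = i * twist_deg
        centre = np.array([0.0, 0.0, i * rise_A])
        y_dir = _unit(phi - 90.0)          # Watson C1' -> Crick C1'
        x_dir = _unit(phi + 180.0)         # toward the major groove
        rw, rc = i, n_bp + i
        wname, cname = "D" + base, "D" + COMPLEMENT[base]

        add(rw, "P", wname, "W", centre + _R_P * _unit(phi - _P_OFFSET_DEG))
        add(rw, "C1'", wname, "W", centre + _R_C1 * _unit(phi + 90.0))
        add(rw, "WCC", wname, "W", centre.copy())
        add(rw, "MIN", wname, "W", centre + _MARKER_R * _unit(phi))
        add(rw, "MAJ", wname, "W", centre + _MARKER_R * _unit(phi + 180.0))

        add(rc, "P", cname, "C", centre + _R_P * _unit(phi + _P_OFFSET_DEG))
        add(rc, "C1'", cname, "C", centre + _R_C1 * _unit(phi - 90.0))
        add(rc, "WCC", cname, "C", centre.copy())

        nb = _N_WC_BONDS[base]
        for k in range(nb):
            s = (k - (nb - 1) / 2.0) * _BOND_SPREAD
            anchor = centre + s * x_dir
            add(rw, f"WD{k + 1}", wname, "W",
                anchor - _BOND_HALF_SEP * y_dir)
            add(rw, f"WH{k + 1}", wname, "W",
                anchor + (1.0 - _BOND_HALF_SEP) * y_dir)
            add(rc, f"WA{k + 1}", cname, "C",
                anchor + _BOND_HALF_SEP * y_dir)

    # keep residues contiguous in the atom table (PDB writers/readers
    # re-split residues by file order)
    order = np.argsort(np.asarray(resids), kind="stable")
    names = [names[i] for i in order]
    resnames = [resnames[i] for i in order]
    segids = [segids[i] for i in order]
    xyz = [xyz[i] for i in order]
    resids = [resids[i] for i in order]

    base_coords = np.asarray(xyz)
    coords = np.broadcast_to(base_coords, (n_frames,) + base_coords.shape) \
        .copy()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)

    traj = Trajectory(coords, names, np.array(resids), resnames, segids)
    traj.meta.update(sequence=seq, pairing=wc_pairing(n_bp),
                     twist_deg=twist_deg, rise_A=rise_A,
                     jitter_sd=jitter_sd, seed=seed)
    return traj
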