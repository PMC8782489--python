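"""Helical-parameter statistics and duplex mechanics.

Covers extraction of the twelve Cambridge-convention helical parameters
from base(-pair) frames via the symmetric mid-frame construction,
Kullback–Leibler divergence between parameter distributions, harmonic
stiffness by covariance inversion (K = k_B·T·C⁻¹), groove widths from
cross-strand phosphate distances, Watson–Crick hydrogen-bond counting, and
essential dynamics (positional-covariance eigendecomposition with subspace
overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import kBT_kJ
from .helix import BasePairFrameSeries
from .trajectory import Trajectory

INTRA_PARAMS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
STEP_PARAMS = ("shift", "slide", "rise", "tilt", "roll", "twist")


# ---------------------------------------------------------------------------
# helical parameters
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * K
            + (1 - np.cos(angle_rad)) * (K @ K))


def _signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    return np.arctan2(np.dot(np.cross(a, b), about), np.dot(a, b))


def _mid_frame_params(T1: np.ndarray, o1: np.ndarray,
                      T2: np.ndarray, o2: np.ndarray):
    """Translations and rotations between two triads, mid-frame convention.

    Returns (translations, rotations): translations are (o2 − o1) on the
    mid-frame x/y/z axes (Å); rotations are (about_x, about_y, about_z) in
    degrees — the bend decomposed through the hinge phase angle, the third
    component the twist-like rotation about the shared z.
    """
    z1, z2 = T1[:, 2], T2[:, 2]
    hinge = np.cross(z1, z2)
    # atan2 keeps full precision for near-parallel z axes (arccos loses
    # ~sqrt(eps) there, which would break rigid-motion invariance)
    gamma = np.arctan2(np.linalg.norm(hinge), np.dot(z1, z2))
    if np.linalg.norm(hinge) < 1e-12:
        T1p, T2p = T1, T2
        hinge = T1[:, 1]  # parallel z axes: no bend, hinge immaterial
    else:
        T1p = _rotation_about(hinge, +gamma / 2) @ T1
        T2p = _rotation_about(hinge, -gamma / 2) @ T2
    zm = T1p[:, 2] / np.linalg.norm(T1p[:, 2])
    omega = _signed_angle(T1p[:, 0], T2p[:, 0], zm)
    Tm = _rotation_about(zm, omega / 2) @ T1p
    phase = _signed_angle(hinge, Tm[:, 1], zm)
    about_y = gamma * np.cos(phase)
    about_x = gamma * np.sin(phase)
    trans = Tm.T @ (o2 - o1)
    return trans, np.degrees([about_x, about_y, omega])


@dataclass
class HelParSeries:
    """Time series of helical parameters.

    ``step_values`` has shape (n_frames, n_bp − 1, 6) ordered as
    ``STEP_PARAMS``; ``bp_values`` (intra-bp, ordered ``INTRA_PARAMS``) is
    None when the trajectory lacks per-base frames.  Translations are in Å,
    rotations in degrees within (−180, 180].
    """

    step_values: np.ndarray
    bp_values: np.ndarray | None = None
    step_labels: list[str] | None = None
    bp_labels: list[str] | None = None

    def get(self, parameter: str) -> np.ndarray:
        """(n_frames, n_units) series of one named parameter."""
        if parameter in STEP_PARAMS:
            return self.step_values[:, :, STEP_PARAMS.index(parameter)]
        if parameter in INTRA_PARAMS:
            if self.bp_values is None:
                raise ValueError("intra-bp parameters unavailable")
            return self.bp_values[:, :, INTRA_PARAMS.index(parameter)]
        raise KeyError(parameter)


def helpar_extract(frames: BasePairFrameSeries) -> HelParSeries:
    """Helical parameters from a base-pair frame series.

    Step parameters come from consecutive bp triads; intra-bp parameters
    from the Watson base triad against the Crick base triad flipped 180°
    about its own x-axis (so that a perfect Watson–Crick pair scores zero
    on all six coordinates).
    """
    nf, n_bp = frames.n_frames, frames.n_bp
    if n_bp < 2:
        raise ValueError("need >= 2 base pairs for step parameters")
    steps = np.empty((nf, n_bp - 1, 6))
    for f in range(nf):
        for k in range(n_bp - 1):
            tr, rot = _mid_frame_params(frames.triads[f, k], frames.origins[f, k],
                                        frames.triads[f, k + 1],
                                        frames.origins[f, k + 1])
            steps[f, k] = np.concatenate([tr, rot])

    bp_vals = None
    if frames.base_triads_w is not None:
        flip = np.diag([1.0, -1.0, -1.0])
        bp_vals = np.empty((nf, n_bp, 6))
        for f in range(nf):
            for k in range(n_bp):
                Tc = frames.base_triads_c[f, k] @ flip
                tr, rot = _mid_frame_params(Tc, frames.base_origins_c[f, k],
                                            frames.base_triads_w[f, k],
                                            frames.base_origins_w[f, k])
                bp_vals[f, k] = np.concatenate([tr, rot])

    step_labels = [f"step_{k}" for k in range(n_bp - 1)]
    bp_labels = [f"bp_{k}" for k in range(n_bp)]
    return HelParSeries(steps, bp_vals, step_labels, bp_labels)


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def kl_divergence(a, b, bins: int = 50, pseudocount: float = 1e-6) -> float:
    """Histogram estimate of D_KL(a‖b) in nats.

    Both samples are binned on shared edges spanning the pooled range; a
    pseudocount is added to every bin before normalization, which keeps the
    estimate finite on disjoint supports.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty samples")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(a, bins=edges)[0].astype(float) + pseudocount
    q = np.histogram(b, bins=edges)[0].astype(float) + pseudocount
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


# ---------------------------------------------------------------------------
# stiffness
# ---------------------------------------------------------------------------

@dataclass
class StiffnessMatrix:
    """Harmonic force constants K = k_B·T·C⁻¹ for one bp step.

    Units follow the parameters: kJ/mol/Å² for translation-translation
    entries, kJ/mol/deg² for rotation-rotation, mixed for cross terms.
    The diagonal holds the "pure" force constants.
    """

    K: np.ndarray
    step_label: str = ""
    pseudo_inverse: bool = False

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.K)


def _stiffness_one(values: np.ndarray, T: float, label: str) -> StiffnessMatrix:
    nf, p = values.shape
    if nf < 10 * p:
        raise ValueError("need >= 10x more frames than parameters")
    C = np.cov(values, rowvar=False)
    C = np.atleast_2d(C)
    pseudo = False
    if np.linalg.cond(C) > 1e12:
        warnings.warn("singular covariance: falling back to pseudo-inverse")
        Ki = np.linalg.pinv(C)
        pseudo = True
    else:
        Ki = np.linalg.inv(C)
    return StiffnessMatrix(kBT_kJ(T) * Ki, label, pseudo)


def stiffness_from_covariance(series, T: float):
    """Stiffness matrices from parameter fluctuations.

    ``series`` may be a :class:`HelParSeries` (one matrix per bp step), a
    (n_frames, n_units, p) array, or a single (n_frames, p) sample block
    (one matrix).
    """
    if isinstance(series, HelParSeries):
        vals = series.step_values
        labels = series.step_labels
    else:
        vals = np.asarray(series, dtype=float)
        if vals.ndim == 2:
            return _stiffness_one(vals, T, "")
        labels = [f"step_{k}" for k in range(vals.shape[1])]
    return [_stiffness_one(vals[:, k, :], T, labels[k])
            for k in range(vals.shape[1])]


@dataclass
class OverallStiffness:
    """Scalar stiffness summaries: per step and molecule-averaged.

    ``combined`` is the arithmetic mean of the six diagonal constants;
    translations (shift/slide/rise) and rotations (tilt/roll/twist) are
    also averaged separately, and ``zscored`` averages the per-constant
    z-scores across steps (dimensionless profile shape).
    """

    per_step_combined: np.ndarray
    per_step_translational: np.ndarray
    per_step_rotational: np.ndarray
    per_step_zscored: np.ndarray
    molecule_combined: float
    molecule_translational: float
    molecule_rotational: float


def overall_stiffness(matrices: list[StiffnessMatrix]) -> OverallStiffness:
    if len(matrices) == 0:
        raise ValueError("no stiffness matrices given")
    diags = np.array([m.diagonal for m in matrices])  # (steps, p)
    p = diags.shape[1]
    n_tr = 3 if p == 6 else p
    comb = diags.mean(axis=1)
    tr = diags[:, :n_tr].mean(axis=1)
    rot = diags[:, n_tr:].mean(axis=1) if p > n_tr else np.full(len(matrices), np.nan)
    sd = diags.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = ((diags - diags.mean(axis=0)) / sd).mean(axis=1)
    return OverallStiffness(comb, tr, rot, z, float(comb.mean()),
                            float(tr.mean()), float(np.nanmean(rot)))


# ---------------------------------------------------------------------------
# grooves and hydrogen bonds
# ---------------------------------------------------------------------------

def groove_widths(traj: Trajectory, pairing: list[tuple[int, int]],
                  minor_offsets=(-3, -2, -1), major_offsets=(1, 2, 3),
                  correction: float = 5.8) -> dict[str, np.ndarray]:
    """Minor/major groove widths from cross-strand P–P distances.

    The width at bp level i is the minimum over the offset range of the
    distance from the Watson phosphate at level i to the Crick phosphate at
    level i+o, minus a phosphate-radius correction (5.8 Å).  Levels whose
    offsets leave the duplex are NaN.  Returns per-frame-per-level arrays
    plus level means.
    """
    n_bp = len(pairing)
    nf = traj.n_frames
    pw = np.full((nf, n_bp, 3), np.nan)
    pc = np.full((nf, n_bp, 3), np.nan)
    for k, (rw, rc) in enumerate(pairing):
        for arr, res in ((pw, rw), (pc, rc)):
            try:
                arr[:, k] = traj.atom_positions(res, "P")
            except KeyError:
                if k in (0, n_bp - 1):
                    continue  # terminal phosphate may be absent
                raise ValueError(f"residue {res} is missing its phosphate")

    def widths(offsets):
        w = np.full((nf, n_bp), np.nan)
        for i in range(n_bp):
            js = [i + o for o in offsets if 0 <= i + o < n_bp]
            if not js:
                continue
            d = np.stack([np.linalg.norm(pw[:, i] - pc[:, j], axis=1)
                          for j in js], axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                w[:, i] = np.nanmin(d, axis=1) - correction
        return w

    minor = widths(minor_offsets)
    major = widths(major_offsets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = {"minor": minor, "major": major,
               "minor_by_level": np.nanmean(minor, axis=0),
               "major_by_level": np.nanmean(major, axis=0),
               "minor_mean": float(np.nanmean(minor)),
               "major_mean": float(np.nanmean(major))}
    return out


def count_hbonds(traj: Trajectory, pairing: list[tuple[int, int]],
                 d_max: float = 3.5, angle_min: float = 150.0,
                 tail_window: float | None = None) -> dict:
    """Watson–Crick hydrogen bonds per frame.

    A WC donor/hydrogen pair (atoms ``WDk``/``WHk`` on one base) and the
    matching acceptor ``WAk`` on its partner count as bonded when the
    donor–acceptor distance is ≤ ``d_max`` Å and the D–H···A angle is
    ≥ ``angle_min`` degrees.  ``tail_window`` restricts the statistics to
    the last given fraction of frames.
    """
    known = {"DA", "DT", "DG", "DC"}
    triplets = []  # (donor_idx, h_idx, acceptor_idx)
    for rw, rc in pairing:
        for res in (rw, rc):
            mask = traj.resids == res
            rn = {traj.resnames[i] for i in np.where(mask)[0]}
            if not rn <= known:
                raise ValueError(f"unknown residue type(s) {rn - known} "
                                 f"in residue {res}")
        for k in range(1, 4):
            for donor_res, acc_res in ((rw, rc), (rc, rw)):
                try:
                    d = traj.atom_index(donor_res, f"WD{k}")
                    h = traj.atom_index(donor_res, f"WH{k}")
                    a = traj.atom_index(acc_res, f"WA{k}")
                except KeyError:
                    continue
                triplets.append((d, h, a))

    counts = np.zeros(traj.n_frames, dtype=int)
    for d, h, a in triplets:
        da = np.linalg.norm(traj.coords[:, d] - traj.coords[:, a], axis=1)
        v1 = traj.coords[:, d] - traj.coords[:, h]
        v2 = traj.coords[:, a] - traj.coords[:, h]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        counts += ((da <= d_max) & (ang >= angle_min)).astype(int)

    n_used = traj.n_frames
    if tail_window is not None:
        n_used = int(round(tail_window * traj.n_frames))
        counts_used = counts[traj.n_frames - n_used:]
    else:
        counts_used = counts
    return {"per_frame": counts_used, "n_frames_used": n_used,
            "mean": float(counts_used.mean()),
            "distribution": np.bincount(counts_used)}


# ---------------------------------------------------------------------------
# essential dynamics
# ---------------------------------------------------------------------------

@dataclass
class EDResult:
    """Essential-dynamics spectrum: eigenvalues in Å², descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    sum_first_k: float
    k: int

    @property
    def trace(self) -> float:
        return float(self.eigenvalues.sum())


def kabsch_superpose(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superposition of every frame onto the reference."""
    ref = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        x = coords[f] - coords[f].mean(axis=0)
        H = x.T @ ref
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        out[f] = x @ R.T
    return out


def ed_eigen(coords: np.ndarray, reference: np.ndarray, k: int = 10,
             align: bool = True) -> EDResult:
    """Eigendecomposition of the positional covariance of a trajectory.

    ``coords`` is (n_frames, n_atoms, 3); every frame is least-squares
    superposed onto the shared reference before the 3N×3N covariance is
    accumulated.  Requires at least k+1 frames.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} frames")
    x = kabsch_superpose(coords, np.asarray(reference, dtype=float)) \
        if align else coords
    flat = x.reshape(x.shape[0], -1)
    C = np.cov(flat, rowvar=False)
    return ed_from_covariance(C, k)


def ed_from_covariance(C: np.ndarray, k: int = 10) -> EDResult:
    C = np.atleast_2d(np.asarray(C, dtype=float))
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    kk = min(k, len(vals))
    return EDResult(vals, vecs, float(vals[:kk].sum()), kk)


def ed_sum_difference(a: EDResult, b: EDResult) -> float:
    """Difference of the first-k eigenvalue sums between two conditions."""
    return a.sum_first_k - b.sum_first_k


def covariance_overlap(cov_a: np.ndarray, cov_b: np.ndarray,
                       k: int = 10) -> float:
    """Normalized overlap of the leading k-dimensional eigen-subspaces.

    (1/k)·Σ_{i≤k,j≤k} (v_i·w_j)² over unit eigenvectors of each covariance:
    1 for identical subspaces, 0 for orthogonal ones.  Symmetric in its
    arguments.
    """
    A = np.atleast_2d(np.asarray(cov_a, dtype=float))
    B = np.atleast_2d(np.asarray(cov_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("covariance dimension mismatch")
    va = ed_from_covariance(A, k).eigenvectors[:, :k]
    vb = ed_from_covariance(B, k).eigenvectors[:, :k]
    M = va.T @ vb
    return float(np.sum(M * M) / k)
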