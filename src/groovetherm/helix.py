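"""Base-pair frames, instantaneous helical axis and curvilinear helicoidal
coordinates for DNA duplex trajectories.

A particle near a duplex is described by (D, R, A): arclength along the
instantaneous helical axis, radial distance from the axis, and azimuth in
the plane normal to the local tangent.  The minor groove of canonical
B-DNA occupies the azimuthal window [33°, 147°); the inner-groove radius
is 10.25 Å and the total radial cutoff 20.5 Å.  Densities are reported as
molarities by dividing mean per-cell counts by the curvilinear cell volume.

The axis is a smoothing spline through the base-pair origins — a simpler
convention than a full optimal-axis refinement, adopted because every
consumer in this package maps through the same convention (placement and
read-back are exact inverses on straight axes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, UnivariateSpline

from .constants import N_AVOGADRO
from .trajectory import Trajectory

#: Azimuth offset (deg) fixing A so that the minor groove of the canonical
#: fixture duplex is centred at 90°, inside the [33°, 147°) window.  The
#: raw angle is measured from the base-pair x-axis (major-groove direction)
#: toward the y-axis; the minor groove sits at raw 180°.
GROOVE_CALIBRATION_DEG: float = -90.0


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

@dataclass
class BasePairFrameSeries:
    """Per-frame, per-bp origins and orthonormal triads.

    origins : (n_frames, n_bp, 3) Å — midpoints of the paired C1' atoms.
    triads : (n_frames, n_bp, 3, 3) — columns are the x, y, z axes
        (x toward the major groove, y along Watson C1' -> Crick C1',
        z roughly the helical advance); right-handed, det = +1.
    base_triads_w / base_triads_c : per-base triads used for intra-bp
        helical parameters; same layout.  base_origins_* hold the WC-edge
        centre pseudo-atom positions.
    """

    origins: np.ndarray
    triads: np.ndarray
    base_triads_w: np.ndarray | None = None
    base_triads_c: np.ndarray | None = None
    base_origins_w: np.ndarray | None = None
    base_origins_c: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.origins.shape[0]

    @property
    def n_bp(self) -> int:
        return self.origins.shape[1]


def _orthonormal_triad(y: np.ndarray, z_hint: np.ndarray) -> np.ndarray:
    """Right-handed triad with exact y, z ≈ z_hint orthogonalized, x = y×z."""
    y = y / np.linalg.norm(y)
    z = z_hint - np.dot(z_hint, y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("degenerate (collinear) base-pair geometry")
    z = z / nz
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def compute_bp_frames(traj: Trajectory,
                      pairing: list[tuple[int, int]]) -> BasePairFrameSeries:
    """Base-pair origins and triads for every frame.

    ``pairing`` lists (watson_resid, crick_resid) per bp, 5'->3' along the
    Watson strand.  The origin is the midpoint of the two C1' atoms, the
    y-axis runs Watson C1' -> Crick C1', the z-axis follows the helical
    advance (central differences of the origins) and x = y × z.

    Per-base triads (for intra-bp parameters) are built from each residue's
    own atoms when the WC-edge centre pseudo-atom ``WCC`` and at least one
    WC-bond atom are present; otherwise they are omitted.
    """
    n_bp = len(pairing)
    nf = traj.n_frames
    c1w = np.empty((nf, n_bp, 3))
    c1c = np.empty((nf, n_bp, 3))
    for k, (rw, rc) in enumerate(pairing):
        try:
            c1w[:, k] = traj.atom_positions(rw, "C1'")
        except KeyError:
            raise ValueError(f"residue {rw} is missing its C1' atom") from None
        try:
            c1c[:, k] = traj.atom_positions(rc, "C1'")
        except KeyError:
            raise ValueError(f"residue {rc} is missing its C1' atom") from None

    origins = 0.5 * (c1w + c1c)
    triads = np.empty((nf, n_bp, 3, 3))
    for f in range(nf):
        o = origins[f]
        # helical-advance hints: central differences, one-sided at the ends
        hints = np.empty_like(o)
        hints[1:-1] = o[2:] - o[:-2]
        hints[0] = o[1] - o[0]
        hints[-1] = o[-1] - o[-2]
        for k in range(n_bp):
            triads[f, k] = _orthonormal_triad(c1c[f, k] - c1w[f, k], hints[k])

    series = BasePairFrameSeries(origins=origins, triads=triads)
    _attach_base_triads(traj, pairing, series)
    return series


def _base_triad(traj: Trajectory, resid: int, frame: int,
                strand_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """(origin, triad) of one base from its own atoms, or None if absent.

    y runs C1' -> WC-edge centre; the base normal is oriented along the
    strand's 5'->3' direction ``strand_dir``; x completes x = y × z.
    """
    try:
        c1 = traj.coords[frame, traj.atom_index(resid, "C1'")]
        wcc = traj.coords[frame, traj.atom_index(resid, "WCC")]
    except KeyError:
        return None
    edge = None
    for nm in ("WD1", "WA1", "WD2", "WA2", "WD3", "WA3"):
        try:
            edge = traj.coords[frame, traj.atom_index(resid, nm)]
            break
        except KeyError:
            continue
    if edge is None:
        return None
    a = wcc - c1
    b = edge - c1
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        return None
    n = n / nn
    if np.dot(n, strand_dir) < 0:
        n = -n
    return wcc, _orthonormal_triad(a, n)


def _attach_base_triads(traj: Trajectory, pairing: list[tuple[int, int]],
                        series: BasePairFrameSeries) -> None:
    nf, n_bp = series.n_frames, series.n_bp
    tw = np.empty((nf, n_bp, 3, 3))
    tc = np.empty((nf, n_bp, 3, 3))
    ow = np.empty((nf, n_bp, 3))
    oc = np.empty((nf, n_bp, 3))
    for f in range(nf):
        adv = series.origins[f]
        for k, (rw, rc) in enumerate(pairing):
            lo, hi = max(k - 1, 0), min(k + 1, n_bp - 1)
            up = adv[hi] - adv[lo]  # Watson 5'->3' advance
            got_w = _base_triad(traj, rw, f, up)
            got_c = _base_triad(traj, rc, f, -up)
            if got_w is None or got_c is None:
                return  # fixture lacks WC-edge pseudo-atoms; skip intra-bp
            ow[f, k], tw[f, k] = got_w
            oc[f, k], tc[f, k] = got_c
    series.base_triads_w, series.base_triads_c = tw, tc
    series.base_origins_w, series.base_origins_c = ow, oc


# ---------------------------------------------------------------------------
# helical axis
# ---------------------------------------------------------------------------

@dataclass
class HelicalAxis:
    """Ordered axis points with tangents, azimuth references and arclength.

    ``ref`` holds, per axis point, the unit vector from which azimuths are
    measured (the bp x-axis projected perpendicular to the tangent).
    """

    points: np.ndarray      # (n, 3) Å
    tangents: np.ndarray    # (n, 3) unit
    ref: np.ndarray         # (n, 3) unit, perpendicular to tangent
    arclength: np.ndarray   # (n,) cumulative chord length, Å

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


def straight_axis(n_points: int, spacing: float,
                  origin=(0.0, 0.0, 0.0)) -> HelicalAxis:
    """Straight axis along +z with the reference direction along +x."""
    if n_points < 2:
        raise ValueError("axis needs at least 2 points")
    pts = np.asarray(origin, dtype=float) + np.outer(
        np.arange(n_points) * spacing, np.array([0.0, 0.0, 1.0]))
    tan = np.tile([0.0, 0.0, 1.0], (n_points, 1))
    ref = np.tile([1.0, 0.0, 0.0], (n_points, 1))
    arc = np.arange(n_points) * spacing
    return HelicalAxis(pts, tan, ref, arc.astype(float))


def fit_helical_axis(frames: BasePairFrameSeries, frame: int = 0,
                     smoothing: float = 0.0) -> HelicalAxis:
    """Axis through the bp origins of one frame.

    A cubic (smoothing) spline is fitted per coordinate against bp index;
    ``smoothing=0`` interpolates the origins exactly.  Tangents are
    normalized first differences; arclength is chord-summed; the azimuth
    reference is the bp x-axis orthogonalized against the tangent.
    """
    if frames.n_bp < 4:
        raise ValueError("need at least 4 base pairs to fit an axis")
    o = frames.origins[frame]
    idx = np.arange(frames.n_bp, dtype=float)
    if smoothing > 0:
        pts = np.column_stack([
            UnivariateSpline(idx, o[:, d], k=3, s=smoothing)(idx)
            for d in range(3)])
    else:
        pts = np.column_stack([CubicSpline(idx, o[:, d])(idx)
                               for d in range(3)])

    diffs = np.empty_like(pts)
    diffs[1:-1] = pts[2:] - pts[:-2]
    diffs[0] = pts[1] - pts[0]
    diffs[-1] = pts[-1] - pts[-2]
    tangents = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)

    xaxes = frames.triads[frame, :, :, 0]
    ref = xaxes - np.sum(xaxes * tangents, axis=1, keepdims=True) * tangents
    ref = ref / np.linalg.norm(ref, axis=1, keepdims=True)

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return HelicalAxis(pts, tangents, ref, arc)


# ---------------------------------------------------------------------------
# helicoidal coordinates
# ---------------------------------------------------------------------------

@dataclass
class HelicoidalCoords:
    """Arrays of (D, R, A) positions; ``region`` filled by assign_region."""

    D: np.ndarray
    R: np.ndarray
    A: np.ndarray
    region: np.ndarray | None = None


def _local_frame(axis: HelicalAxis, seg: np.ndarray, t: np.ndarray):
    """Interpolated point/tangent/reference at parameter t of segment seg."""
    p = axis.points[seg] + t[:, None] * (axis.points[seg + 1] - axis.points[seg])
    tan = (1 - t)[:, None] * axis.tangents[seg] + t[:, None] * axis.tangents[seg + 1]
    tan = tan / np.linalg.norm(tan, axis=1, keepdims=True)
    ref = (1 - t)[:, None] * axis.ref[seg] + t[:, None] * axis.ref[seg + 1]
    ref = ref - np.sum(ref * tan, axis=1, keepdims=True) * tan
    ref = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    s = axis.arclength[seg] + t * (axis.arclength[seg + 1] - axis.arclength[seg])
    return p, tan, ref, s


def to_helicoidal(axis: HelicalAxis, positions: np.ndarray) -> HelicoidalCoords:
    """Map Cartesian particle positions to (D, R, A).

    Each particle is projected onto its nearest axis segment; D is the
    arclength at the foot point, R the distance to the axis and A the
    azimuth of the radial vector measured from the local reference axis
    toward the local y-axis, shifted by the groove calibration so canonical
    minor-groove probes land inside [33°, 147°).  A particle on the axis is
    returned as the (R=0, A=0) sentinel.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n_seg = len(axis.points) - 1
    if n_seg < 1:
        raise ValueError("axis must contain at least one segment")

    a = axis.points[:-1]                        # (S, 3)
    ab = axis.points[1:] - a                    # (S, 3)
    ab2 = np.sum(ab * ab, axis=1)               # (S,)
    # (P, S) projection parameter, clamped to the segment
    diff = pos[:, None, :] - a[None, :, :]      # (P, S, 3)
    t_raw = np.einsum("psd,sd->ps", diff, ab) / ab2[None, :]
    t = np.clip(t_raw, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = np.sum((pos[:, None, :] - foot) ** 2, axis=2)
    seg = np.argmin(d2, axis=1)
    rows = np.arange(len(pos))
    tbest = t[rows, seg]
    # particles projecting past the first/last axis point: extend the end
    # segment as an infinite line so D can leave the span (-> bulk) and the
    # radial distance stays perpendicular
    t_end = t_raw[rows, seg]
    end = ((seg == 0) & (t_end < 0)) | ((seg == n_seg - 1) & (t_end > 1))
    tbest = np.where(end, t_end, tbest)

    p, tan, ref, s = _local_frame(axis, seg, tbest)
    v = pos - p
    v_perp = v - np.sum(v * tan, axis=1, keepdims=True) * tan
    R = np.linalg.norm(v_perp, axis=1)
    yloc = np.cross(tan, ref)
    raw = np.degrees(np.arctan2(np.sum(v_perp * yloc, axis=1),
                                np.sum(v_perp * ref, axis=1)))
    A = np.mod(raw + GROOVE_CALIBRATION_DEG, 360.0)
    A[R < 1e-9] = 0.0
    R[R < 1e-9] = 0.0
    return HelicoidalCoords(D=s, R=R, A=A)


def helicoidal_to_cartesian(axis: HelicalAxis, D, R, A) -> np.ndarray:
    """Inverse of :func:`to_helicoidal` (exact on straight axes)."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    R = np.atleast_1d(np.asarray(R, dtype=float))
    A = np.atleast_1d(np.asarray(A, dtype=float))
    seg = np.clip(np.searchsorted(axis.arclength, D, side="right") - 1,
                  0, len(axis.points) - 2)
    ds = axis.arclength[seg + 1] - axis.arclength[seg]
    t = (D - axis.arclength[seg]) / ds
    p, tan, ref, _ = _local_frame(axis, seg, t)
    yloc = np.cross(tan, ref)
    raw = np.radians(A - GROOVE_CALIBRATION_DEG)
    return p + R[:, None] * (np.cos(raw)[:, None] * ref
                             + np.sin(raw)[:, None] * yloc)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Groove/radius boundaries: minor groove [33°, 147°), inner radius
    10.25 Å, total radial cutoff 20.5 Å."""

    minor_lo: float = 33.0
    minor_hi: float = 147.0
    inner_R: float = 10.25
    cutoff_R: float = 20.5

    def __post_init__(self) -> None:
        if not (0 <= self.minor_lo < self.minor_hi < 360):
            raise ValueError("invalid minor-groove window")
        if not (0 < self.inner_R < self.cutoff_R):
            raise ValueError("invalid radial boundaries")


REGIONS = ("minor_inner", "major_inner", "minor_outer", "major_outer", "bulk")


def assign_region(coords: HelicoidalCoords, spec: RegionSpec = RegionSpec(),
                  d_span: tuple[float, float] | None = None) -> np.ndarray:
    """Label every particle with exactly one region.

    Minor iff A in [minor_lo, minor_hi) (half-open); inner iff R <= inner_R;
    outer iff inner_R < R <= cutoff_R; bulk beyond the cutoff or when D
    falls outside ``d_span`` (the duplex's bp-level span).
    """
    minor = (coords.A >= spec.minor_lo) & (coords.A < spec.minor_hi)
    labels = np.full(coords.R.shape, "bulk", dtype=object)
    inner = coords.R <= spec.inner_R
    outer = (coords.R > spec.inner_R) & (coords.R <= spec.cutoff_R)
    labels[inner & minor] = "minor_inner"
    labels[inner & ~minor] = "major_inner"
    labels[outer & minor] = "minor_outer"
    labels[outer & ~minor] = "major_outer"
    if d_span is not None:
        off = (coords.D < d_span[0]) | (coords.D > d_span[1])
        labels[off] = "bulk"
    coords.region = labels
    return labels


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

_LITRE_PER_A3 = 1e-27


def _molarity(mean_count: float, volume_A3: float) -> float:
    if volume_A3 <= 0:
        raise ValueError("zero-volume cell")
    return mean_count / (N_AVOGADRO * volume_A3 * _LITRE_PER_A3)


@dataclass
class DensityMap:
    """(R, A) molarity map integrated over the duplex arclength span."""

    r_edges: np.ndarray
    a_edges: np.ndarray
    counts: np.ndarray        # mean count per frame per cell
    molarity: np.ndarray      # mol/L per cell
    bulk_molarity: float
    d_span: tuple[float, float]


def density_map(frames: list[HelicoidalCoords], r_edges, a_edges,
                d_span: tuple[float, float],
                box_volume: float | None = None,
                spec: RegionSpec = RegionSpec()) -> DensityMap:
    """Molarity-normalized (R, A) density map.

    Cell volume is the curvilinear ΔD·R̄·ΔR·ΔA(rad) with ΔD the arclength
    span and R̄ the bin mid-radius.  Bulk molarity comes from the particles
    beyond the radial cutoff (or outside the span), normalized by the box
    volume minus the cutoff cylinder; it requires ``box_volume``.
    """
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    r_edges = np.asarray(r_edges, dtype=float)
    a_edges = np.asarray(a_edges, dtype=float)
    nf = len(frames)
    counts = np.zeros((len(r_edges) - 1, len(a_edges) - 1))
    n_bulk = 0.0
    for fr in frames:
        inside = (fr.D >= d_span[0]) & (fr.D <= d_span[1])
        h, _, _ = np.histogram2d(fr.R[inside], fr.A[inside],
                                 bins=[r_edges, a_edges])
        counts += h
        n_bulk += np.sum(~inside | (fr.R > spec.cutoff_R))
    counts /= nf
    n_bulk /= nf

    L = d_span[1] - d_span[0]
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    dr = np.diff(r_edges)
    da = np.radians(np.diff(a_edges))
    vol = L * r_mid[:, None] * dr[:, None] * da[None, :]
    if np.any(vol <= 0):
        raise ValueError("zero-volume cell in the density grid")
    molar = counts / (N_AVOGADRO * vol * _LITRE_PER_A3)

    bulk = float("nan")
    if box_volume is not None:
        v_bulk = box_volume - np.pi * spec.cutoff_R ** 2 * L
        bulk = _molarity(n_bulk, v_bulk)
    return DensityMap(r_edges, a_edges, counts, molar, bulk, d_span)


def bulk_ratio(dmap: DensityMap) -> tuple[np.ndarray, float]:
    """Per-cell molarity over bulk molarity, plus the maximum ratio."""
    if not np.isfinite(dmap.bulk_molarity) or dmap.bulk_molarity <= 0:
        raise ValueError("bulk molarity is zero or undefined")
    ratio = dmap.molarity / dmap.bulk_molarity
    return ratio, float(ratio.max())


@dataclass
class ConvergenceSeries:
    running_mean: np.ndarray
    block_means: np.ndarray
    block_se: float
    drift_flag: bool


def convergence_series(frames: list[HelicoidalCoords], region: str,
                       spec: RegionSpec = RegionSpec(),
                       d_span: tuple[float, float] | None = None,
                       n_blocks: int = 10,
                       drift_sigmas: float = 3.0) -> ConvergenceSeries:
    """Running mean of per-frame region occupancy plus block statistics.

    The drift flag is raised when the last and first block means differ by
    more than ``drift_sigmas`` combined standard errors.
    """
    if len(frames) < 10:
        raise ValueError("need at least 10 frames for convergence analysis")
    counts = np.array([
        float(np.sum(assign_region(fr, spec, d_span) == region))
        for fr in frames])
    running = np.cumsum(counts) / np.arange(1, len(counts) + 1)
    blocks = np.array_split(counts, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    bse = np.array([b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0
                    for b in blocks])
    se = float(np.sqrt(np.mean(bse ** 2)))
    comb = np.hypot(bse[0], bse[-1])
    drift = bool(abs(bm[-1] - bm[0]) > drift_sigmas * max(comb, 1e-12))
    return ConvergenceSeries(running, bm, se, drift)


def radial_distribution(frames: list[HelicoidalCoords], dR: float,
                        d_span: tuple[float, float],
                        spec: RegionSpec = RegionSpec(),
                        r_max: float | None = None) -> dict[str, np.ndarray]:
    """Shell-normalized molarity versus R, split into minor/major sectors.

    Returns ``{"r_mid", "minor", "major", "all"}``; each profile is in
    mol/L, normalized by the curvilinear shell volume of its own azimuthal
    window.
    """
    if dR <= 0:
        raise ValueError("dR must be positive")
    r_max = spec.cutoff_R if r_max is None else r_max
    edges = np.arange(0.0, r_max + dR / 2, dR)
    nf = len(frames)
    L = d_span[1] - d_span[0]
    out = {}
    win_minor = np.radians(spec.minor_hi - spec.minor_lo)
    win_major = 2 * np.pi - win_minor
    for label, win in (("minor", win_minor), ("major", win_major),
                       ("all", 2 * np.pi)):
        counts = np.zeros(len(edges) - 1)
        for fr in frames:
            inside = (fr.D >= d_span[0]) & (fr.D <= d_span[1])
            minor = (fr.A >= spec.minor_lo) & (fr.A < spec.minor_hi)
            if label == "minor":
                sel = inside & minor
            elif label == "major":
                sel = inside & ~minor
            else:
                sel = inside
            counts += np.histogram(fr.R[sel], bins=edges)[0]
        counts /= nf
        r_mid = 0.5 * (edges[:-1] + edges[1:])
        vol = L * r_mid * dR * win
        out[label] = counts / (N_AVOGADRO * vol * _LITRE_PER_A3)
    out["r_mid"] = 0.5 * (edges[:-1] + edges[1:])
    return out
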