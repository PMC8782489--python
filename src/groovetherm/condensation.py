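"""Multi-duplex condensation metrics.

For systems of many duplexes the package reports three observables: the
mean pairwise centre-of-mass distance relative to a reference system
(ΔCOM), the pairwise alignment of helical axes (|cos θ| — the nematic
convention, since duplex axes are head–tail symmetric), and translational
diffusion from the mean squared displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DuplexEnsemble:
    """Per-duplex COM and axis-vector time series.

    com : (n_frames, n_duplexes, 3) wrapped positions, Å.
    axes : (n_frames, n_duplexes, 3) unit axis vectors.
    dt : frame spacing, ns.  box : (3,) orthorhombic box lengths, Å.
    com_unwrapped : optional continuous COM series for diffusion analysis.
    """

    com: np.ndarray
    axes: np.ndarray
    dt: float
    box: np.ndarray
    labels: list[str] = field(default_factory=list)
    com_unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        norms = np.linalg.norm(self.axes, axis=-1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("axis vectors must be unit-norm")

    @property
    def n_frames(self) -> int:
        return self.com.shape[0]

    @property
    def n_duplexes(self) -> int:
        return self.com.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_indices(n: int):
    return np.triu_indices(n, k=1)


def mean_pairwise_distance(ens: DuplexEnsemble) -> np.ndarray:
    """Per-frame mean over duplex pairs of the minimum-image COM distance."""
    i, j = _pair_indices(ens.n_duplexes)
    d = minimum_image(ens.com[:, i] - ens.com[:, j], ens.box)
    return np.linalg.norm(d, axis=-1).mean(axis=1)


def com_series(ens: DuplexEnsemble, reference: DuplexEnsemble,
               mode: str = "pairwise") -> np.ndarray:
    """ΔCOM: system minus reference mean pairwise COM distance per frame.

    ``mode="pairwise"`` (default) compares mean pairwise minimum-image
    distances; ``mode="displacement"`` compares the mean displacement of
    each duplex from its starting position instead.  Series of different
    lengths are interpolated to the system's time grid.
    """
    if ens.n_duplexes != reference.n_duplexes:
        raise ValueError("duplex count mismatch between system and reference")
    if mode == "pairwise":
        a = mean_pairwise_distance(ens)
        b = mean_pairwise_distance(reference)
    elif mode == "displacement":
        a = _mean_displacement(ens)
        b = _mean_displacement(reference)
    else:
        raise ValueError("mode must be 'pairwise' or 'displacement'")
    if len(b) != len(a):
        b = np.interp(ens.times, reference.times, b)
    return a - b


def _mean_displacement(ens: DuplexEnsemble) -> np.ndarray:
    com = ens.com_unwrapped if ens.com_unwrapped is not None \
        else unwrap_com(ens.com, ens.box)
    return np.linalg.norm(com - com[:1], axis=-1).mean(axis=1)


@dataclass
class AxisCorrelation:
    matrix: np.ndarray          # (n, n) time-averaged |cos|
    series: np.ndarray          # (n_frames,) ensemble mean over pairs
    window_means: dict          # window label -> mean over pairs and frames
    order_parameter: float      # overall mean |cos| over pairs and frames
    signed_series: np.ndarray   # same, without the absolute value


def axis_correlation(ens: DuplexEnsemble,
                     windows: dict[str, tuple[float, float]] | None = None
                     ) -> AxisCorrelation:
    """Pairwise |cos θ| between duplex axes (head–tail symmetric).

    ``windows`` maps labels to (t0, t1) ns intervals (e.g. first/last
    10 ns); each window's mean over pairs and frames is reported.
    """
    if ens.n_duplexes < 2:
        raise ValueError("need at least 2 duplexes")
    norms = np.linalg.norm(ens.axes, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length axis vector")
    cosmat = np.einsum("fid,fjd->fij", ens.axes, ens.axes)
    i, j = _pair_indices(ens.n_duplexes)
    signed = cosmat[:, i, j]
    absval = np.abs(signed)
    series = absval.mean(axis=1)
    t = ens.times
    wm = {}
    for label, (t0, t1) in (windows or {}).items():
        sel = (t >= t0) & (t <= t1)
        wm[label] = float(series[sel].mean()) if sel.any() else float("nan")
    matrix = np.abs(cosmat).mean(axis=0)
    return AxisCorrelation(matrix, series, wm, float(series.mean()),
                           signed.mean(axis=1))


def unwrap_com(com: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Continuous COM series from wrapped positions via accumulated
    minimum-image displacements."""
    steps = minimum_image(np.diff(com, axis=0), box)
    out = np.empty_like(com)
    out[0] = com[0]
    out[1:] = com[0] + np.cumsum(steps, axis=0)
    return out


@dataclass
class MSDResult:
    lags: np.ndarray        # ns
    msd: np.ndarray         # Å²
    D: float                # Å²/ns
    fit_window: tuple[float, float]
    linear_r2: float
    nonlinear_flag: bool


def msd_diffusion(ens: DuplexEnsemble, fit_window: tuple[float, float],
                  n_lags: int = 200, r2_threshold: float = 0.98) -> MSDResult:
    """MSD over duplexes and time origins, and D = slope/6 on the window.

    The MSD is evaluated on unwrapped COMs at up to ``n_lags`` lag times
    spanning [0, t1]; D comes from an ordinary least-squares line over
    [t0, t1].  A fit with R² below ``r2_threshold`` raises the nonlinear
    flag (ballistic or otherwise non-diffusive motion).
    """
    t0, t1 = fit_window
    span = (ens.n_frames - 1) * ens.dt
    if not (0 <= t0 < t1 <= span):
        raise ValueError("fit window outside the trajectory span")
    com = ens.com_unwrapped if ens.com_unwrapped is not None \
        else unwrap_com(ens.com, ens.box)
    max_lag = int(round(t1 / ens.dt))
    lag_idx = np.unique(np.linspace(0, max_lag, min(n_lags, max_lag) + 1)
                        .astype(int))
    msd = np.empty(len(lag_idx))
    for m, lag in enumerate(lag_idx):
        if lag == 0:
            msd[m] = 0.0
            continue
        d = com[lag:] - com[:-lag]
        msd[m] = np.mean(np.sum(d * d, axis=-1))
    lags = lag_idx * ens.dt

    sel = (lags >= t0) & (lags <= t1)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than 2 lag points")
    coef = np.polyfit(lags[sel], msd[sel], 1)
    pred = np.polyval(coef, lags[sel])
    ss_res = float(np.sum((msd[sel] - pred) ** 2))
    ss_tot = float(np.sum((msd[sel] - msd[sel].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = float(coef[0] / 6.0)
    return MSDResult(lags, msd, D, fit_window, r2, bool(r2 < r2_threshold))
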