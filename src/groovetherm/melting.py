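"""UV-melting analysis of DNA duplexes.

A duplex melting curve (absorbance at 260 nm versus temperature) is reduced
to a melting temperature Tm by the smoothed first derivative, and the
concentration dependence of Tm yields van 't Hoff thermodynamics through
the linear relation

    1/Tm = (R/ΔrH0) ln(Ct/2) + ΔrS0/ΔrH0

with Ct the total strand concentration.  ΔrH0 and ΔrS0 are stored in the
association direction (both negative for duplex formation);
ΔG0(300 K) = ΔrH0 − 300·ΔrS0.  The Ct/2 concentration convention is the
default; the textbook Ct/4 convention for non-self-complementary duplexes
is available through ``ct_divisor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .constants import R_GAS_KCAL


class TransitionNotCaptured(ValueError):
    """The derivative maximum falls on the grid boundary: the curve does
    not span the melting transition."""


@dataclass
class MeltingCurve:
    """Temperature (K, strictly increasing) / absorbance series tagged with
    the total strand concentration and buffer condition."""

    T: np.ndarray
    A: np.ndarray
    Ct: float
    condition: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.T.shape != self.A.shape or self.T.size < 7:
            raise ValueError("T and A must be equal-length with >= 7 points")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.Ct <= 0:
            raise ValueError("strand concentration must be positive")


@dataclass
class ThermoParams:
    """Van 't Hoff thermodynamic parameters (kcal/mol, kcal/mol/K)."""

    Tm_by_Ct: dict[float, float]
    dH: float
    dS: float
    dG300: float
    r2: float
    direction: str = "association"
    T_ref: float = 300.0

    def to_direction(self, direction: str) -> "ThermoParams":
        """Same parameters with the sign convention flipped if needed."""
        if direction not in ("association", "melting"):
            raise ValueError("direction must be 'association' or 'melting'")
        if direction == self.direction:
            return self
        return ThermoParams(self.Tm_by_Ct, -self.dH, -self.dS, -self.dG300,
                            self.r2, direction, self.T_ref)


def smooth_curve(curve: MeltingCurve, window: int = 11,
                 order: int = 3) -> MeltingCurve:
    """Savitzky–Golay smoothing of the absorbance series.

    ``window`` must be odd, larger than ``order`` and no larger than the
    series; endpoints are handled by the filter's polynomial end-fit.
    """
    n = curve.T.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (window > order >= 1):
        raise ValueError("require window > order >= 1")
    if window > n:
        raise ValueError("window larger than the series")
    A = savgol_filter(curve.A, window, order, mode="interp")
    return MeltingCurve(curve.T.copy(), A, curve.Ct, curve.condition,
                        curve.sequence_id)


def find_tm(curve: MeltingCurve, window: int = 11, order: int = 3) -> float:
    """Tm (K) at the maximum of dA/dT of the smoothed curve.

    The grid maximum is refined by 3-point quadratic interpolation; a
    maximum on the grid boundary raises :class:`TransitionNotCaptured`.
    """
    sm = smooth_curve(curve, window, order)
    dAdT = np.gradient(sm.A, sm.T)
    if np.ptp(dAdT) <= 1e-9 * max(np.abs(dAdT).max(), 1e-30):
        raise TransitionNotCaptured(
            "derivative is flat — no melting transition in the window")
    i = int(np.argmax(dAdT))
    if i == 0 or i == len(dAdT) - 1:
        raise TransitionNotCaptured(
            "derivative maximum at the grid boundary — transition not captured")
    y0, y1, y2 = dAdT[i - 1], dAdT[i], dAdT[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(sm.T[i])
    # local quadratic on an (approximately) uniform grid around the maximum
    h = 0.5 * (sm.T[i + 1] - sm.T[i - 1])
    return float(sm.T[i] + h * (y0 - y2) / (2 * denom))


def fit_vant_hoff(tm_by_ct: dict[float, float], T_ref: float = 300.0,
                  ct_divisor: float = 2.0) -> ThermoParams:
    """Ordinary least squares of 1/Tm on ln(Ct/ct_divisor).

    The slope s and intercept b give ΔrH0 = R/s and ΔrS0 = b·ΔrH0 in the
    association direction; ΔG0(T_ref) = ΔrH0 − T_ref·ΔrS0.
    """
    if len(tm_by_ct) < 3:
        raise ValueError("need Tm at >= 3 distinct strand concentrations")
    ct = np.array(sorted(tm_by_ct), dtype=float)
    tm = np.array([tm_by_ct[c] for c in ct], dtype=float)
    x = np.log(ct / ct_divisor)
    if np.ptp(x) < 1e-12:
        raise ValueError("ln(Ct) has zero variance across the points")
    res = linregress(x, 1.0 / tm)
    dH = R_GAS_KCAL / res.slope
    dS = res.intercept * dH
    return ThermoParams(dict(zip(ct, tm)), dH, dS, dH - T_ref * dS,
                        res.rvalue ** 2, "association", T_ref)


def tm_average(replicas) -> tuple[float, float]:
    """Mean Tm over replicate measurements plus the spread (max − min)."""
    reps = np.asarray(list(replicas), dtype=float)
    return float(reps.mean()), float(np.ptp(reps))


def delta_tm(a: dict[str, float], b: dict[str, float]) -> dict[str, float]:
    """Per-condition Tm differences a − b over matched condition labels."""
    if set(a) != set(b):
        missing = set(a) ^ set(b)
        raise KeyError(f"unmatched condition labels: {sorted(missing)}")
    return {k: a[k] - b[k] for k in a}


def delta_tm_vs_reference(tms: dict[str, float], reference: str) -> dict[str, float]:
    """Tm of each condition minus the Tm of a named reference buffer."""
    if reference not in tms:
        raise KeyError(f"reference condition {reference!r} absent")
    ref = tms[reference]
    return {k: v - ref for k, v in tms.items() if k != reference}


def thermo_deltas(cond: ThermoParams, ref: ThermoParams) -> tuple[float, float, float]:
    """(ΔΔH, ΔΔS, ΔΔG at T_ref) between two conditions, reported in the
    melting-direction sign convention."""
    if cond.direction != ref.direction:
        raise ValueError("mixed direction flags; convert with to_direction")
    c = cond.to_direction("melting")
    r = ref.to_direction("melting")
    return (c.dH - r.dH, c.dS - r.dS, c.dG300 - r.dG300)


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases in a sequence over the {A, C, G, T} alphabet."""
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)
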