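"""Quantitative analysis of the wet-lab readouts.

Size-exclusion chromatography calibration (partition coefficient
Kav = (Ve - Vo)/(Vc - Vo), linear in log10 molecular mass), ATPase rate
from the linear part of an NADH absorbance trace, kymograph construction
and sine-fit oscillation periods, cell-size phenotype classification,
QCMD frequency drop, and wave-occurrence fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

#: default SEC standards: (name, molecular mass in kDa); Blue Dextran 2000
#: marks the void volume and is not part of the calibration line.
SEC_STANDARD_MASSES = [
    ("Aldolase", 158.0),
    ("Conalbumin", 75.0),
    ("Ovalbumin", 44.0),
    ("Carbonic Anhydrase", 29.0),
    ("RNaseA", 13.7),
    ("Aprotinin", 6.5),
]

#: geometric volume of the Superdex 75 Increase 10/300 GL column (mL)
SUPERDEX75_VC = 23.5

#: phenotype thresholds: any cell longer than 25 µm -> filamentous;
#: sub-µm cells at a fraction strictly above 6.3 % (three times the 2.1 %
#: wild-type baseline) -> minicell.
FILAMENTOUS_LENGTH_UM = 25.0
MINICELL_LENGTH_UM = 1.0
MINICELL_FRACTION = 0.063


class NoOscillationError(RuntimeError):
    """Raised when a trace has no dominant oscillatory component."""


@dataclass(frozen=True)
class SecCalibration:
    vo: float                     # void volume (mL), Blue Dextran elution
    vc: float                     # geometric column volume (mL)
    slope: float                  # of Kav vs log10(mass/kDa); negative
    intercept: float
    standards: tuple = ()

    def __post_init__(self):
        if self.vc <= self.vo:
            raise ValueError("column volume must exceed void volume")


@dataclass(frozen=True)
class CellPopulation:
    lengths: np.ndarray           # µm

    def __post_init__(self):
        arr = np.asarray(self.lengths, dtype=float)
        if arr.size == 0:
            raise ValueError("empty cell population")
        if np.any(arr <= 0):
            raise ValueError("cell lengths must be positive")
        object.__setattr__(self, "lengths", arr)

    @property
    def minicell_fraction(self) -> float:
        return float((self.lengths < MINICELL_LENGTH_UM).mean())

    @property
    def median_length(self) -> float:
        return float(np.median(self.lengths))

    @property
    def variance(self) -> float:
        return float(self.lengths.var(ddof=1)) if self.lengths.size > 1 else 0.0


# ---------------------------------------------------------------------------
# size-exclusion chromatography


def kav(ve: float, vo: float, vc: float) -> float:
    """Partition coefficient (Ve - Vo)/(Vc - Vo); 0 at the void volume,
    1 at the geometric column volume."""
    if vc <= vo:
        raise ValueError("vc must exceed vo")
    return (ve - vo) / (vc - vo)


def fit_sec_calibration(
    standards: list[tuple[str, float, float]], vo: float, vc: float = SUPERDEX75_VC
) -> SecCalibration:
    """Least-squares line Kav = a*log10(mass) + b through standards given
    as (name, mass kDa, Ve mL); larger species elute earlier, so a < 0 on
    a sane column."""
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    masses = np.array([m for _, m, _ in standards], dtype=float)
    if np.unique(masses).size < 2:
        raise ValueError("standards need at least 2 distinct masses")
    kavs = np.array([kav(ve, vo, vc) for _, _, ve in standards])
    slope, intercept = np.polyfit(np.log10(masses), kavs, 1)
    return SecCalibration(vo=vo, vc=vc, slope=float(slope),
                          intercept=float(intercept),
                          standards=tuple(standards))


def estimate_oligomer_mass(ve: float, calibration: SecCalibration) -> float:
    """Invert the standard curve: mass = 10**((Kav(Ve) - b)/a) in kDa.
    Elution volumes outside [Vo, Vc] extrapolate (warning via ValueError is
    deliberately not raised; the caller sees the extrapolated value)."""
    if calibration.slope == 0:
        raise ValueError("flat calibration: mass is unidentifiable")
    k = kav(ve, calibration.vo, calibration.vc)
    return float(10 ** ((k - calibration.intercept) / calibration.slope))


# ---------------------------------------------------------------------------
# ATPase assay


def atpase_rate(
    times_min: np.ndarray,
    absorbance: np.ndarray,
    window: tuple[float, float],
    extinction_coeff: float | None = None,
    path_length_cm: float | None = None,
) -> dict:
    """Least-squares slope (absorbance/min) of an NADH 340 nm trace over a
    user-chosen linear window.  Conversion to µM ATP/min happens only when
    the user supplies both the NADH extinction coefficient (1/(mM*cm)) and
    the optical path length — there are no silent defaults."""
    t = np.asarray(times_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in the fit window")
    slope, intercept = np.polyfit(t[mask], a[mask], 1)
    out = {"slope_abs_per_min": float(slope), "intercept": float(intercept),
           "n_points": int(mask.sum())}
    if extinction_coeff is not None and path_length_cm is not None:
        # dA/dt = -eps * l * d[NADH]/dt; 1 NADH oxidized per ATP hydrolyzed
        out["rate_uM_atp_per_min"] = float(
            -slope / (extinction_coeff * path_length_cm) * 1000.0
        )
    return out


# ---------------------------------------------------------------------------
# kymographs and oscillation periods


def build_kymograph(
    stack: np.ndarray, dt: float, n_bins: int = 100, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Build a (time x position) kymograph from an image stack (t, y, x).

    The cell's long axis is the first principal axis of the time-averaged
    intensity (or of the supplied boolean mask); pixel intensities are
    binned into ``n_bins`` positions along it and each row (frame) is
    normalized by its maximum.  Returns (kymograph, dt)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (time, y, x)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    mean_img = stack.mean(axis=0)
    if mask is None:
        mask = mean_img >= mean_img.mean()
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty cell mask")
    pts = np.column_stack([ys, xs]).astype(float)
    centered = pts - pts.mean(axis=0)
    # principal axis of the mask footprint
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    edges = np.linspace(proj.min(), proj.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(proj, edges) - 1, 0, n_bins - 1)
    kymo = np.zeros((stack.shape[0], n_bins))
    for frame in range(stack.shape[0]):
        vals = stack[frame, ys, xs]
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                kymo[frame, b] = vals[sel].mean()
        if np.all(stack[frame] == 0):
            raise ValueError(f"empty frame {frame}")
        row_max = kymo[frame].max()
        if row_max > 0:
            kymo[frame] /= row_max
    return kymo, dt


def oscillation_period(signal: np.ndarray, dt: float) -> dict:
    """Oscillation period (seconds) of an intensity-vs-time signal by
    nonlinear least squares of A*sin(2*pi*t/T + phi) + c, with the
    frequency initialized at the dominant discrete-Fourier peak and T
    bounded to [2*dt, total duration] to exclude aliased fits.

    Raises :class:`NoOscillationError` when no spectral peak stands above
    the noise floor (peak amplitude < 4x the median non-DC amplitude, or a
    flat trace)."""
    y = np.asarray(signal, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = y.size
    if n < 4 or np.ptp(y) == 0:
        raise NoOscillationError("no oscillation detected")
    t = np.arange(n) * dt
    amp = np.abs(np.fft.rfft(y - y.mean()))
    amp[0] = 0.0
    peak = int(amp.argmax())
    floor = np.median(amp[1:]) if n > 4 else 0.0
    if peak == 0 or (floor > 0 and amp[peak] < 4.0 * floor):
        raise NoOscillationError("no oscillation detected")
    t_init = n * dt / peak
    duration = n * dt
    t_init = float(np.clip(t_init, 2 * dt, duration))
    a0 = float(np.sqrt(2) * (y - y.mean()).std())

    def model(tt, a, period, phi, c):
        return a * np.sin(2 * np.pi * tt / period + phi) + c

    popt, _ = optimize.curve_fit(
        model, t, y,
        p0=[a0, t_init, 0.0, float(y.mean())],
        bounds=([0.0, 2 * dt, -2 * np.pi, -np.inf],
                [np.inf, duration, 2 * np.pi, np.inf]),
        maxfev=20000,
    )
    residual = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return {"period_s": float(popt[1]), "amplitude": float(popt[0]),
            "phase": float(popt[2]), "offset": float(popt[3]),
            "rms_residual": residual}


# ---------------------------------------------------------------------------
# phenotypes, wave occurrence, QCMD


def classify_phenotype(population: CellPopulation) -> str:
    """Filamentous if any cell exceeds 25 µm; else minicell if the
    fraction of sub-µm cells is strictly above 6.3 %; else normal.
    Filamentous takes precedence when both criteria fire."""
    if np.any(population.lengths > FILAMENTOUS_LENGTH_UM):
        return "filamentous"
    if population.minicell_fraction > MINICELL_FRACTION:
        return "minicell"
    return "normal"


def wave_occurrence(n_oscillating: int, n_total: int) -> float:
    """Fraction of droplets in a field exhibiting Min oscillations."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_oscillating <= n_total:
        raise ValueError("n_oscillating must be in [0, n_total]")
    return n_oscillating / n_total


def qcmd_frequency_drop(frequency_trace: np.ndarray) -> float:
    """QCMD frequency change: smooth the trace with a 5-point moving
    average, then subtract the smoothed maximum (baseline) from the
    smoothed minimum — membrane binding shows as a negative drop in Hz."""
    f = np.asarray(frequency_trace, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 points")
    smoothed = np.convolve(f, np.ones(5) / 5.0, mode="valid")
    return float(smoothed.min() - smoothed.max())
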