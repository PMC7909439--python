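"""Ultrafiltration membrane sieving calibration from paired SEC traces.

In total-recirculation mode the permeate and retentate streams are at
steady state, so the observed retention of the solute eluting at time x is

    R_x = 1 - A_p,x / A_r,x

with A_p and A_r the permeate and retentate absorbances at that time. For
peptide mixtures on hydrophilic (regenerated-cellulose) membranes, R is
well described as linear in log10 molar mass over the fractionation range;
ordinary least squares of R on log10(MW) gives a per-membrane calibration
that is reused for every hydrolysate of the same substrate protein. The
apparent molecular-weight cut-off is the molar mass retained at 90%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chromatogram import Chromatogram, ColumnCalibration

__all__ = [
    "MembraneCalibration",
    "RetentionSeries",
    "RC_MEMBRANE_1K",
    "RC_MEMBRANE_3K",
    "pointwise_retention",
    "fit_calibration",
    "retention_at",
    "apparent_mwco",
]


@dataclass(frozen=True)
class MembraneCalibration:
    """Linear sieving law ``R = slope * log10(MW) + intercept``.

    Retention is clipped to [0, 1] at evaluation time; the fitted line
    itself is stored unclipped. ``mwco_nominal`` is the manufacturer's
    label, ``fit_mw_window`` the molar-mass range the fit covered.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")
    mwco_nominal: float | None = None
    fit_mw_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("sieving slope must be positive (retention grows with size)")

    def retention(self, mw):
        """Clipped retention of a solute of molar mass ``mw`` (g/mol)."""
        mw = np.asarray(mw, dtype=float)
        if np.any(mw <= 0):
            raise ValueError("molar mass must be positive")
        r = np.clip(self.slope * np.log10(mw) + self.intercept, 0.0, 1.0)
        return float(r) if r.ndim == 0 else r

    def apparent_mwco(self, level: float = 0.9) -> float:
        """Molar mass (g/mol) retained at fraction ``level`` (default 90%)."""
        if not max(0.0, self.intercept) < level < 1.0:
            raise ValueError(
                f"retention level {level} is outside the invertible range "
                f"({max(0.0, self.intercept):.3g}, 1)"
            )
        return float(10.0 ** ((level - self.intercept) / self.slope))


#: Reference calibrations of 1 and 3 kg/mol regenerated-cellulose membranes
#: against bovine-hemoglobin peptide hydrolysates (retention vs log10 MW,
#: total-recirculation SEC method).
RC_MEMBRANE_1K = MembraneCalibration(0.7978, -1.6206, mwco_nominal=1000.0)
RC_MEMBRANE_3K = MembraneCalibration(1.0552, -2.666, mwco_nominal=3000.0)


@dataclass(frozen=True)
class RetentionSeries:
    """Pointwise observed retention with its source absorbances."""

    time: np.ndarray
    mw: np.ndarray
    retention: np.ndarray
    permeate_absorbance: np.ndarray
    retentate_absorbance: np.ndarray

    def __len__(self) -> int:
        return int(self.time.size)


def pointwise_retention(
    permeate: Chromatogram,
    retentate: Chromatogram,
    column_cal: ColumnCalibration,
    *,
    threshold: float = 0.02,
) -> RetentionSeries:
    """Observed retention R = 1 - A_p/A_r at each usable chromatogram point.

    The permeate trace is linearly resampled onto the retentate time grid.
    Points where the retentate signal falls below ``threshold`` times its
    maximum are discarded: the ratio there is dominated by detector noise.
    R values outside [0, 1] are kept (clipping before regression would bias
    the fitted line).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if permeate.wavelength != retentate.wavelength:
        raise ValueError(
            "permeate and retentate were detected at different wavelengths "
            f"({permeate.wavelength} vs {retentate.wavelength} nm)"
        )
    a_r = retentate.absorbance
    a_p = np.interp(retentate.time, permeate.time, permeate.absorbance)
    if not a_r.max() > 0:
        raise ValueError("no retentate points above the signal threshold")
    keep = a_r >= threshold * a_r.max()
    if not keep.any():
        raise ValueError("no retentate points above the signal threshold")
    t = retentate.time[keep]
    return RetentionSeries(
        time=t,
        mw=column_cal.mw_at_time(t),
        retention=1.0 - a_p[keep] / a_r[keep],
        permeate_absorbance=a_p[keep],
        retentate_absorbance=a_r[keep],
    )


def fit_calibration(
    series: RetentionSeries,
    *,
    mw_window: tuple[float, float] | None = None,
    mwco_nominal: float | None = None,
) -> MembraneCalibration:
    """Ordinary least squares of observed retention on log10 molar mass.

    ``mw_window`` restricts the fit to its molar-mass range — useful to
    exclude the fully-retained plateau (R saturated at 1 carries no
    information about the sieving line) and trace-level tails.
    """
    mw = series.mw
    r = series.retention
    if mw_window is not None:
        lo, hi = mw_window
        sel = (mw >= lo) & (mw <= hi)
        mw, r = mw[sel], r[sel]
    if mw.size < 3:
        raise ValueError(f"need at least 3 points to fit, have {mw.size}")
    if mw.max() <= mw.min():
        raise ValueError("degenerate molar-mass range")
    fit = stats.linregress(np.log10(mw), r)
    if not fit.slope > 0:
        raise ValueError(
            f"fitted sieving slope is non-positive ({fit.slope:.4g}); "
            "the data do not show retention increasing with molar mass"
        )
    return MembraneCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mwco_nominal=mwco_nominal,
        fit_mw_window=(float(mw.min()), float(mw.max())),
    )


def retention_at(cal: MembraneCalibration, mw):
    """Retention predicted by the calibration, clipped to [0, 1]."""
    return cal.retention(mw)


def apparent_mwco(cal: MembraneCalibration, level: float = 0.9) -> float:
    """Apparent molecular-weight cut-off: molar mass retained at ``level``."""
    return cal.apparent_mwco(level)
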