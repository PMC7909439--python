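"""Size-exclusion chromatogram handling and molar-mass characterization.

Analytical SEC of a protein hydrolysate records UV absorbance at 214 nm
(peptide-bond absorption) against elution time. Two conversions turn that
trace into a molar-mass description of the peptide mixture:

* a **column calibration** maps elution time to log10 molar mass
  (``log10(MW) = slope * t + intercept``, fitted on peptide standards);
* a **per-residue Beer-Lambert conversion** maps absorbance to mass
  concentration, ``C = A * MWaa / (eps_aa * l)``, using the substrate
  protein's mean residue mass ``MWaa`` (g/mol) and mean residue molar
  extinction coefficient ``eps_aa`` (L/mol/cm) at 214 nm and the detector
  path length ``l`` (cm).

The resulting per-point (MW, concentration) profile supports the usual
hydrolysate characterization summaries: cumulative mass distribution over
molar mass, median molar mass, and the mass fraction below a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - annotation only
    from .uf import TargetPeptide

__all__ = [
    "Chromatogram",
    "ColumnCalibration",
    "ProteinReference",
    "HydrolysateProfile",
    "MassDistribution",
    "BOVINE_HEMOGLOBIN",
    "SUPERDEX_PEPTIDE",
    "read_chromatogram",
    "write_chromatogram",
    "mw_at_time",
    "absorbance_to_concentration",
    "cumulative_mass_distribution",
    "median_mw",
    "fraction_below",
    "write_profile",
]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Chromatogram:
    """A UV elution trace: absorbance (AU) on a strictly increasing time grid (min).

    Parameters
    ----------
    time
        Elution time in minutes, strictly increasing.
    absorbance
        Detector signal in absorbance units at `wavelength`.
    wavelength
        Detection wavelength in nm (214 nm probes the peptide bond).
    path_length
        Optical path of the detector cell in cm.
    label
        Free-text sample identifier.
    """

    time: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 214.0
    path_length: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        t = _as_1d_float(self.time, "time")
        a = _as_1d_float(self.absorbance, "absorbance")
        if t.size != a.size:
            raise ValueError(
                f"time and absorbance differ in length ({t.size} vs {a.size})"
            )
        if t.size < 2:
            raise ValueError("a chromatogram needs at least two points")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite elution times")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite absorbance values")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time must be strictly increasing; first violation at index {bad[0] + 1}"
            )
        if not self.path_length > 0:
            raise ValueError("path_length must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class ColumnCalibration:
    """Linear SEC column calibration ``log10(MW) = slope * t + intercept``.

    `mw_range` is the molar-mass window spanned by the calibration
    standards; evaluations outside it are extrapolations and are flagged,
    not rejected.
    """

    slope: float
    intercept: float
    mw_range: tuple[float, float] = (220.0, 1890.0)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        lo, hi = self.mw_range
        if not (0 < lo < hi):
            raise ValueError("mw_range must satisfy 0 < min < max")

    def mw_at_time(self, t):
        """Molar mass (g/mol) eluting at time ``t`` (min)."""
        return 10.0 ** (self.slope * np.asarray(t, dtype=float) + self.intercept)

    def time_at_mw(self, mw):
        """Elution time (min) of a solute of molar mass ``mw`` (g/mol)."""
        return (np.log10(np.asarray(mw, dtype=float)) - self.intercept) / self.slope

    def in_window(self, mw):
        lo, hi = self.mw_range
        mw = np.asarray(mw, dtype=float)
        return (mw >= lo) & (mw <= hi)


@dataclass(frozen=True)
class ProteinReference:
    """Per-residue optical constants of the substrate protein.

    ``residue_mass`` is the mean molar mass per amino-acid residue (g/mol)
    and ``residue_extinction`` the mean molar extinction coefficient per
    residue at 214 nm (L/mol/cm), both derived from the primary sequence.
    """

    residue_mass: float
    residue_extinction: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.residue_mass > 0 and self.residue_extinction > 0):
            raise ValueError("residue constants must be positive")


#: Bovine hemoglobin per-residue constants (primary-sequence averages).
BOVINE_HEMOGLOBIN = ProteinReference(115.0, 987.0, name="bovine hemoglobin")

#: Peptide-range SEC column calibration (Superdex Peptide HR 10/300 class
#: column, standards 220-1890 g/mol, aqueous acetonitrile/TFA eluent).
SUPERDEX_PEPTIDE = ColumnCalibration(-0.082, 5.382, (220.0, 1890.0))


class MwResult(NamedTuple):
    """Molar mass with an extrapolation flag for each input time."""

    mw: np.ndarray | float
    out_of_window: np.ndarray | bool


def mw_at_time(cal: ColumnCalibration, tr) -> MwResult:
    """Map elution time(s) to molar mass, flagging calibration extrapolation.

    The value is always returned; ``out_of_window`` marks points falling
    outside the standards' molar-mass range.
    """
    mw = cal.mw_at_time(tr)
    flag = ~cal.in_window(mw)
    if np.ndim(mw) == 0:
        return MwResult(float(mw), bool(flag))
    return MwResult(mw, flag)


# ---------------------------------------------------------------------------
# I/O

def read_chromatogram(
    path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
    header: bool = True,
    wavelength: float = 214.0,
    path_length: float = 1.0,
    label: str | None = None,
) -> Chromatogram:
    """Read a two-column (time, absorbance) delimited text file.

    Raises
    ------
    ValueError
        If a cell is non-numeric (reported with its line number) or the
        time column is not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        decimal=decimal,
        header=0 if header else None,
        comment="#",
        dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, found {df.shape[1]}")
    cols = []
    for j in range(2):
        raw = df.iloc[:, j]
        if raw.dtype == object:
            raw = raw.str.strip()
            if decimal != ".":
                raw = raw.str.replace(decimal, ".", regex=False)
        num = pd.to_numeric(raw, errors="coerce")
        bad = np.nonzero(num.isna().to_numpy() & df.iloc[:, j].notna().to_numpy())[0]
        if bad.size:
            line = bad[0] + (2 if header else 1)
            raise ValueError(
                f"{path}: non-numeric value {df.iloc[bad[0], j]!r} in column "
                f"{j + 1}, line {line}"
            )
        cols.append(num.to_numpy(dtype=float))
    return Chromatogram(
        cols[0],
        cols[1],
        wavelength=wavelength,
        path_length=path_length,
        label=path.stem if label is None else label,
    )


def write_chromatogram(chrom: Chromatogram, path, *, delimiter: str = ",") -> None:
    """Write `time_min,absorbance_au` CSV, lossless for round-tripping."""
    df = pd.DataFrame({"time_min": chrom.time, "absorbance_au": chrom.absorbance})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Profiles

@dataclass(frozen=True)
class HydrolysateProfile:
    """Per-point molar mass and mass-concentration density of a hydrolysate.

    ``concentration`` is a density over elution time (g/L per min, after the
    configured area normalization); its trapezoidal integral over ``time``
    is the total peptide concentration of the sample in g/L.
    """

    time: np.ndarray
    mw: np.ndarray
    concentration: np.ndarray
    label: str = ""
    target: "TargetPeptide | None" = None

    def __post_init__(self) -> None:
        t = _as_1d_float(self.time, "time")
        mw = _as_1d_float(self.mw, "mw")
        c = _as_1d_float(self.concentration, "concentration")
        if not (t.size == mw.size == c.size):
            raise ValueError("time, mw and concentration must have equal length")
        if t.size < 2:
            raise ValueError("a profile needs at least two points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(mw > 0):
            raise ValueError("molar masses must be positive")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentrations must be finite and non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "mw", mw)
        object.__setattr__(self, "concentration", c)

    @property
    def total_concentration(self) -> float:
        """Total peptide concentration (g/L), trapezoidal integral over time."""
        return float(np.trapezoid(self.concentration, self.time))

    def point_masses(self) -> np.ndarray:
        """Per-point mass weights (g/L) from composite trapezoid quadrature."""
        t = self.time
        w = np.empty_like(t)
        w[0] = (t[1] - t[0]) / 2.0
        w[-1] = (t[-1] - t[-2]) / 2.0
        if t.size > 2:
            w[1:-1] = (t[2:] - t[:-2]) / 2.0
        return self.concentration * w


def absorbance_to_concentration(
    chrom: Chromatogram,
    column_cal: ColumnCalibration,
    ref: ProteinReference = BOVINE_HEMOGLOBIN,
    *,
    baseline_window: tuple[float, float] | None = None,
    scale: float = 1.0,
    target: "TargetPeptide | None" = None,
) -> HydrolysateProfile:
    """Convert an absorbance trace to a (MW, concentration) profile.

    Applies the per-residue Beer-Lambert form ``C = A * MWaa / (eps_aa * l)``
    pointwise and assigns molar masses from the column calibration.

    Parameters
    ----------
    baseline_window
        Optional (t0, t1) window in minutes; the minimum absorbance inside
        it is subtracted as a constant baseline. Negative results are
        clipped to zero (a warning reports how many points were clipped).
    scale
        Dimensionless normalization converting the integrated trace to the
        sample concentration (injection-volume / elution-volume convention
        of the acquisition setup). 1.0 leaves the trace on the
        concentration-density scale used when synthesizing it.
    """
    a = chrom.absorbance
    if baseline_window is not None:
        lo, hi = baseline_window
        sel = (chrom.time >= lo) & (chrom.time <= hi)
        if not sel.any():
            raise ValueError("baseline_window contains no chromatogram points")
        a = a - a[sel].min()
    n_neg = int(np.count_nonzero(a < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} negative absorbance value(s) clipped to zero",
            stacklevel=2,
        )
        a = np.clip(a, 0.0, None)
    conc = a * ref.residue_mass / (ref.residue_extinction * chrom.path_length) * scale
    return HydrolysateProfile(
        time=chrom.time,
        mw=column_cal.mw_at_time(chrom.time),
        concentration=conc,
        label=chrom.label,
        target=target,
    )


def write_profile(profile: HydrolysateProfile, path) -> None:
    pd.DataFrame(
        {
            "time_min": profile.time,
            "mw_gmol": profile.mw,
            "conc_gL": profile.concentration,
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Molar-mass distribution summaries

@dataclass(frozen=True)
class MassDistribution:
    """Cumulative mass fraction over ascending molar mass."""

    mw: np.ndarray
    cumulative_fraction: np.ndarray

    def fraction_below(self, mw_threshold: float) -> float:
        """Mass fraction of peptides with molar mass <= ``mw_threshold``."""
        idx = np.searchsorted(self.mw, mw_threshold, side="right")
        if idx == 0:
            return 0.0
        return float(self.cumulative_fraction[idx - 1])

    def quantile(self, q: float) -> float:
        """Molar mass at cumulative mass fraction ``q``.

        Generalized inverse of the cumulative curve: the smallest grid MW
        whose cumulative fraction reaches ``q``. On the dense grids SEC
        traces provide this agrees with interpolation to within one grid
        step, while point masses (isolated species) resolve to their exact
        molar mass instead of being smeared over the empty interval.
        """
        if not 0 <= q <= 1:
            raise ValueError("quantile level must lie in [0, 1]")
        idx = int(np.searchsorted(self.cumulative_fraction, q, side="left"))
        idx = min(idx, self.mw.size - 1)
        return float(self.mw[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mw_gmol": self.mw, "cum_mass_fraction": self.cumulative_fraction}
        )


def cumulative_mass_distribution(profile: HydrolysateProfile) -> MassDistribution:
    """Cumulative mass-fraction distribution over molar mass.

    Each chromatogram point contributes its quadrature mass weight at its
    molar mass; the result is non-decreasing and ends at 1.
    """
    masses = profile.point_masses()
    total = masses.sum()
    if not total > 0:
        raise ValueError("profile has zero total mass")
    order = np.argsort(profile.mw, kind="stable")
    return MassDistribution(
        mw=profile.mw[order],
        cumulative_fraction=np.cumsum(masses[order]) / total,
    )


def median_mw(profile: HydrolysateProfile) -> float:
    """Median molar mass (g/mol): the MW at cumulative mass fraction 0.5."""
    return cumulative_mass_distribution(profile).quantile(0.5)


def fraction_below(profile: HydrolysateProfile, mw_threshold: float) -> float:
    """Mass fraction of the hydrolysate below a molar-mass threshold."""
    return cumulative_mass_distribution(profile).fraction_below(mw_threshold)
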