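"""Batch ultrafiltration mass balance: permeate composition at any VRF.

A batch (concentration-mode) tangential UF run is parameterized by the
volume reduction factor VRF = V0 / V_R. For a solute of constant observed
retention R, integrating the mass balance dm = -(1 - R) (m / V) dV from V0
down to V_R gives the volume-averaged concentration of the collected
permeate relative to the feed,

    Cp_bar / C0 = (VRF - VRF^R) / (VRF - 1),        (limit 1 - R at VRF -> 1)

and the permeate-compartment yield

    eta = (Cp_bar / C0) * (1 - 1/VRF) = 1 - VRF^(R - 1).

Applied pointwise to a hydrolysate SEC profile — each chromatogram point
carries the retention its molar mass gets from the membrane calibration —
this predicts the whole permeate chromatogram, hence the total permeate
peptide concentration, the enrichment factor of a target peptide

    tau = (Cp_target / C0_target) * (sum C0 / sum Cp_bar),

and its permeate purity = feed purity x tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chromatogram import HydrolysateProfile
from .membrane import MembraneCalibration

__all__ = [
    "TargetPeptide",
    "NEOKYOTORPHIN",
    "UFOperatingPoint",
    "UFPrediction",
    "relative_permeate_concentration",
    "species_yield",
    "predict_permeate_profile",
    "enrichment",
    "permeate_purity",
    "concentration_from_area",
    "purity_from_areas",
    "vrf_for_yield",
    "vrf_sweep",
    "productivity",
    "default_vrf_grid",
]

_VRF_UNITY_TOL = 1e-9


@dataclass(frozen=True)
class TargetPeptide:
    """The peptide whose recovery the simulation optimizes.

    ``rp_area_coefficient`` converts an RP-HPLC peak area (uV s) into a
    concentration (mg/L) via an external standard curve. ``initial_purity``
    is the peptide's mass purity in the feed, in percent.
    """

    name: str = "neokyotorphin"
    mw: float = 653.0
    rp_area_coefficient: float = 4419.6
    initial_purity: float | None = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError("target molar mass must be positive")
        if not self.rp_area_coefficient > 0:
            raise ValueError("area coefficient must be positive")


#: Neokyotorphin (NKT), the alpha137-141 fragment of bovine hemoglobin
#: (TSKYR, 653 g/mol, pI 10.5), a natural antimicrobial peptide.
NEOKYOTORPHIN = TargetPeptide()


@dataclass(frozen=True)
class UFOperatingPoint:
    """A concrete batch-UF run: scale and (optionally) duration."""

    vrf: float
    initial_volume: float = 0.2  # L
    membrane_area: float = 88e-4  # m^2
    duration: float | None = None  # h

    def __post_init__(self) -> None:
        if not self.vrf >= 1:
            raise ValueError("vrf must be >= 1")
        if not (self.initial_volume > 0 and self.membrane_area > 0):
            raise ValueError("volume and area must be positive")

    @property
    def permeate_volume(self) -> float:
        """Collected permeate volume V0 (1 - 1/VRF), in L."""
        return self.initial_volume * (1.0 - 1.0 / self.vrf)


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("retention must lie in [0, 1]")
    return r


def relative_permeate_concentration(r, vrf: float):
    """Permeate-compartment concentration relative to the feed, Cp_bar/C0.

    ``(vrf - vrf**r) / (vrf - 1)`` for vrf > 1; the analytic limit ``1 - r``
    is used within 1e-9 of vrf = 1.
    """
    r = _check_r(r)
    if not vrf >= 1:
        raise ValueError("vrf must be >= 1")
    if vrf - 1 < _VRF_UNITY_TOL:
        out = 1.0 - r
    else:
        out = (vrf - vrf**r) / (vrf - 1.0)
    return float(out) if out.ndim == 0 else out


def species_yield(r, vrf: float):
    """Fraction of a solute's feed mass recovered in the permeate at ``vrf``.

    Equal to ``relative_permeate_concentration(r, vrf) * (1 - 1/vrf)``,
    i.e. ``1 - vrf**(r - 1)``.
    """
    out = relative_permeate_concentration(r, vrf) * (1.0 - 1.0 / vrf)
    return float(out) if np.ndim(out) == 0 else out


def predict_permeate_profile(
    profile: HydrolysateProfile, cal: MembraneCalibration, vrf: float
) -> HydrolysateProfile:
    """Predicted permeate chromatogram (as a concentration profile) at ``vrf``.

    Each point of the feed profile is scaled by the mass-balance factor at
    the retention its molar mass receives from the membrane calibration;
    integrating the result gives the total permeate concentration.
    """
    r = cal.retention(profile.mw)
    factor = relative_permeate_concentration(r, vrf)
    return replace(
        profile,
        concentration=profile.concentration * factor,
        label=f"{profile.label} permeate @ VRF {vrf:g}".strip(),
    )


def enrichment(
    profile: HydrolysateProfile,
    cal: MembraneCalibration,
    target: TargetPeptide,
    vrf: float,
) -> float:
    """Enrichment factor tau of the target peptide in the permeate.

    The target's own transmission uses the scalar mass balance at its molar
    mass; the mixture term uses the integrated predicted permeate profile.
    """
    if not (profile.mw.min() <= target.mw <= profile.mw.max()):
        raise ValueError(
            f"target molar mass {target.mw} g/mol outside profile support "
            f"[{profile.mw.min():.3g}, {profile.mw.max():.3g}]"
        )
    sum_c0 = profile.total_concentration
    sum_cp = predict_permeate_profile(profile, cal, vrf).total_concentration
    if not sum_cp > 0:
        raise ValueError("predicted permeate concentration is zero")
    ratio_target = relative_permeate_concentration(cal.retention(target.mw), vrf)
    return float(ratio_target * sum_c0 / sum_cp)


def permeate_purity(initial_purity: float, tau: float) -> float:
    """Permeate purity (%) = feed purity (%) x enrichment factor, capped at 100."""
    if not (initial_purity > 0 and tau > 0):
        raise ValueError("purity and enrichment must be positive")
    purity = initial_purity * tau
    if purity > 100.0:
        warnings.warn(
            f"computed purity {purity:.1f}% exceeds 100%; capping", stacklevel=2
        )
        purity = 100.0
    return float(purity)


def concentration_from_area(area: float, target: TargetPeptide) -> float:
    """Target concentration (mg/L) from its RP-HPLC peak area (uV s)."""
    if area < 0:
        raise ValueError("peak area must be non-negative")
    return float(target.rp_area_coefficient * area)


def purity_from_areas(a_target: float, a_total: float) -> float:
    """Mass purity (%) as the target's share of the total RP-HPLC area."""
    if a_target < 0 or not a_total > 0:
        raise ValueError("areas must be non-negative with positive total")
    if a_target > a_total:
        raise ValueError("target area exceeds total area")
    return float(a_target / a_total * 100.0)


def vrf_for_yield(
    cal: MembraneCalibration, target: TargetPeptide, yield_goal: float
) -> float:
    """VRF at which the target reaches ``yield_goal`` in the permeate.

    Inverts eta = 1 - vrf**(R-1): vrf = (1 - goal)**(1/(R-1)).
    """
    if not 0 < yield_goal < 1:
        raise ValueError("yield goal must lie in (0, 1)")
    r = cal.retention(target.mw)
    if r >= 1:
        raise ValueError("target is fully retained; the yield goal is unreachable")
    return float((1.0 - yield_goal) ** (1.0 / (r - 1.0)))


def default_vrf_grid(start: float = 1.1, stop: float = 10.0, num: int = 90) -> np.ndarray:
    """Log-spaced VRF grid covering the usual batch-concentration range."""
    return np.geomspace(start, stop, num)


@dataclass(frozen=True)
class UFPrediction:
    """Per-VRF predicted performance of the fractionation."""

    vrf: np.ndarray
    target_yield: np.ndarray
    enrichment: np.ndarray
    permeate_total_concentration: np.ndarray
    purity: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "vrf": self.vrf,
                "yield": self.target_yield,
                "enrichment": self.enrichment,
                "purity": np.full_like(self.vrf, np.nan)
                if self.purity is None
                else self.purity,
                "sum_cp_gL": self.permeate_total_concentration,
            }
        )
        return df

    def write_csv(self, path) -> None:
        # full double precision so reports derived from the frame and the
        # CSV re-read agree exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def vrf_sweep(
    profile: HydrolysateProfile,
    cal: MembraneCalibration,
    target: TargetPeptide,
    vrf_grid=None,
    *,
    initial_purity: float | None = None,
) -> UFPrediction:
    """Yield, enrichment (and purity) curves of the target over a VRF grid."""
    grid = default_vrf_grid() if vrf_grid is None else np.asarray(vrf_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("vrf grid must be a non-empty 1-d array")
    if np.any(grid < 1) or np.any(np.diff(grid) <= 0):
        raise ValueError("vrf grid must be increasing with values >= 1")
    if initial_purity is None:
        initial_purity = target.initial_purity

    r_target = cal.retention(target.mw)
    yields = np.empty_like(grid)
    taus = np.empty_like(grid)
    sum_cp = np.empty_like(grid)
    for i, vrf in enumerate(grid):
        yields[i] = species_yield(r_target, vrf)
        taus[i] = enrichment(profile, cal, target, vrf)
        sum_cp[i] = predict_permeate_profile(profile, cal, vrf).total_concentration
    purity = None
    if initial_purity is not None:
        purity = np.array([permeate_purity(initial_purity, t) for t in taus])
    return UFPrediction(
        vrf=grid,
        target_yield=yields,
        enrichment=taus,
        permeate_total_concentration=sum_cp,
        purity=purity,
    )


def productivity(permeate_mass: float, area: float, duration: float) -> float:
    """Process productivity in g m^-2 h^-1.

    ``permeate_mass`` in g, ``area`` in m^2, ``duration`` in h.
    """
    if not (area > 0 and duration > 0):
        raise ValueError("area and duration must be positive")
    if permeate_mass < 0:
        raise ValueError("permeate mass must be non-negative")
    return float(permeate_mass / (area * duration))
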