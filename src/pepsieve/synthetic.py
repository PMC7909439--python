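"""Seeded synthetic hydrolysate chromatograms and a brute-force UF oracle.

Pepsin hydrolysis of a globular protein follows a zipper-type course: the
intact protein is converted early into large intermediate peptides that
are then progressively cleaved into small final peptides. The generator
emulates this with a bimodal log-normal molar-mass mixture whose mass
shifts from a high-MW component toward a low-MW one as the degree of
hydrolysis (DH) grows, plus a fixed-mass target peptide at 653 g/mol.
Species are rendered as Gaussian elution peaks through the inverse column
calibration and the inverse Beer-Lambert conversion, so every downstream
computation can be checked against the generator's exact species list.

``batch_oracle`` is an explicit forward-stepping discretization of the
batch-UF mass balance, independent of the closed-form expressions it is
used to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chromatogram import (
    BOVINE_HEMOGLOBIN,
    SUPERDEX_PEPTIDE,
    Chromatogram,
    ColumnCalibration,
    ProteinReference,
)
from .membrane import MembraneCalibration

__all__ = [
    "SyntheticHydrolysateSpec",
    "SyntheticTruth",
    "BatchOracleResult",
    "PRESETS",
    "preset",
    "generate_hydrolysate",
    "generate_recycle_pair",
    "batch_oracle",
]


@dataclass(frozen=True)
class SyntheticHydrolysateSpec:
    """Recipe for one synthetic hydrolysate.

    ``mw_mixture`` lists (median g/mol, log-sd of ln(MW), mass weight)
    components; weights plus ``target_mass_fraction`` must sum to 1.
    ``peak_sigma`` is the chromatographic peak width (min), ``noise_sd``
    the additive detector noise as a fraction of the maximum signal.
    """

    mw_mixture: tuple[tuple[float, float, float], ...]
    target_mass_fraction: float = 0.025
    target_mw: float = 653.0
    n_species: int = 200
    peak_sigma: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0
    total_concentration: float = 10.0
    mw_hard_range: tuple[float, float] = (150.0, 30000.0)
    time_step: float = 0.02
    label: str = "synthetic hydrolysate"

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.mw_mixture)
        if abs(w + self.target_mass_fraction - 1.0) > 1e-9:
            raise ValueError(
                "component weights plus target_mass_fraction must sum to 1 "
                f"(got {w + self.target_mass_fraction:.6g})"
            )
        if not 0 <= self.target_mass_fraction < 1:
            raise ValueError("target_mass_fraction must lie in [0, 1)")
        for med, sd, wt in self.mw_mixture:
            if not (med > 0 and sd > 0 and wt > 0):
                raise ValueError("mixture medians, log-sds and weights must be positive")
        if not (self.peak_sigma > 0 and self.time_step > 0 and self.total_concentration > 0):
            raise ValueError("scales must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact species list behind a generated chromatogram.

    ``concentration`` is each species' contribution (g/L) to the sample;
    the target peptide is the species at index ``target_index``. When a
    membrane calibration is attached, ``retention`` holds each species'
    true (clipped) retention.
    """

    mw: np.ndarray
    concentration: np.ndarray
    target_index: int
    membrane_calibration: MembraneCalibration | None = None
    retention: np.ndarray | None = None

    def with_membrane(self, cal: MembraneCalibration) -> "SyntheticTruth":
        return replace(
            self, membrane_calibration=cal, retention=cal.retention(self.mw)
        )

    @property
    def total_concentration(self) -> float:
        return float(self.concentration.sum())

    @property
    def target_purity(self) -> float:
        """Target mass purity of the feed, in percent."""
        return float(self.concentration[self.target_index] / self.concentration.sum() * 100)


# Preset recipes spanning the zipper-type proteolysis course: low DH keeps
# nearly all mass in large intermediate peptides (maximal enrichment
# potential), high DH accumulates small final peptides near the target's
# size. Colored (col) low-DH feeds carry extra large-peptide mass relative
# to the decolored (dec) ones. Medians/weights are fixture choices that
# reproduce the characteristic medians and below-target fractions of such
# hydrolysates, not reconstructions of any measured sample.
PRESETS: dict[str, SyntheticHydrolysateSpec] = {
    "3dh-col": SyntheticHydrolysateSpec(
        mw_mixture=((4000.0, 0.30, 0.955), (700.0, 0.30, 0.020)),
        target_mass_fraction=0.025,
        label="3%DH colored-like",
    ),
    "3dh-dec": SyntheticHydrolysateSpec(
        mw_mixture=((2500.0, 0.35, 0.870), (800.0, 0.35, 0.104)),
        target_mass_fraction=0.026,
        label="3%DH decolored-like",
    ),
    "5dh": SyntheticHydrolysateSpec(
        mw_mixture=((2000.0, 0.35, 0.780), (750.0, 0.35, 0.175)),
        target_mass_fraction=0.045,
        label="5%DH-like",
    ),
    "10dh": SyntheticHydrolysateSpec(
        mw_mixture=((1600.0, 0.40, 0.620), (720.0, 0.35, 0.325)),
        target_mass_fraction=0.055,
        label="10%DH-like",
    ),
    "18dh": SyntheticHydrolysateSpec(
        mw_mixture=((1800.0, 0.40, 0.336), (720.0, 0.35, 0.600)),
        target_mass_fraction=0.064,
        label="18%DH-like",
    ),
}


def preset(name: str, **overrides) -> SyntheticHydrolysateSpec:
    """A preset spec, optionally with fields overridden (e.g. seed, noise_sd)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(base, **overrides) if overrides else base


def _sample_species(spec: SyntheticHydrolysateSpec, rng: np.random.Generator):
    """Sample species molar masses and per-species concentrations."""
    lo, hi = spec.mw_hard_range
    mws: list[float] = []
    concs: list[float] = []
    comp_weight = sum(c[2] for c in spec.mw_mixture)
    for median, log_sd, weight in spec.mw_mixture:
        n = max(1, round(spec.n_species * weight / comp_weight))
        samples = np.empty(n)
        for i in range(n):
            for _ in range(1000):
                mw = rng.lognormal(mean=np.log(median), sigma=log_sd)
                if lo <= mw <= hi:
                    break
            else:
                raise RuntimeError(
                    f"could not sample a molar mass inside {spec.mw_hard_range}"
                )
            samples[i] = mw
        # uneven species abundances within the component, fixed total mass
        shares = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        shares /= shares.sum()
        mws.extend(samples)
        concs.extend(weight * spec.total_concentration * shares)
    mws.append(spec.target_mw)
    concs.append(spec.target_mass_fraction * spec.total_concentration)
    return np.asarray(mws), np.asarray(concs), len(mws) - 1


def generate_hydrolysate(
    spec: SyntheticHydrolysateSpec,
    column_cal: ColumnCalibration = SUPERDEX_PEPTIDE,
    ref: ProteinReference = BOVINE_HEMOGLOBIN,
) -> tuple[Chromatogram, SyntheticTruth]:
    """Render a seeded synthetic hydrolysate chromatogram and its truth.

    Each species becomes a Gaussian elution peak centered at the time its
    molar mass elutes (inverse column calibration) whose integrated
    concentration density equals the species concentration; absorbance is
    the inverse of the per-residue Beer-Lambert conversion. Additive
    Gaussian noise of sd ``noise_sd * max(signal)`` emulates the detector.
    """
    rng = np.random.default_rng(spec.seed)
    mw, conc, target_idx = _sample_species(spec, rng)

    centers = column_cal.time_at_mw(mw)
    pad = 5.0 * spec.peak_sigma
    t0 = column_cal.time_at_mw(spec.mw_hard_range[1]) - pad
    t1 = column_cal.time_at_mw(spec.mw_hard_range[0]) + pad
    if t0 > t1:
        t0, t1 = t1, t0
    time = np.arange(t0, t1 + spec.time_step, spec.time_step)

    # sum of normalized Gaussians weighted by species concentration:
    # integral over time of the density equals total_concentration
    density = np.zeros_like(time)
    norm = 1.0 / (spec.peak_sigma * np.sqrt(2.0 * np.pi))
    for c, tc in zip(conc, centers):
        density += c * norm * np.exp(-0.5 * ((time - tc) / spec.peak_sigma) ** 2)

    absorbance = density * ref.residue_extinction / ref.residue_mass  # path 1 cm
    if spec.noise_sd > 0:
        absorbance = absorbance + rng.normal(
            0.0, spec.noise_sd * absorbance.max(), absorbance.size
        )
    chrom = Chromatogram(time, absorbance, label=spec.label)
    return chrom, SyntheticTruth(mw=mw, concentration=conc, target_index=target_idx)


def generate_recycle_pair(
    chrom: Chromatogram,
    true_cal: MembraneCalibration,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    column_cal: ColumnCalibration = SUPERDEX_PEPTIDE,
) -> tuple[Chromatogram, Chromatogram]:
    """Retentate/permeate pair as observed in total-recirculation mode.

    The retentate trace is the feed chromatogram; the permeate trace is its
    pointwise transmission ``(1 - R(MW))`` through the true sieving law.
    Multiplicative Gaussian noise of sd ``noise_sd`` is applied to both
    traces independently (noise lives in the measured absorbances).
    """
    rng = np.random.default_rng(seed)
    r = true_cal.retention(column_cal.mw_at_time(chrom.time))
    ret = chrom.absorbance.copy()
    perm = (1.0 - r) * chrom.absorbance
    if noise_sd > 0:
        ret = ret * (1.0 + rng.normal(0.0, noise_sd, ret.size))
        perm = perm * (1.0 + rng.normal(0.0, noise_sd, perm.size))
    retentate = Chromatogram(
        chrom.time, ret, wavelength=chrom.wavelength,
        path_length=chrom.path_length, label=f"{chrom.label} retentate",
    )
    permeate = Chromatogram(
        chrom.time, perm, wavelength=chrom.wavelength,
        path_length=chrom.path_length, label=f"{chrom.label} permeate",
    )
    return retentate, permeate


@dataclass(frozen=True)
class BatchOracleResult:
    """Per-species outcome of the stepped batch-UF simulation."""

    retention: np.ndarray
    retentate_concentration: np.ndarray
    mean_permeate_concentration: np.ndarray
    species_yield: np.ndarray


def batch_oracle(
    truth: SyntheticTruth, vrf: float, n_steps: int = 100_000
) -> BatchOracleResult:
    """Brute-force batch-UF mass balance by explicit forward volume stepping.

    Removes the permeate volume in ``n_steps`` equal increments; at each
    step every species loses ``(1 - R) * c_retentate * dV`` of mass to the
    permeate. Reports end-state retentate concentrations, volume-averaged
    permeate concentrations and yields, all relative to the feed volume
    V0 = 1. Independent of the closed-form mass-balance expressions.
    """
    if truth.retention is None:
        raise ValueError("truth has no membrane attached; call with_membrane() first")
    if not vrf > 1:
        raise ValueError("the oracle requires vrf > 1")
    if n_steps < 1000:
        raise ValueError("use at least 1000 steps")
    r = truth.retention
    v0 = 1.0
    v_perm_total = v0 * (1.0 - 1.0 / vrf)
    dv = v_perm_total / n_steps
    mass = truth.concentration * v0
    permeate_mass = np.zeros_like(mass)
    v = v0
    for _ in range(n_steps):
        dm = (1.0 - r) * (mass / v) * dv
        mass = mass - dm
        permeate_mass += dm
        v -= dv
    return BatchOracleResult(
        retention=r,
        retentate_concentration=mass / v,
        mean_permeate_concentration=permeate_mass / v_perm_total,
        species_yield=permeate_mass / (truth.concentration * v0),
    )
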