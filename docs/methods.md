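# Methods

## Scope and model

`pepsieve` predicts the composition of the permeate compartment of a
batch (concentration-mode) tangential ultrafiltration of a protein
hydrolysate, and from it the yield η, enrichment factor τ and purity of a
target peptide, as functions of the volume reduction factor
VRF = V₀/V_R. Three sub-models feed the prediction.

### SEC characterization

Elution time t (min) maps to molar mass through a linear column
calibration `log₁₀(MW) = a·t + b`. The default (`SUPERDEX_PEPTIDE`,
a = −0.082, b = 5.382) represents a peptide-range column calibrated with
short synthetic peptides between 220 and 1890 g·mol⁻¹. Logarithms are
base 10 throughout — the intercept is only dimensionally sensible that
way. Evaluations outside the standards' range are extrapolations of a
linear law; they are returned but flagged, because hydrolysate
chromatograms routinely extend beyond the standards on both sides.

The 214 nm absorbance trace is converted to a mass-concentration density
with the per-residue Beer–Lambert form

    C(t) = A(t) · M̄aa / (ε̄aa · l),

where M̄aa and ε̄aa are the substrate protein's mean residue mass and mean
residue extinction coefficient at 214 nm (bovine hemoglobin defaults: 115
g·mol⁻¹ and 987 L·mol⁻¹·cm⁻¹) and l the cell path (1 cm). This is the
only closed form consistent with per-residue constants: at 214 nm the
chromophore is essentially the peptide bond, so absorbance counts
residues, and multiplying by the mean residue mass converts residue
molarity to mass concentration. `C(t)` is a density over elution time; a
single dimensionless `scale` factor (default 1) carries whatever
injection-volume/flow normalization links the integrated trace to the
sample concentration in a given acquisition setup. All integrals are
trapezoidal on the recorded grid. An optional constant baseline (minimum
over a user-chosen pre-peak window) can be subtracted; negative values
are clipped to zero with a warning.

Distribution summaries treat each grid point as a point mass with its
trapezoid quadrature weight. Quantiles use the generalized inverse of the
cumulative curve (smallest grid MW reaching the requested fraction):
exact for isolated species, within one grid step of interpolation for
dense traces.

### Membrane sieving calibration

In total-recirculation mode both outlet streams are at steady state, so
`Rₓ = 1 − A_p,x/A_r,x` is the observed retention of whatever elutes at
time x. Retention of peptide mixtures on hydrophilic regenerated-cellulose
membranes is modelled as linear in log₁₀(MW) and fitted by unweighted
ordinary least squares. Numerical choices:

* Permeate is linearly resampled onto the retentate time grid (the ratio
  requires same-time points; acquisition grids may differ).
* Points with retentate signal below 2% of its maximum (configurable) are
  dropped: the ratio there is noise over noise.
* Observed R outside [0, 1] is **kept** for the regression and clipped
  only at evaluation time; clipping before the fit would bias both
  coefficients.
* An optional molar-mass fit window excludes the fully-retained plateau:
  once the membrane saturates at R = 1 the data carry no information
  about the sieving line, and including the plateau flattens the fitted
  slope. The natural window is the column-standards range (220–1890
  g·mol⁻¹), inside which the reference membranes stay below full
  retention.
* One calibration per membrane is reused across hydrolysates of the same
  substrate protein; sieving here is dominated by steric hindrance, not
  by peptide chemistry.

The apparent MWCO is `10^((0.9 − intercept)/slope)` — the molar mass
retained at 90% — and generally differs from the manufacturer's nominal
label, which is established with standards of different shape.

Reference calibrations `RC_MEMBRANE_1K` (R = 0.7978·log₁₀MW − 1.6206) and
`RC_MEMBRANE_3K` (R = 1.0552·log₁₀MW − 2.666) describe 1 and 3 kg·mol⁻¹
regenerated-cellulose membranes against bovine-hemoglobin peptides; they
give target (653 g·mol⁻¹) retentions of 0.625 and 0.304 and apparent
MWCOs of ≈1444 and ≈2396 g·mol⁻¹.

### Batch mass balance

For constant observed retention R the solute balance dm = −(1−R)(m/V)dV
integrates to a cumulative (volume-averaged) permeate-compartment
concentration

    C̄p/C₀ = (VRF − VRF^R)/(VRF − 1),

interpreted as the concentration of the *pooled* permeate of a batch
concentration run — not the instantaneous permeate. The VRF → 1 limit is
1 − R; the implementation switches to the analytic limit within 1e-9 of
VRF = 1. Yield follows as η = (C̄p/C₀)(1 − 1/VRF) = 1 − VRF^(R−1), an
identity the test suite enforces to machine precision.

The permeate chromatogram is predicted by applying the balance to every
feed-profile point at the retention its molar mass receives from the
calibration (no experimental per-point R is reused at prediction time);
its integral gives ΣC̄p. Enrichment uses the scalar balance at the
target's molar mass rather than integrating over its chromatographic
peak, matching the single-retention treatment of the target; with a
coarse profile τ·purity can then numerically exceed 100%, so purity is
capped at 100 with a warning. The default sweep grid is 90 log-spaced
VRFs from 1.1 to 10.

Solving η(VRF) = goal uses the exact inverse VRF = (1 − goal)^(1/(R−1)).
Productivity is permeate peptide mass / (membrane area × duration),
g·m⁻²·h⁻¹, with flux and duration supplied by the user — flux is measured,
not modelled.

## Synthetic data

The generator emulates what matters to the pipeline, not peak-shape
realism. A hydrolysate is a mixture of discrete species: molar masses
sampled from a bimodal log-normal mixture (a high-MW "intermediate
peptide" component and a low-MW "final peptide" component, reflecting
zipper-type proteolysis), plus a fixed-mass target species at 653
g·mol⁻¹. Mass splits within a component are log-normal (σ = 0.5) to avoid
implausibly uniform abundances. Each species is rendered as a Gaussian
elution peak (σ = 0.3 min, ≈0.025 decades of MW — sharp but within SEC
practice) centred at the inverse column calibration, with amplitude from
the inverse Beer–Lambert form; detector noise is additive Gaussian with
sd = `noise_sd` × max signal. Recirculation pairs apply the true sieving
law pointwise with independent multiplicative noise on both traces, since
noise lives in measured absorbances. All randomness flows from the single
spec seed.

Presets span a proteolysis course at 10 g/L total peptides: `3dh-col`
(median ≈3900 g·mol⁻¹, ≈1% non-target mass below the target, 2.5% target
purity), `3dh-dec` (≈2330, 2.6%), `5dh` (≈1780, 4.5%), `10dh` (≈1230,
5.5%), `18dh` (≈850 g·mol⁻¹, ≈24% of mass below the target, 6.4%
purity). They are statistical stand-ins chosen once to reproduce the
characteristic medians and below-target fractions of such hydrolysates,
not reconstructions of any measured chromatogram. Two tensions are
accepted rather than tuned away: the `18dh` median sits slightly below
the nominal 1000 g·mol⁻¹ once its below-target mass fraction is matched,
and `3dh-col` holds so much of its mass above the full-retention clip
that its enrichment-vs-VRF curve is flat to within seed noise instead of
clearly decreasing (the decrease is robust on `3dh-dec`). What passing
tests show is therefore self-consistency of calibration, characterization
and prediction under realistic noise — not peak asymmetry, baseline
drift, co-elution or concentration-polarization effects of real runs.

`batch_oracle` is the independent check on the closed-form balance: it
removes the permeate volume in equal increments (explicit forward
stepping, no adaptive solver, for auditability), each species losing
(1−R)·c·ΔV per step. At 10⁵ steps it agrees with the closed form to
better than 1e-4 relative over R ∈ [0, 1], VRF ≤ 10, and its error
decreases monotonically with step count.

## Problem sizes and verification

Synthetic fixtures use ~200 species on ~1500-point time grids; calibration
recovery is checked noiselessly (coefficients to 1e-9) and across 20
seeds at 1% noise (seed-averaged slope within ±0.02, R² ≥ 0.988);
end-to-end recovery of the generator's true target yield and enrichment
at VRF 5 holds within 3% relative. The oracle comparison uses 10⁵ steps.
These sizes make the full suite run in seconds while leaving every
statistical check well-resolved.

## Known limitations

* Constant observed retention per species: no concentration polarization,
  fouling, charge effects or pressure dependence; calibrations are valid
  at the hydrodynamic conditions they were measured under.
* Linear R vs log₁₀(MW) with hard clipping; no sigmoidal sieving model.
* The target is treated as a single point at its molar mass; co-eluting
  species are not deconvolved, so feed purity must come from an
  orthogonal assay (e.g. RP-HPLC peak area with an external standard,
  `C = 4419.6 × A` mg·L⁻¹ per µV·s for neokyotorphin).
* Diafiltration, multi-stage cascades and flux prediction are out of
  scope; productivity is a bookkeeping conversion of user-supplied flux
  and duration.
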