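# Methods

This note records the models implemented in `lnpkit`, their assumptions, the
parameter and unit conventions, the numerical choices made where the design
was genuinely open, and what the synthetic-data generators do and do not
emulate.

## Unit conventions

A single declared convention avoids silent Å/nm errors: molecular distances
are **nm**, angles **degrees**, scattering vectors **q in Å⁻¹**, SAXS
intensities internally in absolute **Å⁻¹** (reduced-data files in mm⁻¹ are
converted at ingest, 1 mm⁻¹ = 10⁻⁷ Å⁻¹), scattering-length densities quoted
in **10⁻⁶ Å⁻²**, diameters at public interfaces in **nm**, specific surface
areas in **m²/g**, forces in **nN**, moduli in **GPa**. With E in GPa and
R, δ in nm, the Hertz force comes out in nN with no further factor; with V in
cm³/mol and δ in MPa^0.5, χ is dimensionless because MPa·cm³ = J exactly.

## Solution thermodynamics

χ = V(δ₁−δ₂)²/(R T) with R = 8.314462618 J/(mol·K) and T defaulting to
298.15 K. For solvent–solute pairs the reference volume V is the organic
solvent's molar volume. For **solvent–water pairs the molar volume of water
(18.07 cm³/mol) is used as the reference volume**: this is a convention, not
a derivation — among the plausible reference-volume choices (organic solvent,
water, geometric mean) only the water volume reproduces the consistent set of
published solvent–water interaction parameters for acetone/THF/dioxane/DMSO,
and the smaller component's molar volume is the usual lattice reference in
Flory–Huggins treatments of small-molecule pairs. The choice is surfaced in
the API (`water_molar_volume` argument of `rank_solvents`) rather than
hidden. Supersaturation is the plain ratio S = s₇₅/s₂₁ of solubility degrees
before and after anti-solvent dilution. Report rounding: one decimal, two
decimals below 0.1, so very small χ (e.g. DMSO–lignin) remain visible.
Hansen parameters are used as totals; the three-component (δd, δp, δh)
decomposition is out of scope.

## SAXS

**Model.** Homogeneous spheres with a *number-weighted log-normal diameter
distribution*, parameterised by (median diameter, σ_log):

I(q) = Δρ² · (φ/⟨V⟩) · ⟨V²P(q,R)⟩ + b,  P(q,R) = [3(sin qR − qR cos qR)/(qR)³]²

where ⟨·⟩ averages over the diameter distribution and the number density
φ/⟨V⟩ ties the distribution's total volume to the volume fraction φ. For
σ_log = 0 this reduces to Δρ²φV·P + b. Interparticle interference (structure
factor) is neglected — appropriate for the dilute dispersions targeted
(φ ≈ 5×10⁻³). Reported mean and SD are the number-weighted moments
median·exp(σ²/2) and mean·√(exp σ²−1); whether a volume weighting is wanted
instead can be computed from the same fitted parameters.

**Quadrature.** 151-point Gauss–Legendre in log-diameter space on
[μ−5σ, μ+5σ+6σ²]. The upper extension matters: the integrand carries V² ~
e^{6u}, whose effective log-normal is shifted by 6σ², and a symmetric ±5σ
window already truncates ~0.2% of that weighted mass at σ ≈ 0.35. The rule
is validated against a 10⁶-sample Monte-Carlo average in the tests. Widths
σ_log > 1.2 are rejected (unresolvable at fixed order).

**Fitting.** Weighted least squares via lmfit (weights 1/σ² when
uncertainties are present, else 1/I²). Contrast and volume fraction are
degenerate in the dilute limit (only Δρ²φ enters), so the contrast is fixed
by default (from known component SLDs) and φ floats; either can be released.
Initialisation: a Guinier regression on the lowest-q fifth gives a size
guess; restarts scan ×{0.5, 0.75, 1, 1.5, 2} of it and the lowest reduced χ²
wins, ties broken by smaller σ_log.

**Invariant chain.** Q = ∫ I q² dq is evaluated as an analytic Guinier head
(closed form with erf) + trapezoidal body (background-subtracted) + analytic
Porod tail K_P/q_max. Then Δρ = √(Q/2π²φ(1−φ)), S/V = K_P/(2πΔρ²), and
SSA = (S/V)/(φρ) with ρ = 1.4 g/cm³ as the particle density. φ is taken as
c/ρ from the known mass concentration. These standard absolute-intensity
two-phase forms are validated by closure properties in the test suite
(recovering the generation Δρ within 1% and S/V = 3φ/R within 2% on
synthetic monodisperse spheres at the study conditions: D = 44 nm,
φ = 4.79×10⁻³, Δρ = 3.13×10⁻⁶ Å⁻²).

**Guinier and Porod estimation.** Guinier: linear regression of ln I on q²;
the validity convention q·R_g ≤ 1.3 is enforced post hoc as a warning, not
an error. Porod: the plateau regression I·q⁴ = K_P + b·q⁴ on the default
window 0.02–0.1 Å⁻¹ (uniform weight in Porod space — an unweighted fit of I
on q⁻⁴ is dominated by the fringe-heavy low-q edge of the window). The flat
background b is then re-estimated from the top 15% of the measured q range,
where a flat background dominates a q⁻⁴ signal, and K_P refitted with it
fixed: the in-window joint estimate of b is poorly conditioned and unsafe to
extrapolate. The high-q splice consistency check compares invariant-weighted
integrals over the top of the measured range rather than single points,
which would sit arbitrarily in form-factor fringe minima; mismatches above
20% raise an error.

**SLD from composition.** SLD = r_e N_A ρ Σ wᵢ(Zᵢ+fᵢ′)/Aᵢ with mass
fractions normalised to 1 (tolerating tabulations that sum to 95–105%, e.g.
an elemental analysis reported to 99.0 wt%) and real anomalous corrections
f′ at Cu Kα applied by default — they matter at the 0.5% level for O and S
(water: 9.47 vs 9.42 ×10⁻⁶ Å⁻² with/without).

## Structural analysis of configurations

Orthorhombic periodic boxes only; the minimum-image convention wraps each
displacement component into [−L/2, L/2).

**Hydrogen bonds.** A (donor, H, acceptor) triple is a bond iff the
heavy-atom donor–acceptor distance is strictly < 0.35 nm **and** the
hydrogen–donor–acceptor angle — vertex at the *donor*, between the D→H and
D→A vectors — is strictly < 30°. The donor-vertex angle convention is
implemented deliberately (it is not the D–H···A angle at the hydrogen used
by some packages), and boundary equality is excluded. Donors are inferred as
H atoms within 0.12 nm of an O/N in the same molecule, or supplied
explicitly; acceptors default to all O/N. Intramolecular pairs are excluded
by default. Neighbour search uses a periodic cell list (falling back to
all-pairs for boxes under 3 cells per edge) and is verified identical to the
O(N²) computation in the tests.

**RDF.** g(r) is the minimum-image pair-distance histogram normalised per
frame by N_a·ρ_b·V_shell; self pairs are excluded; r_max must not exceed
half the smallest box edge. When group A equals group B each unordered pair
is counted twice, which cancels in the mean of g but doubles the counting
variance — the statistical bands in the tests account for this.

**SASA.** Shrake–Rupley with a deterministic Fibonacci-lattice point set
(default 960 points/atom) on spheres of radius rᵢ + probe (probe 0.14 nm),
PBC-aware occlusion, Bondi van der Waals radii by default (overridable).
Points exactly on a lower-index neighbour's sphere are assigned to that
neighbour, so exactly coincident atoms contribute the area of one atom
rather than two or zero. Cross-checked against mdtraj's independent
implementation in the tests.

## Nanomechanics

Hertz sphere-on-flat with a rigid tip: F = (4/3)·E/(1−ν²)·√R·δ^{3/2},
sample-only modulus (no tip compliance — its handling for the calibrated
50 nm tips is not separately modelled), ν = 0.3, R = 50 nm defaults. Fits
run on the 5–50% force-fraction window and co-fit a contact-point offset
bounded to ±5 nm. **Window membership is decided on a 9-point
moving-average-smoothed force trace**: selecting points by their own noisy
values correlates noise with inclusion and biases the fitted modulus low by
~3% at 2% force noise; with smoothed selection the mean bias is below 1%
(the raw forces are what is fitted). Fits spanning more than ~10% of the
particle height should be treated as thin-sample-affected; the study regime
is 2–3 nm indentations on 20–80 nm particles.

Instrument-specific intermodulation-AFM stiffness signals are reported by
their vendors in arbitrary units via proprietary spectral processing; this
package instead provides a documented slope-based proxy (linear slope of
F vs δ over the top 20% of the force range, in N/m), which preserves
relative comparisons but not the vendor's absolute scale. Stiffness/modulus
versus particle height is summarised in user-supplied height bins; records
with E > 4 GPa or height < 15 nm are flagged substrate-affected and excluded
from particle statistics, and the slope t-statistic of modulus on height
tests size-(in)dependence.

## Particle-size statistics

Gaussian least-squares fit to the diameter histogram (Freedman–Diaconis
binning by default, since TEM practice varies); samples under 30 diameters,
degenerate histograms or implausible fits fall back to sample moments with a
flag. **PDI here is SD/mean of the diameter distribution** — the TEM-style
coefficient of variation, *not* the DLS cumulant PDI, which is a different
quantity on a different scale. Published PDIs computed from unrounded
moments cannot always be reproduced from rounded printed means/SDs (e.g.
13/47 = 0.28 from rounded values vs 0.29 from unrounded) — a reporting
artefact, not a discrepancy.

## Synthetic data

Generators are deterministic under an integer seed (NumPy PCG64) and return
a ground-truth record alongside the data.

* **SAXS**: the model intensity on a log-spaced q grid 0.003–0.3 Å⁻¹ (400
  points, matching a lab-source configuration) with multiplicative Gaussian
  noise — a reasonable approximation of counting statistics on
  absolute-scaled, azimuthally averaged data. Default conditions are the
  study's dispersion: 44 ± 16 nm number-weighted log-normal diameters,
  6.7 mg/mL at 1.4 g/cm³ (φ = 4.79×10⁻³), lignin/water contrast
  3.13×10⁻⁶ Å⁻², 0.01 mm⁻¹ flat background. Not emulated: instrument
  smearing, structure factor, incoherent-background q dependence.
* **Force curves**: Hertz responses with additive Gaussian force noise (SD a
  stated fraction of the maximum force); an optional fraction of curves is
  replaced by stiff-substrate responses (6–12 GPa, all above the 4 GPa
  line). Not emulated: adhesion, viscoelasticity, cantilever dynamics.
* **Solvent boxes**: rigid idealised molecule templates (water, acetone,
  THF, dioxane, DMSO — correct bond-length scale, schematic H placement)
  placed uniformly at random with uniform random orientations and no
  overlap check, so centres follow ideal-gas statistics *by construction*
  (g(r) = 1, which the RDF tests exploit). Molecule counts minimise the
  weight-fraction error at a fixed total molecule count (largest-remainder
  rounding plus a zero-sum local search, verified against a brute-force
  oracle). Not emulated: liquid structure, excluded volume, equilibration.
* **Hydrogen-bond scenes**: isolated donor-hydroxyl/acceptor units on a
  shuffled 1.5 nm grid (inter-unit atom distances > 1 nm, so no accidental
  bonds); planted bonds sit ≥10% inside both cutoffs, decoys violate exactly
  one criterion each, so the detected count equals the planted count
  exactly, for any seed.

Passing tests on these generators demonstrates the correctness of the
estimators under their own assumptions (parameter recovery, closure
identities, oracle equivalence); it does not certify accuracy on real
instrument data with smearing, drift, adhesion or non-ideal liquid
structure.

## Problem sizes

Default test/verification sizes: 400-point SAXS curves with 3-seed fit
recovery; 100 force curves for noisy-recovery statistics and 400 records for
substrate flagging; 250–500-molecule solvent boxes for oracle comparisons;
960 sphere points per atom for SASA (within 1% of 9600). These sizes make
every statistical band used in the tests comfortably resolvable.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* No structure factor, instrument smearing or non-spherical form factors in
  SAXS; absolute calibration is assumed done upstream.
* GRO element symbols are inferred from atom names (the format carries no
  element field); unusual naming may need an explicit override.
* The Hertz model assumes an elastic half-space: strongly curved or very
  thin particles violate it, which is why the substrate/height flags exist.
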