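# lnpkit

Quantitative analysis toolkit for **lignin nanoparticle (LNP) characterisation**.
LNPs are formed by nanoprecipitation: softwood Kraft lignin (SKL) dissolved in a
water-miscible organic solvent (aqueous acetone, THF, dioxane or DMSO) is rapidly
diluted with water, driving supersaturation, nucleation and growth of spherical
colloidal particles. `lnpkit` implements the quantitative analyses used to
characterise such particles and the solvents that form them:

* **Solvent screening** (`lnpkit.solvents`) — Flory–Huggins interaction
  parameters χ = V(δ₁−δ₂)²/RT from Hansen solubility parameters, and
  supersaturation levels S = s₇₅/s₂₁ from solubility degrees.
* **SAXS analysis** (`lnpkit.saxs`) — fitting absolute-intensity small-angle
  X-ray scattering curves with a homogeneous-sphere model under a
  number-weighted log-normal diameter distribution, and the invariant chain

  Q = ∫₀^∞ I(q)q²dq = 2π²φ(1−φ)Δρ²,  K_P = lim I q⁴ = 2πΔρ²(S/V),  SSA = (S/V)/(φρ)

  with Guinier (I ∝ exp(−R_g²q²/3)) and Porod (I ∝ q⁻⁴) extrapolations, plus
  X-ray scattering-length densities from elemental composition.
* **Structural analysis of simulation frames** (`lnpkit.mdstruct`) — geometric
  hydrogen-bond counting (donor–acceptor distance < 0.35 nm, hydrogen–donor–acceptor
  angle < 30°), radial distribution functions, Shrake–Rupley solvent-accessible
  surface area (probe 0.14 nm), and solvent-box mass-fraction accounting.
* **AFM nanomechanics** (`lnpkit.nanomech`) — Hertzian spherical contact fits
  F = (4/3)·E/(1−ν²)·√R·δ^{3/2} on force–indentation curves (ν = 0.3, tip radius
  50 nm, 5–50% force window) with stiffness/modulus-versus-height analysis and
  stiff-substrate flagging (4 GPa line, 15 nm height cutoff).
* **Particle-size statistics** (`lnpkit.sizestats`) — Gaussian histogram fits of
  TEM diameter counts, PDI = SD/mean, log-normal moment conversions.
* **Synthetic data** (`lnpkit.synthetic`) — seeded generators for every input
  (SAXS curves, force curves, solvent boxes, hydrogen-bond scenes) with
  machine-readable ground truth, so the whole pipeline is testable end to end.

## Worked example

Generate a synthetic LNP dispersion SAXS curve (44 ± 16 nm number-weighted
log-normal spheres, 6.7 mg/mL at particle density 1.4 g/cm³, 1% noise) and fit it:

```bash
$ lnpkit simulate saxs-lnp --seed 7 --outdir demo/
$ lnpkit saxs-fit demo/saxs_lnp.dat
{
  "mean_diameter_nm": 44.061913835035064,
  "sd_diameter_nm": 15.972788543626738,
  "median_diameter_nm": 41.42409044238395,
  "sigma_log": 0.35137777707075313,
  "volume_fraction": 0.00520482031211339,
  "background_mm_inv": 0.00999650362487614,
  "chi2_reduced": 0.852372135730427
}
```

The fit recovers the generating mean diameter (44 nm) and SD (16 nm) to within
0.2%, the flat background (0.01 mm⁻¹), and a reduced χ² near 1, as expected when
the noise model matches the weights.

Solvent screening from the packaged property table (Hansen δ in MPa^0.5, molar
volume in cm³/mol, solubility degrees of 1 wt% SKL):

```bash
$ lnpkit chi
[
  {
    "name": "DMSO",
    "chi_solvent_solute": 0.01403412789540013,
    "chi_solvent_water": 3.2452941313947012,
    "supersaturation": 115.55555555555557,
    "chi_solvent_solute_str": "0.01",
    "chi_solvent_water_str": "3.2",
  },
  ...
]
```

DMSO ranks first (χ = 0.01 — strongest solvent–lignin affinity, and the highest
supersaturation level S ≈ 115.6 of the screening set); THF ranks last (χ = 2.1).
Lower χ means stronger affinity; higher S means faster nucleation and smaller
particles.

Other subcommands: `lnpkit saxs-ssa` (invariant/Porod specific surface area),
`lnpkit hbonds`, `lnpkit rdf`, `lnpkit sasa`, `lnpkit hertz-fit`,
`lnpkit size-stats`, `lnpkit simulate`. All distances are nm, angles degrees,
q in Å⁻¹, on-disk intensities in mm⁻¹.

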