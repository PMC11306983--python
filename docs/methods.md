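# Methods

## Model and conventions

All spectra live on wavenumber grids ν in cm⁻¹ (1 THz ≈ 33.36 cm⁻¹).
Complex permittivity uses the e^(−iωt) time convention, ε\* = ε′ + iε″, so
passive media have ε″ ≥ 0. Optical constants relate to permittivity by
ε′ = n² − (α/4πν)² and ε″ = nα/2πν with α the Napierian absorption
coefficient in cm⁻¹ (α = −ln Tr / d; decadic input must be converted,
`thzem convert --decadic`). The inverse transform computes
n = √((|ε\*|+ε′)/2) and recovers the extinction factor from the exact
identity ε″ = 2nκ rather than from |ε\*| − ε′, which cancels
catastrophically when ε″ ≪ ε′; the roundtrip is then exact to better than
1e−12 relative.

The mixing model is the symmetric Bruggeman effective-medium
approximation, Σᵢ fᵢ(εᵢ − ε_e)/(εᵢ + 2ε_e) = 0. It assumes inclusions
small against the wavelength and weakly absorbing individually — both
satisfied for ~5 nm globules in the THz band — and needs no inclusion
shape parameters. Two-phase forward mixing reduces to a quadratic
(2x² − bx − ε_aε_b = 0, physical branch), three-phase to a cubic solved
per frequency by `numpy.roots`; the passive root nearest the
volume-weighted linear mixture is selected, and every forward solve is
verified against its defining residual (tolerance 1e−10 relative).

## Volume fractions

Mass concentration converts to volume fraction as f = c/(1000ρ) with ρ
the protein mass density (default 1.41 g/cm³, serum-albumin-like); no
partial-specific-volume correction is applied. The shell fraction in the
dilute solution scales the concentrated solution's aqueous fraction by the
concentration ratio, f_sh = (1 − f_p)·c_dilute/c_conc, which assumes
non-overlapping shells; a warning is emitted when f + f_sh > 0.5. Note the
identity f(1 − f_p) = f_p·f_sh that follows from this construction — it
matters for a degeneracy below. Fractions are kept at full precision
internally; rounding to the three displayed figures happens only at the
presentation layer.

## The inversion and its two solvers

Per frequency the combined equation T1 + T2 + T3 = 0 is solved for ε\*_p,
where T1 is the protein term of the three-phase balance, T2 the shell term
with ε\*_sh expressed through the concentrated solution, T3 the bulk-water
term.

**Reduced solver (default).** Neglecting T1 gives the shell contrast
C = −(1 − f − f_sh)(ε\*_w − ε\*_s)/[(ε\*_w + 2ε\*_s) f_sh], from which
ε\*_sh = ε\*_s(1 + 2C)/(1 − C), and the two-phase closed form inverts to
ε\*_p. The solution is unique and linear in the data — no branch choice —
at the cost of a relative bias of order |T1|/|T2|. C = 1 or a vanishing
inversion denominator invalidates that frequency only; gaps are never
interpolated over.

**Full solver.** Clearing both ε_p-dependent denominators leaves a
quadratic; both roots are computed per frequency. Selection order:
passivity (ε″ ≥ −tiny), then proximity to a hint (default: the reduced
solution), then continuity with the previous frequency's accepted root.
Two caveats are inherent to the mathematics, not the implementation:

* Both quadratic roots are *exact, fully physical* solutions of the
  combined equation (each implies a passive shell). When the protein
  contrasts strongly with the solution — e.g. a weakly dispersive protein
  in water — the reduced hint is biased by tens of percent and selection
  can land on the conjugate branch. In that regime a caller-supplied
  `hint` is required for guaranteed branch identification; for
  solution-state protein spectra, whose response tracks the aqueous
  environment, the default hint identifies the branch correctly and the
  noiseless roundtrip recovers ground truth to better than 1e−8 relative.
* When all three measured spectra coincide and the fractions are
  concentration-consistent (f(1 − f_p) = f_p·f_sh), the equation is
  satisfied identically by every ε\*_p: the polynomial's coefficients
  cancel to zero. The solver detects this against the pre-cancellation
  magnitude of the coefficient addends (threshold 1e−9 relative) and
  returns the hint, which the reduced two-step structure resolves to the
  common spectrum.

**Validity diagnostics.** After either solve, |T1|, |T2|, |T3| are
evaluated at the solution; a frequency is valid when |T2| ≥ r|T1| and
|T3| ≥ r|T1| with r = 10 by default (an order of magnitude), it lies in
the configured analysis window (default 10–70 cm⁻¹), and the extracted
ε″ ≥ −0.05. Loss values in (−0.05, 0) — noise pushing against the passive
bound — are reported as-is with a warning flag, never clamped; more
negative values invalidate the frequency.

**Sensitivity scan.** Input uncertainty is modelled as iid zero-mean
Gaussian noise of SD δ added independently to ε′ and ε″ of all three
input spectra — the minimal assumption for an unstructured
"spread of about 0.01" — with both solvers re-run on the *same* perturbed
draws so their spreads are paired. Reported per frequency: relative
standard deviation and max/min ratio of |ε\*_p| over draws. Fully
reproducible from the seed.

## Synthetic scenes

Water is two Debye bands, ε\*(ν) = ε_inf + Σ Δε_j/(1 − iωτ_j), with
literature-typical 25 °C defaults (Δε ≈ 73, τ ≈ 8.3 ps; Δε ≈ 2,
τ ≈ 0.3 ps; ε_inf = 2.5). These values are *configuration placeholders*,
not fitted constants from any measurement; nothing in the package's
validation depends on their exact values, only on the two-band structure.
Lorentz oscillator terms are supported for resonant bands but unused by
the defaults. A hydration shell is water with every τ multiplied by a
slowing factor and every Δε by a strength factor. Two protein families
ship:

* `weak_protein_model` — ε_inf = 2.5 plus one mild Debye band: a nearly
  dispersion-free interior, strong contrast against water;
* `water_coupled_protein_model` — a mild perturbation of the water bands
  (defaults τ×1.05, Δε×0.98): the solution-state regime in which protein
  losses track the aqueous environment's and the protein term of the
  combined equation is genuinely small.

The package's standard test scene (`reference_scene`) uses the
water-coupled protein with a strongly retarded shell (τ×2.0, Δε×0.85) at
the 334/50 mg/mL fractions on a 10–70 cm⁻¹ grid with 2 cm⁻¹ steps
(31 points). This is the regime the reduced approximation was designed
for, and the scene reproduces its signature properties: term ratios far
above 10 across the window, exact full-solver roundtrip, ~1% reduced-solver
bias shrinking linearly as f → 0, and a several-hundred-fold full-solver
spread under 0.01-SD noise against ~2× for the reduced solver.

Scenes mix constituents forward through the same Bruggeman relations the
inversion assumes, so roundtrip tests validate the solvers, not the
mixing model itself. Real measurements add effects the generator omits:
frequency-correlated (non-iid) errors, etalon residuals, concentration
uncertainty, shell heterogeneity (a radial profile rather than one
effective phase), and ionic conductivity of buffered solvents. Passing
roundtrips therefore demonstrate correctness of the inversion under the
model's own assumptions, not instrument-grade accuracy.

## Numerical choices

* Grid alignment: linear interpolation onto the coarsest grid restricted
  to the common frequency interval; extrapolation is never performed.
* Singular denominators are detected at 1e−12 relative to operand scale
  and invalidate single frequencies rather than aborting spectra.
* Solver outputs are always verified against the un-cleared rational
  residual, normalised by the largest term magnitude (tolerance 1e−10;
  1e−6 for flagging noisy extractions).
* Problem sizes: the standard grid has 31 points and sensitivity scans
  default to 100 draws, which keeps every validation run in the seconds
  range while leaving the Monte-Carlo statistics stable.

## Known limitations

* Branch ambiguity of the full solver under strong protein contrast (see
  above) is intrinsic to the quadratic; only prior information resolves it.
* The shell-scaling rule degrades as shells overlap (high dilute
  concentrations); the warning threshold f + f_sh > 0.5 is heuristic.
* No Kramers–Kronig consistency is enforced on extracted spectra.
* Replicate averaging before inversion is available upstream of the CLI
  (spectra may be averaged externally) but the default pipeline inverts
  single spectra.
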