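# Methods

This note records the models behind `napxps`, the defaults and why they
were chosen, and what the synthetic-data tests do and do not demonstrate.

## Spectral model

A core-level region scan is modelled as

    counts(E) = B(E) + Σ_k A_k · V(E − E_k; Γ_G, Γ_L)

with true Voigt profiles `V` (Gaussian ⊗ Lorentzian, evaluated through the
scaled complex error function `w(z)`), unit-area normalized so each `A_k`
is an area in counts·eV.  Widths are FWHM in eV.  Within a region all
components share one Gaussian FWHM Γ_G ∈ [0.6, 2.5] eV (instrumental
broadening is common to a scan) and one Lorentzian FWHM Γ_L ∈ [0, 0.6] eV
(core-hole lifetimes of one level are comparable).  Sharing is a
deliberate identifiability constraint: with every width free, four
overlapping C1s Voigts are statistically degenerate — the Gauss–Newton
normal matrix turns rank-deficient under Poisson noise and the reported
area uncertainties lose calibration (empirical pull standard deviation
~13 instead of 1).  With shared widths the pulls are standard normal to
within a few percent.  Per-component widths remain available
(`share_*_width = False`).

Centers are bounded ±0.5 eV around their assigned binding energies
(±0.75 eV for literature entries quoted as ranges, centered on the range
midpoint); areas are bounded below by zero.  The P2p line is a linked
spin-orbit doublet: the 2p1/2 follower carries half the 2p3/2 area, sits
1.0 eV higher, and shares its widths (ratio and splitting configurable).
Gas-phase lines (N₂ at 405–406 eV, water vapour at 534–536 eV) are fitted
like any component but flagged `is_gas_phase`, which excludes them from
every damage metric: they report the atmosphere, not the film.

Energy referencing assumes charge-referenced spectra (binding energies on
the Fermi-level scale); an optional rigid shift to C1s = 285.0 eV can be
applied upstream by the user but is not performed by default.

## Shirley background

The inelastic background is the Shirley step: proportional to the
integrated net peak intensity at lower binding energy.  The classic
estimator iterates B(E) = I_hi + (I_lo − I_hi)·A_above(E)/A_total on the
raw data, with the endpoint levels taken as means over the outermost
5 points per side, tolerance 1e−6 (relative), at most 100 iterations.
This estimator is provided (`shirley_background`) and used as the fit
initialization, but it has a structural defect for fitting: its endpoint
levels absorb whatever peak intensity reaches the window edges, and
Lorentzian tails always do.  On noiseless four-component fixtures this
biases recovered areas by 5–10 %, and no exact fixed point of the
data-driven operator even exists when edge tails are nonzero.

The default fit therefore treats the background *as part of the model*:
the step shape is the cumulative fitted peak sum, and the two endpoint
levels — linear parameters — are profiled out by a closed-form 2×2
weighted least squares inside every residual evaluation.  This is the
model-based variant of the iterated ("active") Shirley.  On consistent
noiseless data it recovers generating areas to machine precision; a
fit/background alternation scheme was tried first and stalls at a biased
fixed point (~0.7 % area error), which is why the profiled joint fit is
the default.  `reiterate_background=False` restores the frozen data-driven
background for comparison with legacy analyses.

## Optimization and uncertainties

Bound-constrained least squares (scipy `least_squares`, trust-region
reflective, `ftol = xtol = 1e−10`) on Poisson-weighted residuals
`(y − B − ΣV)/√max(y, 1)`.  Timepoints are fitted independently,
warm-started from the preceding timepoint's optimum to stabilize component
identity.  Non-convergence is flagged, never silently returned; parameters
ending on a bound are recorded in the result's notes.

The covariance of the free parameters is `s²·(JᵀJ)⁻¹` with `J` the
Jacobian at the optimum and `s²` the reduced chi-square (the degrees of
freedom subtract the two profiled background levels).  Because the
background profiling happens inside the residual, `J` automatically
carries the background's dependence on the peak parameters.  Area sigmas
are read from the diagonal (areas are direct parameters; doublet followers
scale by their link ratio).  A rank-deficient normal matrix falls back to
the pseudo-inverse with a warning naming the implicated parameters.
Calibration is verified empirically: over 500 Poisson replicates at peak
SNR 100 the nominal 1σ intervals cover truth at 68 ± 5 % per component,
and covariance sigmas agree with a 200-resample parametric bootstrap
within 20 %.

## Damage metrics

All areas are normalized on the total P2p area of the same timepoint
(one phosphorus per nucleotide; the ratio cancels fluence and
probed-volume drifts).  Percent series are quoted relative to the total
non-gas normalized area of the region at the first timepoint, so each
region starts at a 100 % total.  The scalar indices are endpoint-based —
first versus last timepoint — because endpoints are the least
model-dependent summary of a monotone trend; a slope-based alternative
would presume kinetics the measurement does not constrain:

* strand-break index = (r₀ − r₁)/r₀ of the normalized C1s 286 eV
  (backbone C–O–P / C–N) component;
* base-damage index = the same fractional decrease of the summed
  condensed-phase N1s components;
* waters per nucleotide = (A_water/RSF_O1s)/(A_P2p/RSF_P2p), assuming one
  phosphorus per nucleotide.

Uncertainties propagate through the ratios assuming independence between
regions (they are separate scans); the P2p variance enters every ratio,
cross-region and within-region covariances are neglected.  The shipped
relative sensitivity factors (C1s 1.00, N1s 1.80, O1s 2.93, P2p 1.19) are
derived from the Scofield 1486.6 eV photoionization cross-section
compilation, with no analyzer transmission correction; quantitative work
on measured spectra should substitute an instrument-specific table
(`--rsf`).

## Transport model

Geometry: a 1-D layer stack, normally incident photons — gas column
(default 1 mm path at 10 mbar, 300 K, ideal-gas density; zero layers for
vacuum), an optional 0.3 nm adsorbed-water layer (water atmosphere only),
and a 200 nm DNA film of average nucleotide stoichiometry
C9.75H12.25N3.75O6P at 1.35 g/cm³.  These thicknesses and densities are
package defaults chosen as representative of a near-ambient-pressure
instrument and a drop-cast film; they are configuration, not measured
values.  Tallies are restricted to the top 10 nm of the film — the
effective XPS information depth.

Photon physics is photoelectric absorption only; at 1.4 keV in H/C/N/O/P
coherent scattering and fluorescence are few-percent corrections, which is
a deliberate simplification relative to a full Livermore-physics
treatment.  Free paths are exponential with layer-wise linear coefficients
from the shipped elemental photoabsorption table (Henke/XCOM-derived,
~two-significant-figure accuracy, 100 eV–10 keV, log-log interpolated)
via the mass-weighted mixture rule.  Gas and condensed columns are sampled
with two independent exponential stages — statistically identical to one,
but it keeps condensed-layer interaction points common across geometries
that differ only in their gas column, which sharpens the atmosphere
comparison (common random numbers).

At an absorption event the element is sampled by its share of the local
attenuation; its deepest ionizable shell binding energy (C 284.2, N 409.9,
O 543.1, P 135 eV at Al Kα) is deposited at the event site — the
Auger/relaxation cascade is nm-scale — and the photoelectron carries the
remainder.  Electrons follow straight tracks in the continuous-slowing-
down approximation with Bragg-additive collision stopping powers from the
shipped Joy–Luo table (modified Bethe with ICRU-37 mean excitation
energies; matches ICRU water values at 1–10 keV to ~6 %), down to a 20 eV
thermalization cut where the residual energy is deposited and the electron
counts as thermalized in the layer it stopped in.  The emission direction
follows the dipole sin²θ pattern about the photon axis (the correct
photoelectron angular distribution for s-shells at these energies);
isotropic emission is available as an option.

Electrons born in *gas* layers are tallied as escaping rather than
transported: a straight-track CSDA is meaningful across nanometre
condensed films but not across a millimetre gas column, where the elastic
mean free path (~0.4 mm at 10 mbar) randomizes directions long before the
surface.  Transporting them ballistically (`transport_gas_electrons=True`)
funnels an unphysical ~0.15 eV/photon of gas-phase energy into the 10 nm
scoring layer and inflates the apparent atmosphere dependence to ~13 %.

Energy is conserved exactly in the tally arithmetic: per history, the
deposits over all layers plus the escaping energy sum to the photon
energy.  The closed-form cross-check is the charged-particle-equilibrium
estimate `T_gas · μ_film · d_score · E`, valid when the film is ≥ 5× the
scoring depth.  The Monte Carlo sits ~20–25 % *below* it because the free
film surface breaks equilibrium — upward-going electrons escape without a
compensating inflow — an effect the closed form ignores.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
components at the registry binding energies (Gaussian FWHM 1.3 eV,
Lorentzian 0.2 eV — typical laboratory Al Kα values, not measured ones),
first-order area kinetics A(t) = A₀e^(−kt), a background whose baseline
and step height are proportional to the total region area (so damage
shrinks the background along with the peaks and the Shirley stage is
exercised nontrivially), and Poisson counts with one global scale set so
the tallest peak of the first timepoint reaches the target SNR
(S/√(S+B) = SNR; a single scale keeps cross-region quantification
meaningful).  Default acquisition: 0.05 eV steps, 10 timepoints over two
hours — placeholders for unspecified acquisition parameters.

The three presets encode the study's qualitative contrasts as exact
generator truth: the H₂O backbone (C1s 286 eV) decay rate is exactly 2×
the N₂ rate, the H₂O nitrogen decay exactly 3× the N₂ rate, and the
vacuum rates sit slightly below N₂ with strand-break chemistry dominating
base damage.  Dimensionless decays k·t_end per component (vacuum / N₂ /
H₂O): C1s_286 0.13 / 0.15 / 0.30; N1s 0.06 / 0.08 / 0.24; C1s_288
0.02 / 0.03 / 0.10; the hydration presets put 0.25 / 0.05 / 1.5 waters
per nucleotide into the O1s water component.  First-order kinetics is an
assumption (smooth monotone trends), not an inference.

What passing tests therefore show: the pipeline recovers *its own
statistical model* without bias and with calibrated uncertainties, at
realistic SNR, including the programmed condition contrasts.  What they do
not show: robustness to effects the generator omits — charging drift,
shake-up satellites, transmission-function roll-off, beam-spot
inhomogeneity, non-first-order kinetics, or line shapes that are not
Voigt.

## Problem sizes

Test and reproduction runs use 10⁶ Monte Carlo histories per transport
condition, 200 Poisson replicates for the 3σ-recovery study, 200 bootstrap
resamples plus 500 replicates for calibration, and 50 end-to-end
replicates per atmosphere (first/last timepoint only — the indices are
endpoint-based, so intermediate timepoints add cost but no information)
for the contrast-recovery study.

## Known limitations

* The elemental photoabsorption table is a two-significant-figure reading
  of the standard compilations; absorption-edge fine structure (notably
  the P L-edges) is smoothed.  Adequate for the wide transport tolerances
  here; not a dosimetry-grade dataset.
* Stopping powers below ~300 eV rely on the Joy–Luo extrapolation; the
  20 eV cut and straight tracks ignore elastic scattering, so electron
  *ranges* are effective, not track-structure quantities.
* The VAMAS reader covers single-block REGULAR NORM-experiment files only
  and rejects everything else.
* Damage indices are relative and endpoint-based; absolute G-values,
  dose–response modelling, and OH-radical chemistry are out of scope.
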