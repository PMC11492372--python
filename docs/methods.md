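# Methods

`poresig` models a metal-gated solid-state nanopore as a cylinder of radius
r_np and length L = 55 nm, of which L_Au = 5 nm is a gold gate layer held at
a small constant supply current.  The model is a chain of closed-form
empirical relationships; this note records each one, its assumptions, the
defaults, and what the synthetic data used for validation do and do not
emulate.

## Baseline state

**Activities.** Single-ion activity coefficients follow the extended
Debye–Hückel law at 298 K,

    log10 f_i = -A z_i² √I / (1 + B r̄ √I),  A = 0.509 (mol/L)^-1/2,
                                            B = 3.28 nm⁻¹ (mol/L)^-1/2,

with molar ionic strength I and the *average* ion radius r̄ of the mixture
(unweighted mean by default; a concentration-weighted option exists).  The
coefficients are fixed at their 298 K water values — temperature enters the
model only through the explicit T in the potential and diffusivity
relations.  The reservoir activity sums a_i = c_i f_i over all species.
The pore interior is populated by ions of one polarity only, so the
nanopore activity sums over the majority-polarity species, with activity
coefficients evaluated on that subset composition (its own ionic strength
and mean radius).  This composition difference is what gives the activity
ratio its concentration dependence.

**Majority ion and partitioning.** Confinement selects the smallest ion of
the electrolyte as the majority carrier (an exact radius tie raises an
error unless the caller overrides the choice; for mixtures the smallest ion
overall wins and the minority is the smallest ion of opposite polarity).
The partition coefficient

    P_bs = (D_Kn,maj / D_Kn,min) · (L_C / r_np),   D_Kn,maj/D_Kn,min = r_maj/r_min

quantifies how strongly the pore discriminates by size; the Knudsen
diffusion-coefficient ratio is expressed through the ionic radii (molecular
size tracks molecular weight), and the characteristic length L_C defaults
to 1 nm.  Larger pores are less selective (P_bs ∝ 1/r_np).

**EDL potential and current.**

    V_bs = -sgn(z_bs) · (k_B T / e) · P_bs · ln(a_reservoir / a_nanopore)
    I_bs = m · V_bs + c,   m = 2.0e-8 A/V,  c = 5.0e-12 A

The sign pair makes the potential polarity opposite to the majority-ion
valence; because the in-pore subset has lower ionic strength than the
reservoir, the log ratio shrinks as concentration rises, so |V_bs| (and
with it |I_bs|) decreases monotonically over 10⁻⁷–10⁻¹ M.  Different salts
shift the curves without changing the trend.  The current regression is a
device characteristic: the slope sets the sub-nanoampere current scale and
the picoampere intercept matches the scale of the gate supply current
(37.4 pA, recorded as metadata only).  Both coefficients live in
`poresig/constants.py`; every downstream quantity scales coherently if they
are recalibrated for another device.

**Drift, charge density, capacitance.**

    E = V_bs / L_Au,   v_bs = -sgn(z_bs) · μ_ion · E,
    n_bs = I_bs / (A · v_bs),   C_EDL = d(V_total · n_bs)/dV_bs

The axial orientation is chosen so the baseline drift is positive for every
supported electrolyte; n_bs then carries the current's sign (negative for
the cation-majority salts studied here — it is a bookkeeping density, not a
physical ion concentration; its magnitude is likewise an effective value,
not a molarity).  Majority-ion mobilities default to standard limiting
values shipped in the ion table (Li⁺ 4.01e-8, Na⁺ 5.19e-8, K⁺ 7.62e-8,
F⁻ 5.74e-8, Cl⁻ 7.91e-8 m²V⁻¹s⁻¹); species without a tabulated value must
be given one explicitly.  C_EDL is available in closed form
(sgn(z_bs)·L·L_Au·c/(μ V_bs²), ~0.5 fF at 1 mM NaF in a 2.3 nm pore) and as
a central finite difference (relative step 1e-6); the signed derivative is
positive for cation-majority baselines and is used as-is in the potential
signal.  C_EDL varies slowly with the operating point (≈ 1/V_bs², about
30% across the seven-decade concentration sweep) while the charge–potential
relation itself stays near-linear over the narrow V_bs range the sweep
spans; tests assert local constancy and sweep-level linearity, not global
constancy.

## Perturbed state

An analyte is modelled as fully inside the pore (instantaneous occupancy,
no entry/exit ramp) and far smaller than the pore, so wall interactions are
ignored.  Its excluded volume is a sphere of the Stokes radius
r_Stokes = r_analyte + w (water layer w = 0.14 nm, one water-molecule
radius, configurable); large particles are better described by the bare
radius (`use_stokes=False`) — fitting large-particle signals in Stokes mode
under-predicts the radius, a documented behaviour of the model, not a
target.

    Δn_V = -n_bs · V_analyte / V_total          (blockade: displaced charge)
    Δn_E = -P_bs · z · e / V_total              (partitioned screening)
    Δn   = Δn_V + Δn_E
    Δv   = v_bs · Δn / n_ps,  n_ps = n_bs + Δn
    ΔI_bs = A(Δn v_bs + n_bs Δv + Δn Δv)        (bilinear, cross term kept)
    n_analyte = z e / V_total,  v_analyte = L / t_ic
    I_analyte = n_analyte · A · v_analyte  (= z e / t_ic)
    I_ps = ΔI_bs + I_analyte
    V_ps = V_total (Δn + n_analyte) / C_EDL

The screening term carries P_bs because the compensating ions must enter
through the same size-selective pore as the baseline ions; screening is
therefore partial (P_bs < 1 for the geometries studied), which is why the
analyte's charge is visible in the potential signal at all.  With these
closures the two observables respond with opposite charge gradients —
V_ps increases and I_ps decreases with z, both increase with r³ — which is
what makes (r, z) jointly identifiable from a signal pair.  The direct
analyte current z e/t_ic is three or more orders below ΔI_bs at
millisecond translocation times.  When predicting signals without kinetic
data, t_ic defaults to 1 ms (flagged in the returned state); the default is
immaterial because only I_analyte depends on it.

## Kinetics

From a measured event duration and the baseline potential,

    μ = L · L_Au / (|V_bs| · t_ic),    D = μ k_B T / (|z| e).

Both are reported as magnitudes (the event polarity lives in the signal
record); |z| is used in the diffusivity so the sign convention cannot flip
D.  Typical in-pore values (μ ~ 4e-11 m²/Vs at millisecond events and
millivolt potentials) sit three orders below unconfined bulk references
(~5e-8 m²/Vs, configurable in `constants.BULK_MOBILITY_REFERENCE`),
consistent with transport through a charge- and size-selecting interior.

## Inverse fit

The residual is the weighted mean over events of squared relative errors in
I_ps and V_ps (weights w_I = w_V = 1 by default), making nanoampere-scale
currents and millivolt-scale potentials commensurate.  Events with a zero
observation fall back to absolute error with a logged warning.  The search
is an exhaustive grid — radius 0.1–4.0 nm in 79 steps by default, clipped
below r_np; integer charge −200..200 step 1 — followed by deterministic
local refinement: the radius is re-optimised continuously (bounded scalar
minimisation on a unit-scaled variable) while the charge hill-climbs one
grid step at a time, because an off-grid radius can drag the discrete
charge optimum along a diagonal (r, z) ridge, especially when I_ps passes
near zero and the relative error becomes steep.  Ties break toward smaller
radius, then smaller |z|.  A `separate` mode (CLI `--separate`) fits each
channel alone and reports both, covering the reading in which current and
potential are fitted independently.  All-zero signals return the
minimal-radius zero-charge corner with a degeneracy flag.  The only
uncertainty report is a crude interval: the radius span whose grid
residuals stay within twice the minimum — grid-curvature only, not a
calibrated confidence interval.

## Traces and event extraction

`simulate_trace` writes an 80 kHz trace: constant baseline at I_bs,
triangular spikes of peak amplitude I_ps whose FDHM is the translocation
time (drawn normally around a configurable mean, 10% relative SD), onsets
uniform with a minimum separation of 2.5 base widths, plus additive
Gaussian noise; bit-identical for a fixed seed.  `extract_events` estimates
the baseline with a rolling median (50 ms window, reflective padding —
nearest-padding biases the edge baseline toward single noise samples),
detects excursions of the dominant polarity beyond `threshold_sd` (default
5) robust SDs (1.4826×MAD) of a 0.125 ms boxcar-smoothed residual, and
splits merged excursions at interior peaks of threshold-level prominence
separated by more than one FDHM.  FDHM itself is linearly interpolated at
the half-maximum crossings: on the raw residual when the trace is
effectively noise-free (clean triangular and rectangular pulse widths are
then exact to the sample period), otherwise on a 0.25 ms boxcar-smoothed
residual with the boxcar's apex broadening (a quarter window) subtracted —
exact for pulses with locally linear flanks around a sharp apex, the shape
of translocation spikes, and biased for flat-topped pulses, which do not
arise in this regime.

## Synthetic data and study conditions

No public archive of metal-gated nanopore event tables exists, so
validation data are generated by the forward model itself: the reference
conditions are 1 mM NaF, a 2.3 nm-radius pore, 50 events per condition
with 5% relative Gaussian noise on both channels, millisecond
translocation times (10% relative SD), and SNR-10 traces at 25 events/s
for one second.  Nanoparticle parameters (r = 0.92–1.27 nm, z = 28–112,
a 4× charge increase along the oxidation series) and the small-molecule
analytes (oxalic acid, hydroquinone, ascorbic acid, citric acid with their
tabulated radii and valences) span the regimes the model targets.  Because
generator and fitter share the forward model, recovery tests demonstrate
identifiability and numerical correctness of the inversion under the
stated noise — not that the model captures every feature of real traces
(baseline drift, 1/f noise, event-shape variability, wall interactions and
concentration-dependent event rates are all absent).  The equation-level
checks instead compare every relationship against an independent
re-implementation at fixed parameter points.

## Numerical choices and limitations

* SI units everywhere internally; CSV/CLI boundaries use nm, mV, nA, ms,
  mol/L.
* Electroneutrality of a solution is enforced to 1e-12 relative; activities
  satisfy a = c·f ≤ c.
* The model is calibrated to one device family: the current regression
  coefficients, L = 55 nm, L_Au = 5 nm and L_C = 1 nm are constants, with
  geometry overridable per pore.
* No Poisson–Boltzmann or finite-element electrostatics; the diffuse layer
  is treated as uniform, which degrades accuracy for pores much above
  4 nm radius.
* Only the single-T Debye law — no Davies/Pitzer corrections, no
  temperature-dependent A, B.
* No multi-analyte deconvolution, no time-resolved spike shapes, no
  Bayesian uncertainty.
* The smaller-ion majority rule is a modelling commitment; where size
  differences are marginal (e.g. KCl) electrostatic selection may matter
  in reality, and the override flag exists for exactly that case.
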