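# Methods

This note records the models, parameter choices and numerical details
behind each stage of the `augerdna` pipeline, and what the synthetic
data do and do not establish about real measurements.

## Cumulated-decay accounting

Activity decays exponentially, A(t) = A₀e^{−λt} with λ = ln2/T½, and
the cumulated number of decays over an incubation [0, T] is
N(T) = (A₀/λ)(1 − e^{−λT}), implemented with `expm1` for small λT.
Conversions use 1 μCi = 3.7×10⁴ Bq exactly.  Packaged nuclide
constants: ⁹⁹ᵐTc T½ = 6.02 h with 5 Auger/Coster–Kronig electrons per
decay; ¹²⁵I T½ = 59.4 d with 25 electrons per decay.  Activities are
interpreted as activities at the start of incubation; no
decay-during-preparation correction is applied.  The aliquot protocol
(fixed ~40 μCi sampled every 7 days) is modelled without correcting
for the volume/activity removed at each sampling — each aliquot is
assumed representative of the bulk mixture, whose decays/mL are
unaffected by proportional withdrawal.

## Plasmid strand-break analysis

Gel band intensities are corrected for the weaker staining of the
supercoiled form (default factor 1.4; the existence of such a factor
is standard for intercalator stains but its value varies by stain and
gel system, so it is configurable and echoed in every report) and
normalized to fractions.  The break model assumes independent Poisson
statistics:

* f_SC = e^{−(μ_SSB + μ_DSB)} — a plasmid stays supercoiled only with
  zero breaks;
* f_Lin = μ_DSB·e^{−μ_DSB} — exactly one DSB linearizes; two or more
  fragment the molecule out of the three-band system.

Inversion: μ_tot = −ln f_SC; μ_DSB solves μe^{−μ} = f_Lin on the
physical branch μ ∈ [0, 1] by Brent root-finding (machine-precision
tolerance).  When f_Lin exceeds the branch maximum e^{−1} (heavy
fragmentation) the estimator falls back to μ_DSB = μ_tot; when the SC
band is undetectable the estimate is censored at a configurable
detection floor (default f_SC = 10⁻³) and flagged.  A small-dose
approximation μ_DSB ≈ f_Lin is selectable.

μ_DSB is regressed on accumulated decays/mL by unweighted ordinary
least squares (inverse-variance weighting optional in principle; the
published analyses show no weighting and the synthetic noise is
homoscedastic on the log scale).  Control lanes define a baseline
μ_DSB subtracted before fitting; the intercept remains free.  Then
D₀ = 1/slope and Y(DSB) = ρ/D₀ with plasmid number density
ρ = c·N_A/M.  The duplex molar mass defaults to 3.6×10⁶ g/mol — the
value under which the published D₀ and yield columns are mutually
consistent across all six conjugates at both preparations (20 μg/mL
and 6.67 μg/mL) — and is configurable.  Standard errors propagate to
first order (se(D₀) = se(slope)/slope², se(Y) = ρ·se(slope)).  A
non-positive slope yields a censored result with a diagnostic rather
than an exception.

The DMSO decomposition takes the scavenger-protected yield as the
direct component and the difference as the indirect one, floored at
zero with a flag; a direct share below 10% is classified "exclusively
indirect".

## Binding isotherms

Two intensity models are fitted to titrations I([DNA]_bp):

* Saturable hyperbola ("Kaminoh-style"):
  I = (I₀ + I_sat·K·D)/(1 + K·D).  The exact functional form used in
  the original supplementary material is not published; this
  hyperbolic saturable-enhancement form is adopted because it is the
  minimal model consistent with the reported parameter set (K, I_sat)
  and reduces to a Langmuir binding curve.  This is an assumption and
  is documented as such.
* McGhee–von Hippel neighbor-exclusion isotherm with site size n (bp):
  the bound density r per bp at free ligand C_f satisfies
  r/C_f = K(1 − nr)[(1 − nr)/(1 − (n−1)r)]^{n−1}, r ∈ [0, 1/n).
  The isotherm and the mass balance C_f + r·[bp] = L_tot are solved
  jointly as a single Brent root-find in r (the combined function is
  sign-definite at the interval ends and has a unique physical root);
  residual tolerance 10⁻¹² on r, mass balance exact to ~10⁻¹⁴
  relative.  The fluorescence signal is I = I₀ + (I_sat − I₀)·C_b/L_tot
  (bound-fraction weighting).  Whether the original fits weighted by
  bound fraction or bound density, and whether n was constrained, is
  not published; bound-fraction weighting is the default and n can be
  fixed via `fix_n`.

Nonlinear fits run `scipy.optimize.least_squares` (TRF, bound n ≥ 1,
log-parameterized K) from three data-derived multi-starts with a fixed
RNG seed.  Flat titrations are flagged non-identifiable instead of
fitted.  On synthetic neighbor-exclusion curves with n > 1 the
hyperbolic model systematically under-estimates K; this ordering is
asserted on the packaged fixtures, not claimed as a theorem.

The inner-filter correction I_corr = I_obs·10^{(A_ex+A_em)/2} assumes
the standard 1 cm right-angle geometry with mid-cell excitation and
emission; when absorbances are absent the series passes through with
the corrected flag unset.

## Nanodosimetric Monte Carlo

Geometry: a 10-bp DNA segment as a liquid-water cylinder of radius
1.15 nm and length 3.4 nm, coaxially inside a nucleosome-sized
cylinder (5.0 nm radius, 5.7 nm height); unit-density water
everywhere.  The tally volume is the DNA cylinder alone.  The exact
dimensions used in the original simulation deck are not published;
these defaults are standard nucleosomal dimensions and are
configurable.  The source is a point emitter in the axial mid-plane at
radial distance d from the DNA axis; emission is isotropic (the
original "anisotropically emitting" source is ambiguous; a config hook
allows directional distributions later).

Transport is event-by-event, vectorized over histories:

* Free paths: exponential with the total inverse mean free path.
  Elastic and inelastic mean free paths are log-log interpolations of
  liquid-water anchor values (inelastic minimum ≈ 0.8 nm near 100 eV,
  rising to tens of nm at tens of keV), clamped outside 10 eV–30 keV.
* Elastic scattering: screened-Rutherford angular sampling with a
  Molière-type screening parameter (effective Z = 7.42), giving
  near-isotropic deflections at tens of eV and forward-peaked
  scattering at keV energies.
* Inelastic losses: W sampled from a 1/W² spectrum on [10 eV, E/2],
  deposited locally at the interaction point (no secondary tracking —
  at the sub-keV energies that dominate the tally, secondary ranges
  are comparable to the free path).  The combination mean-loss/IMFP
  approximates published liquid-water collision stopping powers
  within a factor ~2 over 100 eV–10 keV, which fixes the scale of the
  distance fall-off without claiming spectroscopic accuracy.
* No bremsstrahlung (negligible below ~30 keV); electrons below the
  10 eV cutoff deposit their residual energy locally; electrons
  crossing a 1 μm world sphere escape with their residual energy.
  Per-history bookkeeping enforces in-target + out-of-target +
  escaped = E₀ to float round-off.

One history is one emitted electron with energy drawn from the line
spectrum with probability proportional to yield; the per-decay result
is the per-electron mean times the electron multiplicity (an exact
identity under this sampling, asserted in tests).  The RNG is NumPy
PCG64; each distance uses an independent child stream of the seed, so
results are bitwise reproducible and independent of which other
distances are simulated.

The packaged spectra are representative discrete Auger/Coster–Kronig
line lists with the shell structure of standard compilations (K, L, M
Auger plus Coster–Kronig lines; ~33 eV N-shell lines dominating the
counts), scaled so the yields sum exactly to 5 (⁹⁹ᵐTc) and 25 (¹²⁵I).
Absolute deposited-energy values in eV are therefore model-dependent
and no agreement with any specific published absolute curve is
claimed; the supported outputs are the monotone distance dependence,
the per-electron advantage of the 5-electron cascade at 10–13 Å, the
per-decay advantage of the 25-electron cascade, and the normalization
identities.  Default problem sizes (2×10⁵ histories per distance)
give per-electron standard errors of well under 1 eV and run in
seconds per distance on one CPU.

## Correlation stage

Yields and simulated deposits are normalized to their per-nuclide
maxima and paired at the docking-derived distances (top-ranked-pose
column; MD-averaged distances can be supplied instead).  The headline
statistic is a Kendall-type rank concordance computed by explicit pair
counting — the comparison is ordinal by design, so a parametric
correlation would overstate what the data support.  Simulated curves
are linearly interpolated at record distances; extrapolation outside
the simulated span is refused.  Compounds whose normalized deposit
exceeds the normalized yield by more than 0.5 are flagged as
overestimated by the transport model (rigid-rod DNA, no indirect
chemistry).

## Synthetic data

Generators are the exact forward models of the analysis stages, so
noiseless round trips are exact to solver tolerance and seeded runs
are byte-reproducible:

* gel series: μ_DSB = dose/D₀_true, μ_SSB = ratio·μ_DSB (default 5
  SSB per DSB, a typical plasmid-assay ratio), Poisson fractions, SC
  band divided by the true staining factor, multiplicative lognormal
  noise with unit mean (default CV 5%, representative of band
  densitometry repeatability).  Default dose designs mirror the two
  protocols: {5, 10, 50, 100, 200, 500} μCi × 24 h in 30 μL, and
  40 μCi × {7, 14, 21, 28} d in 100 μL.
* titrations: forward isotherm + intensity model with additive
  Gaussian noise.
* decay truth tables: the analytic activity/cumulated-decay curve.

What passing these tests shows: the estimators invert their own
forward models without bias at realistic noise, and the fitted
quantities satisfy their defining identities (Y·D₀ = ρ exactly).  What
they do not show: robustness to gel artefacts the forward model lacks
(band smearing, multi-fragment species, staining nonlinearity beyond
a single SC factor, inter-gel calibration drift) or to titration
systematics (dilution errors, photobleaching).  Conclusions about
real gels inherit the Poisson single-hit assumptions.

## Numerical conventions and limitations

* Root-finding uses Brent's method at machine-precision tolerances;
  fits are multi-start least squares with fixed seeds; regressions are
  OLS via `scipy.stats.linregress`.
* Isoform quantities are fractions internally; percentages only at
  presentation.  All randomness flows from explicit seeds kept below
  2³¹.
* D₀ estimates from 6-point unweighted designs with 5% band noise
  scatter by ~4–5% RMS per replicate; replicate-averaged estimates are
  unbiased to well under 1%.
* The Monte Carlo excludes pre-chemical/chemical radiolysis stages,
  photon transport and condensed-history transport above the
  event-by-event model; indirect (radical-mediated) damage is only
  accessible experimentally, through the DMSO decomposition.
* Plasmid fragments carrying more than one DSB are outside the
  three-isoform model; the μ_DSB branch fallback makes the estimator
  degrade gracefully rather than fail at high damage.
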