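# Methods

This note documents the models implemented in `spinsight`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Label-ensemble model

The MTSL (R1) side chain is modeled as an idealized cysteine adduct:
linker atoms SG–SD–CE built by internal coordinates (bond lengths 1.81,
2.03, 1.81, 1.50, 1.34 Å; tetrahedral/thioether angles), followed by a
rigid 2,5-dihydro-pyrrole-N-oxyl ring with its four methyl carbons, stored
as a fixed template in the C3 frame.  The five dihedrals χ1…χ5 are sampled
uniformly on [0°, 360°) — an accessible-volume treatment rather than a
Boltzmann-weighted rotamer library.  A conformer is rejected when any of
its heavy atoms comes within 2.5 Å (`clash_tolerance`, exposed in the
API) of a protein heavy atom outside the labeled residue; the attempt
budget is 50× the requested ensemble size, and a site where no conformer
survives raises a buried-site error.  Sampling is one seeded stream, so
enlarging an ensemble with the same seed only appends conformers (this
prefix property is what makes distance predictions stabilize monotonically
with n).

The paramagnetic center of a conformer is the midpoint of the nitroxide
N–O bond.  Distances to nuclei use the unweighted ensemble-mean center
position, not ⟨r⁻⁶⟩ averaging: the PRE stage deliberately interprets only
relative attenuation, for which the mean-position distance is the
appropriate structural summary.  Inter-label distributions are histograms
of all pairwise center–center distances of two ensembles on a 1–10 nm
grid with 0.02 nm steps, smoothed with a 0.05 nm Gaussian kernel —
comparable to the granularity of rotamer-library predictions.  Predicted
mean distances carry an intrinsic uncertainty of roughly ±1–1.5 Å from
the clash tolerance and template idealization; they should be read at
that resolution.

## DEER forward model and inversion

Signal model: V(t) = [1 − λ + λ·S(t)]·B(t) with S = K p and
B(t) = exp(−k t^{d/3}), d = 3 for a homogeneous three-dimensional spin
bath (d is exposed because membrane-confined samples can show d < 3).
The kernel uses the standard nitroxide dipolar constant 52.04 MHz·nm³ and
is evaluated in closed form with Fresnel integrals; exchange coupling and
orientation selection are neglected.  Units are µs and nm throughout.

Background correction regresses log V on t^{d/3} over the trace tail
(default: the last 60 % of the trace, `fit_start = 0.4`); the intercept
gives the modulation depth λ, and fits with λ outside (10⁻³, 0.999) are
rejected as failed.  Because a tail-only fit is biased when S(t) has not
fully decayed inside the window, `analyze_trace` refines the background:
after an initial inversion, S is fixed at K p and (amplitude, k, λ) are
refit on the full trace, then the inversion is repeated (two refinement
rounds by default).  On noise-free simulations this recovers k and λ to
better than 0.1 %.

Power scaling for multispin suppression raises the form factor (not the
raw trace) to 1/(n_spins − 1), with values floored at 10⁻³ before
exponentiation; n_spins = 2 is the identity and is the default for doubly
labeled samples.

The inversion solves non-negative Tikhonov least squares with a
second-difference penalty via an active-set NNLS solver on the stacked
system [K; √α L₂].  The automatic α is the maximum-curvature corner of
the log–log L-curve (residual norm vs seminorm) over a 40-point
logarithmic ladder spanning 10⁻⁴–10⁴.  Distributions are normalized to
unit integral; the advisory ceiling on reliable distances is
r_max = 5·(t_max/2)^{1/3} nm, and modes beyond it are flagged, never
truncated.  No uncertainty bands on P(r) are computed.

## PRE ratio statistics

Ratios I_para/I_dia carry first-order propagated spectral noise,
σ = ratio·√((σ_p/I_p)² + (σ_d/I_d)²).  Because absolute scales differ
between samples, ratios are normalized to the maximum ratio in each
experiment (equivalent to referencing against a residue unaffected by the
label).  Attenuation of a residue against a reference set uses the
inverse-variance-weighted reference mean and
z = (r̄_ref − r)/√(σ_ref² + σ²), one-sided by default since attenuation is
the directional hypothesis; a two-sided variant is available.  No
multiple-testing correction is applied by default (per-residue p values
are reported raw; a Bonferroni option exists).  Classification against
the structure uses a 25 Å detection radius — the conventional sensitivity
range of nitroxide PREs on methyl signals — and an operational
normalized-ratio threshold of 0.7 separating "attenuated" from
"unaffected".  Overlapped signals may be merged under a combined id
(e.g. `I252/I420`); merged rows classify against the minimum of their
predicted distances.  The two operational definitions necessarily
disagree in a narrow distance band just above the radius (≈25–28 Å under
the synthetic forward model); discordance inside that band is a threshold
artifact, not conformational evidence.

## Relaxation dispersion

Decays over spin-lock durations are fit to I(T) = I₀·e^{−R1ρ·T}; R2,eff
follows from the rotating-frame geometry with tilt θ = arctan(ν₁/Ω)
(θ = 90° on resonance, where R2,eff = R1ρ exactly).  The exchange model
is the minimal on-resonance fast-exchange Lorentzian
R2,eff(ν₁) = R₂⁰ + Φ·k_ex/(k_ex² + (2πν₁)²), fit by weighted least
squares (1/σ² weights) with multiple k_ex starting points; since Φ = 0
recovers the flat model, the nesting inequality RSS_ex ≤ RSS_flat is
enforced by falling back to the flat solution whenever the optimizer does
worse.  The test statistic is F = ((RSS_flat − RSS_ex)/2)/(RSS_ex/(n−3))
against F(2, n−3) at α = 0.05.  Because the weights are themselves
estimated from five-point decay fits, the test runs slightly
conservative; under the simulated null the flat model is retained in
≈95–100 % of runs.  Off-resonance exchange models and CPMG analysis are
out of scope.

## Screens

Disulfide feasibility uses CB–CB ≤ 5.5 Å, a standard engineering proxy
for whether two cysteine SG atoms can bridge without backbone movement;
no rotamer-level SG geometry is scored.  A pair that crosslinks in vivo
while infeasible by this criterion reports a conformational change.  The
table of observed in-vivo crosslink outcomes shipped in
`spinsight.screens` is experimental input for interpretation reports,
clearly separated from anything the package computes.  Bound-fraction
arithmetic is Σ_{k≥1}I_k/Σ_kI_k with the decoy-protein fraction
subtracted (reported raw and zero-clipped).

## Synthetic generators

The generators emulate the statistical structure of each input, not
instrument physics: dipolar traces (default 4 µs, 500 points ≙ 8 ns
steps, λ = 0.3, k = 0.2/µs, Gaussian noise) from multi-Gaussian P(r),
including a three-component scenario with minor modes at 2.5 and 3.5 nm
beside a dominant 5.5 nm distance; paired intensity tables from
I_para/I_dia = exp(−τ·r⁻⁶) calibrated so r = 25 Å gives ratio 0.5, with
distinct para/dia global scales emulating unequal reconstitution amounts
(the simplest Solomon–Bloembergen-consistent forward model — it exists
only to generate data, mirroring the analysis-side refusal to invert
ratios into distances); spin-lock series over a 1.2–10 kHz field ladder
with five durations of 2.5–80 ms; and ideal poly-Ala helix structures
(exposed site, two-site scaffold with exact CB separation, buried cage).
Default PRE distances avoid the threshold-ambiguous 25–28 Å band so the
zero-noise closed loop is exact.  Not emulated: phase noise, nuclear
modulation, t₁-noise ridges, spectral overlap, baseline drift — so
passing closed-loop tests demonstrates correctness of the estimators
under their own assumptions, not robustness to every instrument artifact.
Fully bleached PRE signals are floored at a tiny positive intensity,
since the analysis requires positive intensities; ratios below 10⁻⁶ are
not meaningful.

All generators are pure functions of their parameters and a single
integer seed (bitwise-reproducible outputs).

## Problem sizes

Validation runs use ensembles of 100–200 conformers, ten-seed DEER
round trips at noise 0.02 (signal-to-noise 50), 10⁴ simulated nulls for
the z-test calibration, and 100 simulations per dispersion selection-rate
estimate; these sizes give stable estimates (Monte-Carlo standard errors
well inside the asserted tolerances) at a few minutes of single-CPU time.

## Known limitations

- The accessible-volume label model ignores rotamer energetics; its
  distance predictions are unweighted and can deviate from
  library-weighted predictions by up to ~1.5 Å at tightly packed sites.
- The L-curve corner can over-smooth very narrow distributions at high
  signal-to-noise; width estimates from inverted P(r) are reliable only
  to ~20 %.
- Background dimensionality is assumed known; misspecifying d biases λ.
- PDB parsing keeps only model 1 and resolves altlocs to highest
  occupancy; mmCIF is not supported.
- The dispersion exchange model is on-resonance only, and the analysis
  treats residues independently (no global k_ex fit).
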