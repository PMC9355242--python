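# spinsight

Integrative spin-label analysis for detecting minor protein conformers.

Membrane transporters such as the two-partner-secretion protein FhaC
populate short-lived alternative conformations that crystal structures do
not show.  Three spin-label observables can reveal them: pulsed
electron–electron double resonance (PELDOR/DEER) distance distributions
between two nitroxide labels, paramagnetic relaxation enhancement (PRE)
attenuation of NMR signals near a single label, and R1ρ relaxation
dispersion probing µs-time-scale exchange.  Each observable only becomes
evidence when compared against what the resting (crystal) structure
predicts, which requires modeling the conformational cloud of the flexible
MTSL label itself.  `spinsight` implements that whole comparison pipeline
for structural biologists and EPR/NMR spectroscopists:

- **structure handling** — PDB reading with author numbering, in-silico
  residue→Cys substitution, atom addressing (`spinsight.structure`);
- **label ensembles** — accessible-volume modeling of the MTSL (R1) side
  chain: uniform sampling of the five linker dihedrals with steric clash
  rejection, mean paramagnetic-center positions, label→nucleus distance
  tables and inter-label distance distributions (`spinsight.label`);
- **DEER processing** — forward simulation V(t) = [1 − λ + λ·S(t)]·B(t),
  background fitting, multispin power scaling f ↦ f^{1/(n−1)}, and
  non-negative Tikhonov inversion
  `p = argmin ‖Kp − f‖² + α‖L₂p‖², p ≥ 0` with L-curve selection of α,
  where K is the powder-averaged dipolar kernel
  K(t,r) = ∫₀¹ cos[(3x² − 1)·2π·52.04·t/r³] dx (`spinsight.deer`);
- **PRE statistics** — para/dia intensity ratios with noise propagation,
  normalization to the maximum ratio, one-sided z tests for attenuation,
  and classification against structure-predicted distances
  (`spinsight.pre`);
- **relaxation dispersion** — monoexponential R1ρ fits, R2,eff extraction
  via R2,eff = (R1ρ − R1·cos²θ)/sin²θ, and an F test of a fast-exchange
  Lorentzian against a flat profile (`spinsight.dispersion`);
- **screens** — disulfide-pair CB–CB feasibility and native-MS
  bound-fraction arithmetic with decoy correction (`spinsight.screens`);
- **synthetic data** — seeded generators for every input format, so the
  whole pipeline can be exercised and validated without downloads
  (`spinsight.synth`).

## Worked example

Simulate a DEER trace from a Gaussian P(r) (mean 4.5 nm, σ 0.3 nm,
modulation depth 0.3, background 0.2/µs, 2 % noise) and invert it:

```console
$ spinsight deer simulate --mean 4.5 --sigma 0.3 --lambda 0.3 --k 0.2 \
      --noise 0.02 --seed 1 -o trace.dat
trace (250 points, t_max 4.0 µs) -> trace.dat
$ spinsight deer invert trace.dat -o pr.csv --report report.json
modes: 4.48 nm (r_max advisory 6.3 nm)
```

The report shows the recovered modulation depth 0.310 (true 0.3),
background rate 0.2008/µs (true 0.2) and a single distance mode at
4.48 nm (true 4.5 nm), within one histogram bin of the truth.  The
"advisory" 6.3 nm is the longest distance a 4 µs dipolar evolution time
can support; modes beyond it would be flagged as unreliable rather than
removed.

A synthetic no-exchange dispersion series is correctly called flat:

```console
$ spinsight synth disp --seed 3 --no-exchange -o disp
$ spinsight disp fit disp/series.csv --r1 1.5
I1: flat (F = 2.56, p = 0.193)
```

The same operations are available from Python (`import spinsight`), and
`spinsight replicate --config run.yaml` chains label predictions, DEER
inversions and PRE/dispersion statistics into a single JSON + Markdown
report whose discordance table (observed attenuation or distances
incompatible with the resting structure) is the minor-conformer evidence.

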