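# Methods

This note documents the models, conventions, numerical choices and known
limitations of `aeropk`, in the order of the pipeline: impactor reduction →
powder descriptors → regional lung deposition → pulmonary PBPK →
statistical screening, plus the synthetic-data generators used for testing.

## Cascade-impactor reduction

A Next Generation Impactor (NGI) run is a table of drug masses recovered on
eleven surfaces: device/capsule residue, induction port, pre-separator,
stages 1–7 and the micro-orifice collector (MOC).  Conventions:

* **Emitted dose (ED)** — all recovered mass except the device residue, so
  device residue + ED equals the total recovery exactly.
* **Sized mass** — stages 1–7 + MOC only.  Induction-port and pre-separator
  mass counts toward ED but not toward the size distribution, because those
  surfaces have no calibrated cut-off at arbitrary flows.  This is the most
  common reduction convention and is recorded in the output metadata.
* **Cut-offs** — the bundled archival NGI calibration gives stage cut-off
  diameters d50 at the 60 L/min reference flow together with per-stage flow
  exponents; at flow Q the cut-off is d50(60)·(60/Q)^x.  The calibration is
  considered valid over 15–100 L/min; outside that window the scaling law is
  extrapolated with a warning.
* **MMAD/GSD** — ordinary least squares of probit(cumulative undersize)
  against ln(diameter).  Points with fraction exactly 0 or 1 carry no probit
  information and are excluded; at least three usable points are required,
  and a non-positive slope is rejected as degenerate.  MMAD is the diameter
  at probit zero (the mass-*median* convention) and GSD = exp(1/slope).
* **FPM/FPF** — fine particle mass is the sized mass multiplied by the
  fitted log-normal probability of the 1–5 µm band (evaluated on the
  regression line, not by piecewise-linear interpolation of raw fractions,
  so FPM is consistent with the reported MMAD/GSD).  FPF = 100·FPM/ED.
* **Replicates** — descriptors are computed per run and then averaged;
  summaries report mean ± SD with n.

Numerical limit worth knowing: when the aerosol is far finer or far coarser
than the cut-off ladder (e.g. MMAD 0.5 µm with GSD 1.1 at 60 L/min), the
usable cumulative fractions sit at |z| > 6.5 where double precision next to
1.0 keeps only ~7 significant digits of the tail; parameter recovery on
noise-free input is then limited to ~1e-7 relative instead of the ~1e-12
achieved in the well-resolved regime.

## Powder descriptors

All descriptor operations are deterministic pure functions; SI units are
used internally and the customary units (µm, N/mm², m²/g) at the interface.

* **Kelvin radius** r_k = 2σV/(RT·ln(p₀/p)) for nitrogen capillary
  condensation (σ = 8.85 mN/m, V = 34.7 cm³/mol, T = 77.35 K).  The
  magnitude convention is used so radii are positive for p < p₀.  The full
  BJH reduction (adsorbed-layer thickness curve, desorption stepping) is not
  reproduced; the pore radius is r_k plus a caller-supplied layer thickness.
* **Heywood diameter** d_e = √(3.08·W·L/π) from the minimum/maximum Ferret
  diameters W, L measured on micrographs.
* **Shape coefficient** α = SSA·ρ_s·d_e + N with N = L/W.  The additive
  form is implemented as printed in the source formula (Wong–Pipel); for an
  ideal sphere it gives α = 7.  A multiplicative reading (SSA·ρ_s·d_e·N) is
  available behind an explicit `variant` switch because the formula is
  dimensionally fragile and the printed values of α cannot adjudicate
  between the readings (ρ_s, W and L are not published per material).
* **Tensile strength** TS = 2P/(πDt) for diametral compression of a compact.
* **Rheology summaries** — σ is the arithmetic mean of a response (incipient
  shear stress SSi, compressibility CPS, or pressure drop PD) over the
  applied-normal-stress window, Δ the absolute difference of the endpoint
  values.  The window endpoints must have been measured.
* **Pressure-titration deltas** — ΔDv0.1 = Dv0.1(baseline) − Dv0.1(target
  pressure) and ΔFines = Fines(target) − Fines(baseline), both signed so
  that de-agglomeration (smaller Dv0.1, more fines) is positive.

## Regional lung deposition

A deterministic, single-typical-path compartment-in-series model.  The
airway tree is the symmetric Weibel-type generation table bundled with the
package (24 generations; generations 0–16 tagged tracheobronchial, 17–23
alveolated), isotropically rescaled from its 4800 mL reference volume to the
subject FRC (default 3000 mL).

Per aerodynamic-diameter bin (log-normal distribution discretised into
128 bins spanning MMAD·GSD^±4, open-ended outer bins):

1. **Mouth-throat (ET) filter** on inhalation with efficiency
   η = 1 − 1/(1 + (d²Q/K)^p), d in µm, Q in L/min — the classical
   impaction-parameter form.  K = 110 µm²·L/min, p = 2.
2. **Airway transport**: generation-by-generation survival
   (1−p_I)(1−p_S)(1−p_D) with the classical kernels — Yeh–Schum bend
   impaction in the Stokes number, inclined-tube gravitational
   sedimentation over the residence time, Gormley–Kennedy laminar
   diffusion.  The flow divides by airway count; residence time is airway
   volume over airway flow, stretched in the alveolated generations by the
   tidal expansion factor ((FRC+V_T)/FRC)^(1/3).
3. **Breath-hold**: mass still airborne resides in the respiratory zone and
   deposits at rate v_s/r + 2D/r² with r = 0.03 cm, an effective
   alveolar-duct-scale settling length.
4. **Exhalation**: the time-reversed pass at the exhale flow, then the ET
   filter once more.

Mass is conserved exactly (ET+TB+AL+exhaled = 1) and the model is
bit-deterministic.  Results change by <1% above 128 bins.

**Choice of the ET constants.**  The two constants were fixed once by a
design exploration documented here.  Two requirements compete: (i) a
polydisperse DPI aerosol inhaled fast through a mouthpiece must lose most
of its dose in the mouth-throat, as observed in vivo for such products, so
that the lower-airway fraction of the reference aerosol (MMAD 1.83 µm,
GSD 3.60, 4520 mL over 2.8 s, 10.3 s hold, 9.7 s exhale) lands in the
10–20% band stated in the reference product description; (ii) the ET curve
must stay steep enough that ~1 µm particles are largely spared, otherwise
the lung-deposition curve loses its physically expected interior maximum as
a function of MMAD.  K = 110, p = 2 satisfies both: the reference scenario
gives ET 65.7%, TB 3.3%, AL 14.2% (lung 17.5%), exhaled 16.8%.  Note the
reference stochastic-lung software reports a higher ET (79.2%) and lower
exhaled fraction for the same input; exact agreement with that split is not
expected from a single-typical-path geometry and is not a goal — the band,
conservation and unimodality properties are.

Excluded physics: hygroscopic growth, electrostatic charge, cloud motion,
nasal pathway (mouthpiece inhalation is mouth-only), and any
generation-resolved output contract (regional sums only).

## Pulmonary PBPK of salbutamol sulphate

Linear ODE system (amounts in µg, time in h), assembled from the bundled
`salbutamol_diskus.cfg`:

**Lung side.**  Each region (ET, TB, AL) holds undissolved and dissolved
drug in its lining fluid.  Dissolution is a first-order Noyes–Whitney term;
at a lung solubility of 384.7 mg/mL it is effectively instantaneous, and
the rate constant is capped at 1000 h⁻¹ to bound stiffness (half-time
2.5 s, still far faster than every other process).  Absorption flux is
Papp·SA_eff·fu·C_dissolved with the Calu-3 permeability (8.53×10⁻⁷ cm/s)
for the ET and bronchiolar epithelium and the A549 permeability
(1.59×10⁻⁵ cm/s) for the alveolar epithelium; fu is the fraction not bound
to epithelial cells (0.15 alveolar, 0.20 ET).  The mucociliary escalator
moves lining drug TB → ET → gut.  Of the ET deposit, 65% is swallowed and
30% expectorated immediately; with first-pass extraction fixed at 100%
(charcoal-block design) the swallowed/gut route is a presystemic sink, so
only the 5% ET remainder is systemically available through the ET
epithelium.

**Systemic side.**  Perfusion-limited tissues (adipose, bone, brain, gut,
heart, kidney, liver, lung, muscle, skin, spleen, rest) with plasma
volumes/flows of a 77 kg adult male (plasma cardiac output 185 L/h, total
plasma 3.78 L split venous 2.27 / arterial 1.51).  Gut and spleen drain
portally into the liver.  Tissue:plasma partition coefficients come from
the tissue-composition equations for a moderate-to-strong base
(Rodgers–Rowland; the Lukacova method is the same family): extracellular
water + pH-partitioned intracellular water + neutral-lipid/phospholipid
partitioning of the neutral species + acidic-phospholipid association of
the cation, with the association constant back-calculated from blood-cell
partitioning (from B:P = 0.96, hematocrit 0.45, fup = 0.92) and clamped at
zero when negative or when the drug is essentially un-ionized.  Absorbed
lung drug enters the systemic lung tissue (pulmonary-vein side); absorbed
ET drug enters venous blood.

**Elimination.**  CL_renal = 4.2 and CL_hepatic = 5.44 mL/min/kg are
applied to the *arterial* plasma pool, with the renal flux accumulating as
cumulative urine.  The component values are used rather than the rounded
printed total (9.62 mL/min/kg vs the exact sum 9.64).  Arterial-side
elimination matters: the kidney and liver are perfused by arterial blood,
whereas the reported Cmax is sampled from venous plasma.  During the
absorption phase arterial concentration exceeds venous, which is what
allows the 30-min urinary mass to reach 3–4 times Cmax×3.78 L; with
elimination drawn from the venous pool that ratio is mathematically capped
near 2.6 (CLr·0.5 h/V_p) and the published calibration range cannot be
reached by any parameterisation.

**Calibration constants.**  The regional lining volumes, *effective*
absorptive surface areas and mucociliary transit times are not printed in
any source and were tuned once against the published single-dose
observations for 600 µg from the reference device (Cmax 6.48–8.27×10⁻⁴
µg/mL, tmax 0.17–0.50 h, AUC₀₋₁₂ 1.790–2.209×10⁻³ µg·h/mL, 30-min
urine/(Cmax·3.78 L) = 3.09–4.05), then frozen in the shipped config:

| knob | value | note |
|---|---|---|
| V_ET / SA_ET | 0.4 mL / 600 cm² | effective; throat retention site |
| V_TB / SA_TB | 10 mL / 2000 cm² | conducting-airway lining |
| V_AL / SA_AL | 15 mL / 14000 cm² | effective area ≪ anatomical 100 m²: absorbs the unmodelled epithelial diffusion resistance |
| mucociliary TB→ET / ET→gut | 6 h / 2 h | slow-phase transit |
| fu_TB | 1.0 | no binding data for the bronchiolar epithelium |

With the published regional split (lung 12.6%, extra-thoracic 79.2% of
600 µg; TB/AL split taken from this package's own deposition run because
the source prints only the lung total), the simulation gives Cmax
7.63×10⁻⁴ µg/mL at 0.24 h, AUC₀₋₁₂ 1.87×10⁻³ µg·h/mL and a 30-min urine
ratio of 3.57 — inside all four observation bands.  The AUC table unit is
implemented as 10⁻³ µg·h/mL (the printed "10³" is inconsistent with Cmax in
10⁻⁴ µg/mL and presumed a sign typo).

**Numerics.**  Stiff BDF integration with analytic Jacobian (the system is
linear), rtol 1e-8 / atol 1e-12; fixed reporting grid of 0.005 h over the
first hour and 0.05 h thereafter (421 points over 12 h).  Halving the
tolerances moves Cmax by <1e-6 relative.  Mass is audited: lining + tissue
+ plasma + urine + hepatic + presystemic + expectorated equals the
deposited dose to ~1e-15 relative at every reported time.  tmax is refined
by a local quadratic through the grid maximum; Cmax is reported as the grid
maximum itself (a parabola overshoots kinked peaks, and on this grid the
smooth-peak bias is ~1e-5).

Not modelled: transporters and enzymes, population variability, any
mechanistic oral absorption (pointless under 100% first-pass extraction),
dissolution-limited kinetics (irrelevant at this solubility).

## Statistical screening

Pearson product-moment correlations between a materials × descriptors table
and a materials × outcomes table, cell by cell; constant columns or fewer
than three paired observations yield NaN (never 0).  No multiple-testing
correction is applied — the matrix is a screening heatmap of raw r values,
not a set of inferences, and should be read accordingly.  Columns are
z-standardised for display only, never before computing r.  The two-way
ANOVA without replication decomposes a complete matrix into row, column and
residual sums of squares (verified to recompose the total to 1e-10) and
tests each margin against the residual mean square; an exactly additive
matrix (zero residual SS) is flagged degenerate rather than given an
arbitrary F.

## Synthetic data

`SynthSpec` defaults describe one capsule-device formulation tested at
60 L/min in triplicate: MMAD 2.6 µm, GSD 1.9, ED 3.10 mg with 0.80 mg
device residue, 40% of the ED on sized surfaces, and 2% multiplicative
log-normal noise per collection surface (mean-one convention, so
expectations are unbiased) — the replicate scatter of a careful impactor
experiment.  The sized mass is apportioned to stages by log-normal CDF
differences at the flow-correct cut-offs, so the noise-free generator/
reduction round trip is exact.  Descriptor/outcome tables are jointly
Gaussian with a designed correlation ρ between the first property and first
outcome column; the 4-row mode mimics a four-carrier design.

One global seed drives named RNG substreams (one per replicate/material),
so enlarging a design never perturbs earlier draws.  What the generators do
*not* emulate: inter-stage mass correlations from shared wall losses,
non-log-normal (multimodal carrier+drug) aerodynamic distributions, and
instrument raw files.  Passing tests therefore demonstrate correctness of
the reduction and statistics under the stated statistical model, not
robustness to real-instrument artefacts.

## Problem sizes

Default problem sizes used throughout the package and its checks: 128
aerosol bins (results stable to <1% beyond that), a 421-point reporting
grid over 12 h, 50-replicate Monte-Carlo checks of the impactor fit, and
4-material descriptor tables matching the study design.
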