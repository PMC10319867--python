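# Methods

This note records the models implemented by `epitomics`, the assumptions
behind the synthetic-data generators, and the numerical and design choices
made where the underlying assay description leaves them open.

## 1. Assay model and normalisation

The single-binder capture inhibition assay is competitive: an immobilised mAb
binds a biotinylated tracer, and epitope-bearing analyte in the sample
displaces it. The raw readout is a background-corrected relative light unit
(RLU) per spot. Two chip layouts are modelled:

| layout | positions / run | tracer-only | sample dilutions |
|--------|-----------------|-------------|------------------|
| QP69   | 18              | 2 (averaged) | 100×, 1000×     |
| QP300  | 3               | 1            | 300×            |

The normalised feature is `100 · RLU / RLUmax`, computed strictly per run so
that any multiplicative run-level effect (operator, reagent lot, instrument
drift) cancels exactly; this scale invariance is asserted by property tests.
Replicate profiles are averaged per (sample, mAb, dilution) and the mean is
then capped at 120 %. **Cap order**: the cap applies to the final analysis
variable, i.e. after averaging; each capped cell is logged. A zero or missing
RLUmax marks the (run, mAb) cell missing rather than infinite, and
missingness propagates to the pairwise-complete correlation handling
downstream. Background correction is assumed done upstream by the imaging
instrument; no background model is implemented.

## 2. Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed); identical inputs give
bitwise-identical outputs.

**Cohort.** Per-mAb epitope abundance is log-normal,
`log a ~ N(baseline_log_mean, baseline_log_sd²)` with defaults (0, 0.5²) in
units of the half-inhibition constant k50 (so a typical sample sits near 50 %
signal, mid-dynamic-range). Case samples of a planted effect mAb are
multiplied by `exp(effect)`; confounder effects multiply samples whose
metadata level is "exposed" (COPD grades C/D, male sex, BMI class C, smoking
classes C/D). Metadata categories copy the clinical cohort coding (COPD GOLD
A–D, BMI classes A–C by 20/30 kg/m² cuts, smoking pack-year classes,
histology codes 0–10).

**Abundance → signal link.** The assay description does not state the
competition transfer function. We use the one-site competitive form

```
RLU = RLUmax / (1 + a / k50)
```

the simplest monotone saturating function consistent with the inhibition
logic: zero analyte gives RLUmax, signal halves at a = k50. Conclusions that
depend only on monotonicity (ranking, ROC, the >30 % screen at matched
designs) are insensitive to this choice.

**Noise.** Four multiplicative log-normal components with unit mean:
intra-replicate (per spot), run, operator, and lot (shared across a run's
records, hence cancelled by normalisation). Defaults cv_intra = 0.08 and
0.05 for the shared components are calibration choices — the assay's
published qualification gate is CV < 20 % with no component magnitudes — set
so a qualified chip comfortably passes the gate. A log-normal with fractional
CV c uses σ² = ln(1 + c²), μ = −σ²/2.

**Mimotopes.** Peptides are uniform random 12-mers over the 20-residue
alphabet (collisions negligible at 20¹²); a planted pair shares one peptide
at the target clone fraction s in both members, so its redundancy is exactly
s²·100 up to count rounding. `planted_redundancy_library` builds a 173-mAb
library whose threshold summary is fully determined: one pair at exactly 92
(via asymmetric fractions 23/25 × 25/25), five symmetric pairs between ~46
and ~71, and a three-mAb chain just above 40, totalling 15 mAbs with a >40 %
partner. It stands in for a profiled library whose peptide lists are not
distributed with the package.

**Not emulated:** mass spectra, ELISA optical densities, absolute plasma
protein concentrations, chip-surface chemistry, bulk refractive-index jumps,
or real clinical correlation structure. A green calibration test therefore
establishes that the *statistical machinery* behaves correctly on its stated
model — not that real cohort figures are reproduced.

## 3. QC: CV decomposition and the gate

CV = 100·sd/mean with the sample (n−1) standard deviation (the denominator is
unspecified upstream; n−1 is the conservative default). Components:
intra-run (mean of within-run CVs), inter-run/operator/lot (CV of per-group
means). Components with fewer than two observations are *missing*, never
zero; a zero mean makes CV undefined. The gate passes a mAb iff every
available component is strictly below the threshold (default 20 %) — the
composite rule is this package's qualification convention; per-component
summaries are also available in the report. No REML variance components: the
upstream procedure uses plain CVs. CVs are meant to be computed on
RLU/RLUmax % for competition conditions and on raw RLUmax for tracer-only
conditions; `cv_decompose` assumes its input is a same-material replication
experiment.

## 4. 4PL qualification

`y = d + (a−d)/(1 + (x/c)^b)` fitted by Levenberg–Marquardt on the
log10-dilution axis with the fixed initialisation a = max y, d = min y,
c = geometric mean of x, b = 1 — deterministic, so qualification decisions
are reproducible. The fit is canonicalised to a ≥ d (the model is invariant
under swapping asymptotes and negating b). R² = 1 − SSres/SStot on the
observed scale, unweighted; non-convergence yields R² = −∞ and fails the
strict R² > 0.9 gate. "Linear inhibitory curves" is interpreted as
goodness-of-4PL-fit, since the upstream protocol couples the phrase directly
to the 4PL Hill-slope model; a straight-line log-axis R² is reported
alongside for transparency. R² is computed per curve (not pooled across
plates). Qualifiers with the total-plasma tracer join QP69, with the
depleted tracer QP300; dual qualifiers join both and are flagged.

## 5. Redundancy statistic

`Red(X,Y) = 100 Σ_p x_p y_p` over peptides common to X and Y, with exact
string identity — no motif collapsing or mismatch tolerance, because no
motif-matching rule is specified upstream. The diagonal (a Simpson-type
concentration of the mAb's own clone distribution) is reported but excluded
from threshold summaries. The ">40 %" summary counts a mAb once if *any*
partner exceeds the threshold; the per-pair count is also reported, and all
pairs attaining the maximum are listed (the maximum may be tied).

## 6. Pooled screen, Venn, correlation, clustering

A mAb is selected for a contrast when `|case − control| > 0.30 · control` on
averaged pool profiles — the absolute difference, since both up- and
down-regulated epitopes are informative; signed up/down subsets are kept.
Control-zero cells are skipped and logged. Venn regions partition the union
of selections; "shared" means present in ≥2 contrasts. Pearson correlations
use pairwise-complete rows by default (listwise available); the histogram
uses 0.1-wide right-closed bins on [−1, 1] so [0.8, 1.0] is exactly the top
two bins. Clustering is Ward linkage on Euclidean distances with rows sorted
by id first, making the flat clustering independent of input order.

## 7. Panel statistics

- Mann–Whitney U with midranks, oriented to the case group; exact null when
  n₁n₂ ≤ 400 and untied, tie-corrected normal approximation otherwise. The
  identity AUC = U/(n₁n₂) is asserted property-style.
- FDR is Benjamini–Hochberg (the default in the SPSS/R ecosystem the
  protocol names); selection is q < 0.01 ranked by |AUC − 0.5|.
- The logistic panel is unpenalised maximum likelihood (statsmodels Newton);
  SEs from the inverse observed information. Quasi-separation makes the
  Hessian singular, in which case the fit falls back to BFGS and is flagged
  — coefficients are still reported, as the upstream report format expects.
- Protocol evaluation: stratified split (70/30 default; 66/34 supported —
  both splits appear upstream for different analyses, so the protocol object
  makes the choice explicit per run), repeated stratified 10-fold CV on the
  training set only, one ROC on the untouched test set. Mean imputation and
  standardisation are fit inside training folds only. kNN/SVM/random-forest
  are scikit-learn models behind the same interface; only the logistic
  report is in-house.
- Subgroup ROC scores the cohort once with the fitted model, then
  re-evaluates within each metadata level; levels lacking a class are
  reported skipped.

## 8. SPR kinetics

For piecewise-constant analyte concentration the two-state mass-action
system is linear, `dx/dt = A x + b` with x = (AL, AL*), so sensorgrams are
computed *exactly* via the 2×2 eigendecomposition (matrix-exponential
fallback for defective A) rather than an adaptive integrator — faster inside
the fit loop and free of truncation error. `K = (ka1/kd1)(1 + ka2/kd2)`
reduces to the 1:1 Langmuir constant at ka2 = 0, and the simulated
equilibrium response approaches Rmax·KC/(1+KC), both checked numerically.
The global fit optimises log10-parameters across the concentration series
from a fixed 6-point multi-start grid (deterministic); per-concentration
fits averaged — the upstream evaluation mode — are obtained by calling the
fitter per trace. Competition IC50 is the inflection of a 4PL sigmoid on the
log-competitor axis, read from signals at the first dissociation-phase
point; zero-competitor levels cannot enter the log fit, so ≥4 positive
levels are required, and fits with no downward transition in range are
flagged `no_inhibition`/`extrapolated`. Drift terms possibly present in
vendor software objectives are not modelled.

## 9. Known limitations

- Real-cohort figures (clinical AUCs, the observed high-correlation
  fraction, published CV pass rates) are not reproducible here: the clinical
  measurement data are not released. The calibration suite covers the same
  machinery on synthetic ground truth instead.
- The null calibration of the held-out AUC is evaluated against a fixed
  [0.4, 0.6] band; at the protocol's 60/60 test-set size that band spans
  ±1.89 null standard deviations (~94 % coverage), so occasional excursions
  are expected behaviour of a correctly calibrated pipeline, not drift.
- The abundance→RLU transfer function and noise magnitudes are modelling
  choices (Sections 1–2); quantities that depend on them nonlinearly (e.g.
  absolute pool differences) should be read as illustrative.
- Whether QP69's two RLUmax positions are shared per rack or per run is
  ambiguous upstream; the per-run reading is implemented and parameterised
  by the layout table.
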