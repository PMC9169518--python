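# Methods

## Problem and scope

`citrusauth` models the detection of undeclared juice-to-juice adulteration
— mandarin juice in sweet orange juice, and Shatianyou-group (SG) or
Wendan-group (WG) pomelo juice in grapefruit juice — from targeted profiles
of oxygenated heterocyclic aglycones (OHAs): methoxyflavones (MFs),
coumarins and furanocoumarins (FCs) measured by HPLC with diode-array (UV)
and fluorescence (FL) detection. The package covers the computational
pipeline only: peak identification from peak tables and spectra, calibrated
quantitation, profile assembly, chemometric variable reduction, virtual
blend purity models and decision rules. Peak picking from raw detector
time-series, extraction chemistry and instrument control are out of scope.

## Compound catalog

The catalog carries 39 calibrated OHAs and 13 screened candidates.
Calibration parameters (linear range, through-origin slope, R², LOD, LOQ,
and a psoralen internal-standard correction factor) and the complete
candidate table (retention time, retention index, UV/emission maxima,
fluorescence monitor pair and ratio, deduced substitution class) are
transcribed reference values. Retention times and spectral metadata of the
39 calibrated compounds are **synthetic** library values: each compound's UV
and emission maxima are its substitution-class landmark bands shifted by
4 nm per within-class rank, its retention time is an even spread over the
elution window, and its fluorescence ratio is a deterministic ramp. These
placeholders make the library self-consistent for round-trip testing; they
are not measurements and are never reported as such.

Two verbatim-storage decisions: the "CF" internal-standard correction
factors are stored but not used in arithmetic (their published definition
does not determine how they enter the calculation; drift correction instead
uses the nominal/observed psoralen response ratio). One published FL R²
(isomeranzin, 0.9986) sits below the 0.999 linearity criterion, so stored
curves validate against a 0.998 floor while *fitted* curves keep the strict
0.999 threshold.

## Peak identification

Three independent gates, all configurable via `MatchGates`:

* **Spectrum conformity** — sample and reference traces are linearly
  resampled to a common 1-nm grid, max-normalized, and compared by Pearson
  correlation clipped to [0, 1]. Defaults: ≥ 0.99 (UV), ≥ 0.98 (emission).
  The source procedure quotes no numeric threshold; these strict values
  express "whole-spectrum conformity" while tolerating grid effects.
* **Fluorescence peak-height ratio** — highest over second-highest of the
  400/450/500 nm responses, ties broken toward the shorter wavelength;
  matched within 25% relative tolerance and requiring the same wavelength
  pair.
* **Retention index** — van den Dool/Kratz-style bracketed linear
  interpolation on the C8–C14 alkylarylketone ladder (anchor index =
  100 × carbon number). Extrapolation is refused: peaks eluting before the
  first or after the last ketone have no index. Window: |ΔRI| ≤ 15, spanning
  the rounding noise observed among printed index values.

A match requires exactly one catalog record to pass every applicable gate;
zero or multiple survivors return no match (ambiguity must not silently
authenticate a sample). When the published candidate indices themselves are
mutually inconsistent with any single linear bracket (rows at 43.0/43.3/43.9
min cannot all round to their printed indices under one line), the stored
printed index is used for gating and the ±15 window absorbs the ~3-unit
discrepancy.

The spectra→substitution-class rules encode the landmark windows (±7 nm)
around the published band positions: coumarin main-band/emission pairs for
7-OR, 7-OR,8-R, 7-OH, 6-OR,7-OH, 6,7-diOR, 5-OR,7-OH and 5,7-diOR
substitution; FC shoulder positions (≈250 nm mono-substituted, ≈270 nm
5,8-disubstituted) with main-peak position separating 5-OR from 8-OR;
quenched emission marking 5-hydroxylation; and MF band-II shoulder counts
separating 4'-OMe from 3',4'-diOMe. Two windows required disambiguation
beyond the narrative: the ~260 nm shoulder separates 5-OR,7-OH coumarins
from plain 7-OH coumarins, and a *double* 245–265 nm shoulder marks
5,7-disubstitution. The rule table reproduces all 13 screened-candidate
classifications, including the uncategorized case.

## Quantitation

Calibration is through-origin least squares (only slopes are
parameterized). Fitting drops the highest level while R² < 0.999 and at
least five levels remain; the retained concentration span defines the
linear range. LOD = 3σ/slope and LOQ = 10σ/slope from the residual noise.
Sample concentrations are area/slope × (nominal/observed psoralen
response), divided by the 9-fold SPE concentration factor (configurable).
Below-LOQ values are retained with a flag; matrix assembly zeroes below-LOD
and not-detected entries only, keeping trace detections informative.
Candidates without calibration are reported as response peak areas — mixed
units are acceptable downstream because autoscaling absorbs per-column
scale.

## Chemometrics

PLS1 is implemented by sequential latent-variable extraction (NIPALS
convention): weight w ∝ Xᵀy, score t = Xw, loadings by least squares on t,
deflation of both X and y (y-deflation is numerically immaterial for PLS1
but fixed for reproducibility). Inputs are autoscaled and y centered
internally, so predictions are invariant under per-column affine transforms
of the raw data. "Full cross-validation" is leave-one-out by default
(segmented mode with a seed is available). The suggested component count is
the RMSECV minimum relaxed by a one-standard-error parsimony rule toward
fewer components.

Martens' uncertainty test uses the jackknife variance
s²_b = Σₘ(bₘ − b)²·(M−1)/M over the M cross-validation submodels
(coefficients compared on the original variable scale, so submodels with
slightly different scaling remain commensurable) and a two-sided t interval
with M−1 degrees of freedom at 95% confidence. Zero-variance coefficients
are significant exactly when nonzero. scikit-learn is used only for its
estimator base classes; the test suite cross-checks PLS and PCA against it
as an independent reference on random matrices.

## Virtual blends and purity models

Blends are exact convex combinations — conservation holds to 1e-12 and is
tested from stored provenance. The orange scenario trains on purities
95/90/80 plus pure orange (100) and pure mandarin (0; the pure-adulterant
level is a flag, default on for orange and off for the grapefruit
scenarios, whose published designs list levels 100/90/80 only). Predicted
purity is unclipped. When the pomelo subgroup is undeclared, both
grapefruit models run and the worst label wins. External validation keeps
training and test cultivars disjoint.

## Synthetic data

Species templates state mean concentrations (mg/L) per compound with totals
inside the species ranges (orange < 5, mandarin 5–10, grapefruit/pomelo
5–100 mg/L) and hot-spot sets reflecting the qualitative species patterns:
sinensetin high in orange with isosinensetin/tangeretin low (and vice versa
in mandarin); grapefruit elevated in heptamethoxyflavone, osthole,
6',7'-epoxybergamottin and bergamottin relative to SG pomelo, which is
instead rich in meranzin (the epoxide stable at its high juice pH); WG
pomelo elevated in the acid-stable bergaptol, isomeranzin and
6',7'-dihydroxybergamottin. Per-compound magnitudes beyond the species
totals are the package's own synthetic choices.

Cultivar profiles are independent lognormal draws per compound with median
at the template mean and sdlog = √ln(1 + cv²), so the empirical CV equals
the configured cv (default 0.25, chosen so that the 90%-purity and
100%-purity prediction clusters separate while the external RMSEP stays in
the low single digits — the qualitative behaviour reported for real data).
Limitations of the generator, and hence of what passing tests demonstrate:
compounds are drawn independently (no covariance structure; a shared
cultivar factor is the only within-cultivar coupling), there are no
co-elution artifacts, no gradient drift beyond a global detector factor,
and no matrix effects. Good synthetic performance therefore shows the
pipeline's correctness and the method's behaviour under the stated noise
model, not field performance on real juices.

The synthetic chromatogram inverts the quantitation model exactly (area =
concentration × 9 × slope, fluorescence heights realizing the catalog
ratio, spectra from the library traces, psoralen peak at nominal × drift,
with the drift factor applied detector-wide so the internal-standard
correction cancels it). With zero noise, the identify→quantify round trip
recovers the generating concentrations to 1e-6 relative and identification
recovers all 52 catalog records uniquely.

## Numerical choices and degenerate inputs

* Conformity is undefined for flat spectra and disjoint supports (errors).
* Fluorescence ratio requires at least two positive channels.
* Retention-index anchors must be strictly increasing; fewer than two
  anchors are rejected.
* Calibration requires ≥ 5 distinct positive levels; all-zero responses are
  a calibration failure.
* Autoscaling drops constant columns (an all-constant matrix is an error);
  PCA reduces its component count at rank deficiency.
* Cross-validation requires every training segment to retain y variance.
* Problem sizes: the packaged study runs 20 training + 10 test cultivars
  per species (1240 training / 320 test blends for the orange scenario) and
  ten seeded repetitions in the acceptance script; these sizes give stable
  medians while keeping a full run in seconds.
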