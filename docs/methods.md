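# Methods notes

This note records the models, numerical conventions, and design choices
behind `toxmetab`, and what the synthetic-data tests do and do not
establish.

## Exact-mass arithmetic

Monoisotopic masses are summed from an embedded constant table
(C 12.0, H 1.00782503207, N 14.0030740048, O 15.9949146196,
S 31.97207100, e⁻ 0.00054858 Da, plus P/Na/K/Cl/F), so results are
bit-stable across environments. Only |z| = 1 ions are supported; that is
the regime of small-molecule electrospray work in the m/z 50–750 window.

**Electron mass.** Whether an ion's m/z subtracts the electron mass is
configurable (`MassConvention`), default on. Published measured values in
this application area mix the two conventions (instrument software
differs); for m/z ≥ 180 they differ by < 3 ppm, inside the 5 ppm matching
tolerance used everywhere, so the choice never changes an annotation.

**Amino-acid condensation adducts.** The amine of a free amino acid
condenses with the cathinone carbonyl, losing water (the classical
Schiff-base/imine product, exposed as `imine_open_chain`). The ion
actually observed in heated-ESI spectra has additionally lost two H₂
(cyclization/aromatization in the source), so `imine_adduct_ion` returns
`[parent + AA − H₂O − 2 H₂ + H]⁺`. This net change is anchored to the
observed ion compositions (C₁₆H₁₉N₂O₂⁺ from C₁₄H₁₉NO + glycine,
C₁₇H₂₁N₂O₂⁺ from C₁₄H₁₉NO + alanine); no mechanism is asserted beyond
the elemental bookkeeping. Subtraction that would drive an element count
negative raises an error, marking a chemically impossible pairing.

**PEG homologs.** The ammoniated polyethylene-glycol series is assembled
as n·C₂H₄O + H₂O + NH₄⁺. Note the NH₄⁺ contribution is +NH₄ minus an
electron, i.e. 18.0338 Da, not the 17.027 Da of neutral NH₃; assembling
by ion formula avoids that classic bookkeeping slip and reproduces the
decamer at m/z 476.3065–476.3071 depending on electron convention.

**Feature names.** `M{round(m/z)}T{round(RT s)}` with half-up rounding on
both components (so 218.1538/222 s → "M218T222", RT 249.4 s → "T249");
Python's banker's rounding is deliberately not used.

## Synthetic dosing experiment

The generator emulates a three-group incubation design: Blank (0 µM),
Low (12.5 µM), High (25 µM), nine wells each, plus a pooled QC. The
injection sequence holds 5 leading QC injections (equilibration), the 27
study samples in seeded random order, and one QC after every 5 study
samples (plus one after a trailing partial block): 38 injections.

Per feature, true levels are built first, then measured values are
`level × (1 + drift_slope·(injection − 1)) × lognormal noise`, with
values below `dropout_lod` recorded as 0:

- 500 background features: dose-independent, baseline 10^N(5, 0.5).
- 20 dose-affected features: multiplicative fold change `effect_size`
  per dose step, direction random per feature. Default effect_size 4.
- 8 drug-derived channels (parent [M+H]⁺, glycine and alanine adduct
  ions, one +O metabolite, and the +1 ¹³C companion of each at a 0.15
  abundance ratio): proportional to dose, hence truly zero in Blank. The
  ¹³C companions sit exactly +1.003355 Da above their parents.
- one internal-standard channel (tryptophan-d₅ analog) at constant level.

The pooled QC's true level is the equal-weight mean of the 27 study
wells, so for dose-proportional features the QC sits exactly at the Low
level — which is why a 4-class classifier confuses QC with Low, and why
the QC class is informative to include in score plots but not separable.

Noise is lognormal (multiplicative, CV-parameterized) — the standard
metabolomics peak-area error model; after log10 transform it is exactly
Gaussian, so the downstream ANOVA operates under its nominal model. The
generator does not emulate retention-time drift, peak-shape artifacts,
co-elution, or multi-batch structure: a green pipeline test establishes
statistical correctness under the stated noise model, not robustness to
those effects.

Defaults (9 wells/group, QC every 5, 5 leading QCs, drift 0.005/inj,
noise CV 0.2, isotopologue ratio 0.15) encode the emulated design; they
are fixed once and not tuned per test.

## Preprocessing

Default order: impute → log10 → drift-correct → IS-normalize, following
the natural processing narrative; the order is configurable (in
particular IS normalization on the raw scale before the log) and the
applied order is recorded in the report, since the original processing
scripts for such studies rarely document it.

- **Surrogate LOD** is the global matrix minimum nonzero abundance (one
  value for the whole matrix, not per feature).
- **Drift model**: piecewise-linear interpolation of each feature's QC
  abundances versus injection index, flat extrapolation beyond the first
  and last anchor. Only features detected in *every* QC injection are
  corrected. Correction subtracts the curve (log scale) and re-anchors at
  the mean QC level, so it is idempotent and pins every anchor QC of a
  corrected feature exactly to that mean: anchor-QC spread is zero after
  correction by construction. The 5 leading QCs are treated as column
  conditioning and excluded from the anchors by default; because they are
  corrected by flat extrapolation they retain their own noise, so over
  *all* QC injections the dispersion guarantee is a median improvement,
  not a per-feature one. A caveat worth knowing: when QC-to-QC noise is
  comparable to the drift amplitude, interpolation chases anchor noise
  and can add variance to individual study samples; the correction's
  guarantee is about the QC trajectory, and the synthetic-data tests
  state it that way.

## Screening

Classical (equal-variance) one-way ANOVA per feature over Blank/Low/High,
strict cut p < α (default 0.001), no multiplicity correction — the screen
is deliberate triage, and with ~500 features α = 0.001 yields ≈ 0.5
expected false positives. Benjamini–Hochberg adjustment is available but
not default. QC samples are excluded by default (they are pooled
mixtures, not an incubation condition) and can be included as a fourth
level. Degenerate features (zero between- and within-group variance) get
F = 0, p = 1 by convention; with the strict inequality they never pass,
even at α = 1.

## PC-DFA and validation

PCA is on the centered, unscaled matrix (peak areas on a log scale share
units; standardizing would up-weight noise features). Kaiser's criterion
is meaningless in its eigenvalue > 1 form for a covariance PCA, so the
Kaiser–Guttman generalization is used: retain components with eigenvalue
above the mean eigenvalue (mean over all feature dimensions, rank-zero
eigenvalues included), floored at two components and capped at the matrix
rank. Fisher LDA on the retained scores solves the generalized
eigenproblem S_b v = λ S_w v with a ridge term 1e-6·trace(S_w)/dim added
to S_w (retained components can approach the sample count). Prediction is
nearest class centroid in discriminant space — equivalent to the LDA
posterior rule under equal covariances and priors — with ties broken to
the lexicographically first label.

Monte-Carlo CV uses stratified random splits (default 1/3 test, 200–1000
iterations, seeded) and refits the *entire* model — centering, PCA,
retention, LDA — on each training portion; nothing is estimated from
held-out samples. Accuracy and κ are averaged over iterations; a pooled
confusion matrix is also kept. κ on a degenerate single-cell confusion
matrix is defined as 0 with a warning.

Two calibration facts the test suite leans on, established on synthetic
data: (i) with the default planted effects and QC excluded, CV κ
saturates at 1; with QC included it settles near 0.86 because QC and Low
genuinely overlap; (ii) on a null experiment (effect size 1, no
drug-derived channels) the *expected* κ is 0 but the per-dataset value
fluctuates with spread ≈ 0.12 (27 samples against ~500 features leave
room for chance separation that a refit classifier finds consistently),
so a |κ| < 0.15 check on one dataset is a seed-level property, not a
distributional guarantee.

## Clustering

Features are z-scored per row (sample sd, n−1), then features and samples
are clustered agglomeratively on Euclidean distances. Linkage is
configurable {complete, average, ward}, default complete; complete and
average linkage are verified against an exhaustive nearest-pair
agglomeration oracle at small n. Constant rows are an error (they carry
no pattern and break scaling); scipy's lowest-index tie-breaking makes
results deterministic. Dendrograms export to Newick for external viewers.

## Annotation

Hypothesis matching only: each significant feature's m/z is tested
against every theoretical ion within `tolerance_ppm` (default 5, the
conventional Orbitrap accuracy bound); all matches are reported with
signed ppm error, unmatched features are labelled "unknown". No
identification level is claimed — confirming a hypothesis requires MS²
or reference standards, both outside this package's scope. Optional
biotransformation mass shifts (+O, +O−H₂, +H₂) are off by default;
hypotheses below m/z 50 are flagged as outside the instrument range.

## Known limitations

- Single batch, single polarity per run; no cross-run merging.
- No raw-data (mzXML/mzML) ingestion; the pipeline starts at the aligned
  feature table.
- Only +1 ions and single-¹³C isotopologue spacing; no isotope-pattern
  simulation or MS² handling.
- The Monte-Carlo CV iterations resample one dataset; uncertainty across
  experiments is larger than the per-iteration spread suggests (see the
  null-κ note above).
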