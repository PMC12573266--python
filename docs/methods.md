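# Methods

## Endpoint carbon budget

The budget treats one dark incubation as a two-point observation: initial
and final cell concentrations of the protozoan, a mean equivalent
spherical diameter (ESD), the incubation time and the initial DOC of the
medium. All internal concentrations are µg C ml⁻¹ (1 mg l⁻¹ ≡ 1 µg ml⁻¹),
time is in days (72 h is represented as t = 3.0 throughout), lengths in µm.

Assumptions and conventions:

- **Biovolume and carbon.** Cells are treated as spheres of the measured
  ESD; per-cell carbon is 0.123 pg C µm⁻³ of biovolume. The per-treatment
  ESD is used when the endpoint table provides one; otherwise the control
  ESD applies.
- **Mean biomass.** C_mean is the *arithmetic* mean of initial and final
  biomass, and the Eq.-5 cell average C_avg the arithmetic mean of the two
  cell concentrations. The time-averaged exponential mean
  B₀(e^{gt}−1)/(gt) is the natural alternative for exponential growth,
  but it yields an assimilation of ≈ 0.755 rather than ≈ 0.713 for the
  0.4 d⁻¹ / 72 h case and does not reproduce the published endpoint
  values; the arithmetic convention does, and is adopted everywhere.
- **Respiration.** R = 0.355 d⁻¹ is taken as already valid at the 20 °C
  incubation temperature (it was assembled from literature rates with a
  Q10 of 2); no further temperature adjustment is applied to it.
- **Bacterivory ceiling.** The satiating ingestion rate
  (71.3 bacteria cell⁻¹ h⁻¹) is referenced to 25 °C by default
  (`BudgetConstants.imax_ref_temp`); the source assay temperature is not
  documented, so the reference is a configurable constant and the Q10
  correction (factor 2^((T−25)/10), i.e. ×0.707 at 20 °C) is applied at
  budget time. With a fixed ESD the ratio C_avg/C_mean collapses to
  1/per-cell-carbon, so I_max is identical across dilutions of one
  experiment.
- **Scaling laws.** C_assimilation is invariant to per-cell carbon (ESD
  and the C:vol factor multiply every biomass term and cancel), whereas
  I_max scales as the *inverse* of per-cell carbon: a fixed per-cell
  ingestion ceiling is a smaller carbon-specific flux for a bigger cell.
  The osmotrophy fraction therefore depends on cell size by construction.
- **Declining populations.** Negative C_growth is allowed; assimilation is
  reported unclamped (it falls below R, and below 0 when respiration
  cannot offset the loss). Only the osmotrophy fraction is clamped to
  [0, 1], and it is NaN when assimilation is non-positive. Bacterial
  carbon use floors net bacterial growth at zero — a decline reports 0 %
  of the DOC used, not a negative percentage.
- **Bacterial carbon use** converts net bacterial growth to carbon at
  20 fg C cell⁻¹ and expresses it as a percentage of the initial DOC (the
  same form as the protozoan PCU). This is the only dimensionally coherent
  reading of the procedure; a respiration-style form has no DOC
  denominator to yield a percentage.

## Treatment statistics

Groups are dilution levels; dilution 0 is the control. The branch
decision is: per-group Shapiro–Wilk (every group must pass at α, default
0.05) → Levene (normal) or Fligner–Killeen (non-normal) for
homoscedasticity → classic ANOVA + Dunnett, Welch ANOVA +
Tamhane–Dunnett-type comparisons, or Kruskal–Wallis + Dunn. Post hoc
comparisons are many-to-one against the control only.

Choices where practice varies:

- Normality is assessed **per group** rather than on pooled residuals:
  with triplicates, residual pooling assumes the very variance
  homogeneity the tree is about to test.
- Dunnett uses `scipy.stats.dunnett` with a fixed internal RNG — its p
  values involve Monte Carlo multivariate-t integration and must be
  reproducible run to run.
- Welch's F is computed directly (inverse-variance weights,
  Welch–Satterthwaite denominator df); it is cross-checked against
  `pingouin.welch_anova` in the test suite.
- The Tamhane–Dunnett comparisons are per-pair Welch t tests against the
  control with single-step Šidák family adjustment — the standard
  approximation when the multivariate-t step is unavailable.
- Dunn's z statistics are tie-corrected joint-rank comparisons with Holm
  adjustment (the adjustment method is a free choice; Holm is uniformly
  more powerful than Bonferroni at the same family-wise error).
- **Small-sample levels.** The ANOVA branch is exact under its
  assumptions at any n. Kruskal–Wallis with the χ² approximation is
  conservative at the triplicate design (true level ≈ 0.02 at nominal
  0.05 with 5 groups of 3 — a distribution-free fact asserted in the test
  suite), and Welch's F is anticonservative at n = 3 under strong
  heteroscedasticity. Calibration checks therefore exercise each test in
  its validity regime: ANOVA and Welch at the triplicate design (Welch
  under an identical-distribution null), Kruskal–Wallis at n = 10 per
  group. Inference from the non-parametric branch on triplicates errs on
  the safe side.

## Dose–response (LL.2)

f(x) = 1/(1 + exp(b·(ln x − ln e))) with asymptotes fixed at 0 and 1.
Because growth-rate responses are unbounded, the response is min–max
normalized to [0, 1] before fitting (the normalization constants are kept
in the fit record and predictions are mapped back). The control (dose 0)
cannot enter the log-dose likelihood (ln 0); it is represented by the
model's asymptotic limit and participates in the lack-of-fit test.
Fitting is multi-start Levenberg–Marquardt least squares: e over the
quartiles of the positive doses, b over {±0.5, ±2}; best residual SS
wins, ties broken by smallest |b|; optimizer failure is reported as
`converged=False`, never raised. The lack-of-fit F compares the model
residual SS against the pure-error SS of the saturated group-means model
with (k−2, N−k) degrees of freedom.

## Synthetic bioassay generator

The generator emulates the study conditions: two designs (400 cells ml⁻¹
with dilutions 0/6.25/12.5/25/50/100 %, and the default 2000 cells ml⁻¹
with 0/3.3/10/33/100 %), triplicates, 72 h dark incubation at 20 °C, ESD
13.8 ± 0.06 µm, bacterial inoculum 4.75×10⁵ cells ml⁻¹, control DOC
1 µg ml⁻¹ enriched 5-fold (BCP) or 34-fold (BioP) at full strength, and
growth plateaus of 0.3 (BCP) and 0.4 (BioP) d⁻¹.

- **Growth dose–response.** The latent growth rate follows the LL.2 shape
  (midpoint 30 %, slope −1.5 — free choices placing significance at the
  top dilutions only) *rescaled so the 100 % dilution reaches the plateau
  exactly*: the plateau is the anchored observable, while the raw LL.2
  form would top out at 86 % of it. A consequence is that LL.2 fits to
  generated assays recover the latent midpoint with a structural bias of
  ≈ 20 % (median error stays inside 25 %), since the rescaled curve is no
  longer exactly log-logistic.
- **Noise.** Counts are positive, so measurement noise is multiplicative
  lognormal (unit median): CV 5 % on protozoan counts with two technical
  measures averaged (as with Coulter duplicates), CV 3 % on DOC, CV 20 %
  on bacterial counts (matching the large reported control SE,
  2.61×10⁶ on 1.29×10⁷). ESD gets a per-bottle treatment shift drawn in
  [−2 %, +5 %].
- **Bacteria.** Net growth from the inoculum towards the control carrying
  capacity (1.29×10⁷ cells ml⁻¹), multiplied by a grazing factor
  (1 + P₀/h)/(1 + P/h) with half-saturation h = 10⁴ cells ml⁻¹, so dense
  protozoan populations suppress the bloom towards the inoculum floor and
  bacterial abundance anticorrelates with protozoan abundance.
- **What it does not emulate:** time-resolved dynamics (endpoints only),
  DOC consumption during the incubation, community composition shifts,
  toxicity at high doses, or any coupling between DOC noise and growth
  noise. Tests passing on synthetic data certify the pipeline's
  arithmetic and statistical behaviour under the stated noise model, not
  the biology of any particular leachate.

Determinism contract: a design's seed fully determines the table
(bit-for-bit); latent truths are stored alongside for recovery tests.

## EEM processing

Inner-filter correction multiplies each cell by 10^((A(ex)+A(em))/2) from
the 1-cm absorbance spectrum. Raman normalization divides by the
trapezoid-integrated Raman band area — emission 371–428 nm at 350 nm
excitation, the community-standard integration limits. Rayleigh scatter
handling is limited to masking ±10 nm around em = ex and em = 2·ex with
NaN propagation; peak picking (protein-like: Ex 275–300/Em 320–360,
bracketing the leachate maximum at 290/340; humic-like: Ex 320–365/
Em 420–460, bracketing 350/440) ignores masked cells and breaks ties
toward the lowest excitation, then emission. No PARAFAC decomposition and
no instrument-standard blocks are implemented.

## Pipeline

All derived quantities are computed per replicate and only then
summarized as mean ± SE (n−1 variance) — never from pooled counts, which
would introduce Jensen bias through the log in the growth rate. Reports
are deterministic JSON (sorted keys, non-finite values serialized as
null, no timestamps); every branch decision and convergence failure is
logged. Statistical degeneracies (e.g. zero within-group variance in a
noise-free run) are recorded as structured error entries in the report
rather than aborting the run, so budget outputs survive degenerate
designs. Problem sizes in the test suite — 1000-replicate null
calibrations, 200–500-simulation recovery and power checks — keep the
whole suite under a minute on one CPU while leaving the binomial
confidence bands narrow enough to be informative.

## Known limitations

- The budget is endpoint-based: no Michaelis–Menten osmotrophy kinetics,
  no intra-incubation DOC drawdown, no mortality term.
- The osmotrophy fraction is an upper-bound argument (assimilation minus
  a bacterivory ceiling), not a tracer measurement.
- The Tamhane–Dunnett adjustment is the Šidák approximation, slightly
  conservative relative to the multivariate-t version.
- Non-parametric inference on triplicates is conservative (see above).
- EEM processing is deliberately lite; quantitative FDOM work beyond net
  peaks should use a full standardization toolchain.
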