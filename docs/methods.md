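# Methods

## The question the package answers

Recirculating aquaculture systems (RAS) rely on a nitrifying biofilter to
strip the ammonia excreted by the fish. In the commercial-scale fluidized
sand biofilter this package models (the UWM system: a ~2.74 m × 1.83 m
column fed at up to 757 L/min), the ammonia-oxidizing consortium is not
the textbook *Nitrosomonas* population: qPCR shows ammonia-oxidizing
archaea (AOA) and comammox *Nitrospira* outnumber *Nitrosomonas* by
roughly three orders of magnitude. The quantitative core is an energy
balance: **can the ammonia actually removed across the filter support the
standing stock of ammonia oxidizers measured by qPCR?** Around that sit
the statistics used to characterise the system: permutation correlations
between marker-gene time series, Kruskal–Wallis tests of depth
stratification, and the Bray–Curtis / PCoA / envfit / PERMANOVA toolkit
for whole-community composition.

## Steady-state biomass model

At steady state the ammonia-oxidizer biomass concentration is

    X_AO = (θ_x / θ) · [ Y_AO / (1 + b_AO·θ_x) ] · ΔS_NH3

| symbol | meaning | default | units |
|---|---|---|---|
| θ | hydraulic retention time | 0.0066 | d |
| θ_x | mean cell residence time (swept 1–30) | — | d |
| Y_AO | growth yield | 0.34 | kg VSS / kg NH₄⁺-N |
| b_AO | endogenous respiration constant | 0.15 | 1/d |
| ΔS_NH3 | ammonia-N removed across the filter | 0.0726 | mg/L |

θ comes from the reactor geometry: cylinder volume ÷ max flow = 9.52 min.
The full column height (2.74 m) reproduces the reported retention time;
using the water level (2.64 m) instead gives 9.17 min and both options
are exposed. ΔS_NH3 converts the influent−effluent difference in μM
total ammonia (9.02 − 3.84 μM at the long-term means) to mg N/L via
14.007 g/mol. A negative difference is clamped to zero with a warning —
the steady-state model has no interpretation for net ammonia production.

The model is **monotone increasing and concave in θ_x**, linear in
ΔS_NH3, and saturates at X_AO(∞) = Y_AO·ΔS/(b_AO·θ) = 24.9 mg/L. With
b_AO = 0.15/d the 20-day MCRT point sits at exactly
b·θ_x/(1+b·θ_x) = 3/4 of the limit, which is why the curve is "near
maximum" by 20 days. Because the true MCRT of a fluidized sand bed is
unknown, the curve is reported over a 1–30 day grid with an envelope
re-evaluated at the minimum and maximum observed removal rates.

### Converting biomass to cell counts

mg VSS/L → cells/L → cells/g sand via:

1. a spherical biovolume from the 0.96 μm mean cell diameter of
   *Ca.* Nitrosocosmicus franklandus (0.463 μm³);
2. a cellular carbon density of 310 fg C/μm³;
3. the sand loading (grams of wet sand per litre of biofilter water).

Two of these are deliberately exposed as assumptions:

* **`vss_to_carbon`** (default 1.0). The carbon density is applied
  directly to the VSS-based biomass, i.e. VSS is treated as carbon. A
  literature VSS→C fraction of ≈0.53 can be substituted; it scales all
  cell counts proportionally.
* **`sand_loading`** (default 40.4 g/L). No measured value is available.
  The default is a *calibration*: it is back-solved so that the mean
  model curve at θ_x = 20 d sits ~6.2× above the depth-averaged qPCR
  AOM total (5.20×10⁸ CN/g). The headline model-vs-observed ratio is
  therefore a consistency replay of the published comparison, not an
  independent measurement; every other model quantity (X_AO in mg/L,
  the saturation fraction, the retention time) is loading-independent.

The observed AOM standing stock sums the four amoA assays (total AOA,
two *Nitrosomonas* genotypes, comammox *Nitrospira*) per sample and
averages over samples; copy numbers divide by `amoA_copies_per_cell`
(default 1 — amoA is single-copy in the relevant genomes) to become
cells.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log₁₀(copies per
reaction), requiring ≥3 distinct levels over the assay's dynamic range
(the study assays spanned 15–1.5×10⁶ copies/reaction). Efficiency uses
the amplification-factor convention E = 10^(−1/slope) − 1; a
non-negative slope marks the curve invalid rather than raising, so batch
fits can flag bad assays. Unknown Cq values invert through the curve;
results outside the calibration range are flagged `in_range=False`, never
censored, because no censoring rule is defensible without the raw data.
Copies per reaction scale to CN per gram wet sand by
elution/template volume ratio over extracted mass (default 100 μL, 1 μL,
1 g — the kit-scale workflow; all overridable). Triplicates are
summarised as mean ± sample SD (n−1).

## Marker-gene statistics

* **CV** — sample SD over mean, on per-date means of triplicates.
* **Pearson correlations** — on raw copy numbers by default (matching
  how the study's series were compared), with a log₁₀ option.
* **Pseudo-p** — a permutation p-value: one series is shuffled, the
  two-sided count of |r_perm| ≥ |r_obs| enters (b+1)/(n_perm+1). The
  default 4999 permutations makes the attainable floor 1/5000 = 0.0002,
  the smallest value the study reports. No multiple-testing correction
  is applied across the correlation matrix (none was used upstream).
* **Kruskal–Wallis** — tie-corrected H with the χ² (df = k−1)
  approximation (the scale the study reports); the fully-tied degenerate
  case returns H = 0, p = 1 instead of erroring. Depth summaries report
  mean ± SD per assay × depth (surface/middle/bottom); single-sample
  cells report SD = 0 with a degeneracy flag so the summary table always
  has the full shape.
* **Dominance ratios** — per-sample sum(numerator assays) /
  sum(denominator assays) with zero-denominator samples excluded and the
  min–max range reported.

## Community statistics

All computed from their definitions on dense arrays (fixtures are tens
of samples); scipy/scikit-bio serve as independent cross-checks in the
test suite, not as the implementation.

* **Bray–Curtis** Σ|x−y|/Σ(x+y), on row-normalised relative abundances
  by default (raw-count mode available). A pair of all-zero samples gets
  distance 0 with a warning.
* **Complete linkage** — naive O(n³) agglomeration; ties broken by the
  smallest (row, column) cluster-index pair, so dendrograms are
  deterministic; exported as Newick with heights-as-branch-lengths.
* **PCoA** — Gower double-centering of −D²/2, eigendecomposition, axes
  ordered by eigenvalue. Negative eigenvalues (non-Euclidean input) are
  dropped from coordinates and from the percent-variance denominator; no
  Cailliez/Lingoes correction.
* **envfit** — each environmental variable is regressed on the first two
  axis scores only (the two-axis table layout the study reports);
  direction cosines are the normalised coefficients, R² the squared
  multiple correlation, significance by permuting the variable
  (default 999 permutations). Constant variables return a flagged zero
  vector with R² = 0, p = 1.
* **PERMANOVA** — one factor, pseudo-F from SS_total = Σ_{i<j}d²/n
  partitioned into within/between components, free label permutation
  (no strata; default 999 permutations, making 0.001 the attainable
  floor). R² = SS_between/SS_total.
* **Minimum-substantive-abundance rule** — floor(total reads / 50,000),
  minimum 1; the direction of rounding is a documented choice.

## Synthetic data

The generators define the default study conditions rather than arbitrary
test noise:

* **Chemistry** — truncated normals (at 0) around the published
  means/SDs (influent/effluent ammonia 9.02±4.76 / 3.84±7.32 μM,
  nitrites 1.69±1.46 / 0.73±0.49 μM, pH 7.01±0.09, ORP 540±50 mV,
  T 21.7±0.9 °C; feed and conductivity settings are plausible defaults
  since only their existence, not their moments, is documented). A
  deterministic exponential-survival fish count rounds out the
  operational covariates. Truncation shifts the realised mean of
  variables with large SD/mean (effluent ammonia most of all); the
  clamped per-date removals therefore average below the printed-mean
  difference, which is the intended behaviour of a nonnegative
  concentration model.
* **Markers** — log-normal marginals (abundances span 10³–10⁸ CN/g;
  additive noise would go negative) parameterised from mean and CV via
  σ² = ln(1+CV²), μ = ln(mean) − σ²/2; cross-genotype correlation
  planted on the log scale through a Gaussian copula, so the planted
  matrix *is* the log-scale correlation and recovery tests compare on
  that scale. Defaults: the six study genotypes at their depth-averaged
  abundances, the published CVs (0.38/1.33/1.32/0.55 and ~0.45 for the
  two nitrite-oxidizer genotypes), and a positive-definite correlation
  matrix assembled from the published pairwise values. Depth multipliers
  (strong bottom enrichment for *Nitrosomonas*, near-flat profiles for
  AOA/comammox/nxrB) apply to the depth-profile samples only, so the
  surface time series retains the configured marginal moments. The
  replicate-SD column is 5% of the value — a free choice, as no
  within-assay replicate CV is published.
* **Community** — Dirichlet draws around a baseline composition taken
  from the study's dominant sand families, with additive per-group
  shifts (surface enriched in *Planctomycetes*, depleted in
  *Chitinophagaceae*/*Sphingomonadaceae*) renormalised before sampling.
  Concentration 200 gives within-group Bray–Curtis scatter of the right
  order.

One root seed expands to fixed per-stream child seeds
(`SeedSequence((seed, stream_id))`), so generating one table never
perturbs another and all outputs are bit-reproducible.

**What the generators do not emulate:** sequence-level structure (no
reads), temporal autocorrelation or trends in either chemistry or
markers, compositional count noise (communities are proportions, not
finite-depth counts), and any coupling between chemistry and marker
abundances. Passing recovery tests therefore demonstrate that the
*pipeline* is correct and calibrated under the assumed noise model, not
that real biofilter data satisfy that model.

## Numerical and scale choices

* Permutation loops use a shared generator; p-value comparisons carry a
  1e-12 slack so exact ties count as "as extreme".
* Oracle-equivalence tests run at ≤10 samples; calibration suites use
  100–200 replicates of 199–499 permutations; recovery suites use the
  study's own sizes (15 timepoints; 3–5 samples per depth, averaged over
  20 seeds). The default end-to-end pipeline (15 timepoints, 14
  community samples, 999/4999 permutations) completes in a few seconds
  on one CPU.
* The PERMANOVA floor fixture uses two clusters of 12: attaining
  p = 1/(n_perm+1) requires a label-permutation space far larger than
  n_perm, which 4+4 or 5+5 designs do not provide.

## Known limitations

* The model-vs-observed ratio inherits the calibrated sand loading; it
  validates internal consistency, not the absolute comparison.
* The steady-state model is algebraic: no Monod kinetics, oxygen or
  nitrite terms, no dynamics, and a single cell size across AOA, AOB and
  comammox — all reasons the published comparison itself treats the
  model as an upper bound.
* Standard-curve parameters per assay and extraction volumes are
  configuration, not data; defaults are kit-scale conventions.
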