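# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Staining-intensity profiles and heterogeneity scores

A sample × marker observation is the fraction vector *p* = (p₀, p₁, p₂, p₃)
over the four ordinal staining intensities (0/+/++/+++). Vectors are
validated to length 4, clipped to [0, 1] and renormalized when they miss a
unit sum by more than 10⁻⁹. Two summaries are computed:

* **H-score** `100·(0·p₀ + 1·p₁ + 2·p₂ + 3·p₃)`, range 0–300. It is linear
  in *p*, so the score of a cell-population mixture is the mixture of the
  scores.
* **SDI** `−Σ pᵢ ln pᵢ` with the 0·ln 0 = 0 convention (natural log), range
  0 to ln 4. Zero iff the distribution is concentrated in one bin; ln 4 iff
  uniform. Computed via `scipy.stats.entropy`; the test suite keeps an
  independent term-by-term summation oracle and requires agreement to
  10⁻¹² on random profiles.

**Observer consensus.** Sections are graded by independent observers; no
published reconciliation rule exists, so the consensus is the element-wise
mean of the observers' fraction vectors (renormalized). The mean preserves
H-score linearity and only ever increases support overlap, which slightly
favours calling heterogeneity — symmetric across markers and models, so
comparisons are unaffected.

**Per-sample heterogeneity call.** "Heterogeneous" is not quantified in
routine pathology reads; the package calls a sample heterogeneous when at
least two intensity bins each hold ≥ `min_minor_fraction` of the cells
(default 0.10, valid range (0, 0.5]). The 10% floor makes the call robust
to single stray cells while still catching a genuine second staining
population.

**Cohort-level call.** Per-marker, the per-sample calls are pooled over
subtypes (Σ heterogeneous / Σ evaluated; subtypes with zero evaluable
samples are excluded rather than treated as 0/0), converted to a percentage,
and rounded half away from zero. The marker is flagged heterogeneous when
the pooled percentage strictly exceeds 40. Pooled counts (not the mean of
per-subtype percentages) are used because they reproduce more rows of the
bundled reference table; the audit in `heterogeneity.audit_reference_table`
shows 10 of its 14 printed percentages reproduce exactly, while Rictor,
p-mTOR, FASN and the boundary case p-S6 (32/37 = 86.49% → 86, printed 87)
do not reproduce from their own counts under any of the candidate
aggregation rules and are therefore reported as inconsistent, never forced.

## Drug-response analysis

Raw replicate signals (fluorescence, absorbance, cell counts, endpoint
volumes) are normalized per model × assay to the mean of the untreated
control arm: `v = 100 · mean(treated) / mean(control)`; the SD is that of
the per-replicate percentages. Per-model viabilities are averaged across
assays with equal weights.

**Effect scale.** The combination index needs effects on [0, 1]; the
package uses fractional inhibition `E = 1 − v/100`, clipped to [0, 1]. For
in vivo arms the same definition applies to the endpoint ratio
(1 − treated/control final mean volume; final weight is available as an
alternative basis). Growth stimulation (v > 100) clips to E = 0 rather than
propagating negative effects.

**Combination index.** `CI = (Ea + Eb)/Eab`, undefined (error) when the
combination shows no effect. Exact additivity is a measure-zero event on
noisy data, so an additivity band `|CI − 1| ≤ τ` (default τ = 0.05,
configurable) is called additive; below it synergistic, above it no
additional effect. A delta-method standard error is available
(`estimate_combination_index`) from the per-arm replicate SDs.

**Sensitivity classes.** Average viability maps to four classes with
half-open bands: resistant `v ≥ 90`, minimal sensitivity `80 ≤ v < 90`,
sensitive `60 ≤ v < 80`, highly sensitive `v < 60`. The "≈90%" resistance
boundary is disambiguated as ≥ 90 so the bands partition the axis; the
classification is monotone in viability by construction.

**Cross-model concordance.** Two models' class patterns over a common arm
set are compared arm-by-arm; agreement is the matching fraction. When
ranking candidate in vitro systems against the xenograft reference, ties in
agreement are broken by the mean absolute viability difference (closer
wins), which keeps the ranking stable when an arm sits on a class boundary.

## Xenograft growth

Tumour volume from two perpendicular caliper diameters (mm):
`V = (π/6)·((2·shorter + longer)/3)³` — the cube of the weighted mean
diameter with the shorter axis counted twice, reducing exactly to the
sphere volume for equal diameters. Swapped diameter pairs are corrected on
ingest. Growth summaries are day-aligned per-group means ± SD with animal
counts; missing days are absent, not zero. Endpoint effects default to the
final-day mean volume because volumes exist for every animal and day,
whereas weights exist only at sacrifice.

## Synthetic-data generator

The generator emulates the three study conditions the analysis expects and
provides the ground truth for the recovery tests.

**Cohorts.** For each marker with heterogeneity prevalence θ, each sample
is latently heterogeneous with probability θ. Heterogeneous latent profiles
are symmetric Dirichlet(1) draws conditioned on carrying a second
population (≥2 bins ≥ 0.15); homogeneous ones are dominant-bin Dirichlet
draws (dominant concentration 15, minors 1) conditioned on at most 5%
strays in any minor bin. The 0.15/0.05 guard bands around the 0.10 call
threshold make the latent label effectively recoverable, so pooled
prevalence estimates are binomial by construction. Dirichlet(1) gives
heterogeneous samples a median SDI ≈ 1.1 and homogeneous ones ≈ 0.30,
matching the magnitudes seen in the cross-model staining comparisons
(homogeneous markers near 0.33, heterogeneous markers 0.9–1.28). Two
observers each grade `n_cells = 200` cells by multinomial sampling from the
latent profile. The default panel carries the 14 reference markers at
their pooled empirical prevalences and 10 samples per subtype.

**Plates.** Each (model, arm, assay) cell gets `n = 6` replicates
`signal = scale · v* · (1 + ε)`, ε ~ N(0, CV) truncated at zero, CV
default 0.10 — multiplicative noise being typical plate-reader behaviour.
Combination-arm truth derives from the configured true combination index:
`Eab = (Ea* + Eb*)/ci*`, truncated to [0, 1]. Default true viabilities
encode the qualitative cross-model pattern (monolayers sensitive to all
arms; spheroids sensitive to rapamycin/doxorubicin but not doxycycline;
scaffolds minimally rapamycin-sensitive and otherwise resistant;
xenografts resistant to all monotherapies) with strong combination synergy
(ci* = 0.3–0.4) in the scaffold and xenograft systems, pulling their
combination arms below 60% viability. Per-assay unit scales are arbitrary
so that normalization is genuinely exercised.

**Xenograft studies.** Control tumours grow exponentially (default: from
100 mm³, ×6 over 21 days); a treated group's rate is shifted by
`ln(multiplier)/21` per day so its day-21 endpoint equals the control
endpoint times the configured multiplier exactly. Diameters are
back-computed from the spherical volume and jittered with N(0, 0.3 mm)
noise; measurements are thrice weekly over days 0–21, 8 animals per group,
with terminal weights proportional to volume (1.05 mg/mm³).

What the generator does **not** emulate: spatial structure within sections
(fields of view, core-vs-edge gradients), observer bias (both observers
resample the same latent profile), assay-specific artefacts
(doxorubicin-induced metabolic shifts that separate metabolic from
protein-content assays), inter-animal growth-rate heterogeneity beyond
measurement noise, and dose–response structure (single concentrations
only). Passing recovery tests therefore demonstrates correctness of the
scoring arithmetic under the stated noise model, not robustness to those
real-data effects.

## Statistical annotations

Group comparisons in reports use one-way ANOVA followed by Tukey's HSD
(statsmodels), flagging arms with adjusted p ≤ 0.05 against the control
arm; Tukey adjustment is applied within each model system, with no
cross-model family correction. Degenerate inputs (single replicates, or
zero variance with equal means) are reported as untestable instead of
raising; zero variance with differing means is flagged directly.

## Reproducibility and problem sizes

Every generator draws from a single `numpy` Generator seeded from its
config, so fixed seeds give bit-identical CSVs. Report CSVs begin with a
`# config_hash=` line derived from the analysis parameters (file locations
excluded; input content hashes live in the JSON manifest), so identical
analyses hash identically wherever they run.

The simulation studies use 500 plates per true combination index and 300
cohorts of 37 samples per prevalence level — sizes at which the Monte-Carlo
standard error of the recovered means (≈0.003 on CI, ≈0.4 percentage
points on prevalence) is an order of magnitude below the tolerances being
checked, while the full study suite completes in well under a minute per
block.

## Known limitations

* The per-sample heterogeneity criterion is a package convention; other
  reasonable thresholds (e.g. ≥2 bins at 5%) shift marker-level
  percentages by several points.
* The combination index is the simple effect-ratio form at a single
  concentration; no median-effect (Chou–Talalay) dose–response CI is
  implemented.
* Four reference-table rows are internally inconsistent as printed; the
  package reports the recomputed values alongside the printed ones and
  takes no side beyond flagging.
* SDI comparisons across models assume profiles were scored over comparable
  tissue areas; the package does not model field-of-view averaging.
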